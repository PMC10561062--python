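"""Synthetic multi-tissue cohorts with known endocrine ground truth.

Emulates the structure of a GTEx-like resource at desk scale: many tissues,
sparse per-donor tissue availability, a latent per-individual high/low
estrogen state that shifts an estrogen-responsive signature in every tissue,
and peripheral-tissue category genes (secreted proteins, ligands, peptide
hormones, feeding-behavior genes) whose correlation with hypothalamic target
genes depends on tissue, functional category and estrogen stratum. A
companion generator produces overdispersed neuron RNA-seq count tables for
the counts-above-reference target-gene filter.

Expression values are continuous log-scale units (background mean 0); every
quantity downstream is correlation-based and therefore unit-free. The
stratum-dependent correlation is built by giving each (peripheral gene,
target gene) pair a shared standard-normal latent and mixing it into the
peripheral gene with a per-individual coefficient chosen by that
individual's latent stratum — one cohort file per tissue, as in GTEx,
rather than pre-split cohorts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .resources import (
    FLOAT_FORMAT,
    GeneSet,
    NeuronCountTable,
    OrthologMap,
    TissueExpression,
    write_expression,
    write_gmt,
    write_neuron_counts,
    write_ortholog_map,
)

logger = logging.getLogger(__name__)

HYPOTHALAMUS = "hypothalamus"

DEFAULT_TISSUES = (
    HYPOTHALAMUS,
    "adipose_subcutaneous",
    "adipose_visceral",
    "skeletal_muscle",
    "stomach",
    "small_intestine",
)

#: Peripheral functional categories (gene-name prefix per category).
CATEGORIES = ("secreted", "ligand", "peptide_hormone", "feeding")
_CATEGORY_PREFIX = {
    "secreted": "SEC",
    "ligand": "LIG",
    "peptide_hormone": "PEP",
    "feeding": "FED",
}

STRATA = ("high", "low")


def default_availability() -> dict[str, float]:
    """Per-tissue donor sampling probabilities.

    Hypothalamus is always collected (targets live there); small intestine is
    deliberately sparse so the downstream tissue screen has something to drop,
    mirroring the rarity of matched small-intestine donors in multi-tissue
    cohorts.
    """
    return {
        HYPOTHALAMUS: 1.0,
        "adipose_subcutaneous": 0.7,
        "adipose_visceral": 0.6,
        "skeletal_muscle": 0.7,
        "stomach": 0.5,
        "small_intestine": 0.15,
    }


def default_rho() -> dict[tuple[str, str, str], float]:
    """Default cross-tissue correlation targets per (tissue, stratum, category).

    The qualitative pattern: adipose communication is stronger in the high
    estrogen stratum; skeletal muscle and stomach are stronger in the low
    stratum; small intestine carries no signal.
    """
    rho: dict[tuple[str, str, str], float] = {}
    for category in CATEGORIES:
        for tissue in ("adipose_subcutaneous", "adipose_visceral"):
            rho[(tissue, "high", category)] = 0.4
            rho[(tissue, "low", category)] = 0.1
        for tissue in ("skeletal_muscle", "stomach"):
            rho[(tissue, "high", category)] = 0.1
            rho[(tissue, "low", category)] = 0.4
        rho[("small_intestine", "high", category)] = 0.0
        rho[("small_intestine", "low", category)] = 0.0
    return rho


def default_n_genes() -> dict[str, int]:
    return {"signature": 20, "category": 10, "target": 15, "background": 40}


@dataclass(frozen=True)
class SimulationConfig:
    """Everything that determines one synthetic cohort.

    ``estrogen_effect`` is the mean shift of signature genes in high-state
    individuals, in units of the gene's own SD (``noise_sd``). ``rho`` maps
    (tissue, stratum, category) to the population correlation between a
    category gene in that tissue and its paired hypothalamic target for
    individuals of that stratum; missing keys mean 0. ``n_genes`` gives the
    count per role; the ``category`` count is per functional category.
    """

    n_individuals: int = 400
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    availability: Mapping[str, float] | None = None
    estrogen_effect: float = 1.0
    high_fraction: float = 0.5
    rho: Mapping[tuple[str, str, str], float] | None = None
    n_genes: Mapping[str, int] = field(default_factory=default_n_genes)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.availability is None:
            defaults = default_availability()
            object.__setattr__(
                self, "availability",
                {t: defaults.get(t, 1.0) for t in self.tissues},
            )
        if self.rho is None:
            object.__setattr__(
                self, "rho",
                {k: v for k, v in default_rho().items() if k[0] in self.tissues},
            )
        if self.n_individuals < 2:
            raise ValueError("n_individuals: must be >= 2")
        if HYPOTHALAMUS not in self.tissues:
            raise ValueError("tissues: must contain 'hypothalamus'")
        if len(set(self.tissues)) != len(self.tissues):
            raise ValueError("tissues: duplicate tissue names")
        for tissue in self.tissues:
            p = self.availability.get(tissue)
            if p is None:
                raise ValueError(f"availability: missing probability for {tissue!r}")
            if not 0.0 < p <= 1.0:
                raise ValueError(
                    f"availability: probability for {tissue!r} must be in (0,1], got {p}"
                )
        if not 0.0 < self.high_fraction < 1.0:
            raise ValueError("high_fraction: must be in (0,1)")
        for key, value in self.rho.items():
            tissue, stratum, category = key
            if tissue not in self.tissues or tissue == HYPOTHALAMUS:
                raise ValueError(f"rho: unknown peripheral tissue in key {key!r}")
            if stratum not in STRATA:
                raise ValueError(f"rho: stratum must be high/low in key {key!r}")
            if category not in CATEGORIES:
                raise ValueError(f"rho: unknown category in key {key!r}")
            if not -1.0 < value < 1.0:
                raise ValueError(f"rho: value for {key!r} must be in (-1,1), got {value}")
        for role in ("signature", "category", "target", "background"):
            count = self.n_genes.get(role)
            if count is None or count < 1:
                raise ValueError(f"n_genes: count for role {role!r} must be positive")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd: must be positive")
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ValueError("seed: must be a non-negative integer")

    @property
    def peripheral_tissues(self) -> tuple[str, ...]:
        return tuple(t for t in self.tissues if t != HYPOTHALAMUS)


@dataclass(frozen=True)
class SimulatedTruth:
    """Ground truth emitted alongside a cohort.

    ``estrogen_state`` maps individual -> latent label; ``pairing`` has one
    row per (peripheral_gene, target_gene, tissue, category) generated pair
    with its high/low generating correlations; ``availability`` is the
    individual x tissue boolean sampling mask.
    """

    estrogen_state: Mapping[str, str]
    pairing: pd.DataFrame
    availability: pd.DataFrame


# ---------------------------------------------------------------------------
# Gene naming (shared between the cohort and its annotations)
# ---------------------------------------------------------------------------

def signature_genes(config: SimulationConfig) -> list[str]:
    return [f"SIG{i:03d}" for i in range(config.n_genes["signature"])]


def target_genes(config: SimulationConfig) -> list[str]:
    return [f"HTG{i:03d}" for i in range(config.n_genes["target"])]


def category_genes(config: SimulationConfig, category: str) -> list[str]:
    prefix = _CATEGORY_PREFIX[category]
    return [f"{prefix}{i:03d}" for i in range(config.n_genes["category"])]


def background_genes(config: SimulationConfig) -> list[str]:
    return [f"BKG{i:03d}" for i in range(config.n_genes["background"])]


def mouse_symbol(human: str) -> str:
    """Human->mouse symbol styling (SST -> Sst)."""
    return human[:1].upper() + human[1:].lower()


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(
    config: SimulationConfig,
) -> tuple[dict[str, TissueExpression], SimulatedTruth]:
    """Draw one cohort: per-tissue expression matrices plus ground truth.

    Per individual: a latent high/low estrogen state (fraction
    ``high_fraction`` high) and a Bernoulli tissue-availability mask
    (hypothalamus forced). Per tissue matrix rows: signature genes shifted by
    ``estrogen_effect`` SD in high individuals; category genes (peripheral
    tissues) mixing their pair's shared latent with stratum-specific rho;
    target genes (hypothalamus) equal to the shared latents; independent
    background noise. Identical config (including seed) reproduces the
    output exactly.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    individuals = [f"IND{i:04d}" for i in range(n)]

    n_high = int(round(config.high_fraction * n))
    n_high = min(max(n_high, 1), n - 1)
    high_idx = rng.choice(n, size=n_high, replace=False)
    is_high = np.zeros(n, dtype=bool)
    is_high[high_idx] = True
    labels = np.where(is_high, "high", "low")

    availability = pd.DataFrame(False, index=individuals, columns=list(config.tissues))
    for tissue in config.tissues:
        if tissue == HYPOTHALAMUS:
            availability[tissue] = True
        else:
            availability[tissue] = rng.random(n) < config.availability[tissue]

    sig = signature_genes(config)
    targets = target_genes(config)
    background = background_genes(config)

    # shared pair latents: one per target gene, reused by every category gene
    # paired to it (round-robin assignment across all categories)
    latents = rng.standard_normal((len(targets), n))

    pair_target: dict[tuple[str, str], str] = {}
    counter = 0
    for category in CATEGORIES:
        for gene in category_genes(config, category):
            pair_target[(category, gene)] = targets[counter % len(targets)]
            counter += 1

    def signature_block() -> np.ndarray:
        shift = config.estrogen_effect * config.noise_sd * is_high[None, :]
        return shift + rng.normal(0.0, config.noise_sd, size=(len(sig), n))

    tissues: dict[str, TissueExpression] = {}
    pairing_rows: list[tuple] = []

    for tissue in config.tissues:
        blocks: list[np.ndarray] = []
        genes: list[str] = []
        if tissue == HYPOTHALAMUS:
            blocks.append(latents)
            genes.extend(targets)
        else:
            for category in CATEGORIES:
                rho_high = config.rho.get((tissue, "high", category), 0.0)
                rho_low = config.rho.get((tissue, "low", category), 0.0)
                rho_i = np.where(is_high, rho_high, rho_low)
                for gene in category_genes(config, category):
                    target = pair_target[(category, gene)]
                    z = latents[targets.index(target)]
                    eps = rng.standard_normal(n)
                    blocks.append((rho_i * z + np.sqrt(1.0 - rho_i**2) * eps)[None, :])
                    genes.append(gene)
                    pairing_rows.append(
                        (gene, target, tissue, category, rho_high, rho_low)
                    )
        blocks.append(signature_block())
        genes.extend(sig)
        blocks.append(rng.normal(0.0, config.noise_sd, size=(len(background), n)))
        genes.extend(background)

        matrix = pd.DataFrame(np.vstack(blocks), index=genes, columns=individuals)
        available = availability[tissue].to_numpy()
        tissues[tissue] = TissueExpression(
            tissue=tissue, data=matrix.loc[:, available]
        )

    pairing = pd.DataFrame(
        pairing_rows,
        columns=["peripheral_gene", "target_gene", "tissue", "category",
                 "rho_high", "rho_low"],
    )
    truth = SimulatedTruth(
        estrogen_state=dict(zip(individuals, labels)),
        pairing=pairing,
        availability=availability,
    )
    return tissues, truth


# ---------------------------------------------------------------------------
# Annotations: gene sets and ortholog map
# ---------------------------------------------------------------------------

def make_annotations(
    config: SimulationConfig,
    unmapped_fraction: float = 0.0,
    multi_fraction: float = 0.0,
) -> tuple[list[GeneSet], OrthologMap]:
    """Gene sets and the mouse->human ortholog map matching a cohort.

    Emits the estrogen signature set plus one pairwise-disjoint set per
    functional category, in the cohort's gene namespace. The ortholog map
    sends mouse-styled target symbols to the human symbols used in the
    cohort; ``unmapped_fraction`` of targets are left out of the map and
    ``multi_fraction`` of the mapped ones get a second (spurious) human
    target, for exercising the mapping policies.
    """
    if not 0.0 <= unmapped_fraction < 1.0:
        raise ValueError("unmapped_fraction: must be in [0,1)")
    if not 0.0 <= multi_fraction <= 1.0:
        raise ValueError("multi_fraction: must be in [0,1]")

    sets = [GeneSet("ESTROGEN_SIGNATURE", frozenset(signature_genes(config)), "signature")]
    for category in CATEGORIES:
        sets.append(
            GeneSet(category.upper(), frozenset(category_genes(config, category)), category)
        )

    targets = target_genes(config)
    rng = np.random.default_rng([config.seed, 97])
    n_unmapped = int(round(unmapped_fraction * len(targets)))
    unmapped = set(rng.choice(len(targets), size=n_unmapped, replace=False))
    entries: dict[str, frozenset[str]] = {}
    mapped_indices = [i for i in range(len(targets)) if i not in unmapped]
    n_multi = int(round(multi_fraction * len(mapped_indices)))
    multi = set(
        rng.choice(mapped_indices, size=n_multi, replace=False)
    ) if n_multi else set()
    for i in mapped_indices:
        human = targets[i]
        humans = {human, human + "B"} if i in multi else {human}
        entries[mouse_symbol(human)] = frozenset(humans)
    return sets, OrthologMap(entries=entries)


# ---------------------------------------------------------------------------
# Neuron counts
# ---------------------------------------------------------------------------

def simulate_neuron_counts(
    n_genes: int,
    n_samples: int = 6,
    reference_quantile: float = 0.5,
    seed: int = 0,
    include_genes: Sequence[str] = (),
    reference_gene: str = "Gfap",
) -> NeuronCountTable:
    """Overdispersed (negative-binomial) neuron RNA-seq counts.

    Gene means are log-normal; the reference gene's mean is pinned at
    ``reference_quantile`` of the gene-mean distribution so the downstream
    counts-above-reference filter retains roughly ``1 - reference_quantile``
    of the generic genes. ``include_genes`` are appended with means well
    above the reference, guaranteeing they pass the filter (used to embed
    known target genes).
    """
    if n_genes < 2:
        raise ValueError(f"n_genes must be >= 2, got {n_genes}")
    if not 0.0 < reference_quantile < 1.0:
        raise ValueError("reference_quantile must be in (0,1)")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    means = rng.lognormal(mean=np.log(200.0), sigma=1.2, size=n_genes)
    reference_mean = float(np.quantile(means, reference_quantile))
    include_means = reference_mean * rng.uniform(3.0, 8.0, size=len(include_genes))

    genes = [f"G{i:05d}" for i in range(n_genes)] + [reference_gene] + list(include_genes)
    all_means = np.concatenate([means, [reference_mean], include_means])
    dispersion_size = 10.0  # NB size parameter; variance = mu + mu^2/size
    p = dispersion_size / (dispersion_size + all_means)
    counts = rng.negative_binomial(
        dispersion_size, p[:, None], size=(len(genes), n_samples)
    )
    frame = pd.DataFrame(
        counts, index=genes, columns=[f"S{j + 1:02d}" for j in range(n_samples)]
    )
    return NeuronCountTable(data=frame, reference_gene=reference_gene)


# ---------------------------------------------------------------------------
# On-disk serialization
# ---------------------------------------------------------------------------

def _config_to_jsonable(config: SimulationConfig) -> dict:
    return {
        "n_individuals": config.n_individuals,
        "tissues": list(config.tissues),
        "availability": dict(config.availability),
        "estrogen_effect": config.estrogen_effect,
        "high_fraction": config.high_fraction,
        "rho": [
            {"tissue": t, "stratum": s, "category": c, "rho": v}
            for (t, s, c), v in config.rho.items()
        ],
        "n_genes": dict(config.n_genes),
        "noise_sd": config.noise_sd,
        "seed": int(config.seed),
    }


def config_from_dict(payload: Mapping) -> SimulationConfig:
    kwargs = dict(payload)
    if "tissues" in kwargs:
        kwargs["tissues"] = tuple(kwargs["tissues"])
    if "rho" in kwargs and isinstance(kwargs["rho"], list):
        kwargs["rho"] = {
            (e["tissue"], e["stratum"], e["category"]): float(e["rho"])
            for e in kwargs["rho"]
        }
    return SimulationConfig(**kwargs)


def write_cohort(
    out_dir: str | Path,
    tissues: Mapping[str, TissueExpression],
    truth: SimulatedTruth,
    config: SimulationConfig,
) -> None:
    """Write a cohort: per-tissue TSVs, availability mask, truth, metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, expr in tissues.items():
        write_expression(expr, out / f"expression_{name}.tsv")
    truth.availability.astype(int).to_csv(
        out / "availability.tsv", sep="\t", index_label="individual"
    )
    states = pd.DataFrame(
        sorted(truth.estrogen_state.items()), columns=["individual", "state"]
    )
    states.to_csv(out / "truth_states.tsv", sep="\t", index=False)
    truth.pairing.to_csv(
        out / "truth_pairing.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    with open(out / "run_metadata.json", "w") as fh:
        json.dump({"simulation_config": _config_to_jsonable(config)}, fh,
                  indent=2, sort_keys=True)
        fh.write("\n")


def write_annotations(
    out_dir: str | Path, gene_sets: Sequence[GeneSet], omap: OrthologMap
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_gmt(gene_sets, out / "gene_sets.gmt")
    write_ortholog_map(omap, out / "orthologs.tsv")
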