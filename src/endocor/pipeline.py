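"""End-to-end orchestration: simulate/ingest -> stratify -> correlate -> compare.

Stages run in a fixed order, each writing its machine-readable output under a
run directory named by the configuration hash, so every stage can also be
re-run standalone from the previous stage's files. A single master seed is
fanned out to per-stage sub-seeds through a documented derivation
(:func:`derive_seed`), which keeps stages isolated without seed collisions.
Reruns with an identical configuration are byte-identical in all
machine-readable outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .compare import ComparisonResult, compare_category, render_summary, render_text, summarize
from .correlate import (
    BICOR_MAD_CONVENTION,
    STRATA,
    cross_tissue_correlations,
    empty_records,
    read_records,
    screen_report_frame,
    screen_tissues,
    write_records,
)
from .estrogen import infer_estrogen_states, read_states, write_states
from .resources import (
    GeneSet,
    read_expression,
    read_gmt,
    read_neuron_counts,
    read_ortholog_map,
    filter_high_expressed,
    map_orthologs,
)
from .simulate import (
    HYPOTHALAMUS,
    SimulationConfig,
    config_from_dict,
    make_annotations,
    mouse_symbol,
    simulate_cohort,
    simulate_neuron_counts,
    target_genes,
    write_annotations,
    write_cohort,
    write_neuron_counts,
    _config_to_jsonable,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the reason."""


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage sub-seed from the master seed (< 2**31)."""
    ss = np.random.SeedSequence([int(master), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration of one pipeline run.

    Exactly one input mode: ``simulate`` (uses ``simulation``) or ``files``
    (uses the ``files`` mapping with keys ``expression`` — tissue name ->
    TSV path, hypothalamus required — plus ``gene_sets`` (GMT),
    ``orthologs`` (TSV) and ``neuron_counts`` (TSV)).
    """

    mode: str = "simulate"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    files: Mapping[str, object] | None = None
    weights: Mapping[str, float] | None = None
    bin_method: str = "median"
    bin_quantile: float = 0.5
    ortholog_policy: str = "unique"
    min_n: int = 30
    max_pairs: int = 50_000
    screen_min_sig_fraction: float = 0.02
    screen_alpha: float = 0.05
    contrast_method: str = "welch_t"
    out_dir: str = "endocor_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ValueError(f"mode must be 'simulate' or 'files', got {self.mode!r}")
        if self.mode == "files":
            if not self.files:
                raise ValueError("files mode requires a 'files' mapping")
            expression = self.files.get("expression")
            if not expression or HYPOTHALAMUS not in expression:
                raise ValueError("files.expression must include the hypothalamus matrix")
            for key in ("gene_sets", "orthologs", "neuron_counts"):
                if key not in self.files:
                    raise ValueError(f"files mode requires files.{key}")
            for path in [*expression.values(),
                         self.files["gene_sets"], self.files["orthologs"],
                         self.files["neuron_counts"]]:
                if not Path(path).exists():
                    raise ValueError(f"input file does not exist: {path}")
        if self.bin_method not in ("median", "quantile"):
            raise ValueError(f"unknown bin_method {self.bin_method!r}")
        if self.contrast_method not in ("welch_t", "rank_sum"):
            raise ValueError(f"unknown contrast_method {self.contrast_method!r}")
        if self.min_n < 3:
            raise ValueError("min_n must be >= 3")

    def to_jsonable(self) -> dict:
        payload = {
            "mode": self.mode,
            "weights": dict(self.weights) if self.weights else None,
            "bin_method": self.bin_method,
            "bin_quantile": self.bin_quantile,
            "ortholog_policy": self.ortholog_policy,
            "min_n": self.min_n,
            "max_pairs": self.max_pairs,
            "screen_min_sig_fraction": self.screen_min_sig_fraction,
            "screen_alpha": self.screen_alpha,
            "contrast_method": self.contrast_method,
            "out_dir": self.out_dir,
            "seed": int(self.seed),
        }
        if self.mode == "simulate":
            payload["simulation"] = _config_to_jsonable(self.simulation)
        else:
            payload["files"] = {
                "expression": {t: str(p) for t, p in self.files["expression"].items()},
                "gene_sets": str(self.files["gene_sets"]),
                "orthologs": str(self.files["orthologs"]),
                "neuron_counts": str(self.files["neuron_counts"]),
            }
        return payload

    @classmethod
    def from_dict(cls, payload: Mapping) -> "PipelineConfig":
        kwargs = dict(payload)
        if "simulation" in kwargs and isinstance(kwargs["simulation"], Mapping):
            kwargs["simulation"] = config_from_dict(kwargs["simulation"])
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_jsonable(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return decorator


@_stage("inputs")
def _load_inputs(config: PipelineConfig, run_dir: Path):
    """Simulate or read the cohort, annotations and neuron counts."""
    if config.mode == "simulate":
        sim = dataclasses.replace(
            config.simulation, seed=derive_seed(config.seed, "cohort")
        )
        tissues, truth = simulate_cohort(sim)
        gene_sets, omap = make_annotations(sim)
        mouse_targets = [mouse_symbol(g) for g in target_genes(sim)]
        counts = simulate_neuron_counts(
            n_genes=400, n_samples=6, reference_quantile=0.8,
            seed=derive_seed(config.seed, "neuron_counts"),
            include_genes=mouse_targets,
        )
        inputs_dir = run_dir / "inputs"
        write_cohort(inputs_dir, tissues, truth, sim)
        write_annotations(inputs_dir, gene_sets, omap)
        write_neuron_counts(counts, inputs_dir / "neuron_counts.tsv")
        return tissues, gene_sets, omap, counts
    tissues = {
        tissue: read_expression(path, tissue)
        for tissue, path in config.files["expression"].items()
    }
    gene_sets = read_gmt(config.files["gene_sets"])
    omap = read_ortholog_map(config.files["orthologs"])
    counts = read_neuron_counts(config.files["neuron_counts"])
    return tissues, gene_sets, omap, counts


@_stage("infer_estrogen")
def _infer_states(config: PipelineConfig, tissues, gene_sets, run_dir: Path):
    signature = next(
        (gs for gs in gene_sets if gs.category_kind == "signature"), None
    )
    if signature is None:
        raise ValueError("no gene set of kind 'signature' among the inputs")
    states = infer_estrogen_states(
        tissues, signature, weights=config.weights,
        method=config.bin_method, q=config.bin_quantile,
    )
    write_states(states, run_dir / "estrogen_states.tsv",
                 tissues=sorted(tissues))
    return states


@_stage("select_targets")
def _select_targets(config: PipelineConfig, counts, omap, run_dir: Path):
    high = filter_high_expressed(counts)
    targets = map_orthologs(high, omap, policy=config.ortholog_policy)
    with open(run_dir / "targets.txt", "w") as fh:
        fh.writelines(f"{g}\n" for g in targets)
    if not targets:
        raise ValueError("no hypothalamic target genes after ortholog mapping")
    return targets


@_stage("correlate")
def _correlate(config: PipelineConfig, tissues, gene_sets, targets, states,
               run_dir: Path):
    hypothalamus = tissues[HYPOTHALAMUS]
    category_sets = [gs for gs in gene_sets if gs.category_kind != "signature"]
    bins = {s.individual: s.bin for s in states if s.bin in STRATA}
    hypo_ids = set(hypothalamus.individuals)

    records_by_tissue: dict[str, object] = {}
    matched_n: dict[str, dict[str, int]] = {}
    for name, expr in tissues.items():
        if name == HYPOTHALAMUS:
            continue
        tissue_ids = set(expr.individuals)
        matched_n[name] = {
            stratum: sum(
                1 for ind, b in bins.items()
                if b == stratum and ind in tissue_ids and ind in hypo_ids
            )
            for stratum in STRATA
        }
        if min(matched_n[name].values()) == 0:
            logger.warning(
                "correlate: tissue %s has a stratum with zero matched "
                "individuals; no records computed", name,
            )
            records_by_tissue[name] = empty_records()
        else:
            import pandas as pd
            frames = [
                cross_tissue_correlations(
                    expr, hypothalamus, cat, targets, states,
                    min_n=config.min_n, max_pairs=config.max_pairs,
                )
                for cat in category_sets
            ]
            frames = [f for f in frames if len(f)]
            records_by_tissue[name] = (
                pd.concat(frames, ignore_index=True) if frames else empty_records()
            )
        write_records(records_by_tissue[name], run_dir / f"records_{name}.tsv")
    return records_by_tissue, matched_n


@_stage("screen")
def _screen(config: PipelineConfig, records_by_tissue, matched_n, run_dir: Path):
    kept, dropped = screen_tissues(
        records_by_tissue,
        min_n=config.min_n,
        min_sig_fraction=config.screen_min_sig_fraction,
        alpha=config.screen_alpha,
        matched_n=matched_n,
    )
    screen_report_frame(kept, dropped).to_csv(
        run_dir / "screen_report.tsv", sep="\t", index=False
    )
    return kept, dropped


@_stage("compare")
def _compare(config: PipelineConfig, records_by_tissue, kept, dropped,
             run_dir: Path):
    import pandas as pd

    kept_frames = [records_by_tissue[t] for t in kept if len(records_by_tissue[t])]
    results: list[ComparisonResult] = []
    if kept_frames:
        records = pd.concat(kept_frames, ignore_index=True)
        for category in sorted(records["category"].unique()):
            try:
                results.append(
                    compare_category(records, category, method=config.contrast_method)
                )
            except ValueError as exc:
                logger.warning("compare: category %s skipped: %s", category, exc)
    echo = config.to_jsonable()
    echo["package_version"] = __version__
    echo["bicor_mad_convention"] = BICOR_MAD_CONVENTION
    summary = summarize(results, screen_kept=kept, screen_dropped=dropped,
                        config_echo=echo)
    (run_dir / "summary.json").write_text(render_summary(summary))
    (run_dir / "summary.txt").write_text(render_text(summary))
    return summary


def run_pipeline(config: PipelineConfig) -> tuple[dict, Path]:
    """Execute every stage in order; returns (summary, run directory).

    The run directory is ``out_dir/run_<config hash>``; rerunning with an
    identical configuration overwrites it with byte-identical files.
    """
    run_dir = Path(config.out_dir) / f"run_{config.config_hash()}"
    run_dir.mkdir(parents=True, exist_ok=True)
    logger.info("run_pipeline: writing to %s", run_dir)

    tissues, gene_sets, omap, counts = _load_inputs(config, run_dir)
    states = _infer_states(config, tissues, gene_sets, run_dir)
    targets = _select_targets(config, counts, omap, run_dir)
    records_by_tissue, matched_n = _correlate(
        config, tissues, gene_sets, targets, states, run_dir
    )
    kept, dropped = _screen(config, records_by_tissue, matched_n, run_dir)
    summary = _compare(config, records_by_tissue, kept, dropped, run_dir)
    return summary, run_dir
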