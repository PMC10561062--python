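"""Shared builders and independent oracles for the test suite.

The oracles here are deliberately naive, straight-line implementations
(pure-python loops, closed forms) kept independent of the package's
vectorised code paths so they can serve as references.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from endocor import (
    SimulationConfig,
    cross_tissue_correlations,
    infer_estrogen_states,
    make_annotations,
    simulate_cohort,
)

CATEGORIES = ("secreted", "ligand", "peptide_hormone", "feeding")


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def oracle_bicor(x, y) -> float:
    """Straight-line evaluation of the biweight midcorrelation formula."""

    def med(v):
        s = sorted(v)
        n = len(s)
        return s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2

    def transform(v):
        m = med(v)
        mad = med([abs(vi - m) for vi in v])
        out = []
        for vi in v:
            if mad == 0:
                return None
            u = (vi - m) / (9 * mad)
            a = (1 - u * u) ** 2 if abs(u) < 1 else 0.0
            out.append((vi - m) * a)
        return out

    xt, yt = transform(list(x)), transform(list(y))
    if xt is None or yt is None:
        raise ValueError("oracle: zero MAD")
    num = sum(a * b for a, b in zip(xt, yt))
    den = math.sqrt(sum(a * a for a in xt)) * math.sqrt(sum(b * b for b in yt))
    return num / den


def oracle_kruskal(groups) -> float:
    """Tie-corrected Kruskal-Wallis H by explicit midranking."""
    pooled = sorted((v, gi) for gi, g in enumerate(groups) for v in g)
    n = len(pooled)
    ranks = [0.0] * n
    i = 0
    tie_sizes = []
    while i < n:
        j = i
        while j < n and pooled[j][0] == pooled[i][0]:
            j += 1
        midrank = (i + 1 + j) / 2
        for k in range(i, j):
            ranks[k] = midrank
        tie_sizes.append(j - i)
        i = j
    rank_sums = [0.0] * len(groups)
    for (value, gi), rank in zip(pooled, ranks):
        rank_sums[gi] += rank
    H = 12.0 / (n * (n + 1)) * sum(
        rs**2 / len(g) for rs, g in zip(rank_sums, groups)
    ) - 3 * (n + 1)
    correction = 1.0 - sum(t**3 - t for t in tie_sizes) / (n**3 - n)
    return H / correction


def oracle_welch_t(a, b) -> float:
    """Closed-form Welch two-sample t statistic."""
    a, b = list(a), list(b)
    ma, mb = sum(a) / len(a), sum(b) / len(b)
    va = sum((x - ma) ** 2 for x in a) / (len(a) - 1)
    vb = sum((x - mb) ** 2 for x in b) / (len(b) - 1)
    return (ma - mb) / math.sqrt(va / len(a) + vb / len(b))


def oracle_t_sf(t: float, df: int) -> float:
    """Student-t upper tail through the regularised incomplete beta."""
    from scipy.special import betainc

    return 0.5 * betainc(df / 2.0, 0.5, df / (df + t * t))


# ---------------------------------------------------------------------------
# Cohort/record builders (small, fast configurations)
# ---------------------------------------------------------------------------

def rho_map(per_tissue: dict[str, tuple[float, float]]):
    """Uniform-across-categories rho map from {tissue: (rho_high, rho_low)}."""
    out = {}
    for category in CATEGORIES:
        for tissue, (high, low) in per_tissue.items():
            out[(tissue, "high", category)] = high
            out[(tissue, "low", category)] = low
    return out


def small_config(
    per_tissue_rho: dict[str, tuple[float, float]],
    n_individuals: int = 150,
    seed: int = 0,
    n_genes: dict | None = None,
    **kwargs,
) -> SimulationConfig:
    tissues = ("hypothalamus", *per_tissue_rho)
    return SimulationConfig(
        n_individuals=n_individuals,
        tissues=tissues,
        availability={t: 1.0 for t in tissues},
        rho=rho_map(per_tissue_rho),
        n_genes=n_genes or {"signature": 8, "category": 10, "target": 10,
                            "background": 5},
        seed=seed,
        **kwargs,
    )


def build_records(
    config: SimulationConfig,
    category: str = "secreted",
    matched: bool = True,
    min_n: int = 30,
):
    """Simulate a cohort and produce stratified records for one category.

    ``matched=True`` restricts the pair universe to the generating pairs
    (parameter recovery against the simulated truth); ``matched=False`` uses
    the default all-pairs universe. Strata come from the inferred estrogen
    states, exactly as in the pipeline.
    """
    tissues, truth = simulate_cohort(config)
    gene_sets, _ = make_annotations(config)
    signature = next(s for s in gene_sets if s.category_kind == "signature")
    category_set = next(s for s in gene_sets if s.category_kind == category)
    states = infer_estrogen_states(tissues, signature)
    frames = []
    for tissue in config.peripheral_tissues:
        pairs = None
        if matched:
            sub = truth.pairing[
                (truth.pairing.tissue == tissue)
                & (truth.pairing.category == category)
            ]
            pairs = list(zip(sub.peripheral_gene, sub.target_gene))
        frames.append(
            cross_tissue_correlations(
                tissues[tissue], tissues["hypothalamus"], category_set,
                list(tissues["hypothalamus"].genes), states,
                min_n=min_n, pairs=pairs,
            )
        )
    frames = [f for f in frames if len(f)]
    records = pd.concat(frames, ignore_index=True) if frames else frames
    return records, tissues, truth, states
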