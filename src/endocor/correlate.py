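"""Biweight midcorrelation and stratified cross-tissue correlation records.

The biweight midcorrelation (bicor) is a robust correlation that replaces
means and standard deviations with medians and median absolute deviations
and downweights observations far from the median with Tukey biweights:

    u_i = (x_i - med(x)) / (9 * MAD(x)),      MAD(x) = med(|x - med(x)|)
    a_i = (1 - u_i^2)^2 * 1[|u_i| < 1]
    x~_i = (x_i - med(x)) * a_i
    bicor(x, y) = sum_i x~_i y~_i / (||x~|| * ||y~||)

The MAD here is the raw median absolute deviation, without the 1.4826
normal-consistency constant: the constant would cancel nowhere in the
weights yet change which points fall inside |u| < 1, so the convention is
fixed once and echoed in all output metadata.

When a vector is degenerate for the biweight transform (zero MAD, or every
weight vanishing), the correlation falls back to the product-moment
(Pearson) coefficient and the record is marked ``pearson_fallback``. A
vector that is degenerate for Pearson too (zero variance) is an error.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .resources import GeneSet, TissueExpression

logger = logging.getLogger(__name__)

#: Column order of a correlation-record table (one row per
#: tissue / category / gene-pair / stratum bicor observation).
RECORD_COLUMNS = (
    "tissue", "category", "peripheral_gene", "target_gene",
    "stratum", "r", "n", "p", "method",
)

#: Convention note propagated into run metadata.
BICOR_MAD_CONVENTION = "raw MAD (no 1.4826 consistency constant)"

STRATA = ("high", "low")


# ---------------------------------------------------------------------------
# bicor core
# ---------------------------------------------------------------------------

def _prepare_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Biweight-transform and L2-normalise each row of ``X`` (shape p x n).

    Returns (normalised rows, fallback mask, degenerate mask). Rows where the
    biweight transform is undefined (MAD 0 or all weights 0) fall back to
    mean-centering (Pearson); rows that are constant even then are flagged
    degenerate and left as zeros.
    """
    # contiguous copy: reductions must not depend on the caller's array layout
    X = np.ascontiguousarray(X, dtype=float)
    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (X - med) / (9.0 * mad)
    u = np.where(np.isfinite(u), u, np.inf)
    inside = np.abs(u) < 1.0
    u_safe = np.where(inside, u, 0.0)
    weights = np.where(inside, (1.0 - u_safe**2) ** 2, 0.0)
    transformed = (X - med) * weights
    norms = np.sqrt(np.sum(transformed**2, axis=1, keepdims=True))
    fallback = (
        (mad[:, 0] == 0.0)
        | np.all(weights == 0.0, axis=1)
        | (norms[:, 0] == 0.0)
    )
    degenerate = norms[:, 0] == 0.0
    safe = np.where(norms == 0.0, 1.0, norms)
    return transformed / safe, fallback, degenerate


def _centered_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centered, L2-normalised rows (the Pearson transform)."""
    X = np.ascontiguousarray(X, dtype=float)
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.sum(centered**2, axis=1, keepdims=True))
    degenerate = norms[:, 0] == 0.0
    safe = np.where(norms == 0.0, 1.0, norms)
    return centered / safe, degenerate


def _validate_vector(v: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def bicor(x: Sequence[float], y: Sequence[float]) -> tuple[float, str]:
    """Biweight midcorrelation of two equal-length vectors (n >= 3).

    Returns ``(r, method)`` with ``method`` either ``"bicor"`` or
    ``"pearson_fallback"``; r is clipped into [-1, 1]. Symmetric in its
    arguments and invariant under positive affine transforms of either.
    """
    ax = _validate_vector(x, "x")
    ay = _validate_vector(y, "y")
    if ax.shape[0] != ay.shape[0]:
        raise ValueError(f"length mismatch: {ax.shape[0]} vs {ay.shape[0]}")
    if ax.shape[0] < 3:
        raise ValueError(f"need at least 3 observations, got {ax.shape[0]}")
    stacked = np.vstack([ax, ay])
    rows, fallback, _ = _prepare_rows(stacked)
    if fallback.any():
        # either side degenerate for the biweight: whole pair falls back
        rows, degenerate = _centered_rows(stacked)
        if degenerate.any():
            which = "x" if degenerate[0] else "y"
            raise ValueError(f"{which} has zero variance: correlation undefined")
        return float(np.clip(rows[0] @ rows[1], -1.0, 1.0)), "pearson_fallback"
    return float(np.clip(rows[0] @ rows[1], -1.0, 1.0)), "bicor"


def bicor_matrix(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs bicor between rows of X (p x n) and rows of Y (q x n).

    Returns ``(R, fallback_x, fallback_y, degenerate_x, degenerate_y)``:
    R is p x q with entries clipped into [-1, 1]; a pair's method is
    ``pearson_fallback`` if either of its rows fell back; pairs touching a
    degenerate row are undefined and must be discarded by the caller.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"column mismatch: {X.shape[1]} vs {Y.shape[1]}")
    if X.shape[1] < 3:
        raise ValueError(f"need at least 3 observations, got {X.shape[1]}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite values in input matrices")
    rows_x, fb_x, _ = _prepare_rows(X)
    rows_y, fb_y, _ = _prepare_rows(Y)
    R = np.clip(rows_x @ rows_y.T, -1.0, 1.0)
    if fb_x.any() or fb_y.any():
        # pairs touching a fallback row use the Pearson transform on BOTH sides
        cx, deg_x = _centered_rows(X)
        cy, deg_y = _centered_rows(Y)
        pair_fallback = fb_x[:, None] | fb_y[None, :]
        R = np.where(pair_fallback, np.clip(cx @ cy.T, -1.0, 1.0), R)
    else:
        deg_x = np.zeros(X.shape[0], dtype=bool)
        deg_y = np.zeros(Y.shape[0], dtype=bool)
    return R, fb_x, fb_y, deg_x, deg_y


def correlation_pvalue(r, n: int):
    """Two-sided p-value for a correlation coefficient via the Student-t map.

    t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom; |r| = 1 gives
    p = 0 exactly. Accepts a scalar or array of coefficients.
    """
    if n < 3:
        raise ValueError(f"need n >= 3 for a correlation p-value, got {n}")
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0 + 1e-12):
        raise ValueError("|r| > 1")
    rr = np.clip(np.abs(arr), 0.0, 1.0)
    with np.errstate(divide="ignore"):
        t = rr * np.sqrt((n - 2) / (1.0 - rr**2))
    p = np.where(rr >= 1.0, 0.0, 2.0 * stats.t.sf(t, df=n - 2))
    p = np.clip(p, 0.0, 1.0)
    return float(p) if np.isscalar(r) or np.ndim(r) == 0 else p


# ---------------------------------------------------------------------------
# Stratified cross-tissue records
# ---------------------------------------------------------------------------

def empty_records() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in RECORD_COLUMNS})


def cross_tissue_correlations(
    peripheral: TissueExpression,
    hypothalamus: TissueExpression,
    category_set: GeneSet,
    targets: Sequence[str],
    states: Sequence,
    *,
    min_n: int = 30,
    max_pairs: int = 50_000,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Stratified bicor records between peripheral category genes and targets.

    For each estrogen stratum separately, individuals present in both tissue
    matrices and carrying that stratum's bin are matched, and bicor is
    computed for every (peripheral gene in ``category_set``, target gene in
    ``targets``) pair — or only the explicit ``pairs`` when given. The pair
    universe is capped at ``max_pairs`` in sorted order for determinism.
    Strata with fewer than ``min_n`` matched individuals contribute no
    records (logged); a stratum with zero matched individuals is an error.

    Returns a DataFrame with columns ``RECORD_COLUMNS``.
    """
    bins: dict[str, str] = {}
    for state in states:
        if getattr(state, "bin", None) in STRATA:
            bins[state.individual] = state.bin

    peripheral_ids = set(peripheral.individuals)
    hypothalamus_ids = set(hypothalamus.individuals)

    matched: dict[str, list[str]] = {}
    for stratum in STRATA:
        ids = sorted(
            ind for ind, b in bins.items()
            if b == stratum and ind in peripheral_ids and ind in hypothalamus_ids
        )
        if not ids:
            raise ValueError(
                f"no matched individuals for tissue {peripheral.tissue!r}, "
                f"stratum {stratum!r}"
            )
        matched[stratum] = ids

    peripheral_genes = sorted(category_set.genes & set(peripheral.genes))
    target_genes = sorted(set(targets) & set(hypothalamus.genes))
    if not peripheral_genes or not target_genes:
        logger.warning(
            "cross_tissue_correlations: no usable gene pairs for tissue %s "
            "category %s (peripheral=%d, targets=%d)",
            peripheral.tissue, category_set.name,
            len(peripheral_genes), len(target_genes),
        )
        return empty_records()

    if pairs is not None:
        pset = set(peripheral_genes)
        tset = set(target_genes)
        universe = sorted((p, t) for p, t in pairs if p in pset and t in tset)
    else:
        universe = [(p, t) for p in peripheral_genes for t in target_genes]
    if len(universe) > max_pairs:
        logger.info(
            "cross_tissue_correlations: capping %d pairs to %d (sorted order)",
            len(universe), max_pairs,
        )
        universe = universe[:max_pairs]
    if not universe:
        return empty_records()

    used_p = sorted({p for p, _ in universe})
    used_t = sorted({t for _, t in universe})
    p_index = {g: i for i, g in enumerate(used_p)}
    t_index = {g: i for i, g in enumerate(used_t)}

    frames: list[pd.DataFrame] = []
    for stratum in STRATA:
        ids = matched[stratum]
        n = len(ids)
        if n < min_n:
            logger.info(
                "cross_tissue_correlations: tissue %s stratum %s has n=%d < "
                "min_n=%d; %d pair(s) skipped",
                peripheral.tissue, stratum, n, min_n, len(universe),
            )
            continue
        X = peripheral.data.loc[used_p, ids].to_numpy()
        Y = hypothalamus.data.loc[used_t, ids].to_numpy()
        R, fb_x, fb_y, deg_x, deg_y = bicor_matrix(X, Y)
        P = correlation_pvalue(R, n)
        rows = []
        n_degenerate = 0
        for pg, tg in universe:
            i, j = p_index[pg], t_index[tg]
            if deg_x[i] or deg_y[j]:
                n_degenerate += 1
                continue
            method = "pearson_fallback" if (fb_x[i] or fb_y[j]) else "bicor"
            rows.append((
                peripheral.tissue, category_set.category_kind, pg, tg,
                stratum, float(R[i, j]), n, float(P[i, j]), method,
            ))
        if n_degenerate:
            logger.warning(
                "cross_tissue_correlations: %d degenerate pair(s) dropped "
                "(tissue %s, stratum %s)", n_degenerate, peripheral.tissue, stratum,
            )
        frames.append(pd.DataFrame(rows, columns=list(RECORD_COLUMNS)))

    if not frames:
        return empty_records()
    out = pd.concat(frames, ignore_index=True)
    out["n"] = out["n"].astype(int)
    return out


def write_records(records: pd.DataFrame, path) -> None:
    from .resources import FLOAT_FORMAT
    records.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_records(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = set(RECORD_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing record columns {sorted(missing)}")
    return frame


# ---------------------------------------------------------------------------
# Tissue screen
# ---------------------------------------------------------------------------

def screen_tissues(
    records_by_tissue: Mapping[str, pd.DataFrame],
    *,
    min_n: int = 30,
    min_sig_fraction: float = 0.02,
    alpha: float = 0.05,
    matched_n: Mapping[str, Mapping[str, int]] | None = None,
) -> tuple[list[str], dict[str, str]]:
    """Drop tissues with too little matching or too few significant records.

    A tissue is dropped when its minimum per-stratum matched-individual count
    is below ``min_n``, or when the fraction of its records significant after
    Benjamini-Hochberg adjustment (adjusted p < ``alpha``) falls below
    ``min_sig_fraction``. ``matched_n`` optionally supplies per-stratum
    matched counts for tissues whose records were skipped entirely; otherwise
    counts are taken from the records.

    Returns ``(kept tissue names, dropped tissue -> reason)``.
    """
    kept: list[str] = []
    dropped: dict[str, str] = {}
    for tissue, records in records_by_tissue.items():
        if matched_n is not None and tissue in matched_n:
            observed = min(matched_n[tissue].values()) if matched_n[tissue] else 0
        elif len(records):
            observed = int(records.groupby("stratum")["n"].min().min())
        else:
            observed = 0
        if observed < min_n:
            dropped[tissue] = (
                f"insufficient matching (min per-stratum n={observed} < {min_n})"
            )
            continue
        if not len(records):
            dropped[tissue] = "no correlation records"
            continue
        reject, _, _, _ = multipletests(
            records["p"].to_numpy(), alpha=alpha, method="fdr_bh"
        )
        fraction = float(reject.mean())
        if fraction < min_sig_fraction:
            dropped[tissue] = (
                f"too few significant co-correlations (BH-significant fraction "
                f"{fraction:.4f} < {min_sig_fraction})"
            )
            continue
        kept.append(tissue)
    for tissue, reason in dropped.items():
        logger.info("screen_tissues: dropping %s: %s", tissue, reason)
    return kept, dropped


def screen_report_frame(
    kept: Sequence[str], dropped: Mapping[str, str]
) -> pd.DataFrame:
    rows = [(t, "kept", "") for t in kept]
    rows += [(t, "dropped", reason) for t, reason in dropped.items()]
    return pd.DataFrame(rows, columns=["tissue", "status", "reason"])
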