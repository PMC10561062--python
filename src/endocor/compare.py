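"""Compare correlation distributions across tissue x estrogen-stratum cells.

Three statistics per functional category:

* an omnibus Kruskal-Wallis test treating every non-empty (tissue, stratum)
  cell as one group of bicor values — the one-way reading of "interaction
  between estrogen category + tissue" that yields a single H and p;
* per-tissue high-vs-low contrasts (Welch t by default, rank-sum optional)
  with Benjamini-Hochberg adjustment across tissues within the category;
* profile similarity: the bicor between the two strata's vectors of matched
  correlation coefficients — negative values mean the strata's cross-tissue
  communication patterns diverge.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .correlate import bicor, correlation_pvalue

logger = logging.getLogger(__name__)

PROFILE_KEY = ["tissue", "category", "peripheral_gene", "target_gene"]


@dataclass(frozen=True)
class ComparisonResult:
    """All comparison outputs for one functional category."""

    category: str
    omnibus_H: float
    omnibus_p: float
    groups: pd.DataFrame      # tissue, stratum, n_records, median_r
    contrasts: pd.DataFrame   # tissue, statistic, raw_p, adjusted_p, direction
    profile_similarity: tuple[float, float, int] | None  # (r, p, n_pairs)


def kw_across_groups(records: pd.DataFrame) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis over (tissue, stratum) groups of r values.

    Ranks all r values jointly (midranks for ties, tie-corrected H); p comes
    from the chi-square tail on groups-1 degrees of freedom. Invariant under
    strictly monotone transforms of the r values. Needs >=2 non-empty groups.
    """
    groups: list[np.ndarray] = []
    rows = []
    for (tissue, stratum), sub in records.groupby(["tissue", "stratum"], sort=True):
        values = sub["r"].to_numpy(dtype=float)
        if len(values) == 0:
            continue
        groups.append(values)
        rows.append((tissue, stratum, len(values), float(np.median(values))))
    if len(groups) < 2:
        raise ValueError(f"need >=2 non-empty (tissue, stratum) groups, got {len(groups)}")
    table = pd.DataFrame(rows, columns=["tissue", "stratum", "n_records", "median_r"])
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        # every observation tied: tie-corrected H is 0/0, defined as no effect
        return 0.0, 1.0, table
    H, p = stats.kruskal(*groups)
    return float(H), float(p), table


def contrast_high_vs_low(
    records: pd.DataFrame, tissue: str, method: str = "welch_t"
) -> tuple[float, float, str]:
    """High-vs-low contrast of r values within one tissue.

    ``welch_t``: Welch two-sample t (direction from the mean difference);
    ``rank_sum``: two-sided Mann-Whitney (direction from the median
    difference). Identical degenerate samples yield (0, 1, "none").
    """
    if method not in ("welch_t", "rank_sum"):
        raise ValueError(f"unknown contrast method {method!r}")
    sub = records[records["tissue"] == tissue]
    r_high = sub.loc[sub["stratum"] == "high", "r"].to_numpy(dtype=float)
    r_low = sub.loc[sub["stratum"] == "low", "r"].to_numpy(dtype=float)
    for stratum, values in (("high", r_high), ("low", r_low)):
        if len(values) == 0:
            raise ValueError(f"tissue {tissue!r}: stratum {stratum!r} is empty")
    if method == "welch_t":
        statistic, p = stats.ttest_ind(r_high, r_low, equal_var=False)
        diff = float(np.mean(r_high) - np.mean(r_low))
    else:
        statistic, p = stats.mannwhitneyu(r_high, r_low, alternative="two-sided")
        diff = float(np.median(r_high) - np.median(r_low))
    statistic, p = float(statistic), float(p)
    if not np.isfinite(statistic) or not np.isfinite(p):
        statistic, p, diff = 0.0, 1.0, 0.0  # zero-variance identical samples
    if diff > 0:
        direction = "high>low"
    elif diff < 0:
        direction = "low>high"
    else:
        direction = "none"
    return statistic, p, direction


def contrast_table(
    records: pd.DataFrame,
    tissues: Sequence[str] | None = None,
    method: str = "welch_t",
) -> pd.DataFrame:
    """Per-tissue contrasts with BH adjustment across the tissue family."""
    if tissues is None:
        tissues = sorted(records["tissue"].unique())
    rows = []
    for tissue in tissues:
        statistic, raw_p, direction = contrast_high_vs_low(records, tissue, method)
        rows.append((tissue, statistic, raw_p, direction))
    frame = pd.DataFrame(rows, columns=["tissue", "statistic", "raw_p", "direction"])
    if len(frame):
        _, adjusted, _, _ = multipletests(
            frame["raw_p"].to_numpy(), method="fdr_bh"
        )
        frame["adjusted_p"] = adjusted
    else:
        frame["adjusted_p"] = []
    return frame[["tissue", "statistic", "raw_p", "adjusted_p", "direction"]]


def profile_similarity(
    records_high: pd.DataFrame, records_low: pd.DataFrame
) -> tuple[float, float, int]:
    """bicor between the strata's aligned correlation profiles.

    Records are matched on (tissue, category, peripheral_gene, target_gene);
    unmatched keys are dropped and counted. Needs >=3 matched keys. Returns
    (r, p, n_pairs) with p from the Student-t transform.
    """
    high = records_high[PROFILE_KEY + ["r"]].rename(columns={"r": "r_high"})
    low = records_low[PROFILE_KEY + ["r"]].rename(columns={"r": "r_low"})
    merged = high.merge(low, on=PROFILE_KEY, how="inner")
    n_dropped = (len(high) - len(merged)) + (len(low) - len(merged))
    if n_dropped:
        logger.info("profile_similarity: %d unmatched record(s) dropped", n_dropped)
    n_pairs = len(merged)
    if n_pairs < 3:
        raise ValueError(f"need >=3 matched record keys, got {n_pairs}")
    r, _ = bicor(merged["r_high"].to_numpy(), merged["r_low"].to_numpy())
    p = correlation_pvalue(r, n_pairs)
    return r, p, n_pairs


def compare_category(
    records: pd.DataFrame, category: str, method: str = "welch_t"
) -> ComparisonResult:
    """Omnibus, contrasts and profile similarity for one category's records."""
    sub = records[records["category"] == category]
    if not len(sub):
        raise ValueError(f"no records for category {category!r}")
    H, p, groups = kw_across_groups(sub)
    contrasts = contrast_table(sub, method=method)
    try:
        similarity = profile_similarity(
            sub[sub["stratum"] == "high"], sub[sub["stratum"] == "low"]
        )
    except ValueError as exc:
        logger.warning("compare_category(%s): profile similarity unavailable: %s",
                       category, exc)
        similarity = None
    return ComparisonResult(
        category=category, omnibus_H=H, omnibus_p=p,
        groups=groups, contrasts=contrasts, profile_similarity=similarity,
    )


# ---------------------------------------------------------------------------
# Run summary
# ---------------------------------------------------------------------------

def summarize(
    results: Sequence[ComparisonResult],
    screen_kept: Sequence[str] = (),
    screen_dropped: Mapping[str, str] | None = None,
    config_echo: Mapping | None = None,
) -> dict:
    """Machine-readable run summary (JSON-serializable dict)."""
    categories = {}
    for result in results:
        similarity = None
        if result.profile_similarity is not None:
            r, p, n_pairs = result.profile_similarity
            similarity = {"r": r, "p": p, "n_pairs": n_pairs}
        categories[result.category] = {
            "omnibus_H": result.omnibus_H,
            "omnibus_p": result.omnibus_p,
            "groups": result.groups.to_dict(orient="records"),
            "contrasts": result.contrasts.to_dict(orient="records"),
            "profile_similarity": similarity,
        }
    return {
        "n_categories": len(categories),
        "categories": categories,
        "screen": {
            "kept": list(screen_kept),
            "dropped": dict(screen_dropped or {}),
        },
        "config": dict(config_echo or {}),
    }


def render_summary(summary: Mapping) -> str:
    """Canonical machine-readable rendering (sorted-key JSON)."""
    return json.dumps(summary, indent=2, sort_keys=True) + "\n"


def parse_summary(text: str) -> dict:
    return json.loads(text)


def render_text(summary: Mapping) -> str:
    """Human-readable rendering of a run summary."""
    lines = ["Cross-tissue co-correlation comparison", "=" * 40]
    if not summary["categories"]:
        lines.append("No categories compared (zero categories).")
    for name, cat in sorted(summary["categories"].items()):
        lines.append(f"\nCategory: {name}")
        lines.append(
            f"  Kruskal-Wallis H = {cat['omnibus_H']:.4g}, p = {cat['omnibus_p']:.4g}"
        )
        for contrast in cat["contrasts"]:
            lines.append(
                f"  {contrast['tissue']}: {contrast['direction']}"
                f" (stat = {contrast['statistic']:.4g},"
                f" adjusted p = {contrast['adjusted_p']:.4g})"
            )
        sim = cat["profile_similarity"]
        if sim is not None:
            lines.append(
                f"  profile similarity: bicor = {sim['r']:.4g},"
                f" p = {sim['p']:.4g}, n = {sim['n_pairs']}"
            )
    screen = summary["screen"]
    lines.append(f"\nTissues kept: {', '.join(screen['kept']) or 'none'}")
    for tissue, reason in sorted(screen["dropped"].items()):
        lines.append(f"Tissue dropped: {tissue} ({reason})")
    return "\n".join(lines) + "\n"
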