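"""Per-individual estrogen-signaling state from multi-tissue expression.

Signature genes (an estrogen-responsive gene set such as the MSigDB hallmark
early-response set) are Z-scored within each tissue, averaged per individual
and tissue, aggregated across available tissues with configurable weights,
and the cohort is split into high/low strata at the median (or a chosen
quantile) of the aggregate score.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .resources import FLOAT_FORMAT, NA_TOKEN, GeneSet, TissueExpression

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EstrogenState:
    """One individual's signature scores and high/low bin.

    ``per_tissue_score`` maps each tissue where the individual was sampled to
    the mean Z of the retained signature genes; ``aggregate_score`` is the
    weighted mean of those per-tissue scores; ``bin`` is set by
    :func:`bin_individuals`.
    """

    individual: str
    per_tissue_score: Mapping[str, float]
    aggregate_score: float
    bin: str | None = None


def zscore_gene_set(expr: TissueExpression, signature: GeneSet) -> pd.DataFrame:
    """Z-score the signature genes within one tissue (gene rows, ddof=1).

    Signature genes absent from the tissue are skipped with a log message;
    genes with zero variance are dropped with a warning. Raises if no
    signature gene survives, naming the tissue.
    """
    if expr.data.shape[1] < 2:
        raise ValueError(
            f"tissue {expr.tissue!r}: need >=2 individuals to Z-score"
        )
    present = [g for g in expr.genes if g in signature.genes]
    n_missing = len(signature.genes) - len(present)
    if n_missing:
        logger.info(
            "zscore_gene_set: %d signature gene(s) absent from tissue %s",
            n_missing, expr.tissue,
        )
    if not present:
        raise ValueError(
            f"no signature gene present in tissue {expr.tissue!r}"
        )
    sub = expr.data.loc[present]
    # contiguous copy: results must not depend on the frame's block layout
    values = np.ascontiguousarray(sub.to_numpy(dtype=float))
    sd = np.std(values, axis=1, ddof=1)
    constant = sd == 0.0
    if constant.any():
        logger.warning(
            "zscore_gene_set: dropping %d zero-variance signature gene(s) "
            "in tissue %s", int(constant.sum()), expr.tissue,
        )
        values = values[~constant]
        sd = sd[~constant]
        present = [g for g, c in zip(present, constant) if not c]
    if values.shape[0] == 0:
        raise ValueError(
            f"no signature gene present in tissue {expr.tissue!r} "
            "after dropping zero-variance genes"
        )
    z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.DataFrame(z, index=present, columns=sub.columns)


def score_individuals(
    z_by_tissue: Mapping[str, pd.DataFrame],
    weights: Mapping[str, float] | None = None,
) -> list[EstrogenState]:
    """Aggregate per-tissue signature Z means into one score per individual.

    Per-tissue score = mean over retained signature genes of that tissue's Z
    matrix; aggregate = sum_t w_t * score_t / sum_t w_t over the tissues the
    individual was sampled in. Default weights are 1 for every tissue (the
    plain mean over available tissues).
    """
    if not z_by_tissue:
        raise ValueError("need at least one tissue Z-matrix")
    if weights is None:
        weights = {t: 1.0 for t in z_by_tissue}
    for tissue, w in weights.items():
        if w < 0:
            raise ValueError(f"negative weight for tissue {tissue!r}")
    used = {t: weights.get(t, 0.0) for t in z_by_tissue}
    if sum(used.values()) == 0.0:
        raise ValueError("all tissue weights are zero")

    per_tissue: dict[str, pd.Series] = {
        tissue: z.mean(axis=0) for tissue, z in z_by_tissue.items()
    }
    individuals = sorted({ind for s in per_tissue.values() for ind in s.index})
    states: list[EstrogenState] = []
    n_excluded = 0
    for ind in individuals:
        scores = {
            t: float(s[ind]) for t, s in per_tissue.items() if ind in s.index
        }
        total_w = sum(used[t] for t in scores)
        if total_w == 0.0:
            n_excluded += 1
            continue
        aggregate = sum(used[t] * v for t, v in scores.items()) / total_w
        states.append(
            EstrogenState(
                individual=ind, per_tissue_score=scores,
                aggregate_score=float(aggregate),
            )
        )
    if n_excluded:
        logger.warning(
            "score_individuals: %d individual(s) excluded (zero total weight "
            "over their available tissues)", n_excluded,
        )
    return states


def bin_individuals(
    states: Sequence[EstrogenState],
    method: str = "median",
    q: float = 0.5,
) -> list[EstrogenState]:
    """Split the cohort into high/low strata on the aggregate score.

    ``median`` assigns high iff score > cohort median (ties go low, so the
    split is deterministic); ``quantile`` uses the q-th quantile as the
    threshold instead.
    """
    if len(states) < 2:
        raise ValueError("need >=2 individuals to bin")
    scores = np.array([s.aggregate_score for s in states])
    if method == "median":
        threshold = float(np.median(scores))
    elif method == "quantile":
        if not 0.0 < q < 1.0:
            raise ValueError(f"quantile must be in (0,1), got {q}")
        threshold = float(np.quantile(scores, q))
    else:
        raise ValueError(f"unknown binning method {method!r}")
    binned = [
        dataclasses.replace(s, bin="high" if s.aggregate_score > threshold else "low")
        for s in states
    ]
    n_high = sum(s.bin == "high" for s in binned)
    logger.info(
        "bin_individuals: threshold=%.6g, %d high / %d low",
        threshold, n_high, len(binned) - n_high,
    )
    return binned


def infer_estrogen_states(
    tissues: Mapping[str, TissueExpression],
    signature: GeneSet,
    weights: Mapping[str, float] | None = None,
    method: str = "median",
    q: float = 0.5,
) -> list[EstrogenState]:
    """Z-score, aggregate and bin in one call (the pipeline's estrogen stage).

    Tissues where no signature gene is present are skipped with a warning;
    at least one tissue must carry the signature.
    """
    z_by_tissue: dict[str, pd.DataFrame] = {}
    for name, expr in tissues.items():
        try:
            z_by_tissue[name] = zscore_gene_set(expr, signature)
        except ValueError as exc:
            logger.warning("infer_estrogen_states: skipping tissue %s: %s", name, exc)
    if not z_by_tissue:
        raise ValueError("signature genes found in no tissue")
    states = score_individuals(z_by_tissue, weights=weights)
    return bin_individuals(states, method=method, q=q)


def states_to_frame(
    states: Sequence[EstrogenState], tissues: Sequence[str] | None = None
) -> pd.DataFrame:
    """Tabulate states: individual, per-tissue scores (NA = unsampled), aggregate, bin."""
    if tissues is None:
        tissues = sorted({t for s in states for t in s.per_tissue_score})
    rows = []
    for s in states:
        row: dict[str, object] = {"individual": s.individual}
        for t in tissues:
            row[f"score_{t}"] = s.per_tissue_score.get(t, np.nan)
        row["aggregate_score"] = s.aggregate_score
        row["bin"] = s.bin if s.bin is not None else ""
        rows.append(row)
    return pd.DataFrame(rows)


def write_states(
    states: Sequence[EstrogenState], path: str | Path,
    tissues: Sequence[str] | None = None,
) -> None:
    frame = states_to_frame(states, tissues)
    frame.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN,
                 float_format=FLOAT_FORMAT)


def read_states(path: str | Path) -> list[EstrogenState]:
    frame = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False)
    score_cols = [c for c in frame.columns if c.startswith("score_")]
    states = []
    for _, row in frame.iterrows():
        scores = {
            c[len("score_"):]: float(row[c])
            for c in score_cols if pd.notna(row[c])
        }
        bin_value = row["bin"] if row["bin"] in ("high", "low") else None
        states.append(
            EstrogenState(
                individual=str(row["individual"]),
                per_tissue_score=scores,
                aggregate_score=float(row["aggregate_score"]),
                bin=bin_value,
            )
        )
    return states
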