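"""Gene-level resources: expression matrices, gene sets, orthologs, count tables.

This module owns the plain-text interchange formats used throughout the
pipeline — per-tissue expression TSV (genes x individuals), MSigDB-style GMT
gene sets, a two-column mouse->human ortholog TSV, and a neuron count TSV —
plus the two selection operations built on them: the counts-above-reference
high-expression filter used to pick hypothalamic target genes, and ortholog
mapping from mouse to human symbol space.

All readers validate and reject malformed input rather than coercing it;
no NaN is ever introduced silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Recognised gene-set kinds. ``signature`` marks the estrogen-responsive set
#: used for cohort stratification; the middle four are the peripheral
#: functional categories whose cross-tissue correlations are compared.
CATEGORY_KINDS = ("signature", "secreted", "ligand", "peptide_hormone", "feeding", "other")

#: Token written for missing values in all TSV outputs.
NA_TOKEN = "NA"

#: Fixed float format for all TSV outputs: 17 significant digits round-trip
#: float64 losslessly, so re-reading a stage's files reproduces downstream
#: results exactly (bit-stable reruns and stage isolation).
FLOAT_FORMAT = "%.17g"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueExpression:
    """One tissue's genes x individuals matrix of log-scale expression.

    Parameters
    ----------
    tissue
        Tissue name (e.g. ``"adipose_subcutaneous"``).
    data
        DataFrame indexed by unique gene symbols with unique individual IDs
        as columns; every value finite. Only individuals with this tissue
        sampled appear as columns — donor-level missingness is encoded by
        column absence, never by NaN.
    """

    tissue: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError(f"tissue {self.tissue!r}: empty expression matrix")
        dup_genes = self.data.index[self.data.index.duplicated()].unique()
        if len(dup_genes):
            raise ValueError(
                f"tissue {self.tissue!r}: duplicate gene symbol {dup_genes[0]!r}"
            )
        dup_ids = self.data.columns[self.data.columns.duplicated()].unique()
        if len(dup_ids):
            raise ValueError(
                f"tissue {self.tissue!r}: duplicate individual ID {dup_ids[0]!r}"
            )
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError(f"tissue {self.tissue!r}: non-numeric values present")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"tissue {self.tissue!r}: non-finite values present")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def individuals(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols with a functional kind."""

    name: str
    genes: frozenset[str]
    category_kind: str = "other"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if self.category_kind not in CATEGORY_KINDS:
            raise ValueError(
                f"gene set {self.name!r}: unknown category_kind {self.category_kind!r}"
            )

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class OrthologMap:
    """Mouse symbol -> set of human symbols."""

    entries: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for mouse, humans in self.entries.items():
            if not humans:
                raise ValueError(f"ortholog map: empty target set for {mouse!r}")


@dataclass(frozen=True)
class NeuronCountTable:
    """Bulk RNA-seq counts from sorted neurons (genes x samples).

    The ``reference_gene`` (Gfap by default, an astrocyte marker) anchors the
    high-expression filter: genes whose mean count exceeds the reference are
    considered genuinely expressed in the sorted neuronal population.
    """

    data: pd.DataFrame
    reference_gene: str = "Gfap"

    def __post_init__(self) -> None:
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("neuron count table is empty")
        dup = self.data.index[self.data.index.duplicated()].unique()
        if len(dup):
            raise ValueError(f"neuron count table: duplicate gene {dup[0]!r}")
        if self.reference_gene not in self.data.index:
            raise ValueError(
                f"reference gene {self.reference_gene!r} absent from count table"
            )
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("neuron count table: non-numeric counts")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValueError("neuron count table: counts must be finite and >= 0")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)


# ---------------------------------------------------------------------------
# Expression TSV
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, tissue: str) -> TissueExpression:
    """Read a genes x individuals expression TSV.

    First column holds gene symbols; the header row holds individual IDs.
    Rows with any non-numeric cell cause a hard error naming the gene.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    ids = header[1:]
    seen: set[str] = set()
    for ident in ids:
        if ident in seen:
            raise ValueError(f"{path}: duplicate individual ID {ident!r}")
        seen.add(ident)
    # round_trip parsing keeps re-read values bit-identical to what was written
    raw = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    raw.index = raw.index.astype(str).str.strip()
    dup = raw.index[raw.index.duplicated()].unique()
    if len(dup):
        raise ValueError(f"{path}: duplicate gene symbol {dup[0]!r}")
    for col in raw.columns:
        if not np.issubdtype(raw[col].dtype, np.number):
            bad = raw.index[pd.to_numeric(raw[col], errors="coerce").isna()]
            raise ValueError(
                f"{path}: non-numeric value for gene {bad[0]!r} "
                f"(individual {col!r})"
            )
    return TissueExpression(tissue=tissue, data=raw.astype(float))


def write_expression(expr: TissueExpression, path: str | Path) -> None:
    """Write a TissueExpression as TSV (gene column first, fixed precision)."""
    expr.data.to_csv(path, sep="\t", index_label="gene", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members...).

    The description field doubles as the category kind when it matches one of
    ``CATEGORY_KINDS``; otherwise the set is kind ``other``. Duplicate members
    within a line are retained once with a logged warning. Lines with fewer
    than three fields are an error reported with their line number.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT line needs >=3 fields, got {len(fields)}"
                )
            name, description = fields[0].strip(), fields[1].strip()
            members = [g.strip() for g in fields[2:] if g.strip()]
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                logger.warning(
                    "%s: line %d (%s): %d duplicate member(s) collapsed",
                    path, lineno, name, len(members) - len(unique),
                )
            kind = description if description in CATEGORY_KINDS else "other"
            sets.append(GeneSet(name=name, genes=frozenset(unique), category_kind=kind))
    return sets


def write_gmt(gene_sets: Sequence[GeneSet], path: str | Path) -> None:
    """Write gene sets as GMT, with the kind in the description column."""
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.category_kind, *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# Ortholog map
# ---------------------------------------------------------------------------

def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a two-column TSV with header ``mouse_symbol<TAB>human_symbol``."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["mouse_symbol", "human_symbol"]
    if list(frame.columns[:2]) != expected:
        raise ValueError(f"{path}: expected header {expected}, got {list(frame.columns)}")
    entries: dict[str, set[str]] = {}
    for mouse, human in zip(frame["mouse_symbol"], frame["human_symbol"]):
        if pd.isna(mouse) or pd.isna(human):
            raise ValueError(f"{path}: blank symbol in ortholog table")
        entries.setdefault(mouse.strip(), set()).add(human.strip())
    return OrthologMap(entries={m: frozenset(h) for m, h in entries.items()})


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mouse_symbol\thuman_symbol\n")
        for mouse in sorted(omap.entries):
            for human in sorted(omap.entries[mouse]):
                fh.write(f"{mouse}\t{human}\n")


def map_orthologs(
    genes: Sequence[str], omap: OrthologMap, policy: str = "unique"
) -> list[str]:
    """Map mouse symbols to human symbols.

    Unmapped symbols are dropped (count logged). One-to-many entries are
    dropped under policy ``"unique"`` (the default) or expanded to all targets
    under ``"all"``. Output is deduplicated preserving first-seen order.
    """
    if policy not in ("unique", "all"):
        raise ValueError(f"unknown ortholog policy {policy!r}")
    out: list[str] = []
    n_unmapped = n_ambiguous = 0
    for gene in genes:
        targets = omap.entries.get(gene)
        if targets is None:
            n_unmapped += 1
            continue
        if len(targets) > 1:
            if policy == "unique":
                n_ambiguous += 1
                continue
            out.extend(sorted(targets))
        else:
            out.append(next(iter(targets)))
    if n_unmapped or n_ambiguous:
        logger.info(
            "map_orthologs: dropped %d unmapped and %d ambiguous symbol(s) "
            "(policy=%s)", n_unmapped, n_ambiguous, policy,
        )
    deduped = list(dict.fromkeys(out))
    if not deduped:
        logger.warning("map_orthologs: no symbols mapped")
    return deduped


# ---------------------------------------------------------------------------
# Neuron counts and the high-expression filter
# ---------------------------------------------------------------------------

def read_neuron_counts(path: str | Path, reference_gene: str = "Gfap") -> NeuronCountTable:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str).str.strip()
    return NeuronCountTable(data=frame, reference_gene=reference_gene)


def write_neuron_counts(table: NeuronCountTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="gene")


def filter_high_expressed(counts: NeuronCountTable) -> list[str]:
    """Genes whose mean count strictly exceeds the reference gene's mean.

    The comparison is on the per-gene mean across samples; the reference gene
    itself is excluded by the strict inequality. Input gene order is
    preserved. Invariant to rescaling all counts by a common positive factor.
    """
    means = counts.data.mean(axis=1)
    reference_mean = float(means[counts.reference_gene])
    kept = [
        gene
        for gene in counts.data.index
        if gene != counts.reference_gene and float(means[gene]) > reference_mean
    ]
    logger.info(
        "filter_high_expressed: %d/%d genes above %s",
        len(kept), counts.data.shape[0], counts.reference_gene,
    )
    return kept
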