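"""TF-gene binding tables from ChIP-seq peak intervals and TSS annotations.

A transcription factor is called *bound* to a gene when at least one of
its peaks, at or above a significance threshold, overlaps the window
``[tss - window, tss + window]`` around the gene's transcription start
site.  Peaks follow the BED convention (0-based, half-open); the TSS is a
0-based point and the window is closed and symmetric, so strand is
recorded but does not change the window.  Peak scores are MACS2-style
``-10*log10(Q)`` values; the defaults (window 5000 bp, score threshold
100) match common ChIP-seq enrichment practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 5000
DEFAULT_SCORE_THRESHOLD = 100.0


@dataclass(frozen=True)
class TssRecord:
    """Transcription start site of one gene (0-based genomic point)."""
    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self):
        if self.tss < 0:
            raise InvalidInputError(f"negative TSS for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise InvalidInputError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class PeakRecord:
    """One ChIP-seq peak for one TF, BED 0-based half-open coordinates."""
    tf_id: str
    chrom: str
    start: int
    end: int
    score: float

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise InvalidInputError(
                f"peak must satisfy 0 <= start < end, got [{self.start}, {self.end})")
        if self.score < 0:
            raise InvalidInputError(f"negative peak score {self.score}")


class BindingTable:
    """Binary TF x gene relation: does the TF bind near the gene's TSS.

    Stores an ordered TF list, an ordered gene list, and a boolean matrix
    (TFs on rows).  Row/column order is part of the identity of the table
    only insofar as downstream signatures align to ``tf_ids``.
    """

    def __init__(self, tf_ids: Sequence[str], gene_ids: Sequence[str],
                 matrix: np.ndarray):
        self.tf_ids = list(tf_ids)
        self.gene_ids = list(gene_ids)
        self.matrix = np.asarray(matrix, dtype=bool)
        if len(set(self.tf_ids)) != len(self.tf_ids):
            raise InvalidInputError("duplicate TF IDs")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InvalidInputError("duplicate gene IDs")
        if self.matrix.shape != (len(self.tf_ids), len(self.gene_ids)):
            raise InvalidInputError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.tf_ids)} TFs x {len(self.gene_ids)} genes")
        self._tf_index = {t: i for i, t in enumerate(self.tf_ids)}
        self._gene_index = {g: j for j, g in enumerate(self.gene_ids)}

    @property
    def n_tfs(self) -> int:
        return len(self.tf_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def is_bound(self, tf_id: str, gene_id: str) -> bool:
        return bool(self.matrix[self._tf_index[tf_id], self._gene_index[gene_id]])

    def bound_genes(self, tf_id: str) -> set:
        row = self.matrix[self._tf_index[tf_id]]
        return {g for g, b in zip(self.gene_ids, row) if b}

    def bound_tfs(self, gene_id: str) -> set:
        col = self.matrix[:, self._gene_index[gene_id]]
        return {t for t, b in zip(self.tf_ids, col) if b}

    def edges(self) -> list[tuple[str, str]]:
        rows, cols = np.nonzero(self.matrix)
        return [(self.tf_ids[i], self.gene_ids[j]) for i, j in zip(rows, cols)]

    def __eq__(self, other) -> bool:
        if not isinstance(other, BindingTable):
            return NotImplemented
        return (self.tf_ids == other.tf_ids and self.gene_ids == other.gene_ids
                and np.array_equal(self.matrix, other.matrix))

    def __repr__(self) -> str:
        return (f"BindingTable({self.n_tfs} TFs x {self.n_genes} genes, "
                f"{int(self.matrix.sum())} edges)")


def build_binding_table(peaks: Iterable[PeakRecord], tss: Sequence[TssRecord],
                        window: int = DEFAULT_WINDOW,
                        score_threshold: float = DEFAULT_SCORE_THRESHOLD,
                        tf_ids: Sequence[str] | None = None) -> BindingTable:
    """Assign TFs to genes by peak-TSS proximity.

    TF ``i`` binds gene ``j`` iff some peak of ``i`` with
    ``score >= score_threshold`` intersects the closed window
    ``[tss_j - window, tss_j + window]`` on the same chromosome.  Many
    experiments per TF simply pool: any qualifying peak binds.

    Parameters
    ----------
    tf_ids : optional
        Explicit TF universe (sorted order of observed TFs otherwise);
        lets callers keep TFs whose peaks were all filtered out.
    """
    if window < 0:
        raise InvalidInputError(f"window must be nonnegative, got {window}")
    if score_threshold < 0:
        raise InvalidInputError(f"score_threshold must be nonnegative, got {score_threshold}")
    gene_ids = [t.gene_id for t in tss]
    if len(set(gene_ids)) != len(gene_ids):
        raise InvalidInputError("duplicate gene_id in TSS table")

    peaks = list(peaks)
    if tf_ids is None:
        tf_ids = sorted({p.tf_id for p in peaks})
    tf_index = {t: i for i, t in enumerate(tf_ids)}
    tss_chroms = {t.chrom for t in tss}

    # One interval tree per (tf, chrom) over qualifying peaks; gene windows
    # are then point-range queries.  tree.overlap(lo, hi) matches half-open
    # [start, end) against [lo, hi), so querying [tss-window, tss+window+1)
    # realises the closed-window convention exactly.
    trees: dict[tuple[str, str], IntervalTree] = {}
    n_skipped = 0
    for p in peaks:
        if p.score < score_threshold:
            continue
        if p.chrom not in tss_chroms:
            n_skipped += 1
            continue
        trees.setdefault((p.tf_id, p.chrom), IntervalTree()).addi(p.start, p.end)
    if n_skipped:
        logger.info("ignored %d qualifying peaks on chromosomes absent from the TSS table",
                    n_skipped)

    matrix = np.zeros((len(tf_ids), len(tss)), dtype=bool)
    for j, rec in enumerate(tss):
        lo = max(rec.tss - window, 0)
        hi = rec.tss + window + 1
        for (tf, chrom), tree in trees.items():
            if chrom == rec.chrom and tree.overlap(lo, hi):
                matrix[tf_index[tf], j] = True
    return BindingTable(tf_ids, gene_ids, matrix)


# ---------------------------------------------------------------------------
# TSV / BED I/O

def read_tss_table(path) -> list[TssRecord]:
    """TSV with columns ``gene_id chrom tss strand``."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    required = {"gene_id", "chrom", "tss", "strand"}
    if not required <= set(df.columns):
        raise InvalidInputError(f"{path}: expected columns {sorted(required)}")
    return [TssRecord(r.gene_id, r.chrom, int(r.tss), r.strand)
            for r in df.itertuples(index=False)]


def write_tss_table(records: Iterable[TssRecord], path) -> None:
    pd.DataFrame([{"gene_id": r.gene_id, "chrom": r.chrom, "tss": r.tss,
                   "strand": r.strand} for r in records]).to_csv(path, sep="\t", index=False)


def read_peaks_bed(path, tf_id: str | None = None) -> list[PeakRecord]:
    """BED5+ (``chrom start end name score``); ``name`` is the TF unless overridden."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "score"],
                     usecols=range(5), dtype={"chrom": str, "name": str})
    return [PeakRecord(tf_id or r.name, r.chrom, int(r.start), int(r.end), float(r.score))
            for r in df.itertuples(index=False)]


def write_peaks_bed(peaks: Iterable[PeakRecord], path) -> None:
    pd.DataFrame([{"chrom": p.chrom, "start": p.start, "end": p.end,
                   "name": p.tf_id, "score": p.score} for p in peaks]
                 ).to_csv(path, sep="\t", index=False, header=False)


def read_peak_manifest(path, cell_type: str | None = None) -> list[PeakRecord]:
    """Manifest TSV (``tf_id cell_type bed_path``) pooling many BED files.

    ``cell_type`` optionally restricts to experiments from one cell type,
    mirroring per-disease selection of appropriate ChIP-seq contexts.
    Relative BED paths resolve against the manifest's directory.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"tf_id", "bed_path"}
    if not required <= set(df.columns):
        raise InvalidInputError(f"{path}: expected columns tf_id, bed_path")
    base = Path(path).parent
    peaks: list[PeakRecord] = []
    for r in df.itertuples(index=False):
        if cell_type is not None and getattr(r, "cell_type", None) != cell_type:
            continue
        bed = Path(r.bed_path)
        peaks.extend(read_peaks_bed(bed if bed.is_absolute() else base / bed,
                                    tf_id=r.tf_id))
    return peaks


def load_binding_table(path) -> BindingTable:
    """Load a table written as long-format TSV (``tf_id gene_id``) or a 0/1 matrix."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) == ["tf_id", "gene_id"]:
        tfs = sorted(df["tf_id"].dropna().unique())
        genes = sorted(df["gene_id"].dropna().unique())
        table = BindingTable(tfs, genes, np.zeros((len(tfs), len(genes)), dtype=bool))
        for r in df.itertuples(index=False):
            table.matrix[table._tf_index[r.tf_id], table._gene_index[r.gene_id]] = True
        return table
    mat = pd.read_csv(path, sep="\t", index_col=0)
    values = mat.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise InvalidInputError(f"{path}: matrix cells must be 0 or 1")
    return BindingTable([str(t) for t in mat.index], [str(g) for g in mat.columns],
                        values.astype(bool))


def write_binding_table(table: BindingTable, path, fmt: str = "long") -> None:
    """Write long-format (default) or wide 0/1 matrix TSV.

    Long format records edges only, so TFs or genes with no edges are not
    reconstructed by :func:`load_binding_table`; use ``fmt="matrix"`` when
    empty rows/columns must round-trip.
    """
    if fmt == "long":
        edges = table.edges()
        pd.DataFrame(edges, columns=["tf_id", "gene_id"]).to_csv(path, sep="\t", index=False)
    elif fmt == "matrix":
        pd.DataFrame(table.matrix.astype(int), index=table.tf_ids,
                     columns=table.gene_ids).rename_axis("tf_id").to_csv(path, sep="\t")
    else:
        raise InvalidInputError(f"unknown format {fmt!r}")
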