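"""Transcriptome signatures: per-gene differential-expression score vectors.

A transcriptome signature holds one score per gene for a single entity
(a drug treatment or a disease-vs-control contrast).  Scores are unitless
differential statistics: LINCS-style moderated Z-scores for drugs,
Characteristic-Direction scores or tumor/normal log2 fold changes for
diseases.  Downstream enrichment consumes only the identity and direction
of regulated genes, so this module also extracts up/down gene sets and
provides the standard preprocessing steps: top/bottom-fraction
sparsification, replicate averaging, and log2 fold change.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError

logger = logging.getLogger(__name__)

Role = Literal["drug", "disease"]

DEFAULT_FRACTION = 0.05


@dataclass
class TranscriptomeSignature:
    """Per-gene score vector for one drug or disease.

    Parameters
    ----------
    entity_id : str
        Opaque identifier of the drug or disease.
    role : {"drug", "disease"}
    genes : sequence of str
        Unique gene identifiers; order is preserved through all operations.
    scores : array-like of float
        Scores aligned to ``genes``; must be finite.
    """

    entity_id: str
    role: str
    genes: np.ndarray
    scores: np.ndarray

    def __post_init__(self):
        self.genes = np.asarray(self.genes, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.role not in ("drug", "disease"):
            raise InvalidInputError(f"role must be 'drug' or 'disease', got {self.role!r}")
        if self.genes.shape != self.scores.shape or self.genes.ndim != 1:
            raise InvalidInputError("genes and scores must be 1-D and equal length")
        if len(set(self.genes)) != len(self.genes):
            raise InvalidInputError(f"duplicate gene IDs in signature {self.entity_id!r}")
        if not np.all(np.isfinite(self.scores)):
            raise InvalidInputError(f"non-finite score in signature {self.entity_id!r}")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def series(self) -> pd.Series:
        """Scores as a pandas Series indexed by gene ID."""
        return pd.Series(self.scores, index=self.genes, name=self.entity_id)

    @classmethod
    def from_series(cls, s: pd.Series, entity_id: str, role: str) -> "TranscriptomeSignature":
        return cls(entity_id=entity_id, role=role,
                   genes=np.asarray(s.index, dtype=object),
                   scores=s.to_numpy(dtype=float))

    def replace_scores(self, scores: np.ndarray) -> "TranscriptomeSignature":
        return TranscriptomeSignature(self.entity_id, self.role, self.genes.copy(), scores)


@dataclass
class RegulatedGeneSets:
    """Up- and down-regulated gene sets extracted from one signature.

    For drug signatures these are the top/bottom-fraction genes; for
    disease signatures they are the positively and negatively scored
    (over-expressed and repressed) genes.
    """

    up: set = field(default_factory=set)
    down: set = field(default_factory=set)
    source_entity: str = ""

    def __post_init__(self):
        self.up = set(self.up)
        self.down = set(self.down)
        if self.up & self.down:
            raise InvalidInputError(
                f"up/down sets overlap for {self.source_entity!r}: {sorted(self.up & self.down)[:5]}")

    @property
    def is_empty(self) -> bool:
        return not self.up and not self.down


def _tail_order(sig: TranscriptomeSignature) -> np.ndarray:
    # Single total order: ascending (score, gene_id).  Bottom tail = head,
    # top tail = tail of this order; the two never overlap for fraction <= 0.5.
    return np.lexsort((sig.genes.astype(str), sig.scores))


def sparsify_signature(sig: TranscriptomeSignature,
                       fraction: float = DEFAULT_FRACTION) -> TranscriptomeSignature:
    """Keep only the top- and bottom-``fraction`` genes by score, zero the rest.

    Retains ``floor(fraction * n)`` genes on each side.  Ties at the rank
    boundary are broken by ascending gene-ID lexicographic order, making
    the result deterministic.

    Raises
    ------
    InvalidParameterError
        If ``fraction`` is not in (0, 0.5].
    """
    if not (0.0 < fraction <= 0.5):
        raise InvalidParameterError(f"fraction must be in (0, 0.5], got {fraction}")
    n = len(sig)
    k = math.floor(fraction * n)
    order = _tail_order(sig)
    keep = np.zeros(n, dtype=bool)
    if k > 0:
        keep[order[:k]] = True
        keep[order[-k:]] = True
    return sig.replace_scores(np.where(keep, sig.scores, 0.0))


def extract_regulated_sets(sig: TranscriptomeSignature,
                           mode: Literal["top_bottom_fraction", "sign"] = "top_bottom_fraction",
                           fraction: float = DEFAULT_FRACTION) -> RegulatedGeneSets:
    """Extract up/down gene sets from a signature.

    ``top_bottom_fraction`` takes the top-``fraction`` genes as up and the
    bottom-``fraction`` as down (drug convention); ``sign`` takes strictly
    positive genes as up and strictly negative as down (disease
    convention).  Genes scoring exactly zero are never included.
    """
    if mode == "sign":
        up = set(sig.genes[sig.scores > 0])
        down = set(sig.genes[sig.scores < 0])
    elif mode == "top_bottom_fraction":
        if not (0.0 < fraction <= 0.5):
            raise InvalidParameterError(f"fraction must be in (0, 0.5], got {fraction}")
        k = math.floor(fraction * len(sig))
        order = _tail_order(sig)
        top = order[len(sig) - k:] if k > 0 else order[:0]
        bottom = order[:k]
        up = set(sig.genes[top][sig.scores[top] > 0])
        down = set(sig.genes[bottom][sig.scores[bottom] < 0])
    else:
        raise InvalidParameterError(f"unknown mode {mode!r}")
    sets = RegulatedGeneSets(up=up, down=down, source_entity=sig.entity_id)
    if sets.is_empty:
        logger.warning("signature %r yields empty up and down sets", sig.entity_id)
    return sets


def average_signatures(sigs: Sequence[TranscriptomeSignature],
                       method: Literal["mean", "median"] = "mean",
                       entity_id: str | None = None) -> TranscriptomeSignature:
    """Aggregate replicate signatures for the same entity.

    The result is defined on the union of the gene universes.  A gene
    absent from a signature is treated as missing for that signature and
    excluded from its average — zero is a meaningful score (no regulation)
    and is never imputed.
    """
    if not sigs:
        raise InvalidInputError("cannot average an empty list of signatures")
    roles = {s.role for s in sigs}
    if len(roles) != 1:
        raise InvalidInputError(f"signatures mix roles: {sorted(roles)}")
    if method not in ("mean", "median"):
        raise InvalidParameterError(f"method must be 'mean' or 'median', got {method!r}")
    frame = pd.concat([s.series for s in sigs], axis=1, join="outer", sort=False)
    agg = frame.mean(axis=1) if method == "mean" else frame.median(axis=1)
    return TranscriptomeSignature(
        entity_id=entity_id or sigs[0].entity_id,
        role=sigs[0].role,
        genes=np.asarray(agg.index, dtype=object),
        scores=agg.to_numpy(dtype=float),
    )


def log2_fold_change(case_mean: Mapping[str, float],
                     control_mean: Mapping[str, float],
                     pseudocount: float = 1.0,
                     entity_id: str = "",
                     role: str = "disease") -> TranscriptomeSignature:
    """log2((case + pc) / (control + pc)) per gene, on a shared gene universe.

    Expression values must be nonnegative normalized abundances (e.g.
    FPKM-UQ); the pseudocount keeps zero-expression genes finite.
    """
    if pseudocount <= 0:
        raise InvalidParameterError(f"pseudocount must be > 0, got {pseudocount}")
    if set(case_mean) != set(control_mean):
        raise InvalidInputError("case and control must share the same gene universe")
    genes = sorted(case_mean)
    case = np.array([case_mean[g] for g in genes], dtype=float)
    ctrl = np.array([control_mean[g] for g in genes], dtype=float)
    if (case < 0).any() or (ctrl < 0).any():
        raise InvalidInputError("expression values must be nonnegative")
    scores = np.log2((case + pseudocount) / (ctrl + pseudocount))
    return TranscriptomeSignature(entity_id=entity_id, role=role,
                                  genes=np.asarray(genes, dtype=object), scores=scores)


# ---------------------------------------------------------------------------
# TSV I/O

def read_signature_tsv(path, entity_id: str | None = None, role: str = "drug") -> TranscriptomeSignature:
    """Read a single-signature TSV with columns ``gene_id`` and ``score``."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if not {"gene_id", "score"} <= set(df.columns):
        raise InvalidInputError(f"{path}: expected columns gene_id, score")
    return TranscriptomeSignature(
        entity_id=entity_id or str(path), role=role,
        genes=df["gene_id"].to_numpy(dtype=object),
        scores=df["score"].to_numpy(dtype=float))


def write_signature_tsv(sig: TranscriptomeSignature, path) -> None:
    pd.DataFrame({"gene_id": sig.genes, "score": sig.scores}).to_csv(path, sep="\t", index=False)


def read_signature_matrix(matrix_path, metadata_path=None,
                          default_role: str = "drug") -> list[TranscriptomeSignature]:
    """Read a wide matrix TSV (rows: genes, columns: entity IDs).

    An optional sidecar metadata TSV with columns ``entity_id`` and
    ``role`` assigns the drug/disease role per column; otherwise every
    column gets ``default_role``.
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    roles = {}
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
        roles = dict(zip(meta["entity_id"], meta["role"]))
    return [
        TranscriptomeSignature(
            entity_id=str(col), role=roles.get(str(col), default_role),
            genes=np.asarray(mat.index, dtype=object),
            scores=mat[col].to_numpy(dtype=float))
        for col in mat.columns
    ]


def write_signature_matrix(sigs: Iterable[TranscriptomeSignature], matrix_path,
                           metadata_path=None) -> None:
    sigs = list(sigs)
    frame = pd.concat([s.series for s in sigs], axis=1, join="outer", sort=False)
    frame.index.name = "gene_id"
    frame.to_csv(matrix_path, sep="\t")
    if metadata_path is not None:
        pd.DataFrame({"entity_id": [s.entity_id for s in sigs],
                      "role": [s.role for s in sigs]}).to_csv(metadata_path, sep="\t", index=False)
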