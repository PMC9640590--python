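"""Signed TF-enrichment scores and regulome signatures.

Each transcription factor is tested for over-representation among a
signature's regulated genes with a 2x2 contingency table

    =============  ======  ==========
    .              bound   not bound
    up genes       a       b
    down genes     c       d
    =============  ======  ==========

scored by Fisher's exact test (two-sided by default) and corrected for
multiple testing across the TFs of the signature with Benjamini-Hochberg.
Direction comes from the fold enrichment

    FE = ((a + pc) / (a + b + 2 pc)) / ((c + pc) / (c + d + 2 pc)),

the ratio of bound fractions among up vs down genes with a pseudocount
``pc`` (default 0.5) per cell: FE > 1 means the TF leans to the
upregulated genes.  The signed enrichment score is

    score = +|log10(q)|  if FE >= 1,   -|log10(q)|  if FE < 1,

with q the FDR-corrected p-value.  A regulome signature is the vector of
these scores over all TFs in the binding table: it summarises which
regulators drive a drug's or disease's expression change, and is what
downstream drug-disease correlation is computed on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .binding import BindingTable
from .errors import InvalidInputError, InvalidParameterError
from .signatures import RegulatedGeneSets

logger = logging.getLogger(__name__)

#: |log10 q| is capped here so that q underflowing to 0 stays finite.
SCORE_CAP = 320.0

DEFAULT_FE_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class ContingencyTable:
    """Gene counts for one TF: (up, down) x (bound, unbound)."""
    a: int  # up & bound
    b: int  # up & not bound
    c: int  # down & bound
    d: int  # down & not bound

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InvalidInputError("contingency cells must be nonnegative")

    @property
    def m(self) -> int:
        """Total number of regulated genes."""
        return self.a + self.b + self.c + self.d

    def swapped(self) -> "ContingencyTable":
        """The table with up and down swapped."""
        return ContingencyTable(self.c, self.d, self.a, self.b)


@dataclass
class EnrichmentResult:
    """Full per-TF enrichment record."""
    tf_id: str
    table: ContingencyTable
    fe: float
    p_raw: float
    q: float
    score: float


@dataclass
class RegulomeSignature:
    """Per-TF signed enrichment score vector for one drug or disease."""
    entity_id: str
    role: str
    tf_ids: np.ndarray
    scores: np.ndarray

    def __post_init__(self):
        self.tf_ids = np.asarray(self.tf_ids, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.tf_ids.shape != self.scores.shape or self.tf_ids.ndim != 1:
            raise InvalidInputError("tf_ids and scores must be 1-D and equal length")
        if len(set(self.tf_ids)) != len(self.tf_ids):
            raise InvalidInputError(f"duplicate TF IDs in signature {self.entity_id!r}")
        if not np.all(np.isfinite(self.scores)):
            raise InvalidInputError(f"non-finite score in signature {self.entity_id!r}")

    def __len__(self) -> int:
        return len(self.tf_ids)

    @property
    def series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.tf_ids, name=self.entity_id)


def contingency(tf_id: str, sets: RegulatedGeneSets,
                binding: BindingTable) -> ContingencyTable:
    """Count the 2x2 table for one TF.

    Regulated genes outside the binding table's gene universe are dropped
    (and logged): the test is only defined over genes whose binding status
    is known.
    """
    universe = set(binding.gene_ids)
    up = sets.up & universe
    down = sets.down & universe
    n_dropped = len(sets.up) + len(sets.down) - len(up) - len(down)
    if n_dropped:
        logger.debug("%s: %d regulated genes outside binding universe dropped",
                     sets.source_entity, n_dropped)
    bound = binding.bound_genes(tf_id)
    a = len(up & bound)
    c = len(down & bound)
    return ContingencyTable(a, len(up) - a, c, len(down) - c)


def fisher_p(t: ContingencyTable, alternative: str = "two-sided") -> float:
    """Fisher exact p-value for one contingency table.

    Two-sided by default: the sum of hypergeometric point probabilities,
    over all tables with the observed margins, that do not exceed the
    observed one (to within a small relative tolerance).  Degenerate
    margins (no up genes, no down genes, or an empty table) give p = 1.
    """
    if t.m == 0 or t.a + t.b == 0 or t.c + t.d == 0:
        return 1.0
    return float(fisher_exact([[t.a, t.b], [t.c, t.d]], alternative=alternative)[1])


def fold_enrichment(t: ContingencyTable,
                    pseudocount: float = DEFAULT_FE_PSEUDOCOUNT) -> float:
    """Ratio of bound fractions among up vs down genes, pseudocounted.

    FE > 1: binding leans to the upregulated genes; FE < 1: to the
    downregulated.  The pseudocount (added to every cell) keeps FE finite
    and positive even with empty cells.
    """
    if pseudocount < 0:
        raise InvalidParameterError(f"pseudocount must be >= 0, got {pseudocount}")
    up_frac = (t.a + pseudocount) / (t.a + t.b + 2 * pseudocount)
    down_frac = (t.c + pseudocount) / (t.c + t.d + 2 * pseudocount)
    return up_frac / down_frac


def fdr_correct(pvals: Mapping[str, float]) -> dict[str, float]:
    """Benjamini-Hochberg step-up adjustment over one signature's TFs."""
    if not pvals:
        return {}
    keys = list(pvals)
    raw = np.array([pvals[k] for k in keys], dtype=float)
    if (raw <= 0).any() or (raw > 1).any():
        raise InvalidInputError("p-values must be in (0, 1]")
    q = multipletests(raw, method="fdr_bh")[1]
    return dict(zip(keys, np.minimum(q, 1.0)))


def enrichment_score(q: float, fe: float, cap: float = SCORE_CAP) -> float:
    """Signed score: +|log10 q| if FE >= 1 else -|log10 q|, magnitude capped."""
    if q <= 0:
        raise InvalidInputError(f"q must be in (0, 1], got {q}")
    magnitude = min(abs(math.log10(q)), cap)
    return magnitude if fe >= 1.0 else -magnitude


def enrich_tfs(sets: RegulatedGeneSets, binding: BindingTable,
               alternative: str = "two-sided",
               fe_pseudocount: float = DEFAULT_FE_PSEUDOCOUNT) -> list[EnrichmentResult]:
    """Run the full per-TF pipeline: contingency -> Fisher -> BH -> signed score.

    The FDR family is the set of TFs in ``binding`` — one multiple-testing
    correction per signature.
    """
    tables = {tf: contingency(tf, sets, binding) for tf in binding.tf_ids}
    pvals = {tf: fisher_p(t, alternative=alternative) for tf, t in tables.items()}
    qvals = fdr_correct(pvals)
    out = []
    for tf in binding.tf_ids:
        fe = fold_enrichment(tables[tf], pseudocount=fe_pseudocount)
        out.append(EnrichmentResult(
            tf_id=tf, table=tables[tf], fe=fe, p_raw=pvals[tf], q=qvals[tf],
            score=enrichment_score(qvals[tf], fe)))
    return out


def build_regulome_signature(sets: RegulatedGeneSets, binding: BindingTable,
                             entity_id: str, role: str,
                             alternative: str = "two-sided",
                             fe_pseudocount: float = DEFAULT_FE_PSEUDOCOUNT) -> RegulomeSignature:
    """Convert regulated gene sets into a signed regulome signature.

    One score per TF in ``binding.tf_ids``, in that order.  A degenerate
    input (no regulated genes inside the binding universe) yields an
    all-zero vector with a warning rather than an error, so that bulk
    conversion of many signatures does not abort on one empty one.
    """
    if binding.n_tfs == 0:
        raise InvalidInputError("binding table has no TFs")
    universe = set(binding.gene_ids)
    if not ((sets.up | sets.down) & universe):
        logger.warning("signature %r: no regulated genes in binding universe; "
                       "all-zero regulome signature", entity_id)
        return RegulomeSignature(entity_id, role, np.asarray(binding.tf_ids, dtype=object),
                                 np.zeros(binding.n_tfs))
    results = enrich_tfs(sets, binding, alternative=alternative,
                         fe_pseudocount=fe_pseudocount)
    return RegulomeSignature(entity_id, role,
                             np.asarray([r.tf_id for r in results], dtype=object),
                             np.asarray([r.score for r in results], dtype=float))


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results (one row per TF)."""
    return pd.DataFrame([{
        "tf_id": r.tf_id, "a": r.table.a, "b": r.table.b, "c": r.table.c,
        "d": r.table.d, "fe": r.fe, "p_raw": r.p_raw, "q": r.q, "score": r.score,
    } for r in results])


# ---------------------------------------------------------------------------
# TSV I/O

def read_regulome_tsv(path, entity_id: str | None = None, role: str = "drug") -> RegulomeSignature:
    df = pd.read_csv(path, sep="\t", dtype={"tf_id": str})
    if not {"tf_id", "score"} <= set(df.columns):
        raise InvalidInputError(f"{path}: expected columns tf_id, score")
    return RegulomeSignature(entity_id or str(path), role,
                             df["tf_id"].to_numpy(dtype=object),
                             df["score"].to_numpy(dtype=float))


def write_regulome_tsv(sig: RegulomeSignature, path) -> None:
    pd.DataFrame({"tf_id": sig.tf_ids, "score": sig.scores}).to_csv(path, sep="\t", index=False)


def read_regulome_matrix(matrix_path, metadata_path=None,
                         default_role: str = "drug") -> list[RegulomeSignature]:
    """Wide matrix TSV: rows TFs, columns entity IDs; optional role sidecar."""
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    roles = {}
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
        roles = dict(zip(meta["entity_id"], meta["role"]))
    return [RegulomeSignature(str(col), roles.get(str(col), default_role),
                              np.asarray(mat.index, dtype=object),
                              mat[col].to_numpy(dtype=float))
            for col in mat.columns]


def write_regulome_matrix(sigs: Iterable[RegulomeSignature], matrix_path,
                          metadata_path=None) -> None:
    sigs = list(sigs)
    frame = pd.concat([s.series for s in sigs], axis=1, join="outer", sort=False)
    frame.index.name = "tf_id"
    frame.to_csv(matrix_path, sep="\t")
    if metadata_path is not None:
        pd.DataFrame({"entity_id": [s.entity_id for s in sigs],
                      "role": [s.role for s in sigs]}).to_csv(metadata_path, sep="\t", index=False)
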