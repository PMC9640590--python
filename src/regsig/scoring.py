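"""Drug-disease prediction scores and approved-drug evaluation.

Transcriptome-level scoring follows the classical connectivity-map idea:
a drug is a candidate when its induced expression changes reverse the
disease's, so the prediction score is S_trans = -cos(x, y) over the
shared gene universe.

Regulome-level scoring is sign-conditional: diseases differ in whether
their approved drugs correlate positively (e.g. immune diseases) or
negatively (e.g. cancers) with the disease regulome signature.  The
disease's *polarity* is the sign of the median cosine between the disease
and its approved drugs' regulome signatures (median >= 0 -> positive);
the prediction score is then S_reg = +cos for positive polarity and
-cos for negative, so that drugs correlating in the therapeutic
direction rank highest either way.

Cosines are always computed on the strict intersection of the two ID
universes; missing IDs are never zero-imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import wilcoxon

from .enrichment import RegulomeSignature
from .errors import InvalidInputError
from .signatures import TranscriptomeSignature

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Approved-drug map and class priors

class ApprovedDrugMap(dict):
    """disease_id -> set of approved drug IDs."""

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "ApprovedDrugMap":
        out = cls()
        for disease, drug in pairs:
            out.setdefault(disease, set()).add(drug)
        return out

    @classmethod
    def read_tsv(cls, path) -> "ApprovedDrugMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"disease_id", "drug_id"} <= set(df.columns):
            raise InvalidInputError(f"{path}: expected columns disease_id, drug_id")
        return cls.from_pairs(zip(df["disease_id"], df["drug_id"]))

    def write_tsv(self, path) -> None:
        rows = [(dis, drug) for dis in sorted(self) for drug in sorted(self[dis])]
        pd.DataFrame(rows, columns=["disease_id", "drug_id"]).to_csv(path, sep="\t", index=False)


#: Default disease-class polarity priors for diseases without approved
#: drugs: cancers tend to anticorrelate with their drugs' regulomes,
#: immune diseases to correlate.
DEFAULT_CLASS_PRIORS = {"neoplasm": "negative", "immune": "positive"}


def read_class_priors(path) -> dict[str, str]:
    """YAML mapping ``disease_class: polarity``."""
    with open(path) as fh:
        priors = yaml.safe_load(fh) or {}
    for cls_name, pol in priors.items():
        if pol not in ("positive", "negative"):
            raise InvalidInputError(f"prior for {cls_name!r} must be positive/negative")
    return priors


# ---------------------------------------------------------------------------
# Cosine on aligned universes

def cosine_aligned(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine of two already-aligned vectors; 0.0 if either is a zero vector."""
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        logger.debug("degenerate cosine: zero vector")
        return 0.0
    return float(np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0))


def _align(ids_x, scores_x, ids_y, scores_y):
    sx = pd.Series(scores_x, index=ids_x)
    sy = pd.Series(scores_y, index=ids_y)
    common = sx.index.intersection(sy.index)
    if len(common) == 0:
        raise InvalidInputError("ID universes do not intersect")
    return sx.loc[common].to_numpy(), sy.loc[common].to_numpy()


def cosine(sig_x, sig_y) -> float:
    """Cosine correlation of two signatures on their shared ID universe.

    Works for both transcriptome (gene-indexed) and regulome (TF-indexed)
    signatures.  Raises if the universes are disjoint; returns 0.0 when
    either restricted vector is all zeros.
    """
    ids_x = sig_x.genes if isinstance(sig_x, TranscriptomeSignature) else sig_x.tf_ids
    ids_y = sig_y.genes if isinstance(sig_y, TranscriptomeSignature) else sig_y.tf_ids
    x, y = _align(ids_x, sig_x.scores, ids_y, sig_y.scores)
    return cosine_aligned(x, y)


def score_transcriptome(drug: TranscriptomeSignature,
                        disease: TranscriptomeSignature) -> float:
    """Connectivity-style score: -cos; higher = stronger signature reversal."""
    return -cosine(drug, disease)


def disease_polarity(disease_id: str, approved: ApprovedDrugMap,
                     disease_sig: RegulomeSignature,
                     drug_sigs: Mapping[str, RegulomeSignature],
                     exclude_drug: str | None = None) -> str:
    """Polarity of one disease from its approved drugs' regulome cosines.

    ``positive`` iff the median cosine between the disease signature and
    its approved drugs' signatures is >= 0.0.  ``exclude_drug`` supports
    leave-one-out evaluation (recompute polarity without the drug being
    scored); by default all approved drugs contribute.

    Returns ``"unset"`` when no approved drug with a regulome signature
    remains — the caller must then fall back to a class prior.
    """
    drugs = [d for d in approved.get(disease_id, set())
             if d in drug_sigs and d != exclude_drug]
    if not drugs:
        return "unset"
    cosines = [cosine(drug_sigs[d], disease_sig) for d in sorted(drugs)]
    return "positive" if float(np.median(cosines)) >= 0.0 else "negative"


def score_regulome(drug: RegulomeSignature, disease: RegulomeSignature,
                   polarity: str) -> float:
    """Sign-conditional regulome score: +cos (positive polarity) or -cos."""
    if polarity not in ("positive", "negative"):
        raise InvalidInputError(f"polarity must be resolved, got {polarity!r}")
    c = cosine(drug, disease)
    return c if polarity == "positive" else -c


# ---------------------------------------------------------------------------
# Score tables

@dataclass
class ScoreTable:
    """Drug x disease prediction-score matrix for one scoring level."""
    scores: pd.DataFrame  # rows: drug_id, columns: disease_id
    level: str  # "transcriptome" | "regulome"
    polarity: dict = field(default_factory=dict)  # disease_id -> polarity

    def __post_init__(self):
        if self.level not in ("transcriptome", "regulome"):
            raise InvalidInputError(f"unknown level {self.level!r}")
        values = self.scores.to_numpy(dtype=float)
        if values.size and (np.abs(values) > 1 + 1e-12).any():
            raise InvalidInputError("scores must lie in [-1, 1]")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def disease_ids(self) -> list[str]:
        return list(self.scores.columns)

    def to_long(self) -> pd.DataFrame:
        long = (self.scores.rename_axis("drug_id")
                .reset_index()
                .melt(id_vars="drug_id", var_name="disease_id", value_name="score"))
        long["level"] = self.level
        long["polarity"] = long["disease_id"].map(lambda d: self.polarity.get(d, "unset"))
        return long.sort_values(["disease_id", "drug_id"]).reset_index(drop=True)

    def write_tsv(self, path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read_tsv(cls, path) -> "ScoreTable":
        long = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "disease_id": str})
        levels = long["level"].unique()
        if len(levels) != 1:
            raise InvalidInputError(f"{path}: expected one scoring level, got {list(levels)}")
        scores = long.pivot(index="drug_id", columns="disease_id", values="score")
        polarity = dict(long.drop_duplicates("disease_id")[["disease_id", "polarity"]]
                        .itertuples(index=False))
        return cls(scores=scores, level=str(levels[0]),
                   polarity={k: v for k, v in polarity.items() if v != "unset"})


def score_table_transcriptome(drugs: Sequence[TranscriptomeSignature],
                              diseases: Sequence[TranscriptomeSignature]) -> ScoreTable:
    """All-pairs S_trans table."""
    mat = pd.DataFrame(
        {dis.entity_id: [score_transcriptome(drug, dis) for drug in drugs]
         for dis in diseases},
        index=[d.entity_id for d in drugs])
    return ScoreTable(scores=mat, level="transcriptome")


def score_table_regulome(drugs: Sequence[RegulomeSignature],
                         diseases: Sequence[RegulomeSignature],
                         approved: ApprovedDrugMap,
                         class_priors: Mapping[str, str] | None = None,
                         disease_classes: Mapping[str, str] | None = None,
                         leave_one_out: bool = False) -> ScoreTable:
    """All-pairs S_reg table with per-disease polarity.

    Polarity comes from the median approved-drug cosine; diseases without
    approved drugs fall back to ``class_priors[disease_classes[id]]`` and
    an explicit prior is required (error otherwise).  With
    ``leave_one_out``, an approved drug's own score uses the polarity
    recomputed without it.
    """
    drug_index = {d.entity_id: d for d in drugs}
    columns = {}
    polarity = {}
    for dis in diseases:
        pol = disease_polarity(dis.entity_id, approved, dis, drug_index)
        if pol == "unset":
            cls_name = (disease_classes or {}).get(dis.entity_id)
            pol = (class_priors or {}).get(cls_name, "unset")
            if pol == "unset":
                raise InvalidInputError(
                    f"disease {dis.entity_id!r} has no approved drugs with regulome "
                    f"signatures and no class prior; supply one")
        polarity[dis.entity_id] = pol
        col = []
        for drug in drugs:
            use_pol = pol
            if leave_one_out and drug.entity_id in approved.get(dis.entity_id, set()):
                loo = disease_polarity(dis.entity_id, approved, dis, drug_index,
                                       exclude_drug=drug.entity_id)
                if loo != "unset":
                    use_pol = loo
            col.append(score_regulome(drug, dis, use_pol))
        columns[dis.entity_id] = col
    mat = pd.DataFrame(columns, index=[d.entity_id for d in drugs])
    return ScoreTable(scores=mat, level="regulome", polarity=polarity)


# ---------------------------------------------------------------------------
# Ranking and evaluation

def rank_drugs(disease_id: str, table: ScoreTable) -> list[tuple[str, float, int]]:
    """Drugs ordered by descending score for one disease.

    Ties share the minimum (competition) rank; listing order among ties is
    ascending drug ID.
    """
    if disease_id not in table.scores.columns:
        raise InvalidInputError(f"unknown disease {disease_id!r}")
    col = table.scores[disease_id].sort_index()
    ranks = col.rank(method="min", ascending=False).astype(int)
    ordered = col.sort_values(ascending=False, kind="mergesort")
    return [(drug, float(score), int(ranks[drug])) for drug, score in ordered.items()]


@dataclass
class SeparationResult:
    """Approved-vs-other score separation across diseases."""
    deltas: pd.Series          # per-disease: median(approved) - median(other)
    approved_medians: pd.Series
    other_medians: pd.Series
    statistic: float           # Wilcoxon signed-rank statistic
    p_value: float
    degenerate: bool           # all paired differences were zero
    excluded: list             # diseases lacking approved or other drugs

    def summary(self) -> str:
        lines = [
            f"diseases evaluated: {len(self.deltas)} (excluded: {len(self.excluded)})",
            f"positive deltas (approved > other): {(self.deltas > 0).sum()}/{len(self.deltas)}",
            f"median delta: {self.deltas.median():+.4f}",
            f"Wilcoxon signed-rank: statistic={self.statistic:.1f}, p={self.p_value:.3g}"
            + (" [degenerate: all differences zero]" if self.degenerate else ""),
        ]
        return "\n".join(lines)


def evaluate_separation(table: ScoreTable, approved: ApprovedDrugMap,
                        statistic: str = "median") -> SeparationResult:
    """Do approved drugs outscore other drugs, disease by disease?

    Per disease the delta is median(approved scores) - median(other
    scores) (mean available via ``statistic="mean"``); across diseases a
    two-sided Wilcoxon signed-rank test is applied to the paired
    (approved, other) group summaries.  Diseases lacking either group are
    excluded and reported.
    """
    if statistic not in ("median", "mean"):
        raise InvalidInputError(f"statistic must be 'median' or 'mean', got {statistic!r}")
    agg = np.median if statistic == "median" else np.mean
    drug_set = set(table.drug_ids)
    app_med, oth_med, excluded = {}, {}, []
    for disease in table.disease_ids:
        approved_here = approved.get(disease, set()) & drug_set
        others = drug_set - approved_here
        if not approved_here or not others:
            excluded.append(disease)
            logger.info("disease %r excluded from separation: approved=%d others=%d",
                        disease, len(approved_here), len(others))
            continue
        col = table.scores[disease]
        app_med[disease] = float(agg(col.loc[sorted(approved_here)]))
        oth_med[disease] = float(agg(col.loc[sorted(others)]))
    if len(app_med) < 2:
        raise InvalidInputError("need >= 2 evaluable diseases for the signed-rank test")
    approved_medians = pd.Series(app_med).sort_index()
    other_medians = pd.Series(oth_med).sort_index()
    deltas = approved_medians - other_medians
    if np.allclose(deltas, 0.0):
        logger.warning("degenerate separation test: all paired differences are zero")
        return SeparationResult(deltas, approved_medians, other_medians,
                                statistic=0.0, p_value=1.0, degenerate=True,
                                excluded=excluded)
    stat, p = wilcoxon(approved_medians.to_numpy(), other_medians.to_numpy(),
                       alternative="two-sided")
    return SeparationResult(deltas, approved_medians, other_medians,
                            statistic=float(stat), p_value=float(p),
                            degenerate=False, excluded=excluded)
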