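import numpy as np
import pandas as pd
import pytest

from regsig import (ApprovedDrugMap, InvalidInputError, RegulomeSignature,
                    ScoreTable, TranscriptomeSignature, cosine,
                    disease_polarity, evaluate_separation, rank_drugs,
                    score_regulome, score_table_regulome,
                    score_table_transcriptome, score_transcriptome)


def reg(entity, scores, tf_ids=None, role="drug"):
    tf_ids = tf_ids or [f"TF{i}" for i in range(len(scores))]
    return RegulomeSignature(entity, role, np.array(tf_ids, dtype=object),
                             np.array(scores, dtype=float))


def trans(entity, scores, genes=None, role="drug"):
    genes = genes or [f"g{i}" for i in range(len(scores))]
    return TranscriptomeSignature(entity, role, np.array(genes, dtype=object),
                                  np.array(scores, dtype=float))


class TestCosine:
    def test_identity_negation_orthogonality(self):
        x = reg("x", [1.0, 2.0, -1.0])
        assert cosine(x, reg("y", [1.0, 2.0, -1.0])) == pytest.approx(1.0)
        assert cosine(x, reg("y", [-1.0, -2.0, 1.0])) == pytest.approx(-1.0)
        assert cosine(reg("x", [1.0, 0.0]), reg("y", [0.0, 1.0])) == pytest.approx(0.0)

    def test_alignment_uses_intersection_only(self):
        x = reg("x", [1.0, 1.0], tf_ids=["TF1", "TF2"])
        y = reg("y", [1.0, -5.0], tf_ids=["TF1", "TF3"])
        assert cosine(x, y) == pytest.approx(1.0)  # only TF1 shared

    def test_disjoint_universes_rejected(self):
        with pytest.raises(InvalidInputError):
            cosine(reg("x", [1.0], tf_ids=["TF1"]), reg("y", [1.0], tf_ids=["TF2"]))

    def test_zero_vector_scores_zero(self):
        assert cosine(reg("x", [0.0, 0.0]), reg("y", [1.0, 2.0])) == 0.0


class TestTranscriptomeScore:
    def test_reversal_scores_highest(self):
        drug = trans("d", [1.0, -2.0, 3.0])
        assert score_transcriptome(drug, trans("y", [1.0, -2.0, 3.0], role="disease")) \
            == pytest.approx(-1.0)
        assert score_transcriptome(drug, trans("y", [-1.0, 2.0, -3.0], role="disease")) \
            == pytest.approx(1.0)
        assert score_transcriptome(trans("d", [1.0, 0.0]),
                                   trans("y", [0.0, 1.0], role="disease")) \
            == pytest.approx(0.0)


class TestPolarity:
    def make_world(self, cosines):
        disease = reg("dis", [1.0, 0.0, 0.0], role="disease")
        drugs = {}
        for i, c in enumerate(cosines):
            # 3-vector with cos = c against the disease signature
            drugs[f"d{i}"] = reg(f"d{i}", [c, float(np.sqrt(1 - c * c)), 0.0])
        approved = ApprovedDrugMap({"dis": set(drugs)})
        return disease, drugs, approved

    def test_median_positive(self):
        disease, drugs, approved = self.make_world([0.4, 0.6, -0.1])
        assert disease_polarity("dis", approved, disease, drugs) == "positive"

    def test_single_negative(self):
        disease, drugs, approved = self.make_world([-0.8])
        assert disease_polarity("dis", approved, disease, drugs) == "negative"

    def test_median_zero_boundary_is_positive(self):
        disease, drugs, approved = self.make_world([0.5, 0.0, -0.5])
        assert disease_polarity("dis", approved, disease, drugs) == "positive"

    def test_no_approved_drugs_unset(self):
        disease, drugs, _ = self.make_world([0.5])
        assert disease_polarity("dis", ApprovedDrugMap(), disease, drugs) == "unset"

    def test_leave_one_out_excludes_scored_drug(self):
        disease, drugs, approved = self.make_world([0.9, -0.2, -0.3])
        # full median is -0.2 -> negative; excluding d1 gives median 0.3 -> positive
        assert disease_polarity("dis", approved, disease, drugs) == "negative"
        assert disease_polarity("dis", approved, disease, drugs,
                                exclude_drug="d1") == "positive"


class TestRegulomeScore:
    def test_sign_conditional_branches(self):
        drug = reg("d", [1.0, 1.0])
        disease = reg("y", [-1.0, -1.0], role="disease")
        assert score_regulome(drug, disease, "negative") == pytest.approx(1.0)
        assert score_regulome(drug, disease, "positive") == pytest.approx(-1.0)
        same = reg("y", [1.0, 1.0], role="disease")
        assert score_regulome(drug, same, "positive") == pytest.approx(1.0)

    def test_unresolved_polarity_rejected(self):
        with pytest.raises(InvalidInputError):
            score_regulome(reg("d", [1.0]), reg("y", [1.0], role="disease"), "unset")

    def test_negated_signature_attains_max_under_negative_polarity(self):
        rng = np.random.default_rng(8)
        disease = reg("dis", rng.normal(size=30), role="disease")
        mirror = reg("drug", -disease.scores)
        assert score_regulome(mirror, disease, "negative") == pytest.approx(1.0)
        twin = reg("drug2", disease.scores.copy())
        assert score_regulome(twin, disease, "positive") == pytest.approx(1.0)


class TestScoreTables:
    def test_regulome_table_polarity_and_range(self):
        diseases = [reg("disA", [1.0, 0.5, 0.0], role="disease"),
                    reg("disB", [-1.0, 0.0, 0.3], role="disease")]
        drugs = [reg("d1", [1.0, 0.5, 0.0]),     # aligned with disA
                 reg("d2", [1.0, 0.0, -0.3]),    # anti-aligned with disB
                 reg("d3", [0.0, 1.0, 1.0])]
        approved = ApprovedDrugMap({"disA": {"d1"}, "disB": {"d2"}})
        table = score_table_regulome(drugs, diseases, approved)
        assert table.polarity == {"disA": "positive", "disB": "negative"}
        assert table.scores.loc["d1", "disA"] == pytest.approx(1.0)
        assert table.scores.loc["d2", "disB"] == pytest.approx(1.0)
        assert (table.scores.abs() <= 1.0 + 1e-12).all().all()

    def test_missing_prior_for_orphan_disease_rejected(self):
        diseases = [reg("orphan", [1.0, 0.0], role="disease")]
        drugs = [reg("d1", [1.0, 0.0])]
        with pytest.raises(InvalidInputError):
            score_table_regulome(drugs, diseases, ApprovedDrugMap())

    def test_class_prior_resolves_orphan_disease(self):
        diseases = [reg("orphan", [1.0, 0.0], role="disease")]
        drugs = [reg("d1", [-1.0, 0.0])]
        table = score_table_regulome(drugs, diseases, ApprovedDrugMap(),
                                     class_priors={"neoplasm": "negative"},
                                     disease_classes={"orphan": "neoplasm"})
        assert table.polarity["orphan"] == "negative"
        assert table.scores.loc["d1", "orphan"] == pytest.approx(1.0)

    def test_long_tsv_round_trip(self, tmp_path):
        drugs = [trans("d1", [1.0, 2.0]), trans("d2", [-1.0, 0.5])]
        diseases = [trans("y1", [1.0, -1.0], role="disease")]
        table = score_table_transcriptome(drugs, diseases)
        path = tmp_path / "scores.tsv"
        table.write_tsv(path)
        back = ScoreTable.read_tsv(path)
        assert back.level == "transcriptome"
        pd.testing.assert_frame_equal(
            back.scores.sort_index(), table.scores.sort_index(), check_names=False)


class TestRankDrugs:
    def table(self, scores):
        mat = pd.DataFrame({"dis": scores})
        return ScoreTable(scores=mat, level="regulome", polarity={"dis": "positive"})

    def test_descending_with_ranks(self):
        ranked = rank_drugs("dis", self.table(pd.Series({"d1": 0.9, "d2": 0.1})))
        assert ranked == [("d1", 0.9, 1), ("d2", 0.1, 2)]

    def test_ties_share_min_rank_ordered_by_id(self):
        ranked = rank_drugs("dis", self.table(pd.Series({"b": 0.5, "a": 0.5, "c": 0.1})))
        assert ranked == [("a", 0.5, 1), ("b", 0.5, 1), ("c", 0.1, 3)]

    def test_single_drug(self):
        assert rank_drugs("dis", self.table(pd.Series({"only": -0.2}))) \
            == [("only", -0.2, 1)]

    def test_unknown_disease_rejected(self):
        with pytest.raises(InvalidInputError):
            rank_drugs("nope", self.table(pd.Series({"d": 0.1})))


class TestEvaluateSeparation:
    def build_table(self, columns):
        return ScoreTable(scores=pd.DataFrame(columns), level="regulome",
                          polarity={k: "positive" for k in columns})

    def test_consistent_advantage_detected(self):
        rng = np.random.default_rng(0)
        cols, approved = {}, {}
        for i in range(8):
            scores = {f"a{j}": (0.9 if j == i else float(rng.uniform(-0.5, 0.5)))
                      for j in range(8)}
            scores |= {f"d{j}": float(rng.uniform(-0.5, 0.5)) for j in range(10)}
            cols[f"dis{i}"] = pd.Series(scores)
            approved[f"dis{i}"] = {f"a{i}"}
        result = evaluate_separation(self.build_table(cols), ApprovedDrugMap(approved))
        assert (result.deltas > 0).all()
        assert result.p_value < 0.05

    def test_identical_groups_degenerate(self):
        cols = {f"dis{i}": pd.Series({"a": 0.5, "b": 0.5, "c": 0.5}) for i in range(3)}
        approved = ApprovedDrugMap({f"dis{i}": {"a"} for i in range(3)})
        result = evaluate_separation(self.build_table(cols), approved)
        assert result.degenerate and result.p_value == 1.0

    def test_disease_without_approved_drugs_excluded(self):
        cols = {f"dis{i}": pd.Series({"a": 0.9, "b": 0.1, "c": 0.2}) for i in range(3)}
        approved = ApprovedDrugMap({"dis0": {"a"}, "dis1": {"a"}})  # dis2 orphan
        result = evaluate_separation(self.build_table(cols), approved)
        assert result.excluded == ["dis2"]
        assert len(result.deltas) == 2

    def test_mean_statistic_available(self):
        cols = {f"dis{i}": pd.Series({"a": 0.9, "b": 0.1, "c": 0.5}) for i in range(2)}
        approved = ApprovedDrugMap({f"dis{i}": {"a"} for i in range(2)})
        result = evaluate_separation(self.build_table(cols), approved, statistic="mean")
        assert result.deltas.iloc[0] == pytest.approx(0.9 - 0.3)
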