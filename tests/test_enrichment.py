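import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regsig import (BindingTable, ContingencyTable, InvalidInputError,
                    RegulatedGeneSets, build_regulome_signature, contingency,
                    enrich_tfs, enrichment_score, fdr_correct, fisher_p,
                    fold_enrichment)
from oracles import bh_step_up, fisher_two_sided_exact


class TestContingency:
    def test_set_counting(self, toy_binding):
        sets = RegulatedGeneSets(up={"g1", "g2"}, down={"g3"})
        t = contingency("tfA", sets, toy_binding)  # tfA binds g1, g3
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 0)
        assert t.m == 3

    def test_tf_binding_nothing(self, toy_binding):
        sets = RegulatedGeneSets(up={"g1", "g2"}, down={"g3", "g4"})
        t = contingency("tfB", sets, toy_binding)
        assert (t.a, t.b, t.c, t.d) == (0, 2, 0, 2)

    def test_genes_outside_universe_dropped(self, toy_binding):
        sets = RegulatedGeneSets(up={"g1", "gX"}, down={"g3"})
        t = contingency("tfA", sets, toy_binding)
        assert t.a + t.b == 1  # gX not in the binding universe

    def test_negative_cells_rejected(self):
        with pytest.raises(InvalidInputError):
            ContingencyTable(-1, 0, 0, 0)


class TestFisherP:
    def test_single_attainable_table_gives_one(self):
        assert fisher_p(ContingencyTable(0, 10, 0, 10)) == 1.0

    def test_balanced_extreme_table(self):
        # margins (5,5)/(5,5): only a=5 and a=0 are as extreme; each 1/252
        assert fisher_p(ContingencyTable(5, 0, 0, 5)) == pytest.approx(2 / 252, rel=1e-9)

    def test_row_swap_symmetry(self):
        t = ContingencyTable(7, 3, 2, 9)
        assert fisher_p(t) == pytest.approx(fisher_p(t.swapped()), rel=1e-12)

    @pytest.mark.parametrize("t", [ContingencyTable(0, 0, 0, 0),
                                   ContingencyTable(0, 0, 3, 4),
                                   ContingencyTable(3, 4, 0, 0)])
    def test_degenerate_margins_give_one(self, t):
        assert fisher_p(t) == 1.0

    @given(st.tuples(*[st.integers(0, 8)] * 4))
    @settings(max_examples=200, deadline=None)
    def test_matches_exact_enumeration(self, cells):
        a, b, c, d = cells
        t = ContingencyTable(a, b, c, d)
        assert fisher_p(t) == pytest.approx(
            fisher_two_sided_exact(a, b, c, d), rel=1e-7, abs=1e-12)

    def test_one_sided_alternative_available(self):
        t = ContingencyTable(5, 0, 0, 5)
        assert fisher_p(t, alternative="greater") == pytest.approx(1 / 252, rel=1e-9)


class TestFoldEnrichment:
    def test_equal_fractions_give_one(self):
        assert fold_enrichment(ContingencyTable(3, 7, 3, 7)) == pytest.approx(1.0)

    def test_up_leaning_extreme(self):
        assert fold_enrichment(ContingencyTable(5, 0, 0, 5)) == pytest.approx(11.0)

    def test_down_leaning_is_reciprocal(self):
        assert fold_enrichment(ContingencyTable(0, 5, 5, 0)) == pytest.approx(1 / 11)

    def test_swap_inverts(self):
        t = ContingencyTable(4, 2, 1, 8)
        assert fold_enrichment(t.swapped()) == pytest.approx(1 / fold_enrichment(t))

    def test_finite_on_empty_cells(self):
        fe = fold_enrichment(ContingencyTable(0, 0, 0, 0))
        assert np.isfinite(fe) and fe > 0


class TestFdrCorrect:
    def test_hand_worked_step_up(self):
        q = fdr_correct({"a": 0.01, "b": 0.02, "c": 0.03})
        assert q == pytest.approx({"a": 0.03, "b": 0.03, "c": 0.03})

    def test_single_p_unchanged(self):
        assert fdr_correct({"a": 0.2}) == pytest.approx({"a": 0.2})

    def test_all_ones_stay_one(self):
        assert fdr_correct({"a": 1.0, "b": 1.0}) == {"a": 1.0, "b": 1.0}

    def test_empty_input(self):
        assert fdr_correct({}) == {}

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            fdr_correct({"a": 0.0})

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_step_up_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 200))
        pvals = rng.uniform(1e-12, 1.0, size=n)
        keys = [f"t{i}" for i in range(n)]
        got = fdr_correct(dict(zip(keys, pvals)))
        expected = bh_step_up(list(pvals))
        np.testing.assert_allclose([got[k] for k in keys], expected, rtol=1e-12)

    def test_q_never_below_p(self):
        rng = np.random.default_rng(99)
        pvals = {f"t{i}": p for i, p in enumerate(rng.uniform(1e-6, 1, 50))}
        q = fdr_correct(pvals)
        assert all(q[k] >= pvals[k] - 1e-15 for k in pvals)


class TestEnrichmentScore:
    @pytest.mark.parametrize("q,fe,expected", [
        (0.01, 2.0, 2.0),
        (1.0, 2.0, 0.0),
        (1.0, 0.5, 0.0),          # q == 1 always scores 0, either branch
        (0.05, 0.5, -np.log10(1 / 0.05)),
        (0.1, 1.0, 1.0),          # FE exactly 1 takes the positive branch
    ])
    def test_sign_and_magnitude(self, q, fe, expected):
        assert enrichment_score(q, fe) == pytest.approx(expected)

    def test_underflow_capped(self):
        assert enrichment_score(1e-321, 2.0) == 320.0
        assert enrichment_score(5e-324, 0.5) == -320.0

    def test_nonpositive_q_rejected(self):
        with pytest.raises(InvalidInputError):
            enrichment_score(0.0, 1.0)

    def test_monotone_in_q(self):
        qs = np.logspace(-10, 0, 25)
        mags = [abs(enrichment_score(q, 2.0)) for q in qs]
        assert all(x >= y for x, y in zip(mags, mags[1:]))


def random_enrichment_instance(rng, n_tfs=8, n_genes=60):
    binding = BindingTable([f"TF{i}" for i in range(n_tfs)],
                           [f"g{j}" for j in range(n_genes)],
                           rng.random((n_tfs, n_genes)) < 0.3)
    genes = list(binding.gene_ids)
    rng.shuffle(genes)
    half = int(rng.integers(5, 25))
    sets = RegulatedGeneSets(up=set(genes[:half]), down=set(genes[half:2 * half]))
    return binding, sets


class TestRegulomeSignature:
    def test_empty_sets_give_all_zero(self, toy_binding):
        sig = build_regulome_signature(RegulatedGeneSets(), toy_binding, "e", "drug")
        np.testing.assert_array_equal(sig.scores, 0.0)
        assert list(sig.tf_ids) == toy_binding.tf_ids

    def test_tf_binding_only_up_genes_scores_positive(self):
        # one discriminating TF against uninformative company
        matrix = np.zeros((2, 20), dtype=bool)
        matrix[0, :10] = True   # TF0 binds exactly the up genes
        binding = BindingTable(["TF0", "TF1"], [f"g{j}" for j in range(20)], matrix)
        sets = RegulatedGeneSets(up={f"g{j}" for j in range(10)},
                                 down={f"g{j}" for j in range(10, 20)})
        sig = build_regulome_signature(sets, binding, "e", "drug")
        scores = dict(zip(sig.tf_ids, sig.scores))
        assert scores["TF0"] > 0
        assert scores["TF1"] == 0.0  # binds nothing: p = 1

    def test_q_at_least_p(self):
        rng = np.random.default_rng(0)
        binding, sets = random_enrichment_instance(rng)
        for r in enrich_tfs(sets, binding):
            assert r.q >= r.p_raw - 1e-15

    def test_tf_order_permutation_permutes_scores(self):
        rng = np.random.default_rng(4)
        binding, sets = random_enrichment_instance(rng)
        sig = build_regulome_signature(sets, binding, "e", "drug")
        perm = rng.permutation(binding.n_tfs)
        permuted = BindingTable([binding.tf_ids[i] for i in perm],
                                binding.gene_ids, binding.matrix[perm])
        sig_p = build_regulome_signature(sets, permuted, "e", "drug")
        np.testing.assert_allclose(sig_p.series.sort_index(), sig.series.sort_index())

    @pytest.mark.parametrize("seed", range(10))
    def test_swapping_up_down_negates_scores(self, seed):
        rng = np.random.default_rng(1000 + seed)
        binding, sets = random_enrichment_instance(rng)
        swapped = RegulatedGeneSets(up=sets.down, down=sets.up)
        fwd = build_regulome_signature(sets, binding, "e", "drug")
        rev = build_regulome_signature(swapped, binding, "e", "drug")
        np.testing.assert_allclose(rev.scores, -fwd.scores, rtol=1e-9, atol=1e-12)
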