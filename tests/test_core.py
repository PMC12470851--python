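import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dirtnorm import core
from dirtnorm.core import (DirtParams, DiRTRecord, build_candidate_db,
                           call_dirts, dedup_and_adjust,
                           denominator_deg_filter, nsd, per_gene_cpm_tests,
                           ratio_profile, select_index_candidates,
                           separation_threshold)
from dirtnorm.io import CountMatrix
from dirtnorm.stats import bh_adjust

from conftest import make_cm, make_design
from naive_reference import naive_pipeline


class TestRatioProfile:
    def test_definition(self):
        cm = make_cm([[2, 4], [1, 2]], genes=["num", "den"])
        out = ratio_profile(cm, "num", "den", ["s1", "s2"])
        assert out.tolist() == [2.0, 2.0]

    def test_self_pair_forbidden(self):
        cm = make_cm([[1, 1]], genes=["gA"])
        with pytest.raises(ValueError, match="self-pairing"):
            ratio_profile(cm, "gA", "gA", ["s1"])

    def test_zero_denominator_is_hard_error(self):
        cm = make_cm([[2, 4], [1, 0]], genes=["num", "den"])
        with pytest.raises(ZeroDivisionError, match="den"):
            ratio_profile(cm, "num", "den", ["s1", "s2"])

    def test_reciprocal_identity(self):
        rng = np.random.default_rng(9)
        cm = make_cm(rng.integers(1, 500, size=(2, 6)), genes=["gA", "gB"])
        fwd = ratio_profile(cm, "gA", "gB", cm.sample_ids)
        rev = ratio_profile(cm, "gB", "gA", cm.sample_ids)
        np.testing.assert_allclose(fwd * rev, 1.0, rtol=1e-12)


class TestNsd:
    def test_constant_ratio_is_zero(self):
        assert nsd([3, 3, 3, 3, 3]) == 0.0

    def test_hand_arithmetic(self):
        assert nsd([1, 2, 3]) == pytest.approx(0.5)  # sd 1, mean 2

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(vec=st.lists(st.floats(0.01, 1e3), min_size=2, max_size=10),
           c=st.floats(0.001, 1e3))
    def test_scale_invariance(self, vec, c):
        assert nsd([c * v for v in vec]) == pytest.approx(nsd(vec), rel=1e-9,
                                                          abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            nsd([1.0])


def _params(**kw):
    defaults = dict(top_n_genes=100, k_candidates=2)
    defaults.update(kw)
    return DirtParams(**defaults)


class TestSelectIndexCandidates:
    def test_proportional_partner_wins_with_zero_nsd(self):
        design = make_design(3, 3)
        cm = make_cm(
            [[10, 20, 30, 5, 5, 5],
             [20, 40, 60, 7, 7, 7],     # exactly 0.5x gA on controls
             [30, 30, 30, 9, 9, 9]],
            genes=["gA", "gB", "gC"],
            samples=["C1", "C2", "C3", "T1", "T2", "T3"])
        out = select_index_candidates(cm, design, _params(k_candidates=1))
        best = {c.target_gene: c for c in out}
        assert best["gA"].index_gene == "gB"
        assert best["gA"].nsd == pytest.approx(0.0)

    def test_matches_bruteforce_oracle(self, small_sim):
        cm, design, _ = small_sim
        params = _params(k_candidates=5)
        ours = select_index_candidates(cm, design, params)
        ref = naive_pipeline(cm.counts, design.table, k=5)["candidates"]
        assert [(c.target_gene, c.index_gene) for c in ours] == \
            [(t, p) for t, p, _ in ref]
        np.testing.assert_allclose([c.nsd for c in ours],
                                   [n for _, _, n in ref], rtol=1e-9)

    @pytest.mark.parametrize("chunk", [1, 7, 64, 1000])
    def test_chunk_size_never_changes_results(self, small_sim, chunk):
        cm, design, _ = small_sim
        base = select_index_candidates(cm, design, _params(k_candidates=3))
        other = select_index_candidates(cm, design, _params(k_candidates=3),
                                        chunk_size=chunk)
        assert base == other

    def test_gene_order_invariance(self, small_sim):
        cm, design, _ = small_sim
        params = _params(k_candidates=3)
        base = select_index_candidates(cm, design, params)
        rng = np.random.default_rng(0)
        shuffled = CountMatrix(
            cm.counts.iloc[rng.permutation(cm.n_genes)])
        assert select_index_candidates(shuffled, design, params) == base

    def test_too_few_eligible_partners_raises(self):
        design = make_design(2, 2)
        # gB and gC have zero control counts: gA has no eligible partner
        cm = make_cm([[5, 5, 1, 1], [0, 3, 1, 1], [2, 0, 1, 1]],
                     genes=["gA", "gB", "gC"],
                     samples=["C1", "C2", "T1", "T2"])
        with pytest.raises(ValueError, match="gA"):
            select_index_candidates(cm, design, _params(k_candidates=1))


class TestCandidateDbAndTests:
    def test_shape_contract(self):
        design = make_design(2, 2)
        cm = make_cm([[4, 6, 2, 2], [2, 3, 1, 1], [8, 12, 4, 4]],
                     genes=["gA", "gB", "gC"],
                     samples=["C1", "C2", "T1", "T2"])
        params = _params(k_candidates=1)
        cands = select_index_candidates(cm, design, params)
        db = build_candidate_db(cm, design, cands, params)
        assert len(db) == 3
        assert all(len(r.ratio_values) == 4 for r in db)

    def test_zero_treated_denominator_dropped_and_counted(self, caplog):
        design = make_design(2, 2)
        cm = make_cm([[4, 6, 2, 2], [2, 3, 0, 1]],
                     genes=["gA", "gB"], samples=["C1", "C2", "T1", "T2"])
        params = _params(k_candidates=1)
        cands = select_index_candidates(cm, design, params)
        with caplog.at_level("WARNING"):
            db = build_candidate_db(cm, design, cands, params)
        kept = {(r.numerator, r.denominator) for r in db}
        assert ("gA", "gB") not in kept      # gB is zero in T1
        assert ("gB", "gA") in kept
        assert "zero" in caplog.text

    def test_identical_ratio_distributions_give_p_one(self):
        design = make_design(2, 2)
        rec = DiRTRecord("gA", "gB", 0.1, pd.Series(
            [1.0, 2.0, 1.0, 2.0], index=["C1", "C2", "T1", "T2"]))
        core.test_dirts([rec], design)
        assert rec.p_discovery == 1.0

    def test_planted_ratio_shift_detected(self):
        design = make_design(5, 5)
        samples = design.samples()
        vals = [1.0, 1.01, 0.99, 1.0, 1.0, 4.0, 4.02, 3.99, 4.0, 4.01]
        rec = DiRTRecord("gA", "gB", 0.0, pd.Series(vals, index=samples))
        core.test_dirts([rec], design)
        assert rec.p_discovery < 1e-3

    def test_label_permutation_within_condition_is_irrelevant(self):
        design = make_design(3, 3)
        vals = pd.Series([1.0, 3.0, 2.0, 5.0, 4.0, 6.0],
                         index=["C1", "C2", "C3", "T1", "T2", "T3"])
        rec1 = DiRTRecord("gA", "gB", 0.0, vals)
        perm = vals[["C3", "C1", "C2", "T2", "T3", "T1"]]
        perm.index = ["C1", "C2", "C3", "T1", "T2", "T3"]
        rec2 = DiRTRecord("gA", "gB", 0.0, perm)
        core.test_dirts([rec1, rec2], design)
        assert rec1.p_discovery == pytest.approx(rec2.p_discovery, rel=1e-12)


class TestDenominatorFilterDedupCall:
    def _record(self, num, den, p):
        rec = DiRTRecord(num, den, 0.0, pd.Series([1.0, 1.0], index=["C1", "T1"]))
        rec.p_discovery = p
        return rec

    def test_denominator_screen_boundaries(self):
        params = _params()
        db = [self._record("gA", "gB", 0.5), self._record("gA", "gC", 0.5)]
        per_gene_p = {"gB": 0.05, "gC": 0.5}
        kept = denominator_deg_filter(db, None, None, params, per_gene_p=per_gene_p)
        assert [(r.denominator) for r in kept] == ["gC"]

    def test_dedup_keeps_lowest_p_with_lex_tiebreak(self):
        params = _params()
        db = [self._record("gA", "gB", 0.3), self._record("gA", "gC", 0.01),
              self._record("gA", "gD", 0.2), self._record("gE", "gZ", 0.2),
              self._record("gE", "gB", 0.2)]
        out = dedup_and_adjust(db, params)
        chosen = {r.numerator: r.denominator for r in out}
        assert chosen == {"gA": "gC", "gE": "gB"}  # tie gZ/gB -> gB

    def test_single_record_m_one(self):
        out = dedup_and_adjust([self._record("gA", "gB", 0.04)], _params())
        assert out[0].p_adj_discovery == pytest.approx(0.04)

    def test_adjustment_matches_bh_oracle(self):
        rng = np.random.default_rng(4)
        db = [self._record(f"g{i:03d}", "gX", p)
              for i, p in enumerate(rng.uniform(size=50))]
        out = dedup_and_adjust(db, _params())
        expected = bh_adjust([r.p_discovery for r in out], m=len(out))
        np.testing.assert_allclose([r.p_adj_discovery for r in out], expected)

    def test_numerators_unique_after_dedup(self, small_sim):
        cm, design, _ = small_sim
        params = _params(k_candidates=3)
        db = build_candidate_db(
            cm, design, select_index_candidates(cm, design, params), params)
        core.test_dirts(db, design)
        out = dedup_and_adjust(db, params)
        nums = [r.numerator for r in out]
        assert len(nums) == len(set(nums))

    def test_call_threshold_is_strict(self):
        params = _params()
        a = self._record("gA", "gB", 0.0)
        a.p_adj_discovery = 0.049
        b = self._record("gB", "gC", 0.0)
        b.p_adj_discovery = 0.05
        assert [r.numerator for r in call_dirts([a, b], params)] == ["gA"]
        assert call_dirts([], params) == []


class TestSeparationThreshold:
    def test_midpoint_of_group_means(self):
        design = make_design(2, 2)
        rec = DiRTRecord("gA", "gB", 0.0, pd.Series(
            [1.9, 2.1, 0.9, 1.1], index=["C1", "C2", "T1", "T2"]))
        assert separation_threshold(rec, design) == pytest.approx(1.5)

    def test_equal_means_threshold_is_common_mean(self):
        design = make_design(2, 2)
        rec = DiRTRecord("gA", "gB", 0.0, pd.Series(
            [2.0, 2.0, 2.0, 2.0], index=["C1", "C2", "T1", "T2"]))
        assert separation_threshold(rec, design) == pytest.approx(2.0)

    def test_validation_samples_on_correct_sides_flag(self):
        design = make_design(2, 2, 2, 2)
        rec = DiRTRecord("gA", "gB", 0.0, pd.Series(
            [1.9, 2.1, 0.9, 1.1], index=["C1", "C2", "T1", "T2"]))
        # threshold 1.5; controls must sit above, treated below
        rec.ratio_values_validation = pd.Series(
            [1.8, 2.2, 1.2, 0.8], index=["C3", "C4", "T3", "T4"])
        assert core.threshold_consistency(rec, design) is True
        rec.ratio_values_validation["C3"] = 1.4  # wrong side
        assert core.threshold_consistency(rec, design) is False


class TestScaleInvariance:
    """Core method claim: per-sample rescaling changes nothing."""

    def test_sample_rescaling_changes_no_statistic(self, small_sim):
        cm, design, _ = small_sim
        params = _params(k_candidates=3)

        def run(matrix):
            cands = select_index_candidates(matrix, design, params)
            db = build_candidate_db(matrix, design, cands, params)
            core.test_dirts(db, design)
            per_gene = per_gene_cpm_tests(matrix, design)
            kept = denominator_deg_filter(db, matrix, design, params,
                                          per_gene_p=per_gene["p"])
            out = dedup_and_adjust(kept, params)
            return cands, out

        base_c, base_r = run(cm)
        scaled = cm.counts.copy()
        scaled["C2"] = scaled["C2"] * 7
        scaled["T3"] = scaled["T3"] * 3
        sc_c, sc_r = run(CountMatrix(scaled))
        assert base_c == sc_c
        assert [(r.numerator, r.denominator, r.p_discovery, r.p_adj_discovery)
                for r in base_r] == \
               [(r.numerator, r.denominator, r.p_discovery, r.p_adj_discovery)
                for r in sc_r]
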