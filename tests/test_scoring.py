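"""Deviation statistics, DP4 probabilities, outlier flagging, and ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import t as student_t

from pyranoshift.scoring import (
    AlignmentError,
    CandidateScore,
    DeviationVector,
    deviations,
    dp4,
    flag_single_outlier,
    max_dev,
    rank_candidates,
    rmsd,
)
from pyranoshift.shift_data import CompoundEntry, ShiftRecord, ValidationError


def entry(cid, rows, kind="experimental"):
    return CompoundEntry(
        id=cid,
        name="",
        subtype=None,
        shifts=tuple(ShiftRecord(l, s, c) for l, s, c in rows),
        kind=kind,
    )


def dv(*values):
    return DeviationVector(tuple((f"C-{i + 1}", v) for i, v in enumerate(values)))


class TestDeviations:
    def test_c7_deviation_between_reported_and_calculated(self):
        exp = entry("allanxanthone-B", [("C-7", 144.1, "core_CH")])
        calc = entry("calc", [("C-7", 135.9, "core_CH")], kind="calculated")
        d = deviations(exp, calc)
        assert abs(d.deltas[0][1]) == pytest.approx(8.2)

    def test_close_agreement_case(self):
        exp = entry("garcinone-B", [("C-7", 138.1, "core_CH")])
        calc = entry("calc", [("C-7", 135.9, "core_CH")], kind="calculated")
        d = deviations(exp, calc)
        assert abs(d.deltas[0][1]) == pytest.approx(2.2)

    def test_identical_entries_zero_everywhere(self):
        rows = [("C-1", 160.0, "core_Cq"), ("C-9", 182.0, "carbonyl")]
        d = deviations(entry("a", rows), entry("b", rows, kind="calculated"))
        assert np.allclose(d.values, 0.0)

    def test_prime_alias_labels_align(self):
        exp = entry("a", [("C-1''", 116.0, "pyran_olefinic_1p")])
        calc = entry("b", [("C-1'", 117.0, "pyran_olefinic_1p")], kind="calculated")
        d = deviations(exp, calc)
        assert d.n_shared == 1 and d.deltas[0][1] == pytest.approx(1.0)

    def test_disjoint_labels_raise(self):
        exp = entry("a", [("C-1", 100.0, "core_Cq")])
        calc = entry("b", [("C-2", 100.0, "core_CH")], kind="calculated")
        with pytest.raises(AlignmentError):
            deviations(exp, calc)

    def test_unshared_labels_reported_excluded(self):
        exp = entry("a", [("C-1", 100.0, "core_Cq"), ("C-2", 110.0, "core_CH")])
        calc = entry("b", [("C-1", 101.0, "core_Cq"), ("C-3", 120.0, "core_CH")], kind="calculated")
        d = deviations(exp, calc)
        assert d.excluded_labels == {"C-2", "C-3"}


class TestRmsdMaxDev:
    def test_closed_form_three_four(self):
        d = dv(3.0, 4.0)
        assert rmsd(d) == pytest.approx(np.sqrt(12.5))
        value, label = max_dev(d)
        assert value == pytest.approx(4.0) and label == "C-2"

    def test_zero_vector(self):
        d = dv(0.0, 0.0, 0.0)
        assert rmsd(d) == 0.0 and max_dev(d)[0] == 0.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-20, 20, allow_nan=False), min_size=1, max_size=10))
    def test_permutation_invariance_and_bound(self, values):
        d1 = dv(*values)
        d2 = DeviationVector(tuple((f"C-{i + 1}", v) for i, v in enumerate(reversed(values))))
        assert rmsd(d1) == pytest.approx(rmsd(d2))
        assert max_dev(d1)[0] == pytest.approx(max_dev(d2)[0])
        assert rmsd(d1) <= max_dev(d1)[0] + 1e-12


class TestDp4:
    def test_single_candidate_normalizes_to_one(self):
        assert dp4([dv(1.0, 2.0)])[0] == pytest.approx(1.0)

    def test_identical_error_vectors_split_evenly(self):
        probs = dp4([dv(1.5, -2.0), dv(-1.5, 2.0)])
        assert probs == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_two_candidate_value_matches_direct_product_oracle(self):
        sigma, nu = 2.306, 11.38
        a, b = dv(1.0, 1.0, 1.0), dv(3.0, 3.0, 3.0)
        l_a = np.prod(student_t.sf(np.abs(a.values) / sigma, df=nu))
        l_b = np.prod(student_t.sf(np.abs(b.values) / sigma, df=nu))
        expected = l_a / (l_a + l_b)
        probs = dp4([a, b], sigma=sigma, nu=nu)
        assert probs[0] == pytest.approx(expected, abs=1e-10)
        assert probs[0] > 0.9

    def test_log_space_matches_direct_product_when_no_underflow(self):
        rng = np.random.default_rng(3)
        cands = [dv(*rng.normal(0, 2, size=6)) for _ in range(4)]
        direct = np.array(
            [np.prod(student_t.sf(np.abs(c.values) / 2.306, df=11.38)) for c in cands]
        )
        direct = direct / direct.sum()
        assert dp4(cands) == pytest.approx(direct, abs=1e-10)

    def test_probabilities_sum_to_one_and_order_invariant(self):
        cands = [dv(0.5, 1.0), dv(2.0, 0.3), dv(4.0, 4.0)]
        probs = dp4(cands)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert dp4(cands[::-1])[::-1] == pytest.approx(probs)

    def test_shared_extra_carbon_leaves_probabilities_unchanged(self):
        base = [dv(0.5, 1.0), dv(2.0, 0.3)]
        extended = [
            DeviationVector(c.deltas + (("C-99", 1.7),)) for c in base
        ]
        assert dp4(extended) == pytest.approx(dp4(base), abs=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            dp4([dv(1.0)], sigma=0.0)
        with pytest.raises(ValidationError):
            dp4([])


class TestSingleOutlier:
    def test_lone_large_deviation_flagged(self):
        d = DeviationVector((("C-7", -8.2), ("C-1", 1.0), ("C-2", -1.5), ("C-3", 0.5)))
        flagged = flag_single_outlier(d, t_major=5.0, t_rest=3.0)
        assert flagged is not None
        label, rescored = flagged
        assert label == "C-7"
        assert rescored == pytest.approx(rmsd(d.drop("C-7")))

    def test_all_small_deviations_not_flagged(self):
        assert flag_single_outlier(dv(1.0, -2.0, 1.5)) is None

    def test_two_large_deviations_not_a_single_outlier(self):
        assert flag_single_outlier(dv(8.0, 7.5, 1.0)) is None

    def test_requires_three_shared_labels(self):
        with pytest.raises(ValidationError):
            flag_single_outlier(dv(8.0, 1.0))


class TestRanking:
    def test_single_candidate_gets_probability_one(self):
        exp = entry("e", [("C-1", 100.0, "core_Cq")])
        cand = entry("c1", [("C-1", 101.0, "core_Cq")], kind="calculated")
        (score,) = rank_candidates(exp, [cand])
        assert score.dp4 == pytest.approx(1.0)

    def test_exact_candidate_ranks_first_with_zero_rmsd(self):
        rows = [("C-1", 100.0, "core_Cq"), ("C-2", 120.0, "core_CH"), ("C-9", 182.0, "carbonyl")]
        exp = entry("e", rows)
        exact = entry("exact", rows, kind="calculated")
        off = entry(
            "off",
            [("C-1", 103.0, "core_Cq"), ("C-2", 124.0, "core_CH"), ("C-9", 179.0, "carbonyl")],
            kind="calculated",
        )
        scores = rank_candidates(exp, [off, exact])
        assert scores[0].candidate_id == "exact"
        assert scores[0].rmsd == pytest.approx(0.0)

    def test_three_candidate_order_matches_direct_oracle(self):
        rng = np.random.default_rng(11)
        labels = [f"C-{i + 1}" for i in range(8)]
        base = rng.uniform(90, 180, size=8)
        exp = entry("e", [(l, v, "core_CH") for l, v in zip(labels, base)])
        cands, oracle_loglik = [], []
        for k, scale in enumerate([0.5, 1.5, 3.0]):
            errs = rng.normal(0, scale, size=8)
            cands.append(
                entry(f"c{k}", [(l, v + e, "core_CH") for l, v, e in zip(labels, base, errs)], kind="calculated")
            )
            oracle_loglik.append(
                student_t.logsf(np.abs(errs) / 2.306, df=11.38).sum()
            )
        scores = rank_candidates(exp, cands)
        oracle_order = [f"c{k}" for k in np.argsort(oracle_loglik)[::-1]]
        assert [s.candidate_id for s in scores] == oracle_order

    def test_score_invariants(self):
        with pytest.raises(ValidationError):
            CandidateScore("x", rmsd=1.0, max_dev=2.0, max_dev_label="C-1", dp4=1.5, n_shared=3)
        with pytest.raises(ValidationError):
            CandidateScore("x", rmsd=-1.0, max_dev=2.0, max_dev_label="C-1", dp4=0.5, n_shared=3)
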