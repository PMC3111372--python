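"""Lagged alignment, rule scoring and classifier-profile construction."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from grncop2 import (
    InferenceParams,
    ValidationError,
    align_lagged,
    best_rule_type,
    confusion_counts,
    generate,
    infer_profile,
    infer_rules_dataset,
    score_rule,
)
from grncop2.discretization import TdtResult, compute_tdt

P = 1
M = -1

state_vectors = st.lists(st.sampled_from([M, P]), min_size=4, max_size=50)


def oracle_best(reg, tgt, accuracy, scp):
    """Six-way enumeration from the rule-type definitions, in exact rationals."""
    n = len(reg)
    pairs = list(zip(reg, tgt))
    count = lambda a, b: sum(1 for r, t in pairs if r == a and t == b)
    npp, npm = count(P, P), count(P, M)
    nmp, nmm = count(M, P), count(M, M)

    def frac(a, b):
        return Fraction(a, b) if b else Fraction(0)

    candidates = {}
    candidates[1] = (frac(npp, npp + npm) * frac(nmm, nmm + nmp), True)
    candidates[-1] = (frac(npm, npm + npp) * frac(nmp, nmp + nmm), True)
    candidates[2] = (frac(npp, npp + npm), Fraction(npp, n) >= Fraction(scp))
    candidates[-3] = (frac(npm, npm + npp), Fraction(npm, n) >= Fraction(scp))
    candidates[3] = (frac(nmm, nmm + nmp), Fraction(nmm, n) >= Fraction(scp))
    candidates[-2] = (frac(nmp, nmp + nmm), Fraction(nmp, n) >= Fraction(scp))
    best_c, best_s = 0, Fraction(0)
    for c in (1, -1, 2, 3, -2, -3):  # documented tie-break order
        s, passes = candidates[c]
        if not passes or s < Fraction(accuracy):
            continue
        if s > best_s:
            best_c, best_s = c, s
    return best_c, float(best_s)


class TestAlignLagged:
    def test_zero_delay_is_identity(self):
        reg, tgt = align_lagged([1, 2, 3, 4, 5, 6], [7, 8, 9, 10, 11, 12], 0)
        assert list(reg) == [1, 2, 3, 4, 5, 6]
        assert list(tgt) == [7, 8, 9, 10, 11, 12]

    def test_pairs_regulator_j_with_target_j_plus_w(self):
        reg, tgt = align_lagged([1, 2, 3, 4, 5, 6], [10, 20, 30, 40, 50, 60], 2)
        assert list(reg) == [1, 2, 3, 4]
        assert list(tgt) == [30, 40, 50, 60]

    def test_delay_beyond_window_bound_errors(self):
        with pytest.raises(ValidationError):
            align_lagged([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6], 3)


class TestConfusionCounts:
    def test_perfect_type1_agreement(self):
        c = confusion_counts([P, P, M, M], [P, P, M, M], 1)
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 0, 2, 0)

    def test_perfect_anti_agreement(self):
        c = confusion_counts([P, P, M, M], [M, M, P, P], -1)
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 0, 2, 0)

    def test_mixed_tally(self):
        # brute-force over the 5 positions
        c = confusion_counts([P, M, P, M, P], [P, P, M, M, P], 1)
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 1, 1, 1)

    def test_type_zero_is_undefined(self):
        with pytest.raises(ValidationError):
            confusion_counts([P, M, P, M], [P, M, P, M], 0)

    @settings(max_examples=100, derandomize=True)
    @given(state_vectors, st.data(), st.sampled_from([-3, -2, -1, 1, 2, 3]))
    def test_counts_partition_the_samples(self, reg, data, c):
        tgt = data.draw(st.lists(st.sampled_from([M, P]), min_size=len(reg), max_size=len(reg)))
        counts = confusion_counts(reg, tgt, c)
        assert counts.total == len(reg)


class TestScoreRule:
    def test_perfect_two_sided_scores_one(self):
        from grncop2 import ConfusionCounts

        assert score_rule(ConfusionCounts(2, 0, 2, 0), 1, 4, 0.95) == (1.0, True)

    def test_hand_computed_two_sided(self):
        from grncop2 import ConfusionCounts

        score, _ = score_rule(ConfusionCounts(2, 1, 1, 1), 1, 5, 0.95)
        assert score == pytest.approx((2 / 3) * (1 / 2))

    def test_one_sided_coverage_gate(self):
        from grncop2 import ConfusionCounts

        score, passes = score_rule(ConfusionCounts(3, 0, 1, 0), 2, 4, 0.95)
        assert score == 1.0
        assert not passes  # 3/4 < 0.95


class TestBestRuleType:
    def test_perfect_positive_pair(self):
        params = InferenceParams(accuracy=0.75, scp=0.95)
        assert best_rule_type([P, P, M, M], [P, P, M, M], params) == (1, 1.0)

    def test_perfect_negative_pair(self):
        params = InferenceParams(accuracy=0.75, scp=0.95)
        assert best_rule_type([P, P, M, M], [M, M, P, P], params) == (-1, 1.0)

    def test_uninformative_pair_is_type_zero(self):
        params = InferenceParams(accuracy=0.75, scp=0.95)
        assert best_rule_type([P, M, P, M], [P, P, M, M], params) == (0, 0.0)

    @settings(max_examples=200, derandomize=True)
    @given(state_vectors, st.data(), st.sampled_from([0.6, 0.75, 0.9]), st.sampled_from([0.6, 0.95, 1.0]))
    def test_matches_six_way_enumeration(self, reg, data, accuracy, scp):
        tgt = data.draw(st.lists(st.sampled_from([M, P]), min_size=len(reg), max_size=len(reg)))
        params = InferenceParams(accuracy=accuracy, scp=scp)
        got_c, got_s = best_rule_type(reg, tgt, params)
        exp_c, exp_s = oracle_best(reg, tgt, accuracy, scp)
        assert got_c == exp_c
        assert got_s == pytest.approx(exp_s, abs=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(state_vectors, st.data())
    def test_label_swap_symmetry(self, reg, data):
        # flipping target labels converts optimal type 1 <-> -1 at equal score
        tgt = data.draw(st.lists(st.sampled_from([M, P]), min_size=len(reg), max_size=len(reg)))
        params = InferenceParams(accuracy=0.5, scp=1.0)
        c1, s1 = best_rule_type(reg, tgt, params)
        c2, s2 = best_rule_type(reg, [-t for t in tgt], params)
        if c1 in (1, -1):
            assert c2 == -c1
            assert s2 == pytest.approx(s1, abs=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(state_vectors, st.data(), st.randoms(use_true_random=False))
    def test_invariant_to_joint_permutation(self, reg, data, rnd):
        tgt = data.draw(st.lists(st.sampled_from([M, P]), min_size=len(reg), max_size=len(reg)))
        order = list(range(len(reg)))
        rnd.shuffle(order)
        params = InferenceParams(accuracy=0.6, scp=0.8)
        assert best_rule_type(reg, tgt, params) == best_rule_type(
            [reg[i] for i in order], [tgt[i] for i in order], params
        )

    @settings(max_examples=100, derandomize=True)
    @given(state_vectors, st.data())
    def test_scp_one_suppresses_one_sided_types(self, reg, data):
        # regulator states produced by an RRT always contain both states
        # (every candidate threshold leaves Do and Up non-empty), so a
        # one-sided rule can never cover all samples
        assume(len(set(reg)) == 2)
        tgt = data.draw(st.lists(st.sampled_from([M, P]), min_size=len(reg), max_size=len(reg)))
        params = InferenceParams(accuracy=0.1, scp=1.0)
        c, _ = best_rule_type(reg, tgt, params)
        assert c in (0, 1, -1)


class TestInferProfile:
    def test_planted_pair_recovered_at_its_delay(self):
        truth = generate(n_genes=3, m_timepoints=12, k_datasets=1, seed=7, planted=[])
        ds = truth.datasets[0]
        # plant a noiseless type-1 rule G01 -> G02 at w=2 directly in the values
        w = 2
        m = ds.n_timepoints
        reg = ds.values[0]
        thr_reg = truth.gene_thresholds["G01"]
        thr_tgt = truth.gene_thresholds["G02"]
        states = np.where(reg > thr_reg, 1, -1)
        ds.values[1, w:] = np.where(states[: m - w] == 1, thr_tgt + 0.5, thr_tgt - 0.5)
        params = InferenceParams(accuracy=0.75, scp=0.95, max_delay=w)
        tdt = compute_tdt(ds.values[1][w:])
        profile = infer_profile(ds, "G02", w, params, tdt)
        assignment = profile.assignments["G01"]
        assert assignment.rule_type == 1
        assert assignment.score == 1.0

    def test_excluded_tdt_is_a_precondition_violation(self, tiny_dataset, default_params):
        excluded = TdtResult(threshold=None, excluded=True, split_index=1, objective=0.0)
        with pytest.raises(ValidationError):
            infer_profile(tiny_dataset, "A", 0, default_params, excluded)

    def test_constant_regulators_get_type_zero(self):
        values = np.array(
            [
                [0.0, 1.0, 0.0, 1.0, 0.0, 1.0],
                [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],
            ]
        )
        from grncop2 import ExpressionDataset

        ds = ExpressionDataset("c", ["T", "R"], [f"T{i}" for i in range(6)], values)
        params = InferenceParams(accuracy=0.5, scp=0.95)
        tdt = compute_tdt(values[0])
        profile = infer_profile(ds, "T", 0, params, tdt)
        assert profile.assignments["R"].rule_type == 0


class TestInferRulesDataset:
    def test_w_zero_emits_only_simultaneous_rules(self, noiseless_truth):
        params = InferenceParams(accuracy=0.75, scp=0.95, max_delay=0)
        res = infer_rules_dataset(noiseless_truth.datasets[0], params)
        assert set(res.rules_by_delay) == {0}
        assert all(r.delay == 0 for r in res.all_rules())

    def test_planted_rules_recovered_with_score_one(self, noiseless_truth, default_params):
        res = infer_rules_dataset(noiseless_truth.datasets[0], default_params)
        found = {r.identity: r.score for r in res.all_rules()}
        for planted in noiseless_truth.rules:
            key = (planted.regulator, planted.target, planted.delay, planted.rule_type)
            assert key in found
            assert found[key] == 1.0

    def test_missing_values_are_rejected(self, tiny_dataset, default_params):
        tiny_dataset.values[0, 0] = np.nan
        with pytest.raises(ValidationError, match="missing"):
            infer_rules_dataset(tiny_dataset, default_params)

    def test_delay_window_bound_enforced(self, tiny_dataset):
        params = InferenceParams(accuracy=0.75, scp=0.95, max_delay=3)
        with pytest.raises(ValidationError, match="window bound"):
            infer_rules_dataset(tiny_dataset, params)
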