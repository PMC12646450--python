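"""Sleep-architecture metrics: state percentages, censored latencies,
symbolic Lempel-Ziv complexity and transition matrices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canisleep.hypnogram import (compare_architecture, latency, lzc_normalized,
                                 lzc_sequence, percent_time,
                                 summarize_architecture, transition_matrix)
from canisleep.io import Hypnogram
from canisleep.synthetic import gen_hypnogram
from oracles import lzc_pointer


def _hyp(states, artifact=None):
    states = np.asarray(states, int)
    if artifact is None:
        artifact = np.zeros(states.size, bool)
    return Hypnogram(states, artifact)


class TestPercentTime:
    def test_mixed_states_arithmetic(self):
        pct = percent_time(_hyp([0] * 4 + [2] * 6))
        assert pct.tolist() == [40.0, 0.0, 60.0, 0.0]

    def test_single_state_degenerate(self):
        assert percent_time(_hyp([3] * 7)).tolist() == [0, 0, 0, 100.0]

    def test_sums_to_100_and_counts_artifact_epochs(self):
        hyp = _hyp([0, 1, 2], artifact=[True, True, True])
        pct = percent_time(hyp)
        assert pct.sum() == pytest.approx(100.0)
        assert pct[0] == pytest.approx(100.0 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percent_time(_hyp([]))


class TestLatency:
    def test_never_entered_state_censored_at_total_duration(self):
        hyp = _hyp([0] * 2400)          # 120 min of 3-s epochs
        lat, censored = latency(hyp, 3)
        assert (lat, censored) == (120.0, True)

    def test_state_at_first_epoch_has_zero_latency(self):
        assert latency(_hyp([3, 0, 0]), 3) == (0.0, False)

    def test_epoch_index_to_minutes(self):
        states = [0] * 40 + [3] * 5
        assert latency(_hyp(states), 3) == (2.0, False)


class TestLZC:
    def test_constant_sequence_has_complexity_two(self):
        assert lzc_sequence("0000000000") == 2

    def test_single_symbol(self):
        assert lzc_sequence("0") == 1

    def test_four_state_demo_sequence_matches_pointer_oracle(self):
        seq = "000011001100112221113333"
        assert lzc_sequence(seq) == lzc_pointer(seq)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lzc_sequence("")

    @given(st.lists(st.integers(0, 3), min_size=1, max_size=40))
    @settings(max_examples=300, deadline=None)
    def test_matches_pointer_oracle_on_quaternary_strings(self, seq):
        assert lzc_sequence(seq) == lzc_pointer(seq)

    @given(st.lists(st.integers(0, 3), min_size=1, max_size=30),
           st.permutations([0, 1, 2, 3]))
    @settings(max_examples=150, deadline=None)
    def test_invariant_under_alphabet_relabeling(self, seq, perm):
        relabeled = [perm[s] for s in seq]
        assert lzc_sequence(seq) == lzc_sequence(relabeled)

    def test_increases_with_markov_entropy_rate(self):
        """Stickier chains (dominant diagonal) give simpler hypnograms."""
        rng = np.random.default_rng(42)
        medians = []
        for diag in (0.99, 0.9, 0.75, 0.5):
            off = (1 - diag) / 3
            p = np.full((4, 4), off) + np.eye(4) * (diag - off)
            vals = [lzc_sequence(gen_hypnogram(p, 500, 0, rng))
                    for _ in range(50)]
            medians.append(np.median(vals))
        assert all(a <= b for a, b in zip(medians, medians[1:]))

    def test_normalized_variant_scale(self):
        rng = np.random.default_rng(0)
        seq = rng.integers(0, 2, 2000)
        assert 0.7 < lzc_normalized(seq, 2) < 1.2


class TestTransitionMatrix:
    def test_direct_counting(self):
        tm = transition_matrix(_hyp([0, 0, 1, 1]))
        assert tm.probs[0, 0] == 0.5
        assert tm.probs[0, 1] == 0.5
        assert tm.probs[1, 1] == 1.0
        assert tm.counts.sum() == 3

    def test_unvisited_rows_undefined_not_zero(self):
        tm = transition_matrix(_hyp([2, 2, 2, 2]))
        assert tm.probs[2, 2] == 1.0
        assert np.isnan(tm.probs[0]).all()
        assert np.isnan(tm.probs[3]).all()

    def test_defined_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        tm = transition_matrix(_hyp(rng.integers(0, 4, 500)))
        sums = np.nansum(tm.probs, axis=1)[tm.defined_rows]
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(_hyp([1]))

    def test_recovers_generating_markov_chain(self):
        p = np.array([[0.7, 0.2, 0.1, 0.0],
                      [0.1, 0.6, 0.2, 0.1],
                      [0.05, 0.15, 0.7, 0.1],
                      [0.2, 0.1, 0.2, 0.5]])
        states = gen_hypnogram(p, 10_000, 0, np.random.default_rng(7))
        tm = transition_matrix(_hyp(states))
        assert np.nanmax(np.abs(tm.probs - p)) < 0.02


class TestCompareArchitecture:
    def _summaries(self, seed, traz_like=False, n=12):
        from canisleep.synthetic import (_TRANSITIONS_CONTROL,
                                         _TRANSITIONS_TRAZODONE)
        rng = np.random.default_rng(seed)
        p = _TRANSITIONS_TRAZODONE if traz_like else _TRANSITIONS_CONTROL
        out = {}
        for k in range(n):
            states = gen_hypnogram(p, 600, 0, rng)
            out[f"dog{k}"] = summarize_architecture(
                _hyp(states))
        return out

    def test_identical_summaries_are_null(self):
        ctrl = self._summaries(1)
        res = compare_architecture(ctrl, ctrl)
        assert (res["p_value"] == 1.0).all()

    def test_fewer_than_two_common_subjects_rejected(self):
        ctrl = self._summaries(1)
        with pytest.raises(ValueError):
            compare_architecture(ctrl, {"dog0": ctrl["dog0"]})

    def test_sticky_chain_flagged_as_lower_lzc(self):
        """The trazodone-like chain has longer bouts, hence lower
        hypnogram complexity; the paired test should catch it."""
        hits = 0
        for rep in range(10):
            ctrl = self._summaries(100 + rep)
            traz = self._summaries(100 + rep, traz_like=True)
            res = compare_architecture(ctrl, traz).set_index(["metric",
                                                              "state"])
            if res.loc[("hypnogram_lzc", ""), "p_value"] < 0.05:
                hits += 1
        assert hits >= 8

    def test_censored_rem_latency_enters_at_total_duration(self):
        states = np.zeros(2400, int)
        summ = summarize_architecture(_hyp(states))
        assert summ.latency_min[3] == 120.0
        assert summ.censored[3]
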