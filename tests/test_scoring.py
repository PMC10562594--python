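import math

import numpy as np
import pytest

from recallorg.scoring import (
    adjacent_remote_summary,
    chance_level,
    extract_transitions,
    lag_crp,
    probability_of_first_recall,
    score_sequence,
    serial_position_curve,
    transition_factor,
)
from recallorg.simulate import generate_similarity
from recallorg.types import StudyList, ValidationError

from _oracle import brute_crp, brute_factor
from conftest import resolved_sequence


class TestExtractTransitions:
    def test_worked_lag_example(self):
        """Recalls at positions 5, 6, 2 give lags 1 and -4."""
        seq = resolved_sequence([5, 6, 2])
        trans = extract_transitions(seq, 32)
        assert [t.lag for t in trans] == [1, -4]

    def test_intrusion_invalidates_both_sides(self):
        seq = resolved_sequence([3, "ELI", 7])
        trans = extract_transitions(seq, 32)
        assert len(trans) == 2
        assert not any(t.valid for t in trans)

    def test_repetition_invalidates_both_sides(self):
        seq = resolved_sequence([3, 5, 3, 7])  # second 3 is a repetition
        trans = extract_transitions(seq, 32)
        assert [t.valid for t in trans] == [True, False, False]

    def test_possible_lag_sets_L4(self):
        seq = resolved_sequence([2, 3, 1])
        t1, t2 = extract_transitions(seq, 4)
        assert {q - t1.from_position for q in t1.possible_targets} == {-1, 1, 2}
        assert {q - t2.from_position for q in t2.possible_targets} == {-2, 1}

    def test_possible_excludes_recalled(self):
        seq = resolved_sequence([1, 2, 3, 4])
        trans = extract_transitions(seq, 8)
        assert trans[-1].possible_targets == frozenset({4, 5, 6, 7, 8})


class TestLagCRP:
    def test_hand_enumerated_L4(self):
        seq = resolved_sequence([2, 3, 1])
        curve = lag_crp(extract_transitions(seq, 4), 4)
        assert curve.crp_at(1) == 0.5
        assert curve.crp_at(-2) == 1.0
        assert curve.crp_at(-1) == 0.0
        assert curve.crp_at(2) == 0.0

    def test_conservation(self):
        seq = resolved_sequence([2, 3, 1])
        curve = lag_crp(extract_transitions(seq, 4), 4)
        assert curve.actual.sum() == 2

    def test_no_valid_transitions_all_undefined(self):
        seq = resolved_sequence([3, "ELI", 7])
        curve = lag_crp(extract_transitions(seq, 32), 32)
        assert np.isnan(curve.crp).all()

    def test_bounds(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 9))
            pos = list(rng.permutation(8)[:n] + 1)
            curve = lag_crp(extract_transitions(resolved_sequence(pos), 8), 8)
            assert (curve.actual <= curve.possible).all()
            crp = curve.crp
            defined = ~np.isnan(crp)
            assert ((crp[defined] >= 0) & (crp[defined] <= 1)).all()
            assert curve.actual.sum() == n - 1


class TestTransitionFactor:
    def test_worked_tf_example_L4(self):
        seq = resolved_sequence([2, 3, 1])
        fs = transition_factor(extract_transitions(seq, 4), "temporal")
        assert fs.scores == (0.75, 0.0)
        assert fs.mean == pytest.approx(0.375)

    def test_forward_serial_recall_is_one(self):
        seq = resolved_sequence(list(range(1, 11)))
        fs = transition_factor(extract_transitions(seq, 32), "temporal")
        assert fs.mean == 1.0

    def test_semantic_unique_maximizer_is_one(self, study32):
        # similarity structured so each recalled word's actual successor
        # uniquely maximizes similarity among available candidates
        sim = generate_similarity(seed=8)
        study = StudyList("L1", sim.vocabulary)
        # find a designated pair and recall its two members consecutively
        i, j = np.unravel_index(
            np.argmax(np.triu(sim.values, 1)), sim.values.shape
        )
        seq = resolved_sequence([int(i) + 1, int(j) + 1])
        fs = transition_factor(
            extract_transitions(seq, 32), "semantic", study=study, sim=sim
        )
        assert fs.scores == (1.0,)

    def test_single_possible_target_excluded(self):
        # L=2: after recalling position 1, only position 2 remains (N=1)
        seq = resolved_sequence([1, 2])
        fs = transition_factor(extract_transitions(seq, 2), "temporal")
        assert fs.n_transitions == 0
        assert math.isnan(fs.mean)

    def test_semantic_requires_matrix(self):
        seq = resolved_sequence([1, 2])
        with pytest.raises(ValidationError):
            transition_factor(extract_transitions(seq, 4), "semantic")

    def test_scores_in_unit_interval(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 9))
            pos = list(rng.permutation(8)[:n] + 1)
            fs = transition_factor(
                extract_transitions(resolved_sequence(pos), 8), "temporal"
            )
            assert all(0 <= s <= 1 for s in fs.scores)

    def test_semantic_possible_all_mode(self):
        sim = generate_similarity(L=4, n_pairs=2, seed=1)
        study = StudyList("L1", sim.vocabulary)
        seq = resolved_sequence([1, 2, 3, 4])
        restricted = transition_factor(
            extract_transitions(seq, 4), "semantic", study=study, sim=sim
        )
        unrestricted = transition_factor(
            extract_transitions(seq, 4), "semantic", study=study, sim=sim,
            semantic_possible="all",
        )
        # restricted mode drops the final N=1 transition; the unrestricted
        # reading ranks every transition within all 3 other list words
        assert restricted.n_transitions == 2
        assert unrestricted.n_transitions == 3


def test_chance_level():
    assert chance_level() == 0.5


def _random_instance(rng, L):
    """Random resolved transcript over L positions with rare errors."""
    n = int(rng.integers(2, L + 1))
    pos = list(rng.permutation(L)[:n] + 1)
    out = []
    for p in pos:
        r = rng.random()
        if r < 0.1:
            out.append("ELI")
        elif r < 0.15 and out and isinstance(out[0], (int, np.integer)):
            out.append(int(out[0]))  # repetition of the first recall
        out.append(int(p))
    return out


class TestOracleEquivalence:
    """Scoring agrees exactly with an independent brute-force enumerator."""

    def test_small_instances(self, rng):
        sim = generate_similarity(L=8, n_pairs=4, seed=123)
        study = StudyList("L1", sim.vocabulary)
        for _ in range(300):
            L = int(rng.integers(3, 9))
            entries = _random_instance(rng, L)
            seq = resolved_sequence(entries)
            labeled = []
            seen = set()
            for e in entries:
                if e == "ELI":
                    labeled.append(("ELI", None))
                elif e in seen:
                    labeled.append(("repetition", e))
                else:
                    seen.add(e)
                    labeled.append(("correct", e))
            trans = extract_transitions(seq, L)

            tf = transition_factor(trans, "temporal")
            oracle_tf = brute_factor(
                labeled, L, key=lambda frm, q: -abs(q - frm)
            )
            assert list(tf.scores) == pytest.approx(oracle_tf)

            sf = transition_factor(trans, "semantic", study=study, sim=sim)
            oracle_sf = brute_factor(
                labeled, L,
                key=lambda frm, q: sim.similarity(
                    study.word_at(frm), study.word_at(q)
                ),
            )
            assert list(sf.scores) == pytest.approx(oracle_sf)

            curve = lag_crp(trans, L)
            oracle_actual, oracle_possible = brute_crp(labeled, L)
            for lag in list(range(-(L - 1), 0)) + list(range(1, L)):
                assert curve.actual_at(lag) == oracle_actual.get(lag, 0)
                assert curve.possible_at(lag) == oracle_possible.get(lag, 0)


class TestAdjacentRemote:
    def test_simple_arithmetic(self):
        seq = resolved_sequence([1, 2, 3])
        curve = lag_crp(extract_transitions(seq, 32), 32)
        # build a curve-like check via the real API on crafted counts
        s = adjacent_remote_summary(curve)
        assert s["forward_adjacent"] == pytest.approx(
            np.nanmean([curve.crp_at(1), curve.crp_at(2)])
        )

    def test_known_values(self):
        from recallorg.scoring import CRPCurve

        L = 32
        actual = np.zeros(2 * (L - 1), dtype=int)
        possible = np.zeros(2 * (L - 1), dtype=int)
        curve = CRPCurve(L=L, actual=actual, possible=possible)
        possible[curve._idx(1)] = 10
        actual[curve._idx(1)] = 4
        possible[curve._idx(2)] = 10
        actual[curve._idx(2)] = 2
        s = adjacent_remote_summary(curve)
        assert s["forward_adjacent"] == pytest.approx(0.3)
        assert math.isnan(s["forward_remote"])
        assert math.isnan(s["backward_adjacent"])

    def test_all_undefined(self):
        seq = resolved_sequence([3, "ELI", 7])
        curve = lag_crp(extract_transitions(seq, 32), 32)
        s = adjacent_remote_summary(curve)
        assert all(math.isnan(v) for v in s.values())

    def test_remote_bound_respects_16(self):
        seq = resolved_sequence([1, 20])  # lag +19 beyond the remote bound
        curve = lag_crp(extract_transitions(seq, 32), 32)
        s = adjacent_remote_summary(curve)
        # lag +19 was actual but must not enter the forward-remote pool
        pool = [curve.crp_at(k) for k in range(3, 17)]
        assert s["forward_remote"] == pytest.approx(np.nanmean(pool))


class TestCurves:
    def _measures(self, position_sets, L=32, study=None, sim=None):
        study = study or StudyList("L1", tuple(f"w{i}" for i in range(1, L + 1)))
        out = []
        for i, pos in enumerate(position_sets):
            seq = resolved_sequence(list(pos), subject_id=f"s{i}")
            out.append(score_sequence(seq, study, sim=sim))
        return out

    def test_spc_first_bin_only(self):
        meas = self._measures([range(1, 9)] * 5)
        per_pos, bins = serial_position_curve(meas, 32, n_bins=4)
        assert bins[0] == 1.0
        assert bins[1:].sum() == 0.0
        assert per_pos[:8].sum() == 8

    def test_spc_indivisible_bins_error(self):
        meas = self._measures([[1, 2]])
        with pytest.raises(ValidationError, match="divisible"):
            serial_position_curve(meas, 32, n_bins=5)

    def test_spc_uniform_random(self, rng):
        sets = [rng.permutation(32)[:12] + 1 for _ in range(2000)]
        meas = self._measures(sets)
        _, bins = serial_position_curve(meas, 32)
        assert np.allclose(bins, 12 / 32, atol=0.01)

    def test_pfr_point_mass(self):
        meas = self._measures([[32, 1], [32, 5]])
        pfr = probability_of_first_recall(meas, 32)
        assert pfr[31] == 1.0
        assert pfr.sum() == pytest.approx(1.0)

    def test_pfr_sums_to_one(self, rng):
        sets = [rng.permutation(32)[:5] + 1 for _ in range(40)]
        meas = self._measures(sets)
        assert probability_of_first_recall(meas, 32).sum() == pytest.approx(1.0)

    def test_pfr_uniform_starters(self, rng):
        sets = [[int(rng.integers(1, 33))] for _ in range(5000)]
        meas = self._measures(sets)
        pfr = probability_of_first_recall(meas, 32)
        assert np.allclose(pfr, 1 / 32, atol=0.01)


class TestScoreSequence:
    def test_counts_and_pfr(self, study32):
        seq = resolved_sequence([5, "ELI", 6, 5, "PLI", 2])
        m = score_sequence(seq, study32)
        assert m.n_correct == 3
        assert m.n_eli == 1
        assert m.n_pli == 1
        assert m.n_repetition == 1
        assert m.pfr_position == 5
        assert m.spc[[4, 5, 1]].sum() == 3

    def test_factor_nan_when_unscorable(self, study32):
        seq = resolved_sequence([5])
        m = score_sequence(seq, study32)
        assert math.isnan(m.temporal_factor)
        assert m.pfr_position == 5
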