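"""Mutual information, padding alignment, averaging, scale normalisation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import mutual_info_score

from plantarpress import CohortConfig, generate_cohort
from plantarpress.preprocessing import (
    AlignmentError,
    MI_TIE_TOL,
    SubjectSignalSet,
    aggregate_subject,
    align_trial,
    max_walking_vertical_force,
    mutual_information_2d,
    normalize_scale,
    preprocess_cohort,
    select_reference,
)


def reference_mi(x, y, n_bins=256):
    """Independent MI route: numpy 2D histogram + sklearn contingency MI."""
    joint, _, _ = np.histogram2d(x, y, bins=n_bins)
    return mutual_info_score(None, None, contingency=joint + 1e-300)


def brute_force_alignment(values, reference, n_bins=256):
    """Enumerate every padding, score with the independent MI route."""
    n, m = len(values), len(reference)
    mis = []
    for left in range(m - n + 1):
        padded = np.zeros(m)
        padded[left:left + n] = values
        mis.append(reference_mi(padded, reference, n_bins))
    mis = np.asarray(mis)
    return int(np.flatnonzero(mis >= mis.max() - MI_TIE_TOL)[0]), mis


class TestMutualInformation:
    def test_identical_four_level_signal_gives_ln4(self):
        x = np.repeat([0.0, 1.0, 2.0, 3.0], 8)
        assert mutual_information_2d(x, x) == pytest.approx(np.log(4), abs=1e-12)

    def test_constant_signal_gives_zero(self):
        assert mutual_information_2d(np.zeros(10), np.arange(10.0)) == 0.0

    def test_factorizing_joint_gives_zero(self):
        x = np.array([0.0, 0.0, 1.0, 1.0])
        y = np.array([0.0, 1.0, 0.0, 1.0])
        assert mutual_information_2d(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            mutual_information_2d(np.zeros(3), np.zeros(4))

    def test_matches_histogram2d_route(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            n = int(rng.integers(10, 200))
            x = rng.normal(0, 1, n)
            y = 0.5 * x + rng.normal(0, 1, n)
            assert mutual_information_2d(x, y) == pytest.approx(
                reference_mi(x, y), abs=1e-9)

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=40),
           st.integers(0, 1000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_symmetry_and_nonnegativity(self, xs, seed):
        x = np.asarray(xs)
        y = np.random.default_rng(seed).permutation(x) + 0.1
        mi_xy = mutual_information_2d(x, y)
        mi_yx = mutual_information_2d(y, x)
        assert mi_xy >= 0.0
        assert mi_xy == pytest.approx(mi_yx, abs=1e-9)


class TestSelectReference:
    def test_longest_run_trial_wins(self, tiny_cohort):
        _, store, _, _ = tiny_cohort
        for fw in ("barefoot", "shod"):
            ref = select_reference(store, fw)
            lengths = [len(t.values) for t in store.iter_trials(
                footwear=fw, gait="run")]
            assert ref.length == max(lengths)
            assert set(ref.signals) == {"mean_pressure", "peak_pressure",
                                        "mean_force", "vertical_force"}

    def test_tie_breaks_to_lowest_subject_and_trial(self, make_trial):
        from plantarpress.cohort import TrialStore
        store = TrialStore([
            make_trial(np.ones(5), subject_id="S2", trial_index=0),
            make_trial(np.ones(5), subject_id="S1", trial_index=1),
            make_trial(np.ones(5), subject_id="S1", trial_index=0),
        ])
        ref = select_reference(store, "barefoot")
        assert (ref.subject_id, ref.trial_index) == ("S1", 0)

    def test_empty_store_raises(self):
        from plantarpress.cohort import TrialStore
        with pytest.raises(AlignmentError):
            select_reference(TrialStore(), "barefoot")


class TestAlignTrial:
    def test_equal_length_identity(self, make_trial):
        ref = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
        at = align_trial(make_trial(ref), ref)
        assert (at.left_pad, at.right_pad) == (0, 0)
        np.testing.assert_array_equal(at.values, ref)

    def test_trial_longer_than_reference_raises(self, make_trial):
        with pytest.raises(AlignmentError):
            align_trial(make_trial(np.ones(6)), np.ones(4))

    def test_recovers_slice_offset_noise_free(self, make_trial):
        ref = np.concatenate([np.zeros(6),
                              np.sin(np.linspace(0, np.pi, 40)) ** 2 * 90,
                              np.zeros(8)])
        a, b = 4, 50
        at = align_trial(make_trial(ref[a:b]), ref)
        assert at.left_pad == a
        assert at.left_pad + len(ref[a:b]) + at.right_pad == len(ref)

    def test_padding_preserves_value_multiset(self, make_trial):
        rng = np.random.default_rng(3)
        ref = np.abs(rng.normal(0, 1, 30))
        x = np.abs(rng.normal(0, 1, 12))
        at = align_trial(make_trial(x), ref)
        assert sorted(at.values[at.values != 0]) == sorted(x[x != 0])
        assert np.count_nonzero(at.values == 0) >= 30 - 12

    def test_matches_brute_force_enumeration(self, make_trial):
        rng = np.random.default_rng(21)
        for _ in range(40):
            m = int(rng.integers(15, 70))
            n = int(rng.integers(4, m + 1))
            ref = np.abs(rng.normal(0, 1, m))
            ref[:int(rng.integers(0, 4))] = 0.0
            x = np.abs(rng.normal(0, 1, n))
            at = align_trial(make_trial(x), ref)
            oracle_left, mis = brute_force_alignment(x, ref)
            assert at.left_pad == oracle_left
            assert at.mi == pytest.approx(mis[at.left_pad], abs=1e-9)


class TestAggregation:
    def test_identical_trials_average_to_themselves(self):
        x = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(aggregate_subject([x, x, x]), x)

    def test_zero_twin_halves_values(self):
        x = np.array([2.0, 4.0])
        np.testing.assert_array_equal(aggregate_subject([x, np.zeros(2)]),
                                      x / 2)

    def test_empty_and_ragged_inputs_raise(self):
        with pytest.raises(AlignmentError):
            aggregate_subject([])
        with pytest.raises(AlignmentError):
            aggregate_subject([np.zeros(3), np.zeros(4)])


class TestNormalization:
    def _signal_set(self, scale=1.0):
        return SubjectSignalSet("S0", {
            ("toe_1", "mean_pressure", "barefoot"): scale * np.array([400.0, 800.0]),
            ("midfoot", "mean_force", "shod"): scale * np.array([100.0, 50.0]),
            ("whole_foot", "vertical_force", "barefoot"): scale * np.array([700.0, 900.0]),
        })

    def test_divides_by_walking_maximum(self):
        out = normalize_scale(self._signal_set(), 800.0)
        np.testing.assert_array_equal(
            out.signals[("toe_1", "mean_pressure", "barefoot")], [0.5, 1.0])
        assert out.scale_factor == 800.0

    def test_vertical_force_not_rescaled(self):
        out = normalize_scale(self._signal_set(), 800.0)
        np.testing.assert_array_equal(
            out.signals[("whole_foot", "vertical_force", "barefoot")],
            [700.0, 900.0])

    def test_zone_ratios_preserved(self):
        sset = self._signal_set()
        out = normalize_scale(sset, 640.0)
        a = ("toe_1", "mean_pressure", "barefoot")
        b = ("midfoot", "mean_force", "shod")
        np.testing.assert_allclose(out.signals[a] / out.signals[b],
                                   sset.signals[a] / sset.signals[b])

    def test_proportional_subjects_normalize_identically(self):
        out1 = normalize_scale(self._signal_set(1.0), 800.0)
        out2 = normalize_scale(self._signal_set(2.5), 2.5 * 800.0)
        for key in out1.signals:
            if key[1] != "vertical_force":
                np.testing.assert_allclose(out1.signals[key],
                                           out2.signals[key])

    def test_unit_scale_is_identity(self):
        sset = self._signal_set()
        out = normalize_scale(sset, 1.0)
        for key, sig in sset.signals.items():
            np.testing.assert_array_equal(out.signals[key], sig)

    def test_nonpositive_scale_raises(self):
        with pytest.raises(AlignmentError):
            normalize_scale(self._signal_set(), 0.0)


class TestPreprocessCohort:
    def test_signal_inventory_and_lengths(self, tiny_cohort):
        _, store, _, _ = tiny_cohort
        signal_sets, info = preprocess_cohort(store)
        ref_len = {fw: info["references"][fw]["length"]
                   for fw in ("barefoot", "shod")}
        assert len(signal_sets) == 8
        for sset in signal_sets.values():
            assert len(sset.signals) == 62  # (10*3 + 1) * 2 footwears
            for (zone, meas, fw), sig in sset.signals.items():
                assert sig.size == ref_len[fw]
            assert sset.scale_factor > 0

    def test_walking_maximum_used_as_scale(self, tiny_cohort):
        _, store, _, _ = tiny_cohort
        signal_sets, _ = preprocess_cohort(store)
        for sid, sset in signal_sets.items():
            assert sset.scale_factor == pytest.approx(
                max_walking_vertical_force(store, sid))
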