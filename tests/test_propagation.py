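"""Pair association, lead-lag matrices, velocity fitting, and controls."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mycospike.propagation import (AssociationParams, SeparationDelay,
                                   associate_spike_pairs, delay_distribution,
                                   delay_vs_separation, fit_velocity,
                                   lead_lag_matrix, surrogate_control,
                                   threshold_sensitivity,
                                   velocity_from_adjacent)
from mycospike.trains import SpikeTrain


def train(channel, onsets, duration=1e5):
    return SpikeTrain(channel, np.asarray(onsets, dtype=float), duration)


FIXED = AssociationParams(window_policy="fixed")


class TestAssociation:
    def test_onsets_outside_window_never_pair(self):
        pairs = associate_spike_pairs(train(0, [0.0]), train(1, [400.0]), FIXED)
        assert pairs == []

    def test_unique_candidate_pairs_with_signed_delay(self):
        pairs = associate_spike_pairs(train(0, [0.0]), train(1, [120.0]), FIXED)
        assert len(pairs) == 1
        assert pairs[0].delay == 120.0

    def test_greedy_tie_prefers_smaller_lead_onset(self):
        """Leads at 0 and 10 compete for the lag at 5: both are 5 s away, and
        the tie rule assigns the earlier lead, giving delay +5."""
        pairs = associate_spike_pairs(train(0, [0.0, 10.0]), train(1, [5.0]),
                                      FIXED)
        assert len(pairs) == 1
        assert pairs[0].lead_onset == 0.0
        assert pairs[0].delay == 5.0

    def test_one_to_one_uses_each_spike_once(self):
        pairs = associate_spike_pairs(
            train(0, [0.0, 50.0]), train(1, [10.0, 60.0]), FIXED)
        assert len(pairs) == 2
        assert {p.lead_onset for p in pairs} == {0.0, 50.0}
        assert {p.lag_onset for p in pairs} == {10.0, 60.0}
        assert all(p.delay == 10.0 for p in pairs)

    def test_all_pairs_keeps_every_candidate(self):
        params = AssociationParams(window_policy="fixed", matching="all_pairs")
        pairs = associate_spike_pairs(
            train(0, [0.0, 100.0]), train(1, [50.0]), params)
        assert len(pairs) == 2

    def test_scaled_policy_widens_window_with_separation(self):
        lead, lag = train(0, [0.0]), train(2, [450.0])
        scaled = AssociationParams(window_policy="scaled")
        assert associate_spike_pairs(lead, lag, scaled) != []
        assert associate_spike_pairs(lead, lag, FIXED) == []

    def test_empty_trains_give_empty_list(self):
        assert associate_spike_pairs(train(0, []), train(1, [5.0]), FIXED) == []

    @given(st.lists(st.integers(0, 10_000), min_size=1, max_size=30,
                    unique=True),
           st.lists(st.integers(0, 10_000), min_size=1, max_size=30,
                    unique=True))
    def test_window_bound_and_antisymmetry(self, a, b):
        """No reported delay exceeds the window, and swapping lead/lag
        channels negates every matched delay."""
        ta = train(0, sorted(float(x) for x in a))
        tb = train(1, sorted(float(x) + 0.5 for x in b))
        fwd = associate_spike_pairs(ta, tb, FIXED)
        rev = associate_spike_pairs(tb, ta, FIXED, separation=-1)
        for p in fwd:
            assert abs(p.delay) <= FIXED.dt_max
        assert sorted(p.delay for p in fwd) == \
            sorted(-p.delay for p in rev)


class TestDelayDistribution:
    def test_median_of_three(self):
        pairs = associate_spike_pairs(
            train(0, [0.0, 1000.0, 2000.0]),
            train(1, [10.0, 1020.0, 2030.0]), FIXED)
        summary = delay_distribution(pairs)
        assert summary["median"] == 20.0
        assert summary["n"] == 3

    def test_symmetric_delays_have_zero_median(self):
        pairs = associate_spike_pairs(
            train(0, [100.0, 1000.0]), train(1, [50.0, 1050.0]), FIXED)
        assert delay_distribution(pairs)["median"] == 0.0

    def test_empty_summary_is_explicit(self):
        summary = delay_distribution([])
        assert summary["n"] == 0
        assert np.isnan(summary["median"])


class TestLeadLagMatrix:
    def test_identical_trains_give_zero_delays(self):
        onsets = [0.0, 1000.0, 5000.0]
        mat = lead_lag_matrix([train(c, onsets) for c in range(3)], FIXED)
        assert np.allclose(mat.median_delay, 0.0)
        assert mat.monotone_ordering() is False  # zero is not positive

    def test_uniformly_shifted_trains_recover_linear_delays(self):
        """Channel c shifted by 60c s: entry (c, d) = 60 (d - c) under the
        scaled window policy."""
        base = np.array([0.0, 3000.0, 9000.0, 15000.0])
        trains = [train(c, base + 60.0 * c) for c in range(4)]
        mat = lead_lag_matrix(trains, AssociationParams(window_policy="scaled"))
        for c in range(4):
            for d in range(4):
                assert mat.median_delay[c, d] == pytest.approx(60.0 * (d - c))
        assert mat.monotone_ordering()

    def test_zero_pair_entries_flagged_undefined(self):
        trains = [train(0, [0.0]), train(1, [5000.0])]
        mat = lead_lag_matrix(trains, FIXED)
        assert np.isnan(mat.median_delay[0, 1])
        assert mat.pair_count[0, 1] == 0

    @given(st.integers(0, 2**31 - 1))
    def test_global_time_shift_leaves_matrix_unchanged(self, seed):
        rng = np.random.default_rng(seed)
        base = np.sort(rng.uniform(0, 5e4, 15))
        trains = [train(c, np.unique(base + 100.0 * c + rng.normal(0, 5, 15)))
                  for c in range(3)]
        shifted = [SpikeTrain(t.channel, t.onsets + 7000.0, t.duration + 7000.0)
                   for t in trains]
        a = lead_lag_matrix(trains, FIXED)
        b = lead_lag_matrix(shifted, FIXED)
        np.testing.assert_allclose(a.median_delay, b.median_delay)
        np.testing.assert_array_equal(a.pair_count, b.pair_count)


class TestSeparationAndVelocity:
    def test_pooling_by_separation(self):
        """Three channels with single-pair entries 100, 100 and 200 s pool
        into medians 100 s at 2 cm and 200 s at 4 cm."""
        base = [0.0, 5000.0]
        trains = [train(0, base),
                  train(1, [100.0, 5100.0]),
                  train(2, [200.0, 5200.0])]
        mat = lead_lag_matrix(trains, AssociationParams(window_policy="scaled"))
        seps = delay_vs_separation(mat, spacing_cm=2.0)
        assert seps[0].median_delay == 100.0 and seps[0].distance_cm == 2.0
        assert seps[1].median_delay == 200.0 and seps[1].distance_cm == 4.0

    def test_undefined_separations_reported_with_zero_pairs(self):
        trains = [train(0, [0.0]), train(1, [50.0]), train(2, [])]
        mat = lead_lag_matrix(trains, FIXED)
        seps = delay_vs_separation(mat)
        assert seps[1].n_pairs == 0
        assert np.isnan(seps[1].median_delay)

    def test_exact_line_yields_closed_form_velocity(self):
        """Medians 90 s per separation step at 2 cm spacing: slope 45 s/cm,
        velocity 60/45 = 1.333 cm/min."""
        pts = [SeparationDelay(s, 2.0 * s, 90.0 * s, 10) for s in range(1, 8)]
        est = fit_velocity(pts)
        assert est.slope == pytest.approx(45.0)
        assert est.velocity_cm_per_min == pytest.approx(4.0 / 3.0)
        assert est.velocity_cm_per_h == pytest.approx(80.0)
        for s, v in est.per_separation_velocities.items():
            assert v == pytest.approx(4.0 / 3.0)

    def test_constant_medians_leave_velocity_undefined(self):
        pts = [SeparationDelay(s, 2.0 * s, 150.0, 5) for s in range(1, 5)]
        est = fit_velocity(pts)
        assert est.slope == pytest.approx(0.0)
        assert est.velocity_cm_per_min is None

    def test_too_few_separations_raise(self):
        with pytest.raises(ValueError):
            fit_velocity([SeparationDelay(1, 2.0, 100.0, 3)])

    @pytest.mark.parametrize("delay,spacing,v_min", [
        (180.0, 2.0, 2.0 / 3.0),
        (60.0, 2.0, 2.0),
        (120.0, 4.0, 2.0),
    ])
    def test_velocity_from_adjacent(self, delay, spacing, v_min):
        got_min, got_h = velocity_from_adjacent(delay, spacing)
        assert got_min == pytest.approx(v_min)
        assert got_h == pytest.approx(60.0 * v_min)

    def test_nonpositive_delay_rejected(self):
        with pytest.raises(ValueError):
            velocity_from_adjacent(0.0, 2.0)


class TestSurrogates:
    def _propagating_trains(self, seed=0, n=20, n_channels=8):
        rng = np.random.default_rng(seed)
        base = np.sort(rng.uniform(0, 9e4, n))
        base = base[np.concatenate(([True], np.diff(base) > 3000))]
        return [train(c, np.sort(base + 170.0 * c + rng.normal(0, 10, base.size)))
                for c in range(n_channels)]

    def test_counts_preserved_in_every_surrogate(self):
        from mycospike.propagation import _randomise_train

        trains = self._propagating_trains()
        rng = np.random.default_rng(1)
        for mode in ("redraw", "isi_shuffle"):
            for tr in trains:
                surr = _randomise_train(tr, rng, mode)
                assert surr.n_spikes == tr.n_spikes
                assert surr.onsets[0] >= 0 and surr.onsets[-1] <= surr.duration
                assert np.all(np.diff(surr.onsets) > 0)
                if mode == "isi_shuffle":
                    np.testing.assert_allclose(
                        np.sort(np.diff(surr.onsets)),
                        np.sort(np.diff(tr.onsets)))

    def test_fixed_seed_reproduces_ensemble(self):
        trains = self._propagating_trains()
        _, a = surrogate_control(trains, 10, seed=99)
        _, b = surrogate_control(trains, 10, seed=99)
        np.testing.assert_array_equal(a.pooled_adjacent_medians,
                                      b.pooled_adjacent_medians)
        assert a.monotone_fraction == b.monotone_fraction

    def test_surrogates_collapse_delays_toward_zero(self):
        trains = self._propagating_trains(seed=3, n=40)
        observed = lead_lag_matrix(trains, AssociationParams())
        assert observed.monotone_ordering()
        _, summary = surrogate_control(trains, 50, seed=5)
        assert abs(np.nanmedian(summary.pooled_adjacent_medians)) < 60.0
        assert summary.monotone_fraction <= 0.05


class TestSensitivity:
    def test_counts_non_increasing_and_sign_stable(self, small_synthetic):
        rec, _ = small_synthetic
        table = threshold_sensitivity(rec, [1.5, 2.0, 2.5])
        counts = table.n_spikes.to_numpy()
        assert np.all(np.diff(counts) <= 0)
        assert (table.adjacent_delay_sign > 0).all()

    def test_single_k_degenerate_report(self, small_synthetic):
        rec, _ = small_synthetic
        table = threshold_sensitivity(rec, [2.0])
        assert len(table) == 1

    def test_empty_k_list_rejected(self, small_synthetic):
        rec, _ = small_synthetic
        with pytest.raises(ValueError):
            threshold_sensitivity(rec, [])
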