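"""FRET computation, event calling, at-risk time, and rate estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synapsefret import (
    KineticModel,
    AcquisitionConfig,
    ParameterError,
    compute_fret,
    detect_sr_events,
    estimate_rate,
    fold_change,
    observable_time,
    poisson_rate_ci,
    simulate_experiment,
)
from synapsefret.fretcore import MoleculeRecord
from synapsefret.pipeline import analyze_trajectories
from synapsefret.config import PipelineConfig

from conftest import brute_force_event_spans, make_fret_trace, make_trajectory


class TestComputeFret:
    @pytest.mark.parametrize(
        "i_d,i_a,bg_d,bg_a,expected",
        [
            (500.0, 500.0, 0.0, 0.0, 0.5),
            (300.0, 100.0, 0.0, 0.0, 0.25),
            (550.0, 150.0, 50.0, 50.0, 100.0 / 600.0),
        ],
    )
    def test_apparent_efficiency_arithmetic(self, i_d, i_a, bg_d, bg_a, expected):
        traj = make_trajectory([i_d] * 12, [i_a] * 12)
        ft = compute_fret(traj, bg_d, bg_a)
        assert ft.efficiency[ft.valid] == pytest.approx(expected)

    def test_nonpositive_denominator_masks_frame(self):
        donor = np.full(12, 500.0)
        acceptor = np.full(12, 100.0)
        donor[3] = -200.0  # denominator goes negative on a donor frame
        ft = compute_fret(make_trajectory(donor, acceptor), 0.0, 0.0)
        # frame 3 is the 4th donor-excitation frame
        assert not ft.valid[3]
        assert ft.valid.sum() == ft.valid.size - 1

    def test_acceptor_presence_follows_direct_excitation_signal(self):
        # direct frames (every 5th) dark from the 4th direct frame on
        n = 30
        donor = np.full(n, 500.0)
        acceptor = np.full(n, 500.0)
        traj = make_trajectory(donor, acceptor)
        direct = ~traj.donor_excitation()
        idx_a = np.flatnonzero(direct)
        acceptor[idx_a[3:]] = 0.0
        traj = make_trajectory(donor, acceptor)
        ft = compute_fret(traj, 0.0, 0.0)
        # donor frames before the 4th direct frame still have the acceptor
        dark_from = traj.time_s[idx_a[3]]
        assert ft.acceptor_present[ft.times < dark_from].all()
        assert not ft.acceptor_present[ft.times > dark_from].any()


class TestEventCalling:
    def test_five_consecutive_frames_above_threshold_is_one_event(self):
        e = [0, 0, 0.5, 0.5, 0.5, 0.5, 0.5, 0, 0, 0, 0, 0]
        ft = make_fret_trace(e)
        es = detect_sr_events(ft, threshold=0.25, min_frames=5)
        assert len(es.events) == 1
        ev = es.events[0]
        assert ev.start_s == ft.times[2]
        assert ev.end_s == ft.times[7]
        assert not ev.censored and not ev.preformed

    def test_run_of_four_is_no_event(self):
        e = [0, 0.5, 0.5, 0.5, 0.5, 0, 0, 0, 0, 0]
        es = detect_sr_events(make_fret_trace(e), 0.25, 5)
        assert es.events == []

    def test_run_reaching_truncation_is_censored_and_ligated(self):
        e = [0.0] * 5 + [0.5] * 7
        ft = make_fret_trace(e)
        es = detect_sr_events(ft, 0.25, 5)
        assert len(es.events) == 1
        ev = es.events[0]
        assert ev.censored and ev.ligated
        assert ev.end_s == ft.truncation_time_s

    def test_run_from_first_frame_is_flagged_preformed(self):
        e = [0.5] * 8 + [0.0] * 6
        es = detect_sr_events(make_fret_trace(e), 0.25, 5)
        assert len(es.events) == 1
        assert es.events[0].preformed
        assert es.n_events == 0  # not a witnessed formation

    def test_parameter_validation(self):
        ft = make_fret_trace([0.0] * 10)
        with pytest.raises(ParameterError):
            detect_sr_events(ft, 0.25, 0)
        with pytest.raises(ParameterError):
            detect_sr_events(ft, 1.5, 5)

    def test_matches_brute_force_window_scan_on_random_traces(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = rng.integers(5, 60)
            e = rng.choice([0.0, 0.5], size=n, p=[0.6, 0.4])
            m = int(rng.integers(2, 7))
            ft = make_fret_trace(e)
            es = detect_sr_events(ft, 0.25, m)
            assert es.spans == brute_force_event_spans(e > 0.25, m)

    @settings(derandomize=True, max_examples=250, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=-0.1, max_value=1.1, allow_nan=False),
            min_size=1,
            max_size=60,
        ),
        st.integers(min_value=1, max_value=8),
    )
    def test_event_spans_match_oracle_for_arbitrary_traces(self, effs, m):
        ft = make_fret_trace(effs)
        es = detect_sr_events(ft, 0.25, m)
        assert es.spans == brute_force_event_spans(np.asarray(effs) > 0.25, m)

    def test_raising_threshold_or_min_frames_never_adds_events(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            e = np.clip(rng.normal(0.25, 0.25, rng.integers(20, 80)), -0.1, 1.1)
            ft = make_fret_trace(e)
            for lo, hi in [(0.2, 0.3), (0.25, 0.4)]:
                assert len(detect_sr_events(ft, hi, 5).events) <= len(
                    detect_sr_events(ft, lo, 5).events
                )
            for m_lo, m_hi in [(3, 5), (5, 8)]:
                assert len(detect_sr_events(ft, 0.25, m_hi).events) <= len(
                    detect_sr_events(ft, 0.25, m_lo).events
                )


class TestObservableTime:
    def _trace_900s(self, high_windows=(), truncation_s=900.0):
        """E series for a 900 s acquisition truncated at truncation_s."""
        n_frames = int(truncation_s / 2.0)
        donor_idx = [f for f in range(n_frames) if f % 5 != 4]
        times = np.array(donor_idx) * 2.0
        e = np.full(len(donor_idx), 0.05)
        for a, b in high_windows:
            e[(times >= a) & (times < b)] = 0.5
        return make_fret_trace(e, truncation_time_s=truncation_s)

    def test_eventless_trace_yields_truncated_duration(self):
        ft = self._trace_900s(truncation_s=500.0)
        es = detect_sr_events(ft, 0.25, 5)
        assert observable_time(ft, es) == pytest.approx(500.0)

    def test_event_persisting_to_truncation_stops_the_clock(self):
        ft = self._trace_900s(high_windows=[(300.0, 900.0)], truncation_s=900.0)
        es = detect_sr_events(ft, 0.25, 5)
        assert es.n_events == 1
        assert observable_time(ft, es) == pytest.approx(300.0)

    def test_reversible_event_returns_molecule_to_risk_pool(self):
        ft = self._trace_900s(high_windows=[(300.0, 400.0)], truncation_s=600.0)
        es = detect_sr_events(ft, 0.25, 5)
        assert es.n_events == 1
        assert observable_time(ft, es) == pytest.approx(500.0)

    def test_total_mode_keeps_in_event_time(self):
        ft = self._trace_900s(high_windows=[(300.0, 400.0)], truncation_s=600.0)
        es = detect_sr_events(ft, 0.25, 5)
        assert observable_time(ft, es, mode="total") == pytest.approx(600.0)

    def test_at_risk_and_in_event_frames_partition_the_trace(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            e = rng.choice([0.05, 0.5], size=60, p=[0.5, 0.5])
            ft = make_fret_trace(e)
            es = detect_sr_events(ft, 0.25, 5)
            t_risk = observable_time(ft, es)
            n_in_event = sum(b - a for a, b in es.spans)
            assert t_risk + n_in_event * ft.time_quantum_s == pytest.approx(
                60 * ft.time_quantum_s
            )


class TestRateEstimate:
    def test_rate_is_events_over_observable_time(self):
        recs = [
            MoleculeRecord("a", 0, 10, 6000.0),
            MoleculeRecord("b", 1, 7, 4000.0),
        ]
        est = estimate_rate(recs, condition="wt")
        assert est.rate_per_s == pytest.approx(17.0 / 10_000.0)
        assert est.n_events == 17 and est.t_observable_s == 10_000.0
        assert est.ci95 is not None  # two replicates

    def test_zero_events_exact_poisson_upper_bound(self):
        est = estimate_rate([MoleculeRecord("a", 0, 0, 10_000.0)])
        assert est.rate_per_s == 0.0
        assert est.ci95 is None  # single replicate
        lo, hi = est.poisson_ci95
        assert lo == 0.0
        assert hi == pytest.approx(-math.log(0.025) / 10_000.0, rel=1e-6)

    def test_zero_event_replicate_counts_as_rate_zero(self):
        recs = [
            MoleculeRecord("a", 0, 5, 1000.0),
            MoleculeRecord("b", 1, 0, 1000.0),
            MoleculeRecord("c", 2, 4, 1000.0),
        ]
        est = estimate_rate(recs)
        assert est.replicate_rates == [5e-3, 0.0, 4e-3]

    def test_estimator_consistency_across_bleach_hazards(self):
        # Exposure-based denominator corrects bleach censoring: the
        # pooled estimate stays near k_form whatever the hazards.
        # Averaged over seeds so the band reflects bias, not one draw.
        import dataclasses

        k = 1.7e-3
        cfg = PipelineConfig()
        eff = dataclasses.replace(
            cfg, qc=dataclasses.replace(cfg.qc, bg_donor=100.0, bg_acceptor=100.0)
        )
        for hd, ha in [(0.0, 0.0), (5e-4, 1e-3), (1e-3, 2e-3)]:
            rates = []
            for seed in (101, 102, 103):
                m = KineticModel(k_form=k, h_bleach_donor=hd, h_bleach_acceptor=ha)
                acq = AcquisitionConfig(
                    n_replicates=1, n_fovs_per_replicate=3,
                    n_molecules_per_fov=250, seed=seed,
                )
                trajs, _ = simulate_experiment(m, acq)
                rates.append(analyze_trajectories(trajs, eff).estimate.rate_per_s)
            assert np.mean(rates) == pytest.approx(k, rel=0.15)


class TestFoldChange:
    def _est(self, n, t):
        return estimate_rate([MoleculeRecord("a", 0, n, t)])

    def test_wt_to_buffer_scale_ratio_exceeds_twenty_five(self):
        wt = self._est(17, 10_000.0)  # 1.7e-3 s^-1
        low = self._est(16, 250_000.0)  # 6.4e-5 s^-1
        fc = fold_change(wt, low)
        assert fc.ratio == pytest.approx(1.7e-3 / 6.4e-5)
        assert fc.ratio >= 25

    def test_identity_ratio_is_one(self):
        a = self._est(5, 1000.0)
        assert fold_change(a, a).ratio == pytest.approx(1.0)

    def test_zero_denominator_gives_infinite_sentinel_with_bound(self):
        a = self._est(10, 1000.0)
        b = self._est(0, 50_000.0)
        fc = fold_change(a, b)
        assert math.isinf(fc.ratio)
        assert 0 < fc.lower_bound95 < fc.ratio

    def test_simulated_twenty_five_fold_gap_recovered(self):
        # Ratio of mean recovered rates over three simulated runs per
        # condition (the low condition yields only tens of events per
        # run, so a single draw is sampling-noise dominated).
        import dataclasses

        cfg = PipelineConfig()
        eff = dataclasses.replace(
            cfg, qc=dataclasses.replace(cfg.qc, bg_donor=100.0, bg_acceptor=100.0)
        )
        mean_rates = []
        for kf, seeds in [(1.7e-3, (31, 33, 35)), (6.8e-5, (32, 34, 36))]:
            rates = []
            for seed in seeds:
                m = KineticModel(k_form=kf)
                acq = AcquisitionConfig(
                    n_replicates=3, n_fovs_per_replicate=3,
                    n_molecules_per_fov=100, seed=seed,
                )
                trajs, _ = simulate_experiment(m, acq)
                rates.append(analyze_trajectories(trajs, eff).estimate.rate_per_s)
            mean_rates.append(np.mean(rates))
        assert mean_rates[0] / mean_rates[1] == pytest.approx(25.0, rel=0.30)
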