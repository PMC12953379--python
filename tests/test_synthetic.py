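"""Synthetic cohort generator: hypnogram statistics, waveform physiology,
longitudinal structure."""

import dataclasses

import numpy as np
import pytest
from scipy import signal as sps

from cardiosleep.evaluation import sleep_metrics
from cardiosleep.synthetic import (CohortPlan, HypnogramParams, ParameterError,
                                   generate_cohort, generate_hypnogram,
                                   generate_night, stationary_distribution,
                                   transition_from_stationary)
from cardiosleep.types import CLASS_STAGES, Hypnogram, Stage


class TestHypnogram:
    def test_ten_hours_is_1200_epochs(self, hyp_params):
        assert len(generate_hypnogram(hyp_params, 10.0)) == 1200

    def test_identity_matrix_absorbs_initial_state(self, hyp_params):
        params = dataclasses.replace(hyp_params, transition=np.eye(4),
                                     initial_stage=Stage.WAKE)
        hyp = generate_hypnogram(params, 0.5)
        assert len(hyp) == 60
        assert np.all(hyp.stages == Stage.WAKE)

    def test_non_stochastic_matrix_rejected(self, hyp_params):
        bad = np.full((4, 4), 0.3)
        with pytest.raises(ParameterError):
            HypnogramParams(transition=bad)

    def test_same_seed_identical(self, hyp_params):
        a = generate_hypnogram(hyp_params, 8.0)
        b = generate_hypnogram(hyp_params, 8.0)
        assert np.array_equal(a.stages, b.stages)

    def test_starts_with_wake_run_of_expected_length(self, hyp_params):
        # mean initial wake run should match the sleep-onset latency target
        runs = []
        for seed in range(300):
            hyp = generate_hypnogram(
                dataclasses.replace(hyp_params, seed=seed), 6.0)
            first_sleep = np.argmax(hyp.stages != Stage.WAKE)
            runs.append(first_sleep)
        mean_sol_min = np.mean(runs) * 0.5
        assert mean_sol_min == pytest.approx(hyp_params.sol_min, rel=0.25)

    def test_stage_fractions_match_stationary_distribution(self, hyp_params):
        """Empirical stage mix over 200 nights vs the chain's eigenvector."""
        counts = np.zeros(4)
        total = 0
        for seed in range(200):
            hyp = generate_hypnogram(
                dataclasses.replace(hyp_params, seed=seed), 8.0)
            for j, s in enumerate(CLASS_STAGES):
                counts[j] += np.sum(hyp.stages == s)
            total += len(hyp)
        frac = counts / total
        pi = stationary_distribution(hyp_params.transition)
        assert np.all(np.abs(frac - pi) < 0.05)

    def test_rem_present_in_long_nights(self, hyp_params):
        for seed in (0, 7, 42, 99, 1234):
            hyp = generate_hypnogram(
                dataclasses.replace(hyp_params, seed=seed), 3.0)
            assert np.any(hyp.stages == Stage.REM)

    def test_transition_from_stationary_eigenvector(self):
        pi = np.array([0.1, 0.4, 0.3, 0.2])
        P = transition_from_stationary(pi, 0.05)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(stationary_distribution(P), pi, atol=1e-10)

    def test_duration_bounds(self, hyp_params):
        with pytest.raises(ParameterError):
            generate_hypnogram(hyp_params, 0.0)
        with pytest.raises(ParameterError):
            generate_hypnogram(hyp_params, 11.0)


class TestNight:
    def test_waveform_alignment(self, hyp_params, physio_params):
        hyp = generate_hypnogram(hyp_params, 0.25)  # 30 epochs
        rec = generate_night(hyp, physio_params)
        n_expected = len(hyp) * 30 * 125
        assert abs(rec.ecg.size - n_expected) <= 1
        assert abs(rec.accel.n_samples - n_expected) <= 1

    def test_mean_heart_rate_matches_stage(self, physio_params):
        """Peak detection on an all-N3 night recovers the N3 heart rate."""
        hyp = Hypnogram(np.full(20, int(Stage.N3)))  # 10 minutes
        rec = generate_night(hyp, physio_params)
        peaks, _ = sps.find_peaks(rec.ecg, height=0.5, distance=int(0.3 * 125))
        hr = 60.0 * (peaks.size - 1) / ((peaks[-1] - peaks[0]) / 125.0)
        assert hr == pytest.approx(physio_params.hr_by_stage[Stage.N3], abs=1.0)

    def test_no_posture_changes_keeps_gravity_fixed(self, physio_params):
        phys = dataclasses.replace(physio_params, posture_change_rate=0.0,
                                   wake_motion_burst_rate=0.0)
        hyp = Hypnogram(np.full(10, int(Stage.N3)))
        rec = generate_night(hyp, phys)
        sos = sps.butter(2, 0.04 / 62.5, btype="low", output="sos")
        g = sps.sosfiltfilt(sos, rec.accel.samples, axis=0)
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        cosang = np.clip(g @ g[0], -1, 1)
        assert np.degrees(np.arccos(cosang)).max() < 1.0

    def test_respiratory_spectral_peak(self, physio_params):
        """Accelerometer projection during N1N2 peaks at the stage's rate."""
        phys = dataclasses.replace(physio_params, posture_change_rate=0.0)
        hyp = Hypnogram(np.full(20, int(Stage.N1N2)))  # 10 min
        rec = generate_night(hyp, phys)
        proj = rec.accel.samples @ phys.resp_axis
        sos = sps.butter(4, [0.08 / 62.5, 0.8 / 62.5], btype="band",
                         output="sos")
        x = sps.sosfiltfilt(sos, proj)
        f = np.fft.rfftfreq(x.size, 1 / 125.0)
        spec = np.abs(np.fft.rfft(x * np.hanning(x.size)))
        peak = f[np.argmax(spec)]
        expected = phys.resp_rate_by_stage[Stage.N1N2] / 60.0
        assert peak == pytest.approx(expected, abs=0.02)

    def test_same_seed_bit_identical(self, hyp_params, physio_params):
        hyp = generate_hypnogram(hyp_params, 0.25)
        a = generate_night(hyp, physio_params)
        b = generate_night(hyp, physio_params)
        assert np.array_equal(a.ecg, b.ecg)
        assert np.array_equal(a.accel.samples, b.accel.samples)

    def test_empty_hypnogram_rejected(self, physio_params):
        with pytest.raises(ParameterError):
            generate_night(Hypnogram(np.array([], dtype=int)), physio_params)


class TestCohort:
    def test_cohort_counting(self, hyp_params, physio_params):
        plan = CohortPlan(n_participants=13, seed=5)
        records = generate_cohort(plan, hyp_params, physio_params)
        assert len(records) == 117
        assert len({r.participant_id for r in records}) == 13
        per = {}
        for r in records:
            per.setdefault(r.participant_id, set()).add(r.night_label)
        assert all(len(labels) == 9 for labels in per.values())

    def test_tib_restriction_recovered(self, hyp_params, physio_params):
        """Mean TIB drop from B1 to I1 matches the injected restriction."""
        plan = CohortPlan(n_participants=13, srt_tib_restriction_min=120.0,
                          seed=3)
        records = generate_cohort(plan, hyp_params, physio_params)
        tib = {}
        for r in records:
            tib.setdefault(r.night_label, []).append(
                sleep_metrics(r.hypnogram).tib_min)
        drop = np.mean(tib["B1"]) - np.mean(tib["I1"])
        assert drop == pytest.approx(120.0, abs=10.0)

    def test_n3_slope_recovered(self, hyp_params, physio_params):
        """Cohort-mean %N3 over I1..I7 has the injected per-night slope.

        Uses a large cohort so per-night stage-mix noise averages out of
        the regression oracle.
        """
        plan = CohortPlan(n_participants=150, n3_trend_per_night=-1.0,
                          seed=11)
        records = generate_cohort(plan, hyp_params, physio_params)
        labels = [f"I{k}" for k in range(1, 8)]
        means = []
        for label in labels:
            vals = [sleep_metrics(r.hypnogram).pct_n3
                    for r in records if r.night_label == label]
            means.append(np.mean(vals))
        slope = np.polyfit(np.arange(7), means, 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.3)

    def test_cohort_determinism(self, hyp_params, physio_params):
        plan = CohortPlan(n_participants=3, night_labels=("B1",),
                          baseline_tib_min=130.0, tib_between_sd_min=5.0,
                          tib_within_sd_min=2.0, seed=9)
        a = generate_cohort(plan, hyp_params, physio_params,
                            with_waveforms=True)
        b = generate_cohort(plan, hyp_params, physio_params,
                            with_waveforms=True)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.hypnogram.stages, rb.hypnogram.stages)
            assert np.array_equal(ra.ecg, rb.ecg)

    def test_plan_invariants(self):
        with pytest.raises(ParameterError):
            CohortPlan(n_participants=2)
        with pytest.raises(ParameterError):
            CohortPlan(night_labels=("B1", "B1"))
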