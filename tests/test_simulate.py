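"""Simulator correctness: analytic agreement, conservation laws,
sampling determinism, FRAP generation, and frame rendering round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import spliffkit as sk
from spliffkit.config import ValidationError

from oracles import analytic_reporter_trajectory


def _random_schedule(rng, total=60.0):
    n_windows = rng.integers(1, 4)
    edges = np.sort(rng.uniform(0, total, 2 * n_windows))
    phases = ["PCDI", "PCDII", "PCDIII"]
    windows = []
    for i in range(n_windows):
        a, b = edges[2 * i], edges[2 * i + 1]
        if b - a > 0.5:
            windows.append((float(a), float(b), phases[i % 3]))
    return sk.InteractionSchedule(
        windows=windows, total_duration=total, sampling_interval=2.0, fusion_time=4.0
    )


class TestReporterKinetics:
    def test_matches_closed_form_on_random_piecewise_schedules(self):
        """Numerical trajectories agree with the closed-form solution of the
        piecewise-constant linear system to < 1e-6 relative error."""
        rng = np.random.default_rng(42)
        for _ in range(5):
            cfg = sk.ReporterKineticsConfig(
                synthesis_rate=float(rng.uniform(0, 1)),
                cleavage_rate_on=float(rng.uniform(0.01, 0.2)),
                cleavage_rate_off=float(rng.uniform(0, 0.005)),
                gfp_degradation_rate=float(rng.uniform(0.1, 2.0)),
                reporter_degradation_rate=float(rng.uniform(0, 0.02)),
            )
            sched = _random_schedule(rng)
            truth = sk.simulate_reporter_kinetics(cfg, sched)
            post = truth.times >= 0
            U, R, G = analytic_reporter_trajectory(cfg, sched, truth.times[post])
            scale = cfg.initial_reporter
            for num, ana in ((truth.U[post], U), (truth.R_c[post], R), (truth.G_c[post], G)):
                assert np.max(np.abs(num - ana)) / scale < 1e-6

    def test_no_interaction_null_keeps_reporter_intact(self):
        cfg = sk.ReporterKineticsConfig(
            cleavage_rate_on=0.0, cleavage_rate_off=0.0,
            gfp_degradation_rate=0.0, reporter_degradation_rate=0.0,
        )
        sched = sk.standard_benchmark_schedule()
        truth = sk.simulate_reporter_kinetics(cfg, sched)
        assert np.allclose(truth.U, cfg.initial_reporter, rtol=1e-9)
        assert np.all(truth.R_c == 0) and np.all(truth.G_c == 0)
        assert np.allclose(truth.fd_true(), 0.0, atol=1e-9)

    def test_exhaustion_limit_follows_one_minus_exp(self):
        """With no synthesis and fast GFP turnover, FD(t) -> 1 - e^(-k t)
        and approaches 100% as the intact reporter is consumed."""
        k = 0.05
        cfg = sk.ReporterKineticsConfig(
            synthesis_rate=0.0, cleavage_rate_on=k, gfp_degradation_rate=100.0,
        )
        sched = sk.InteractionSchedule(
            windows=[(0.0, 115.0, "PCDI")], total_duration=115.0,
            sampling_interval=2.0, fusion_time=2.0,
        )
        truth = sk.simulate_reporter_kinetics(cfg, sched)
        post = truth.times > 1.0  # skip the brief GFP-equilibration transient
        expected = 100.0 * (1.0 - np.exp(-k * truth.times[post]))
        assert np.max(np.abs(truth.fd_true()[post] - expected)) < 1.0
        assert truth.fd_true()[-1] > 99.0  # conversion exhausts toward 100%

    def test_conservation_without_synthesis_and_degradation(self):
        cfg = sk.ReporterKineticsConfig(
            synthesis_rate=0.0, reporter_degradation_rate=0.0,
            gfp_degradation_rate=0.9,
        )
        truth = sk.simulate_reporter_kinetics(cfg, sk.standard_benchmark_schedule())
        total = truth.U + truth.R_c
        assert np.allclose(total, total[0], rtol=1e-9)

    @given(
        k_on=st.floats(0.005, 0.2),
        d_g=st.floats(0.2, 5.0),
        d_r=st.floats(0.0, 0.2),
        w0=st.floats(0.0, 30.0),
        w1len=st.floats(1.0, 30.0),
    )
    def test_fd_monotone_nondecreasing_without_synthesis(self, k_on, d_g, d_r, w0, w1len):
        """Pure conversion can only accumulate: with synthesis off and GFP
        degraded at least as fast as the reporter, noiseless FD never
        decreases."""
        if d_g < d_r:
            d_g = d_r  # monotonicity requires faster GFP turnover
        cfg = sk.ReporterKineticsConfig(
            synthesis_rate=0.0, cleavage_rate_on=k_on,
            gfp_degradation_rate=d_g, reporter_degradation_rate=d_r,
        )
        sched = sk.InteractionSchedule(
            windows=[(w0, min(w0 + w1len, 60.0), "PCDI")] if w0 < 59.0 else [],
            total_duration=60.0, sampling_interval=2.0, fusion_time=2.0,
        )
        truth = sk.simulate_reporter_kinetics(cfg, sched)
        fd = truth.fd_true()
        assert np.all(np.diff(fd) > -1e-7)
        assert np.all(truth.U >= 0) and np.all(truth.R_c >= 0) and np.all(truth.G_c >= 0)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValidationError):
            sk.ReporterKineticsConfig(cleavage_rate_on=-0.1)
        with pytest.raises(ValidationError):
            sk.ReporterKineticsConfig(roi_fraction=0.0)
        with pytest.raises(ValidationError):
            sk.InteractionSchedule(sampling_interval=4.0)
        with pytest.raises(ValidationError):
            sk.InteractionSchedule(windows=[(10.0, 5.0, "PCDI")])


class TestIntensitySampling:
    def test_noiseless_trace_proportional_to_species(self, noiseless_config, short_schedule):
        truth = sk.simulate_reporter_kinetics(noiseless_config, short_schedule)
        trace = sk.sample_intensity_trace(truth, seed=0)
        red = trace[trace.channel == "red"]
        U, R, _ = truth.at(red["time_min"].to_numpy())
        expected = noiseless_config.roi_fraction * (U + R)
        assert np.allclose(red["roi"].to_numpy(), expected, rtol=1e-9)
        assert np.allclose(red["background"].to_numpy(), 0.0)

    def test_background_offset_cancels_in_relative_intensity(self, short_schedule):
        base = sk.ReporterKineticsConfig(noise_sd=0.0, background_level=0.0,
                                         bleach_per_exposure_red=0.0,
                                         bleach_per_exposure_green=0.0)
        offset = sk.ReporterKineticsConfig(noise_sd=0.0, background_level=50.0,
                                           bleach_per_exposure_red=0.0,
                                           bleach_per_exposure_green=0.0)
        t0 = sk.simulate_reporter_kinetics(base, short_schedule)
        t1 = sk.simulate_reporter_kinetics(offset, short_schedule)
        a = sk.sample_intensity_trace(t0, seed=0)
        b = sk.sample_intensity_trace(t1, seed=0)
        ra = sk.relative_intensity(a["roi"], a["cytosol"], a["background"])
        rb = sk.relative_intensity(b["roi"], b["cytosol"], b["background"])
        assert np.allclose(ra, rb, rtol=1e-9)

    def test_fixed_seed_is_deterministic(self, short_schedule):
        cfg = sk.ReporterKineticsConfig()
        truth = sk.simulate_reporter_kinetics(cfg, short_schedule)
        a = sk.sample_intensity_trace(truth, seed=7)
        b = sk.sample_intensity_trace(truth, seed=7)
        pd.testing.assert_frame_equal(a, b)
        c = sk.sample_intensity_trace(truth, seed=8)
        assert not np.allclose(a["roi"], c["roi"])


class TestPopulation:
    def test_single_cell_no_jitter_matches_single_path(self, short_schedule):
        cfg = sk.ReporterKineticsConfig()
        sim = sk.simulate_population(cfg, short_schedule, 1, fusion_jitter_sd=0.0, seed=3)
        assert sim.traces["cell_id"].nunique() == 1
        assert sim.truths[0].schedule.windows == short_schedule.windows

    def test_seeds_change_noise_not_core(self, short_schedule):
        cfg = sk.ReporterKineticsConfig()
        a = sk.simulate_population(cfg, short_schedule, 2, fusion_jitter_sd=0.0, seed=0)
        b = sk.simulate_population(cfg, short_schedule, 2, fusion_jitter_sd=0.0, seed=1)
        assert not np.allclose(a.traces["roi"], b.traces["roi"])
        assert np.allclose(a.truths[0].U, b.truths[0].U)

    def test_mean_of_noiseless_cores_equals_single_cell_curve(self, noiseless_config,
                                                              short_schedule):
        sim = sk.simulate_population(noiseless_config, short_schedule, 200,
                                     fusion_jitter_sd=0.0, seed=0)
        single = sk.simulate_reporter_kinetics(noiseless_config, short_schedule)
        fd_mean = np.mean([t.fd_true() for t in sim.truths], axis=0)
        assert np.allclose(fd_mean, single.fd_true(), atol=1e-9)

    def test_zero_cells_rejected(self, short_schedule):
        with pytest.raises(ValidationError):
            sk.simulate_population(sk.ReporterKineticsConfig(), short_schedule, 0)


class TestFrapSimulation:
    def test_full_mobility_recovers_prebleach_level(self):
        cfg = sk.FrapSimConfig(mobile_fraction=1.0, noise_sd=0.0, n_frames=200)
        norm = sk.double_normalize(sk.simulate_frap_trace(cfg))
        pre = norm[norm.prebleach_flag]
        assert np.isclose(pre["normalized"].mean(), 1.0, atol=1e-9)
        assert abs(norm["normalized"].iloc[-1] - 1.0) < 1e-3

    def test_partial_mobility_sets_normalized_plateau(self):
        cfg = sk.FrapSimConfig(mobile_fraction=0.6, noise_sd=0.0)
        fit = sk.fit_one_phase(sk.double_normalize(sk.simulate_frap_trace(cfg)))
        assert abs(fit.plateau - 0.6) < 0.01

    def test_noiseless_round_trip_recovers_half_time(self):
        cfg = sk.FrapSimConfig(rate_k=np.log(2) / 8.82, noise_sd=0.0)
        fit = sk.fit_one_phase(sk.double_normalize(sk.simulate_frap_trace(cfg)))
        assert abs(fit.t_half - 8.82) / 8.82 < 1e-3


class TestFrameRendering:
    def test_zero_image_measures_zero(self):
        geom = sk.FrameGeometry()
        stack = np.zeros((1, 2, geom.n_z, *geom.shape))
        df = sk.quantify_frames(stack, [0.0], geom)
        assert (df[["roi", "cytosol", "background"]] == 0).all().all()

    def test_render_quantify_round_trip(self, noiseless_config, short_schedule):
        truth = sk.simulate_reporter_kinetics(
            sk.ReporterKineticsConfig(noise_sd=0.2, background_level=10.0),
            short_schedule,
        )
        trace = sk.sample_intensity_trace(truth, seed=4)
        geom = sk.FrameGeometry()
        stack = sk.render_synthetic_frames(trace, geom)
        times = np.sort(trace["time_min"].unique())
        back = sk.quantify_frames(stack, times, geom)
        merged = trace.merge(back, on=["time_min", "channel"], suffixes=("", "_rt"))
        for col in ("roi", "cytosol", "background"):
            rel = np.abs(merged[col + "_rt"] - merged[col]) / np.maximum(
                np.abs(merged[col]), 1e-9
            )
            assert rel.max() < 0.01

    def test_oversized_geometry_rejected(self):
        with pytest.raises(ValidationError):
            sk.FrameGeometry(shape=(512, 512))
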