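"""Rolling/unrolling quantification, logistic fitting and Welch's t."""

import math

import numpy as np
import pytest

from memroll.exceptions import LogisticFitError
from memroll.kinetics import (
    FrameStack,
    RollingTrace,
    extract_line_profile,
    fit_logistic,
    incremental_rolled_area,
    relative_area_increase,
    welch_t,
)
from memroll.synthetic import gen_rolling_movie, gen_unrolling_movie


def logistic_trace(tau, t0, amplitude, t_end, dt=0.5, noise=0.0, rng=None):
    t = np.arange(dt, t_end, dt)
    y = amplitude / (1.0 + np.exp(-(t - t0) / tau))
    if noise > 0:
        y = y + rng.normal(0, noise * amplitude, t.size)
    inc = np.diff(np.concatenate([[0.0], y]))
    return RollingTrace(times=t, incremental_area=inc, cumulative_area=y)


class TestIncrementalRolledArea:
    def test_static_stack_yields_zero(self, rng):
        frames = 0.5 + rng.normal(0, 0.01, (20, 64, 64))
        stack = FrameStack(frames=frames, pixel_size=0.32, frame_interval=0.1)
        trace = incremental_rolled_area(stack, check_drift=False)
        assert np.all(trace.incremental_area == 0)
        assert np.all(trace.cumulative_area == 0)

    def test_shrinking_disc_recovers_annulus_areas(self):
        # disc radius shrinks one pixel per frame: the measured increment
        # must match the analytic annulus area up to boundary discretization
        size, r0 = 96, 30
        yy, xx = np.mgrid[0:size, 0:size]
        rr = np.hypot(yy - size / 2, xx - size / 2)
        radii = [r0 - i for i in range(6)]
        frames = np.stack([np.where(rr <= r, 1.0, 0.1) for r in radii])
        px = 0.5
        stack = FrameStack(frames=frames, pixel_size=px, frame_interval=1.0)
        trace = incremental_rolled_area(
            stack, cutoff=0.45, median_filter=False, check_drift=False
        )
        for inc, r in zip(trace.incremental_area, radii[:-1]):
            annulus = math.pi * (r**2 - (r - 1) ** 2) * px**2
            bound = 2 * (2 * math.pi * r) * px**2  # two pixel-rows of rim
            assert abs(inc - annulus) < bound

    def test_movie_final_cumulative_matches_amplitude(self):
        stack, truth = gen_rolling_movie(
            tau=8.0, onset=15.0, seed=11, noise_sigma=0.02, size_px=128,
            shape=9.0, frame_interval=0.4,
        )
        trace = incremental_rolled_area(stack, check_drift=False)
        amp = truth.parameters["amplitude_um2"]
        assert abs(trace.cumulative_area[-1] / amp - 1) < 0.03

    def test_cumulative_is_nondecreasing(self):
        stack, _ = gen_rolling_movie(
            tau=6.0, onset=10.0, seed=3, noise_sigma=0.2, size_px=96,
            shape=7.0, frame_interval=0.5,
        )
        trace = incremental_rolled_area(stack, check_drift=False)
        assert np.all(np.diff(trace.cumulative_area) >= 0)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            FrameStack(frames=np.zeros((1, 8, 8)), pixel_size=1, frame_interval=1)


class TestLogisticFit:
    @pytest.mark.parametrize("tau", [1.0, 5.0, 20.0, 100.0])
    def test_noiseless_recovery_is_exact(self, tau):
        trace = logistic_trace(tau, t0=5 * tau, amplitude=400.0,
                               t_end=10 * tau, dt=tau / 20)
        fit = fit_logistic(trace)
        assert abs(fit.tau / tau - 1) < 1e-3
        assert abs(fit.t0 / (5 * tau) - 1) < 1e-3
        assert abs(fit.amplitude / 400.0 - 1) < 1e-3
        assert fit.onset_time <= fit.t0

    def test_mean_recovery_under_trace_noise(self, rng):
        taus = []
        for i in range(20):
            trace = logistic_trace(8.0, t0=40.0, amplitude=400.0, t_end=90.0,
                                   noise=0.05, rng=rng)
            taus.append(fit_logistic(trace).tau)
        assert abs(np.mean(taus) / 8.0 - 1) < 0.05

    def test_onset_rule_stable_as_noise_doubles(self, rng):
        # at SNR >= 10 the 5%-crossing onset moves by < 1 frame interval
        onsets = []
        for noise in (0.05, 0.1):
            trace = logistic_trace(10.0, t0=50.0, amplitude=400.0,
                                   t_end=110.0, noise=noise,
                                   rng=np.random.default_rng(42))
            onsets.append(fit_logistic(trace).onset_time)
        assert abs(onsets[1] - onsets[0]) <= 0.5  # one sample interval

    def test_flat_trace_raises_with_diagnostics(self):
        trace = RollingTrace(
            times=np.arange(1, 20.0),
            incremental_area=np.zeros(19),
            cumulative_area=np.zeros(19),
        )
        with pytest.raises(LogisticFitError) as err:
            fit_logistic(trace)
        assert "flat" in str(err.value)
        assert err.value.diagnostics["n"] == 19


class TestUnrolling:
    def test_static_stack_stays_at_unity(self):
        stack, _ = gen_unrolling_movie(
            initial_area=50.0, growth=0.0, duration=80.0, seed=5,
            noise_sigma=0.02, size_px=160,
        )
        trace = relative_area_increase(stack)
        assert trace.relative_area[0] == 1.0
        assert trace.times[0] == 0.0
        # fully crosslinked roll: deviation bounded by binarization jitter
        assert np.max(np.abs(trace.relative_area - 1.0)) < 0.03

    def test_linear_growth_slope_recovered(self):
        growth = 0.005
        stack, _ = gen_unrolling_movie(
            initial_area=50.0, growth=growth, duration=80.0, seed=6,
            noise_sigma=0.02, size_px=256,
        )
        trace = relative_area_increase(stack)
        slope = np.polyfit(trace.times, trace.relative_area, 1)[0]
        assert abs(slope / growth - 1) < 0.03

    def test_duration_truncation(self):
        stack, _ = gen_unrolling_movie(
            initial_area=50.0, growth=0.0, duration=80.0, seed=7, size_px=160
        )
        trace = relative_area_increase(stack, duration=40.0)
        assert trace.times[-1] <= 40.0

    def test_zero_initial_area_rejected(self):
        frames = np.zeros((5, 32, 32))
        stack = FrameStack(frames=frames, pixel_size=0.32, frame_interval=1.0)
        with pytest.raises(ValueError):
            relative_area_increase(stack, cutoff=0.5)


def two_channel_patch(rim_on_edge: bool):
    """Patch with a dye rim at the edge; protein either rims or covers."""
    size = 96
    yy, xx = np.mgrid[0:size, 0:size]
    rr = np.hypot(yy - size / 2, xx - size / 2)
    disc, edge = rr <= 30, (rr <= 30) & (rr > 27)
    dye = np.where(disc, 1.0, 0.05) + np.where(edge, 0.8, 0.0)
    protein = np.where(edge, 1.0, 0.05) if rim_on_edge else np.where(disc, 0.6, 0.05)
    frames = np.stack([np.stack([dye, protein])] * 2)
    return FrameStack(
        frames=frames, pixel_size=0.32, frame_interval=0.1,
        channel_names=("membrane", "protein"),
    )


class TestLineProfile:
    def test_uniform_image_normalizes_to_zero(self):
        frames = np.full((2, 32, 32), 3.7)
        stack = FrameStack(frames=frames, pixel_size=0.32, frame_interval=0.1)
        prof = extract_line_profile(stack, 0, (16, 2), (16, 30))
        assert np.all(prof.intensities["ch0"] == 0.0)
        assert math.isnan(prof.peak_positions["ch0"])

    def test_protein_rim_coincides_with_dye_edge(self):
        stack = two_channel_patch(rim_on_edge=True)
        prof = extract_line_profile(stack, 0, (48, 48), (48, 94), width=3)
        offset = abs(
            prof.peak_positions["protein"] - prof.peak_positions["membrane"]
        )
        assert offset <= stack.pixel_size  # within one pixel

    def test_uniform_protein_coverage_has_no_isolated_peak(self):
        stack = two_channel_patch(rim_on_edge=False)
        prof = extract_line_profile(stack, 0, (48, 48), (48, 94), width=3)
        raw = prof.raw_intensities["protein"]
        pk = prof.peak_positions["protein"]
        if not math.isnan(pk):
            idx = int(np.argmin(np.abs(prof.positions - pk)))
            assert raw[idx] < 2.0 * np.median(raw)

    def test_degenerate_segment_rejected(self):
        stack = two_channel_patch(rim_on_edge=True)
        with pytest.raises(ValueError):
            extract_line_profile(stack, 0, (10, 10), (10, 10))
        with pytest.raises(ValueError):
            extract_line_profile(stack, 0, (10, 10), (200, 10))


def welch_reference(a, b):
    """Textbook Welch statistic and Welch-Satterthwaite df, coded separately."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    from scipy.special import betainc

    x = df / (df + t**2)
    p = betainc(df / 2.0, 0.5, x)
    return t, p, df


class TestWelch:
    def test_identical_samples(self):
        res = welch_t([1.0, 2, 3, 4, 5], [1.0, 2, 3, 4, 5])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_gross_separation(self):
        res = welch_t([1.0, 2, 3, 4, 5], [11.0, 12, 13, 14, 15])
        assert res.pvalue < 1e-3

    def test_matches_textbook_formula(self, rng):
        for _ in range(200):
            a = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), rng.integers(3, 40))
            b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), rng.integers(3, 40))
            res = welch_t(a, b)
            t_ref, p_ref, df_ref = welch_reference(a, b)
            assert abs(res.statistic - t_ref) < 1e-10
            assert abs(res.pvalue - p_ref) < 1e-10
            assert abs(res.df - df_ref) < 1e-8

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])
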