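"""Spiral Helfrich rolling model: quadrature, minimiser and sweep behaviour."""

import math

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from memroll.energetics import (
    PRESETS,
    RollModelParams,
    energy_profile,
    reference_params,
    rolled_length,
    spiral_arclength,
    spiral_arclength_thin_pitch,
    spiral_radius_at_arclength,
    sweep_adhesion,
    sweep_spontaneous_curvature,
)


def brute_force_rolled_length(params, l_max=1e-3, n=1_000_001):
    """Independent oracle: dense-grid minimisation of the rolled-state energy."""
    lengths = np.linspace(0.0, l_max, n)
    r = spiral_radius_at_arclength(lengths, params.inner_radius, params.b)
    f = 0.5 * params.k_c * ((1.0 / r - params.c0) ** 2 - params.c0**2) + params.w_ad
    energy = cumulative_trapezoid(f, lengths, initial=0.0)
    return lengths[np.argmin(energy)], lengths[1] - lengths[0]


def random_params(rng):
    """Parameter set within x/÷10 of the reference values."""
    ref = reference_params()
    s = lambda: 10.0 ** rng.uniform(-1, 1)
    return RollModelParams(
        k_c=ref.k_c * s(), c0=ref.c0 * s(), w_ad=ref.w_ad * s(), b=ref.b
    )


class TestSpiralGeometry:
    def test_arclength_roundtrip(self):
        p = reference_params()
        r = np.array([4e-8, 1e-7, 5e-7])
        s = spiral_arclength(r, p.inner_radius, p.b)
        back = spiral_radius_at_arclength(s, p.inner_radius, p.b)
        np.testing.assert_allclose(back, r, rtol=1e-12)

    def test_thin_pitch_agrees_at_nanometre_pitch(self):
        # the fast quadratic map must track the exact arclength to < 1%
        p = reference_params()
        r = np.linspace(p.inner_radius * 1.01, 1e-6, 50)
        exact = spiral_arclength(r, p.inner_radius, p.b)
        approx = spiral_arclength_thin_pitch(r, p.inner_radius, p.b)
        assert np.max(np.abs(approx / exact - 1)) < 1e-2


class TestEnergyProfile:
    def test_zero_at_origin_for_random_params(self, rng):
        for _ in range(20):
            prof = energy_profile(random_params(rng), 10e-6, 64)
            assert prof.energy_per_width[0] == 0.0

    def test_marginal_condition_at_inner_turn(self):
        # w_ad = (k/2) c0^2 with r0 = 1/c0: the integrand vanishes at s = 0,
        # so the profile starts flat (dE/dL = 0 at the innermost turn)
        ref = reference_params()
        p = RollModelParams(
            k_c=ref.k_c, c0=ref.c0, w_ad=0.5 * ref.k_c * ref.c0**2, b=ref.b
        )
        prof = energy_profile(p, 1e-8, 2001)
        slope0 = prof.energy_per_width[1] / prof.lengths[1]
        scale = 0.5 * p.k_c * p.c0**2  # natural energy-density scale
        assert abs(slope0) < 1e-3 * scale

    def test_matches_fine_grid_quadrature_oracle(self):
        p = reference_params()
        prof = energy_profile(p, 100e-6, 10_000)
        lengths = np.linspace(0.0, 100e-6, 400_001)
        r = spiral_radius_at_arclength(lengths, p.inner_radius, p.b)
        f = 0.5 * p.k_c * ((1.0 / r - p.c0) ** 2 - p.c0**2) + p.w_ad
        oracle = cumulative_trapezoid(f, lengths, initial=0.0)
        assert abs(prof.energy_per_width[-1] / oracle[-1] - 1) < 1e-3

    def test_quadrature_converges_on_refinement(self):
        p = reference_params()
        e1 = energy_profile(p, 100e-6, 10_000).energy_per_width[-1]
        e2 = energy_profile(p, 100e-6, 20_000).energy_per_width[-1]
        assert abs(e2 / e1 - 1) < 1e-4

    def test_invalid_inputs(self):
        p = reference_params()
        with pytest.raises(ValueError):
            energy_profile(p, -1.0, 100)
        with pytest.raises(ValueError):
            energy_profile(p, 1e-6, 1)
        with pytest.raises(ValueError):
            RollModelParams(k_c=-1e-19, c0=3.33e7, w_ad=1e-5)


class TestRolledLength:
    def test_zero_when_adhesion_exceeds_curvature_gain(self):
        ref = reference_params()
        p = RollModelParams(
            k_c=ref.k_c, c0=ref.c0, w_ad=0.5 * ref.k_c * ref.c0**2 * 1.01, b=ref.b
        )
        assert rolled_length(p) == 0.0

    def test_diverges_as_adhesion_vanishes(self):
        ref = reference_params()
        tiny = RollModelParams(k_c=ref.k_c, c0=ref.c0, w_ad=1e-12, b=ref.b)
        assert rolled_length(tiny) > 1e-2  # far beyond any patch scale
        assert rolled_length(tiny, l_max=1e-3) == 1e-3

    def test_monotone_nonincreasing_in_adhesion(self):
        ref = reference_params()
        lengths = [
            rolled_length(
                RollModelParams(k_c=ref.k_c, c0=ref.c0, w_ad=w, b=ref.b)
            )
            for w in np.geomspace(1e-6, 1e-4, 12)
        ]
        assert all(a >= b_ for a, b_ in zip(lengths, lengths[1:]))

    def test_matches_brute_force_minimiser(self, rng):
        for _ in range(10):
            p = random_params(rng)
            l_brute, step = brute_force_rolled_length(p)
            l_star = rolled_length(p, l_max=1e-3)
            assert abs(l_star - l_brute) <= step

    def test_scale_invariance_of_energy_ratio(self):
        # scaling (k_c, w_ad) together leaves the minimiser unchanged
        ref = reference_params()
        scaled = RollModelParams(
            k_c=ref.k_c * 7.3, c0=ref.c0, w_ad=ref.w_ad * 7.3, b=ref.b
        )
        assert rolled_length(scaled) == pytest.approx(
            rolled_length(ref), rel=1e-12
        )


class TestSweeps:
    def test_identity_adhesion_sweep(self):
        p = reference_params()
        res = sweep_adhesion(p, [1.0])
        assert res.rolled_lengths[0] == pytest.approx(rolled_length(p))
        assert math.isnan(res.critical_factor)

    def test_adhesion_sweep_monotone_and_bracketed(self):
        p = reference_params()
        res = sweep_adhesion(p, np.linspace(1, 10, 19))
        assert np.all(np.diff(res.rolled_lengths) <= 0)
        assert 1.0 < res.critical_factor < 10.0
        # the refined crossing really sits at the resolution limit
        from dataclasses import replace

        at = rolled_length(replace(p, w_ad=p.w_ad * res.critical_factor))
        assert at == pytest.approx(1e-6, rel=1e-3)

    def test_curvature_sweep_monotone_and_bracketed(self):
        p = reference_params()
        res = sweep_spontaneous_curvature(p, np.linspace(0.05, 1.0, 39))
        assert np.all(np.diff(res.rolled_lengths) >= 0)
        assert 0.05 < res.critical_factor < 1.0

    def test_curvature_sweep_r0_conventions_differ(self):
        p = reference_params()
        follow = sweep_spontaneous_curvature(p, [0.6], r0_convention="follow_c0")
        fixed = sweep_spontaneous_curvature(p, [0.6], r0_convention="fixed")
        assert follow.rolled_lengths[0] != pytest.approx(
            fixed.rolled_lengths[0], rel=1e-3
        )

    def test_sweep_input_validation(self):
        p = reference_params()
        with pytest.raises(ValueError):
            sweep_adhesion(p, [])
        with pytest.raises(ValueError):
            sweep_adhesion(p, [2.0, 1.0])
        with pytest.raises(ValueError):
            sweep_spontaneous_curvature(p, [0.5, 1.5])


class TestOrderingProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        w_scale=st.floats(0.1, 10.0),
        c_scale=st.floats(0.5, 2.0),
        bump=st.floats(1.01, 3.0),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_rolled_length_ordering_in_wad_and_c0(self, w_scale, c_scale, bump):
        # more adhesion never lengthens the roll; more spontaneous
        # curvature never shortens it
        ref = reference_params()
        base = RollModelParams(
            k_c=ref.k_c, c0=ref.c0 * c_scale, w_ad=ref.w_ad * w_scale, b=ref.b
        )
        stickier = RollModelParams(
            k_c=base.k_c, c0=base.c0, w_ad=base.w_ad * bump, b=base.b
        )
        curvier = RollModelParams(
            k_c=base.k_c, c0=base.c0 * bump, w_ad=base.w_ad, b=base.b
        )
        l_base = rolled_length(base, l_max=1e-2)
        assert rolled_length(stickier, l_max=1e-2) <= l_base * (1 + 1e-12)
        assert rolled_length(curvier, l_max=1e-2) >= l_base * (1 - 1e-12)


def test_presets_share_reference_geometry():
    assert set(PRESETS) == {"results", "methods"}
    for p in PRESETS.values():
        assert p.c0 == 3.33e7 and p.b == 2.1e-9 and p.w_ad == 1.0e-5
    assert PRESETS["results"].k_c == 1.0e-19
    assert PRESETS["methods"].k_c == 4.0e-20
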