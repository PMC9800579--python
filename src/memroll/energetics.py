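"""Spiral Helfrich model of membrane-patch rolling.

Annexin binding to one leaflet of a supported membrane patch imposes a
spontaneous curvature ``c0``; if the curvature-energy gain outweighs the
adhesion ``w_ad`` holding the patch to the underlying membrane, the patch
rolls up from its free edge into an Archimedean spiral of pitch ``b``,

    r(theta) = r0 + (b / 2 pi) * theta.

Per unit roll width, the energy difference between the rolled and flat state
after a membrane length ``L`` (arclength along the spiral) has rolled is

    dE(L) = integral_0^L [ (k_c/2) * ((1/r(s) - c0)^2 - c0^2) + w_ad ] ds,

where the Helfrich density ``(k_c/2)(c - c0)^2`` of the rolled membrane
(local curvature ``c = 1/r``) is measured against the flat, curvature-
frustrated state ``(k_c/2) c0^2``, and ``w_ad`` is the adhesion energy per
area forfeited by lifting membrane off the support.  Rolling proceeds while
the integrand is negative and stops at the marginal radius where curvature
relaxation no longer pays for the lost adhesion; the equilibrium rolled
length ``L*`` is the minimiser of ``dE``.

Two published parameterisations of the bending modulus ship as presets
(``"results"``: k_c = 1.0e-19 J, ``"methods"``: k_c = 4.0e-20 J); both share
c0 = 3.33e7 1/m, w_ad = 1.0e-5 J/m^2 and b = 2.1 nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid, quad
from scipy.optimize import brentq

__all__ = [
    "RollModelParams",
    "EnergyProfile",
    "SweepResult",
    "PRESETS",
    "reference_params",
    "energy_profile",
    "rolled_length",
    "sweep_adhesion",
    "sweep_spontaneous_curvature",
    "spiral_arclength",
    "spiral_radius_at_arclength",
]

#: Default detection limit below which a rolled length is unobservable (m).
RESOLUTION_LIMIT = 1.0e-6


@dataclass(frozen=True)
class RollModelParams:
    """Physical constants of the rolling model (SI units).

    Parameters
    ----------
    k_c : float
        Mean-curvature bending modulus, J.
    c0 : float
        Spontaneous curvature imposed by asymmetric annexin binding, 1/m.
    w_ad : float
        Adhesion energy density between patch and support, J/m^2.
    b : float
        Pitch of the roll spiral (radial spacing per turn), m.
    r0 : float or None
        Innermost roll radius, m.  ``None`` (default) places the innermost
        turn at the spontaneous radius ``1/c0`` so the first wrap is locally
        unfrustrated.
    """

    k_c: float
    c0: float
    w_ad: float
    b: float = 2.1e-9
    r0: float | None = None

    def __post_init__(self):
        for name in ("k_c", "c0", "w_ad", "b"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0 or (v == 0 and name != "w_ad"):
                raise ValueError(f"{name} must be positive (got {v!r})")
        if self.r0 is not None and self.r0 <= 0:
            raise ValueError(f"r0 must be positive (got {self.r0!r})")

    @property
    def inner_radius(self) -> float:
        """Effective innermost radius: ``r0`` if given, else ``1/c0``."""
        return self.r0 if self.r0 is not None else 1.0 / self.c0


#: Named parameter sets from the two published parameterisations.
PRESETS: dict[str, RollModelParams] = {
    "results": RollModelParams(k_c=1.0e-19, c0=3.33e7, w_ad=1.0e-5),
    "methods": RollModelParams(k_c=4.0e-20, c0=3.33e7, w_ad=1.0e-5),
}


def reference_params(preset: str = "results") -> RollModelParams:
    """Return a named preset parameter set."""
    try:
        return PRESETS[preset]
    except KeyError:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")


@dataclass(frozen=True)
class EnergyProfile:
    """Energy difference rolled-minus-flat per unit roll width, vs rolled length."""

    lengths: np.ndarray  # m, strictly increasing, starts at 0
    energy_per_width: np.ndarray  # J/m, energy_per_width[0] == 0

    def __post_init__(self):
        if len(self.lengths) != len(self.energy_per_width):
            raise ValueError("lengths and energy_per_width must have equal length")


@dataclass(frozen=True)
class SweepResult:
    """Rolled length across a multiplicative sweep of one model parameter."""

    factors: np.ndarray
    rolled_lengths: np.ndarray  # m
    critical_factor: float  # nan when no sweep interval brackets the limit


# ---------------------------------------------------------------------------
# spiral geometry


def _arclength_primitive(r: np.ndarray | float, a: float):
    """Primitive of ds/dtheta expressed in r: integral sqrt(r^2+a^2) dr / a."""
    u = np.asarray(r, dtype=float) / a
    return 0.5 * a * (u * np.sqrt(1.0 + u * u) + np.arcsinh(u))


def spiral_arclength(r, r0: float, b: float):
    """Exact arclength along ``r(theta) = r0 + (b/2pi) theta`` from r0 to r."""
    a = b / (2.0 * math.pi)
    return _arclength_primitive(r, a) - _arclength_primitive(r0, a)


def spiral_arclength_thin_pitch(r, r0: float, b: float):
    """Thin-pitch approximation ``L ~ pi (r^2 - r0^2) / b`` (fast path)."""
    r = np.asarray(r, dtype=float)
    return math.pi * (r * r - r0 * r0) / b


def spiral_radius_at_arclength(s, r0: float, b: float, *, tol: float = 1e-14):
    """Invert the exact arclength map: radius reached after arclength ``s``.

    Newton iteration from the thin-pitch estimate; ds/dr = sqrt(r^2+a^2)/a
    is smooth and monotone so convergence is quadratic.
    """
    a = b / (2.0 * math.pi)
    s = np.asarray(s, dtype=float)
    r = np.sqrt(np.maximum(r0 * r0 + b * s / math.pi, r0 * r0))
    for _ in range(50):
        f = spiral_arclength(r, r0, b) - s
        step = f * a / np.sqrt(r * r + a * a)
        r = np.maximum(r - step, r0)
        if np.max(np.abs(step)) <= tol * max(float(np.max(r)), r0):
            break
    return r if r.ndim else float(r)


def _integrand(r, params: RollModelParams) -> np.ndarray:
    """Energy density per arclength (J/m^2 per unit width): Helfrich + adhesion."""
    r = np.asarray(r, dtype=float)
    c = 1.0 / r
    return 0.5 * params.k_c * ((c - params.c0) ** 2 - params.c0**2) + params.w_ad


# ---------------------------------------------------------------------------
# operations


def energy_profile(
    params: RollModelParams, l_max: float, n_points: int
) -> EnergyProfile:
    """Tabulate ``dE(L)`` on a uniform grid of rolled lengths ``[0, l_max]``.

    Uses the exact spiral arclength map and trapezoidal accumulation, so the
    quadrature error vanishes as ``n_points`` grows.
    """
    if not (l_max > 0):
        raise ValueError(f"l_max must be positive (got {l_max!r})")
    if n_points < 2:
        raise ValueError(f"n_points must be >= 2 (got {n_points!r})")
    lengths = np.linspace(0.0, float(l_max), int(n_points))
    r = spiral_radius_at_arclength(lengths, params.inner_radius, params.b)
    e = cumulative_trapezoid(_integrand(r, params), lengths, initial=0.0)
    return EnergyProfile(lengths=lengths, energy_per_width=e)


def rolled_length(
    params: RollModelParams,
    resolution_limit: float = RESOLUTION_LIMIT,
    *,
    l_max: float | None = None,
) -> float:
    """Equilibrium rolled length ``L*`` minimising ``dE(L)`` over ``L >= 0``.

    The integrand is negative exactly on the radius window where
    ``|1/r - c0| < sqrt(c0^2 - 2 w_ad / k_c)``, so the minimiser is either
    L = 0 or the arclength at the outer marginal radius; the two candidates
    are compared by quadrature when the window does not start at ``r0``.

    ``resolution_limit`` is carried for callers that classify sub-resolution
    lengths as "no rolling"; the returned value itself is not clipped.
    ``l_max`` caps the result (useful when the adhesion-free limit diverges);
    without a cap an unbounded roll is returned as ``inf``.
    """
    del resolution_limit  # classification is the caller's concern
    r0 = params.inner_radius
    disc = params.c0**2 - 2.0 * params.w_ad / params.k_c
    if disc <= 0:  # adhesion exceeds the maximal curvature-energy gain
        return 0.0
    delta = math.sqrt(disc)
    r_lo = 1.0 / (params.c0 + delta)
    r_hi = math.inf if delta >= params.c0 else 1.0 / (params.c0 - delta)
    if r_hi <= r0:
        return 0.0
    if math.isinf(r_hi):
        return float(l_max) if l_max is not None else math.inf
    l_star = float(spiral_arclength(r_hi, r0, params.b))
    if r0 < r_lo:
        # Rolling is initially unfavourable; accept L* only if the net
        # energy at the outer marginal radius beats the flat state.
        a = params.b / (2.0 * math.pi)
        e_star, _ = quad(
            lambda r: _integrand(r, params) * math.sqrt(r * r + a * a) / a,
            r0,
            r_hi,
            limit=200,
        )
        if e_star >= 0.0:
            return 0.0
    if l_max is not None:
        l_star = min(l_star, float(l_max))
    return l_star


def _critical_factor(
    factors: np.ndarray,
    lengths: np.ndarray,
    eval_length,
    resolution_limit: float,
) -> float:
    """Bisection refinement of the first sweep interval crossing the limit.

    Works for both sweep directions: any adjacent pair of sweep points on
    opposite sides of the limit brackets the crossing.
    """
    below = lengths <= resolution_limit
    transitions = np.nonzero(below[:-1] != below[1:])[0]
    if transitions.size == 0:
        return math.nan
    i = int(transitions[0])
    lo, hi = float(factors[i]), float(factors[i + 1])
    g = lambda f: eval_length(f) - resolution_limit
    glo, ghi = g(lo), g(hi)
    if glo == 0.0:
        return lo
    if ghi == 0.0:
        return hi
    if glo * ghi > 0:  # numerically degenerate bracket
        return hi if below[i + 1] else lo
    return float(brentq(g, lo, hi, xtol=1e-6 * max(abs(lo), abs(hi))))


def sweep_adhesion(
    params: RollModelParams,
    factors: Sequence[float],
    resolution_limit: float = RESOLUTION_LIMIT,
) -> SweepResult:
    """Rolled length as the adhesion energy is scaled by each factor.

    Models increased crosslinking of the patch to the support.  The critical
    factor is the smallest multiplier at which ``L*`` falls to the
    resolution limit, refined by bisection between the bracketing sweep
    points (``nan`` when the sweep does not bracket the crossing).
    """
    factors = np.asarray(list(factors), dtype=float)
    if factors.size == 0:
        raise ValueError("factors must be non-empty")
    if (factors <= 0).any() or (np.diff(factors) <= 0).any():
        raise ValueError("factors must be positive and strictly increasing")

    def at(factor: float) -> float:
        return rolled_length(replace(params, w_ad=params.w_ad * factor))

    lengths = np.array([at(f) for f in factors])
    crit = _critical_factor(factors, lengths, at, resolution_limit)
    return SweepResult(factors=factors, rolled_lengths=lengths, critical_factor=crit)


def sweep_spontaneous_curvature(
    params: RollModelParams,
    fractions: Sequence[float],
    resolution_limit: float = RESOLUTION_LIMIT,
    *,
    r0_convention: str = "follow_c0",
) -> SweepResult:
    """Rolled length as the spontaneous curvature is reduced to each fraction.

    Models dilution of the curvature-inducing annexin by a competing binder.
    With the default ``"follow_c0"`` convention the innermost radius tracks
    ``1/(c0 * fraction)``; ``"fixed"`` keeps the reference inner radius.  The
    critical factor is the largest fraction at which ``L*`` is at or below
    the resolution limit.
    """
    fractions = np.asarray(list(fractions), dtype=float)
    if fractions.size == 0:
        raise ValueError("fractions must be non-empty")
    if (fractions <= 0).any() or (fractions > 1).any() or (np.diff(fractions) <= 0).any():
        raise ValueError("fractions must lie in (0, 1] and be strictly increasing")
    if r0_convention not in ("follow_c0", "fixed"):
        raise ValueError(f"unknown r0_convention {r0_convention!r}")

    def at(fraction: float) -> float:
        c0 = params.c0 * fraction
        r0 = params.inner_radius if r0_convention == "fixed" else None
        return rolled_length(replace(params, c0=c0, r0=r0))

    lengths = np.array([at(f) for f in fractions])
    # L* grows with the fraction, so the limit crossing seen from increasing
    # fractions is a below->above transition; reuse the bisection helper.
    crit = _critical_factor(fractions, lengths, at, resolution_limit)
    return SweepResult(
        factors=fractions, rolled_lengths=lengths, critical_factor=crit
    )
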