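"""Synthetic datasets with ground truth for every analysis stage.

No deposited raw data exist for this kind of experiment, so each pipeline
input is emulated by a generator that also emits a ``SyntheticTruth`` record
sufficient to regenerate the dataset bit-exactly from its seed:

* rolling movies — a bright membrane patch consumed by erosion fronts whose
  cumulative consumed area follows a logistic schedule with known tau and
  onset (rolling shows as dye loss; a bright 2-pixel rim leads each front);
* unrolling movies — a maximally rolled patch whose area grows linearly
  (zero growth emulates a fully crosslinked roll);
* AFM images — hexagonally packed Gaussian bumps (trimer lattices) of known
  row spacing inside a low domain, with a raised high domain of set area
  fraction and a GFP-scale height step;
* membrane particle frames — two leaflets sampling an analytic surface
  (flat, spherical cap, or Gaussian dimple) of known mean curvature.

All randomness flows from the seed passed to each call; defaults mirror the
experimental setting (0.32 um/px at 10 fps for movies; sub-nm AFM pixels).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .afm import HeightMap
from .curvature import ParticleFrame
from .exceptions import GenerationError
from .kinetics import FrameStack

__all__ = [
    "SyntheticTruth",
    "gen_rolling_movie",
    "gen_unrolling_movie",
    "gen_afm_image",
    "gen_membrane_frame",
    "surface_height",
    "surface_mean_curvature",
]

#: Fraction of the fitted amplitude defining the rolling onset crossing.
ONSET_FRACTION = 0.05


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth record paired with every generated dataset."""

    kind: str  # "movie" | "unroll" | "afm" | "membrane"
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, default=_jsonable)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# rolling movies


def _patch_mask(shape, size_px: int, pixel_size: float) -> np.ndarray:
    """Rasterize the patch outline: a disc (radius in um) or a polygon."""
    from skimage.draw import polygon as draw_polygon

    yy, xx = np.mgrid[0:size_px, 0:size_px]
    c = (size_px - 1) / 2.0
    if isinstance(shape, (int, float)):
        r_px = float(shape) / pixel_size
        if 2 * r_px > size_px - 8:
            raise GenerationError("patch does not fit in the field of view")
        return (yy - c) ** 2 + (xx - c) ** 2 <= r_px**2
    verts = np.asarray(shape, dtype=float) / pixel_size
    rr, cc = draw_polygon(verts[:, 0] + c, verts[:, 1] + c, (size_px, size_px))
    mask = np.zeros((size_px, size_px), dtype=bool)
    mask[rr, cc] = True
    if not mask.any():
        raise GenerationError("polygon patch rasterized to zero pixels")
    return mask


def gen_rolling_movie(
    shape=12.0,
    tau: float = 10.0,
    onset: float = 20.0,
    *,
    mode: str = "multi",
    n_fronts: int = 3,
    noise_sigma: float = 0.02,
    pixel_size: float = 0.32,
    frame_interval: float = 0.1,
    size_px: int = 160,
    duration: float | None = None,
    rim: bool = True,
    seed: int = 0,
) -> tuple[FrameStack, SyntheticTruth]:
    """Dye-channel movie of a patch consumed by rolling fronts.

    ``shape`` is a disc radius in um or an (n, 2) polygon in um centred on
    the field.  Cumulative consumed area follows the logistic
    ``A / (1 + exp(-(t - t0)/tau))`` with ``t0`` set so the 5%-of-A
    crossing equals ``onset``, gated at the onset: frames before the onset
    are exactly static and rolling starts there with the logistic's value
    (a short initial burst standing in for the unresolved early tail).
    Fronts erode the patch as circular arcs from edge seed points (one seed
    for ``mode="uni"``); consumed pixels darken to background and a bright
    2-pixel rim leads each front.  ``noise_sigma`` is Gaussian noise
    relative to the patch-background contrast.
    """
    if tau <= 0 or onset <= 0:
        raise ValueError("tau and onset must be positive")
    if mode not in ("uni", "multi"):
        raise ValueError("mode must be 'uni' or 'multi'")
    n_fronts = 1 if mode == "uni" else int(n_fronts)
    if mode == "multi" and n_fronts < 2:
        raise ValueError("mode='multi' requires n_fronts >= 2")

    rng = np.random.default_rng(seed)
    mask = _patch_mask(shape, size_px, pixel_size)
    t0 = onset + tau * math.log((1 - ONSET_FRACTION) / ONSET_FRACTION)
    if duration is None:
        duration = t0 + 6.0 * tau
    if t0 >= duration:
        raise GenerationError(
            f"logistic mid-rise t0 = {t0:.1f} s lies outside the movie span "
            f"({duration:.1f} s)"
        )

    # seed points on the patch boundary, spread in angle
    boundary = mask & ~ndimage.binary_erosion(mask)
    by, bx = np.nonzero(boundary)
    c = (size_px - 1) / 2.0
    angles = np.arctan2(by - c, bx - c)
    base = rng.uniform(-math.pi, math.pi)
    targets = base + 2 * math.pi * np.arange(n_fronts) / n_fronts
    seeds = []
    for tgt in targets:
        d = np.abs((angles - tgt + math.pi) % (2 * math.pi) - math.pi)
        seeds.append((by[np.argmin(d)], bx[np.argmin(d)]))

    # consumption order: distance to the nearest front seed (circular-arc
    # erosion); deterministic tie-break by a tiny seeded jitter
    yy, xx = np.mgrid[0:size_px, 0:size_px]
    dist = np.full(mask.shape, np.inf)
    for sy, sx in seeds:
        dist = np.minimum(dist, np.hypot(yy - sy, xx - sx))
    dist = dist + rng.uniform(0, 1e-6, size=dist.shape)
    order = np.full(mask.shape, np.inf)
    flat_idx = np.argsort(dist[mask], kind="stable")
    ranks = np.empty(flat_idx.size)
    ranks[flat_idx] = np.arange(flat_idx.size)
    order[mask] = ranks
    dist_in = np.where(mask, dist, np.inf)

    n_patch = int(mask.sum())
    times = np.arange(0.0, duration + 1e-9, frame_interval)
    sig = 1.0 / (1.0 + np.exp(-(times - t0) / tau))
    consumed_frac = np.where(times >= onset - 1e-9, sig, 0.0)
    n_consumed = np.round(consumed_frac * n_patch).astype(int)

    background, patch_level, rim_level = 0.1, 1.0, 1.6
    contrast = patch_level - background
    rim_px = 2.0
    sorted_dist = np.sort(dist_in[mask])
    frames = np.empty((times.size, size_px, size_px), dtype=np.float32)
    for i, n_c in enumerate(n_consumed):
        img = np.where(mask, patch_level, background).astype(np.float32)
        if n_c > 0:
            consumed = order < n_c
            img[consumed] = background
            if rim and n_c < n_patch:
                d_front = sorted_dist[n_c - 1]
                rim_band = mask & ~consumed & (dist_in <= d_front + rim_px)
                img[rim_band] = rim_level
        if noise_sigma > 0:
            img = img + rng.normal(0, noise_sigma * contrast, img.shape).astype(
                np.float32
            )
        frames[i] = img

    px_area = pixel_size**2
    truth = SyntheticTruth(
        kind="movie",
        parameters={
            "tau_s": tau,
            "onset_s": onset,
            "t0_s": t0,
            "amplitude_um2": n_patch * px_area,
            "mode": mode,
            "n_fronts": n_fronts,
            "front_seeds_px": seeds,
            "noise_sigma": noise_sigma,
            "pixel_size_um": pixel_size,
            "frame_interval_s": frame_interval,
            "size_px": size_px,
            "duration_s": float(duration),
            "shape": shape if isinstance(shape, (int, float)) else np.asarray(shape),
        },
        seed=seed,
    )
    stack = FrameStack(
        frames=frames,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        channel_names=("membrane",),
    )
    return stack, truth


def gen_unrolling_movie(
    initial_area: float = 50.0,
    growth: float = 0.005,
    duration: float = 80.0,
    *,
    noise_sigma: float = 0.02,
    pixel_size: float = 0.32,
    frame_interval: float = 1.0,
    size_px: int = 256,
    seed: int = 0,
) -> tuple[FrameStack, SyntheticTruth]:
    """Movie of a rolled patch unrolling with linear relative area growth.

    The patch is a disc of ``initial_area`` um^2 whose area follows
    ``A(t) = A0 (1 + growth * t)``; ``growth = 0`` emulates a fully
    crosslinked roll that cannot unroll.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if growth < 0:
        raise ValueError("growth rate must be non-negative")
    if initial_area <= 0:
        raise ValueError("initial_area must be positive")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration + 1e-9, frame_interval)
    areas = initial_area * (1.0 + growth * times)
    r_max = math.sqrt(areas[-1] / math.pi) / pixel_size
    if 2 * r_max > size_px - 8:
        raise GenerationError("final patch does not fit in the field of view")
    yy, xx = np.mgrid[0:size_px, 0:size_px]
    c = (size_px - 1) / 2.0
    rr2 = (yy - c) ** 2 + (xx - c) ** 2
    background, patch_level = 0.1, 1.0
    frames = np.empty((times.size, size_px, size_px), dtype=np.float32)
    for i, area in enumerate(areas):
        r_px = math.sqrt(area / math.pi) / pixel_size
        img = np.where(rr2 <= r_px**2, patch_level, background).astype(np.float32)
        if noise_sigma > 0:
            img = img + rng.normal(
                0, noise_sigma * (patch_level - background), img.shape
            ).astype(np.float32)
        frames[i] = img
    truth = SyntheticTruth(
        kind="unroll",
        parameters={
            "initial_area_um2": initial_area,
            "growth_per_s": growth,
            "duration_s": duration,
            "noise_sigma": noise_sigma,
            "pixel_size_um": pixel_size,
            "frame_interval_s": frame_interval,
            "size_px": size_px,
        },
        seed=seed,
    )
    stack = FrameStack(
        frames=frames,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        channel_names=("membrane",),
    )
    return stack, truth


# ---------------------------------------------------------------------------
# AFM images


def gen_afm_image(
    spacing: float = 9.08,
    domain_fraction_high: float = 30.0,
    *,
    height_step: float = 2.7,
    roughness_nm: float = 0.2,
    pixel_size: float = 0.5,
    size_px: int = 512,
    bump_height: float = 0.8,
    rotation_deg: float | None = None,
    tilt: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
) -> tuple[HeightMap, SyntheticTruth]:
    """Two-domain AFM height map with a trimer lattice in the low domain.

    Gaussian bumps sit on a hexagonal lattice of row spacing ``spacing``
    (nm) at a random (or given) rotation inside the low domain; the high
    domain is raised by ``height_step`` (default 2.7 nm, the GFP
    differential scale) with a smooth randomized texture and occupies
    ``domain_fraction_high`` percent of the area by construction (smoothed
    noise thresholded at the matching quantile).  ``tilt`` adds a plane
    background (nm per pixel in y, x) to exercise flattening.
    """
    if not 0.0 < domain_fraction_high < 100.0:
        raise ValueError("domain_fraction_high must be in (0, 100)")
    if spacing <= 3.0 * pixel_size:
        raise ValueError("spacing must exceed 3 pixels for a resolvable lattice")
    rng = np.random.default_rng(seed)
    if rotation_deg is None:
        rotation_deg = float(rng.uniform(0, 60.0))
    theta = math.radians(rotation_deg)

    # hexagonal lattice: nearest-neighbour distance a, row spacing d = a*sqrt(3)/2
    a = 2.0 * spacing / math.sqrt(3.0)
    extent = size_px * pixel_size
    e1 = np.array([math.cos(theta), math.sin(theta)]) * a
    e2 = np.array(
        [math.cos(theta + math.pi / 3.0), math.sin(theta + math.pi / 3.0)]
    ) * a
    nmax = int(2 * extent / a) + 4
    ij = np.mgrid[-nmax : nmax + 1, -nmax : nmax + 1].reshape(2, -1).T
    centers = ij @ np.stack([e1, e2]) + extent / 2.0
    inside = (
        (centers[:, 0] > -2 * a)
        & (centers[:, 0] < extent + 2 * a)
        & (centers[:, 1] > -2 * a)
        & (centers[:, 1] < extent + 2 * a)
    )
    centers = centers[inside]

    sigma = 0.22 * spacing
    half = int(math.ceil(3 * sigma / pixel_size))
    pad = 2 * half
    stamp_ax = np.arange(-half, half + 1) * pixel_size
    lattice = np.zeros((size_px + 2 * pad, size_px + 2 * pad))
    for cx, cy in centers:
        px, py = int(round(cx / pixel_size)), int(round(cy / pixel_size))
        if not (-half <= px <= size_px - 1 + half and -half <= py <= size_px - 1 + half):
            continue
        dx = stamp_ax - (cx - px * pixel_size)
        dy = stamp_ax - (cy - py * pixel_size)
        stamp = bump_height * np.exp(
            -(dx[None, :] ** 2 + dy[:, None] ** 2) / (2 * sigma**2)
        )
        y0, x0 = py - half + pad, px - half + pad
        lattice[y0 : y0 + 2 * half + 1, x0 : x0 + 2 * half + 1] += stamp
    lattice = lattice[pad : pad + size_px, pad : pad + size_px]

    # domain layout: smoothed noise thresholded at the exact quantile
    noise_field = ndimage.gaussian_filter(
        rng.standard_normal((size_px, size_px)), sigma=size_px / 10.0
    )
    thr = np.quantile(noise_field, 1.0 - domain_fraction_high / 100.0)
    high = noise_field > thr

    texture = 0.15 * ndimage.gaussian_filter(
        rng.standard_normal((size_px, size_px)), sigma=2.0
    )
    heights = np.where(high, height_step + texture, lattice)
    heights = heights + rng.normal(0, roughness_nm, heights.shape)
    if tilt != (0.0, 0.0):
        yy, xx = np.mgrid[0:size_px, 0:size_px]
        heights = heights + tilt[0] * yy + tilt[1] * xx

    truth = SyntheticTruth(
        kind="afm",
        parameters={
            "spacing_nm": spacing,
            "lattice_constant_nm": a,
            "domain_fraction_high_pct": 100.0 * float(high.mean()),
            "requested_fraction_high_pct": domain_fraction_high,
            "height_step_nm": height_step,
            "roughness_nm": roughness_nm,
            "pixel_size_nm": pixel_size,
            "size_px": size_px,
            "bump_height_nm": bump_height,
            "rotation_deg": rotation_deg,
            "tilt_nm_per_px": tilt,
        },
        seed=seed,
    )
    return HeightMap(heights=heights, pixel_size=pixel_size), truth


# ---------------------------------------------------------------------------
# membrane particle frames


def surface_height(spec: dict, x, y):
    """Analytic midplane height f(x, y) for a surface spec, centred at 0.

    Specs: ``{"kind": "flat"}``; ``{"kind": "sphere-cap", "R": nm,
    "cap_radius": nm}`` (upper hemisphere continued flat beyond the cap
    rim); ``{"kind": "gaussian-dimple", "A": nm, "sigma": nm}`` giving
    ``z = -A exp(-(x^2+y^2)/(2 sigma^2))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    kind = spec["kind"]
    if kind == "flat":
        return np.zeros(np.broadcast(x, y).shape)
    if kind == "sphere-cap":
        r_sph = float(spec["R"])
        cap = float(spec.get("cap_radius", 0.6 * r_sph))
        r2 = x**2 + y**2
        inside = r2 < cap**2
        z = np.zeros(np.broadcast(x, y).shape)
        z[inside] = np.sqrt(r_sph**2 - r2[inside]) - math.sqrt(
            r_sph**2 - cap**2
        )
        return z
    if kind == "gaussian-dimple":
        amp, sig = float(spec["A"]), float(spec["sigma"])
        return -amp * np.exp(-(x**2 + y**2) / (2 * sig**2))
    raise ValueError(f"unknown surface kind {kind!r}")


def surface_mean_curvature(spec: dict, x, y):
    """Closed-form Monge-gauge mean curvature of an analytic surface spec."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    kind = spec["kind"]
    if kind == "flat":
        return np.zeros(np.broadcast(x, y).shape)
    if kind == "sphere-cap":
        r_sph = float(spec["R"])
        cap = float(spec.get("cap_radius", 0.6 * r_sph))
        h_val = np.where(x**2 + y**2 < cap**2, -1.0 / r_sph, 0.0)
        return h_val
    if kind == "gaussian-dimple":
        amp, sig = float(spec["A"]), float(spec["sigma"])
        g = np.exp(-(x**2 + y**2) / (2 * sig**2))
        zx = amp * x * g / sig**2
        zy = amp * y * g / sig**2
        zxx = amp * g / sig**2 * (1 - x**2 / sig**2)
        zyy = amp * g / sig**2 * (1 - y**2 / sig**2)
        zxy = -amp * x * y * g / sig**4
        grad = 1 + zx**2 + zy**2
        return ((1 + zx**2) * zyy - 2 * zx * zy * zxy + (1 + zy**2) * zxx) / (
            2 * grad**1.5
        )
    raise ValueError(f"unknown surface kind {kind!r}")


def gen_membrane_frame(
    surface: dict,
    box: tuple[float, float] = (40.0, 40.0),
    n_lipids_per_leaflet: int = 2000,
    *,
    thickness: float = 4.0,
    z_noise: float = 0.2,
    seed: int = 0,
) -> tuple[ParticleFrame, SyntheticTruth]:
    """Particle frame sampling an analytic midplane with two leaflets.

    Particles are uniform in x, y; each leaflet sits at ``f(x, y) +/-
    thickness/2`` plus Gaussian z-noise on the lipid-protrusion scale.  The
    surface must satisfy the Monge-sampling condition ``|grad f| <= 1``
    (checked on a fine grid), otherwise a
    :class:`~memroll.exceptions.GenerationError` is raised.
    """
    if n_lipids_per_leaflet < 100:
        raise ValueError("need at least 100 lipids per leaflet")
    lx, ly = box
    gx = np.linspace(-lx / 2, lx / 2, 201)
    gy = np.linspace(-ly / 2, ly / 2, 201)
    zg = surface_height(surface, gx[None, :], gy[:, None])
    slope = np.hypot(*np.gradient(zg, gx[1] - gx[0]))
    if float(slope.max()) > 1.0:
        raise GenerationError(
            f"surface slope {slope.max():.2f} exceeds 1; too steep for Monge "
            "sampling"
        )
    rng = np.random.default_rng(seed)
    n = int(n_lipids_per_leaflet)
    xy = rng.uniform([0, 0], [lx, ly], size=(2 * n, 2))
    f_val = surface_height(surface, xy[:, 0] - lx / 2, xy[:, 1] - ly / 2)
    offset = np.repeat([thickness / 2.0, -thickness / 2.0], n)
    z = f_val + offset + rng.normal(0, z_noise, 2 * n)
    leaflet = np.repeat([True, False], n)
    frame = ParticleFrame(
        positions=np.column_stack([xy, z]), leaflet=leaflet, box=(lx, ly)
    )
    truth = SyntheticTruth(
        kind="membrane",
        parameters={
            "surface": dict(surface),
            "box_nm": (lx, ly),
            "n_lipids_per_leaflet": n,
            "thickness_nm": thickness,
            "z_noise_nm": z_noise,
        },
        seed=seed,
    )
    return frame, truth
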