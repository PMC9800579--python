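"""Rolling and unrolling kinetics from time-lapse fluorescence stacks.

A membrane patch exposed to a curvature-inducing annexin rolls up from its
free edges; the rolled membrane leaves the patch footprint, so rolling shows
up as frame-to-frame *loss* of membrane-dye intensity.  The pipeline here
mirrors the standard quantification: difference consecutive frames, clip to
losses, binarize with a cutoff, convert the pixel count to area, and fit the
cumulative rolled area with a three-parameter logistic

    A(t) = A / (1 + exp(-(t - t0) / tau))

whose time constant ``tau`` characterises the rolling speed.  Unrolling
after maximal roll-up is quantified as the relative patch-area increase over
a fixed observation window, and protein/dye colocalization at the patch edge
is measured from two-channel line profiles.  Group comparisons use Welch's
unequal-variance t test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage, stats
from scipy.optimize import curve_fit
from skimage.measure import profile_line
from skimage.filters import threshold_otsu
from skimage.registration import phase_cross_correlation

from .exceptions import LogisticFitError

__all__ = [
    "FrameStack",
    "RollingTrace",
    "LogisticFit",
    "UnrollTrace",
    "LineProfile",
    "WelchResult",
    "incremental_rolled_area",
    "fit_logistic",
    "relative_area_increase",
    "extract_line_profile",
    "welch_t",
]


@dataclass
class FrameStack:
    """Time-lapse image stack with physical calibration.

    ``frames`` has shape (T, H, W) for a single channel or (T, C, H, W) for
    multi-channel data; ``channel_names`` labels axis 1 in the latter case
    (e.g. ``("membrane", "protein")``).
    """

    frames: np.ndarray
    pixel_size: float  # um / pixel
    frame_interval: float  # s / frame
    channel_names: tuple[str, ...] = ()

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim not in (3, 4):
            raise ValueError("frames must be (T, H, W) or (T, C, H, W)")
        if self.frames.shape[0] < 2:
            raise ValueError("a stack needs at least 2 frames")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")
        if self.frames.ndim == 4 and not self.channel_names:
            self.channel_names = tuple(
                f"ch{i}" for i in range(self.frames.shape[1])
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def channel(self, name_or_index: str | int | None = None) -> np.ndarray:
        """Single-channel (T, H, W) view; default is the only/first channel."""
        if self.frames.ndim == 3:
            return self.frames
        if name_or_index is None:
            name_or_index = 0
        if isinstance(name_or_index, str):
            name_or_index = self.channel_names.index(name_or_index)
        return self.frames[:, name_or_index]


@dataclass(frozen=True)
class RollingTrace:
    """Incremental and cumulative rolled area vs time (um^2)."""

    times: np.ndarray  # s, one entry per frame pair
    incremental_area: np.ndarray
    cumulative_area: np.ndarray


@dataclass(frozen=True)
class LogisticFit:
    """Fitted logistic rise of cumulative rolled area."""

    tau: float  # s
    t0: float  # midpoint time, s
    amplitude: float  # final rolled area, um^2
    onset_time: float  # s
    fit_residual: float  # RMS misfit, um^2
    covariance: np.ndarray = field(repr=False, default=None)

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.amplitude / (1.0 + np.exp(-(t - self.t0) / self.tau))


@dataclass(frozen=True)
class UnrollTrace:
    """Relative patch area vs time from the maximally rolled state."""

    times: np.ndarray  # s, times[0] == 0
    relative_area: np.ndarray  # dimensionless, relative_area[0] == 1


@dataclass(frozen=True)
class LineProfile:
    """Per-channel intensity along a segment, min-max normalized.

    ``peak_positions`` holds, per channel, the position (um) of the largest
    local maximum after 3-point smoothing (nan when the profile has none).
    ``raw_intensities`` keeps the unnormalized samples for prominence checks.
    """

    positions: np.ndarray  # um along the segment
    intensities: dict[str, np.ndarray]
    raw_intensities: dict[str, np.ndarray]
    peak_positions: dict[str, float]


class WelchResult(NamedTuple):
    statistic: float
    pvalue: float
    df: float


# ---------------------------------------------------------------------------
# rolling quantification


def _background_cutoff(diff: np.ndarray, margin: int, nsigma: float) -> float:
    """Cutoff from the border margin of a signed difference image: mean + n*SD."""
    h, w = diff.shape
    m = min(margin, h // 4, w // 4)
    border = np.concatenate(
        [
            diff[:m].ravel(),
            diff[-m:].ravel(),
            diff[m:-m, :m].ravel(),
            diff[m:-m, -m:].ravel(),
        ]
    )
    return float(border.mean() + nsigma * border.std())


def _check_drift(frames: np.ndarray, max_shift: float = 2.0) -> None:
    shift, _, _ = phase_cross_correlation(frames[0], frames[-1], normalization=None)
    if float(np.hypot(*shift)) >= max_shift:
        warnings.warn(
            f"stack drift {np.hypot(*shift):.1f} px between first and last "
            "frame exceeds 2 px; traces assume a stationary patch",
            stacklevel=3,
        )


def incremental_rolled_area(
    stack: FrameStack,
    cutoff: float | str = "auto",
    *,
    channel: str | int | None = None,
    median_filter: bool = True,
    roi: tuple[slice, slice] | None = None,
    mask: np.ndarray | None = None,
    border_margin: int = 10,
    cutoff_nsigma: float = 5.0,
    check_drift: bool = True,
) -> RollingTrace:
    """Rolled area per frame pair from dye-intensity loss.

    Each frame is median-filtered (3x3; edge-preserving, so the moving
    patch boundary survives while pixel noise is suppressed), consecutive
    frames are differenced (``previous - current``: rolling removes dye
    signal) and the loss map is binarized.  ``cutoff="auto"`` estimates a
    per-pair threshold as mean + ``cutoff_nsigma`` SD of the signed
    difference image's border margin — counting losses over the whole frame
    across hundreds of frame pairs needs a deep-tail cutoff, hence the 5 SD
    default; a float is used as an absolute intensity cutoff instead.
    ``roi``/``mask`` restrict the summed loss to a patch region; the
    default sums over the whole frame.
    """
    frames = stack.channel(channel)
    if roi is not None:
        frames = frames[(slice(None),) + tuple(roi)]
    if check_drift:
        _check_drift(frames)
    if median_filter:
        frames = np.stack(
            [ndimage.median_filter(f, size=3) for f in frames]
        )
    incremental = np.empty(stack.n_frames - 1)
    px_area = stack.pixel_size**2
    counted = np.zeros(frames.shape[1:], dtype=bool)  # membrane rolls once
    for i in range(stack.n_frames - 1):
        diff = frames[i] - frames[i + 1]
        thr = (
            _background_cutoff(diff, border_margin, cutoff_nsigma)
            if cutoff == "auto"
            else float(cutoff)
        )
        lost = (diff > thr) & ~counted
        if mask is not None:
            lost &= mask.astype(bool)
        counted |= lost
        incremental[i] = int(lost.sum()) * px_area
    times = stack.frame_interval * np.arange(1, stack.n_frames)
    return RollingTrace(
        times=times,
        incremental_area=incremental,
        cumulative_area=np.cumsum(incremental),
    )


def _logistic(t, amplitude, t0, tau):
    return amplitude / (1.0 + np.exp(-(t - t0) / tau))


def fit_logistic(trace: RollingTrace, *, onset_fraction: float = 0.05) -> LogisticFit:
    """Least-squares logistic fit of the cumulative rolled area.

    Initialisation from trace quantiles (amplitude = max, t0 = half-max
    crossing, tau = (t80 - t20)/2.2), then trust-region least squares with
    positivity bounds on amplitude and tau.  The onset time is the first
    time the measured cumulative area exceeds ``onset_fraction`` of the
    fitted amplitude.  Degenerate or non-convergent inputs raise
    :class:`~memroll.exceptions.LogisticFitError` with diagnostics attached.
    """
    t = np.asarray(trace.times, dtype=float)
    y = np.asarray(trace.cumulative_area, dtype=float)
    span = float(y.max() - y.min())
    diag = {"n": t.size, "y_min": float(y.min()), "y_max": float(y.max())}
    if t.size < 4:
        raise LogisticFitError("need at least 4 samples for a 3-parameter fit", diag)
    if span <= 0 or y.max() <= 0:
        raise LogisticFitError("cumulative area trace is flat; nothing to fit", diag)

    a0 = float(y.max())
    t0_0 = float(t[np.argmax(y >= 0.5 * a0)])
    t20 = float(t[np.argmax(y >= 0.2 * a0)])
    t80 = float(t[np.argmax(y >= 0.8 * a0)])
    tau0 = max((t80 - t20) / 2.2, float(t[1] - t[0]))
    try:
        popt, pcov = curve_fit(
            _logistic,
            t,
            y,
            p0=(a0, t0_0, tau0),
            bounds=([0.0, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            method="trf",
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        diag["p0"] = (a0, t0_0, tau0)
        raise LogisticFitError(f"logistic fit did not converge: {exc}", diag) from exc
    amplitude, t0, tau = (float(v) for v in popt)
    if not np.all(np.isfinite(popt)) or amplitude <= 0 or tau <= 0:
        diag["popt"] = popt.tolist()
        raise LogisticFitError("logistic fit converged to a degenerate solution", diag)
    resid = float(np.sqrt(np.mean((y - _logistic(t, *popt)) ** 2)))
    crossed = y > onset_fraction * amplitude
    onset = float(t[np.argmax(crossed)]) if crossed.any() else float(t[-1])
    return LogisticFit(
        tau=tau,
        t0=t0,
        amplitude=amplitude,
        onset_time=onset,
        fit_residual=resid,
        covariance=pcov,
    )


# ---------------------------------------------------------------------------
# unrolling


def relative_area_increase(
    stack: FrameStack,
    duration: float = 80.0,
    cutoff: float | str = "auto",
    *,
    channel: str | int | None = None,
) -> UnrollTrace:
    """Relative patch-area increase from the maximally rolled state.

    Per frame, the patch area is the count of pixels above the cutoff times
    the pixel area; the trace is normalized to the first frame and truncated
    at ``duration`` (80 s by default).  ``cutoff="auto"`` uses Otsu's
    threshold of the first frame, appropriate for a bright patch on a dark
    background.
    """
    frames = stack.channel(channel)
    thr = float(threshold_otsu(frames[0])) if cutoff == "auto" else float(cutoff)
    areas = (frames > thr).sum(axis=(1, 2)) * stack.pixel_size**2
    if areas[0] <= 0:
        raise ValueError("no patch detected in the initial frame (zero area)")
    keep = stack.times <= duration + 1e-9
    return UnrollTrace(
        times=stack.times[keep], relative_area=areas[keep] / areas[0]
    )


# ---------------------------------------------------------------------------
# line profiles


def _largest_local_max(values: np.ndarray) -> int | None:
    """Index of the largest interior local maximum after 3-point smoothing."""
    if values.size < 3:
        return None
    padded = np.concatenate([values[:1], values, values[-1:]])
    smooth = np.convolve(padded, np.ones(3) / 3.0, mode="valid")
    interior = smooth[1:-1]
    is_max = (interior >= smooth[:-2]) & (interior >= smooth[2:]) & (
        (interior > smooth[:-2]) | (interior > smooth[2:])
    )
    idx = np.nonzero(is_max)[0]
    if idx.size == 0:
        return None
    return int(idx[np.argmax(interior[idx])] + 1)


def extract_line_profile(
    stack: FrameStack,
    frame_index: int,
    endpoint_a: tuple[float, float],
    endpoint_b: tuple[float, float],
    width: int = 1,
) -> LineProfile:
    """Per-channel intensity profile along a segment of one frame.

    Endpoints are (row, col) pixel coordinates; intensities are averaged
    across ``width`` pixels perpendicular to the segment and min-max
    normalized per channel (a constant profile normalizes to zero).  Peak
    positions let the caller compute the protein/dye edge offset.
    """
    frames = stack.frames[frame_index]
    if frames.ndim == 2:
        frames = frames[None]
    names = stack.channel_names or ("ch0",)
    h, w = frames.shape[-2:]
    for p in (endpoint_a, endpoint_b):
        if not (0 <= p[0] <= h - 1 and 0 <= p[1] <= w - 1):
            raise ValueError(f"endpoint {p} outside the frame ({h}x{w})")
    if np.hypot(
        endpoint_b[0] - endpoint_a[0], endpoint_b[1] - endpoint_a[1]
    ) < 1.0:
        raise ValueError("endpoints must be at least one pixel apart")

    raw: dict[str, np.ndarray] = {}
    norm: dict[str, np.ndarray] = {}
    peaks: dict[str, float] = {}
    positions = None
    for name, img in zip(names, frames):
        prof = profile_line(
            img, endpoint_a, endpoint_b, linewidth=width, mode="reflect"
        )
        if positions is None:
            step = np.hypot(
                endpoint_b[0] - endpoint_a[0], endpoint_b[1] - endpoint_a[1]
            ) / max(len(prof) - 1, 1)
            positions = np.arange(len(prof)) * step * stack.pixel_size
        raw[name] = prof
        rng = prof.max() - prof.min()
        norm[name] = (prof - prof.min()) / rng if rng > 0 else np.zeros_like(prof)
        pk = _largest_local_max(prof)
        peaks[name] = float(positions[pk]) if pk is not None else float("nan")
    return LineProfile(
        positions=positions,
        intensities=norm,
        raw_intensities=raw,
        peak_positions=peaks,
    )


# ---------------------------------------------------------------------------
# statistics


def welch_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance t test (two-sided).

    Returns the t statistic, the two-sided p value and the
    Welch-Satterthwaite degrees of freedom.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return WelchResult(0.0, 1.0, float(a.size + b.size - 2))
        raise ValueError("both samples have zero variance; t is undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(float(res.statistic), float(res.pvalue), float(res.df))
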