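"""Readers and writers for the formats the pipeline consumes and emits.

Image stacks are multi-page TIFF (single- or dual-channel); physical
calibration (pixel size, frame interval) is never guessed from TIFF tags —
it comes from explicit arguments or a sidecar YAML.  Height maps are
plain-text matrices, CSV, or single-page TIFF with heights in nm.  Particle
frames are whitespace/CSV text (``x y z leaflet``) or a minimal GRO-like
dialect (fixed columns; leaflet assigned by z relative to the global
midplane when no label exists).  Traces and fits go to CSV, results to JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .afm import HeightMap
from .curvature import ParticleFrame
from .energetics import PRESETS, RollModelParams
from .kinetics import FrameStack, LogisticFit, RollingTrace, UnrollTrace

__all__ = [
    "read_stack",
    "write_stack",
    "read_sidecar",
    "read_height_map",
    "write_height_map",
    "read_particle_frames",
    "write_particle_frame",
    "read_roll_params",
    "trace_to_csv",
    "fit_to_csv",
    "unroll_to_csv",
    "result_to_json",
]


# ---------------------------------------------------------------------------
# image stacks


def read_stack(
    path,
    pixel_size: float,
    frame_interval: float,
    *,
    channel_names: tuple[str, ...] = (),
    second_channel=None,
) -> FrameStack:
    """Load a multi-page TIFF as a :class:`FrameStack`.

    Accepts (T, H, W) or (T, C, H, W) files; ``second_channel`` merges a
    separate single-channel file as channel 1.
    """
    frames = tifffile.imread(str(path))
    if frames.ndim == 2:
        raise ValueError("stack must contain at least 2 frames")
    if second_channel is not None:
        other = tifffile.imread(str(second_channel))
        if other.shape != frames.shape:
            raise ValueError("channel files must have identical shapes")
        frames = np.stack([frames, other], axis=1)
    return FrameStack(
        frames=frames.astype(float),
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        channel_names=tuple(channel_names),
    )


def write_stack(path, stack: FrameStack) -> None:
    tifffile.imwrite(str(path), stack.frames.astype(np.float32))


def read_sidecar(path) -> dict:
    """Read acquisition metadata (pixel_size, frame_interval, ...) from YAML."""
    with open(path) as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict):
        raise ValueError("sidecar YAML must hold a mapping")
    return meta


# ---------------------------------------------------------------------------
# height maps


def read_height_map(path, pixel_size: float) -> HeightMap:
    """Read a height map (nm) from text/CSV matrix or single-page TIFF."""
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        heights = tifffile.imread(str(p)).astype(float)
    elif p.suffix.lower() == ".csv":
        heights = np.loadtxt(p, delimiter=",")
    else:
        heights = np.loadtxt(p)
    return HeightMap(heights=heights, pixel_size=pixel_size)


def write_height_map(path, hmap: HeightMap) -> None:
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(p), hmap.heights.astype(np.float32))
    elif p.suffix.lower() == ".csv":
        np.savetxt(p, hmap.heights, delimiter=",")
    else:
        np.savetxt(p, hmap.heights)


# ---------------------------------------------------------------------------
# particle frames


def _frames_from_table(rows: list[list[str]], box) -> ParticleFrame:
    arr = np.array([[float(r[0]), float(r[1]), float(r[2])] for r in rows])
    labels = np.array([r[3] for r in rows])
    return ParticleFrame(positions=arr, leaflet=labels, box=box)


def _read_gro_frame(lines: list[str], box) -> ParticleFrame:
    # minimal GRO dialect: title, atom count, fixed-column atom lines, box
    n = int(lines[1].split()[0])
    pos = np.empty((n, 3))
    for i, line in enumerate(lines[2 : 2 + n]):
        pos[i] = (float(line[20:28]), float(line[28:36]), float(line[36:44]))
    if box is None:
        bx = lines[2 + n].split()
        box = (float(bx[0]), float(bx[1]))
    # no leaflet column in GRO: assign by z relative to the global midplane
    mid = np.median(pos[:, 2])
    return ParticleFrame(positions=pos, leaflet=pos[:, 2] >= mid, box=box)


def read_particle_frames(path, box=None) -> list[ParticleFrame]:
    """Read one or more particle frames from text, CSV, or GRO dialect.

    Plain-text/CSV rows are ``x y z leaflet`` (nm; leaflet 'upper'/'lower');
    multiple frames are separated by lines starting with ``--``.  The box is
    taken from a ``# box Lx Ly`` comment, the ``box`` argument, or (GRO) the
    box line.
    """
    p = Path(path)
    text = p.read_text().splitlines()
    if p.suffix.lower() == ".gro":
        return [_read_gro_frame(text, box)]
    frames: list[ParticleFrame] = []
    rows: list[list[str]] = []
    file_box = box
    for line in text:
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            parts = s[1:].split()
            if parts and parts[0].lower() == "box":
                file_box = (float(parts[1]), float(parts[2]))
            continue
        if s.startswith("--"):
            if rows:
                frames.append(_frames_from_table(rows, file_box))
                rows = []
            continue
        rows.append(s.replace(",", " ").split())
    if rows:
        frames.append(_frames_from_table(rows, file_box))
    if not frames:
        raise ValueError(f"no particle frames found in {path}")
    return frames


def write_particle_frame(path, frame: ParticleFrame, *, append: bool = False) -> None:
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        if append:
            fh.write("--\n")
        else:
            fh.write(f"# box {frame.box[0]} {frame.box[1]}\n")
            fh.write("# x_nm y_nm z_nm leaflet\n")
        for (x, y, z), up in zip(frame.positions, frame.leaflet):
            fh.write(f"{x:.4f} {y:.4f} {z:.4f} {'upper' if up else 'lower'}\n")


# ---------------------------------------------------------------------------
# model parameters


def read_roll_params(path) -> RollModelParams:
    """Load rolling-model parameters from YAML (keys k_c, c0, w_ad, b, r0,
    or a ``preset`` name optionally overridden by explicit keys)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    base = PRESETS[cfg.pop("preset")] if "preset" in cfg else None
    fields = {k: cfg[k] for k in ("k_c", "c0", "w_ad", "b", "r0") if k in cfg}
    if base is not None:
        merged = {**asdict(base), **fields}
        return RollModelParams(**merged)
    return RollModelParams(**fields)


# ---------------------------------------------------------------------------
# tabular / JSON output


def trace_to_csv(path, trace: RollingTrace) -> None:
    pd.DataFrame(
        {
            "time_s": trace.times,
            "incremental_um2": trace.incremental_area,
            "cumulative_um2": trace.cumulative_area,
        }
    ).to_csv(path, index=False)


def fit_to_csv(path, fit: LogisticFit) -> None:
    pd.DataFrame(
        [
            {
                "tau_s": fit.tau,
                "t0_s": fit.t0,
                "amplitude_um2": fit.amplitude,
                "onset_s": fit.onset_time,
                "rms_residual_um2": fit.fit_residual,
            }
        ]
    ).to_csv(path, index=False)


def unroll_to_csv(path, trace: UnrollTrace) -> None:
    pd.DataFrame(
        {"time_s": trace.times, "relative_area": trace.relative_area}
    ).to_csv(path, index=False)


def result_to_json(path, result) -> None:
    """Serialize a result dataclass (arrays become lists) to JSON."""

    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer, np.bool_)):
            return obj.item()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    payload = asdict(result) if is_dataclass(result) else result
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=default)
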