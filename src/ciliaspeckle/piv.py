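"""Ensemble cross-correlation particle image velocimetry on speckle stacks.

Scalar speckle velocimetry measures speed but not direction; PIV recovers
the directional component.  The frame is tiled by square interrogation
windows (default 8 px, step 4 px).  For every consecutive frame pair the
mean-subtracted, unit-energy-normalized cross-correlation plane of each
window is computed in the Fourier domain; planes are averaged over all pairs
in the requested range (the ensemble-correlation method), which suppresses
pairwise noise without ever interpolating vectors.  The ensemble peak is
refined to sub-pixel precision by a three-point Gaussian fit per axis.

Phase-resolved use: restricting the pair range to the power-stroke or
recovery-stroke interval of a beat cycle yields per-phase vector fields
whose directions oppose each other for beating cilia.

Coordinates are array coordinates (row axis pointing down): a power stroke
"bottom to top" in image terms is v < 0 here.  u is the column displacement
(positive rightward), v the row displacement (positive downward), both in
pixels per frame interval unless converted with :func:`vectors_to_velocity`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .velocimetry import SpeckleStack

__all__ = [
    "InterrogationGrid",
    "VectorField",
    "build_grid",
    "ensemble_piv",
    "phase_resolved_piv",
    "vectors_to_velocity",
]


@dataclass(frozen=True)
class InterrogationGrid:
    """Square interrogation windows tiling a frame at a fixed step.

    Border windows that would not fit are dropped, never padded.
    """

    window_size: int
    step: int
    frame_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.window_size < 4:
            raise ValueError("window_size must be at least 4 px")
        if not 1 <= self.step <= self.window_size:
            raise ValueError("step must satisfy 1 <= step <= window_size")
        H, W = self.frame_shape
        if H < self.window_size or W < self.window_size:
            raise ValueError("frame smaller than one interrogation window")

    @property
    def n_rows(self) -> int:
        return (self.frame_shape[0] - self.window_size) // self.step + 1

    @property
    def n_cols(self) -> int:
        return (self.frame_shape[1] - self.window_size) // self.step + 1

    @property
    def starts(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.arange(self.n_rows) * self.step,
            np.arange(self.n_cols) * self.step,
        )

    @property
    def centers(self) -> np.ndarray:
        """(n_rows*n_cols, 2) window-centre coordinates in pixels."""
        r0, c0 = self.starts
        half = (self.window_size - 1) / 2.0
        rr, cc = np.meshgrid(r0 + half, c0 + half, indexing="ij")
        return np.stack([rr.ravel(), cc.ravel()], axis=1)


@dataclass
class VectorField:
    """Gridded displacement vectors from ensemble PIV.

    u: column displacement, v: row displacement, both (n_rows, n_cols) in
    ``units`` ("px_frame" or "um_s").  ``peak_quality`` is the primary-to-
    secondary correlation peak ratio; ``valid`` combines the peak-ratio test
    with a local median-consistency test.  ``planes`` optionally stores the
    ensemble correlation planes for diagnostics.
    """

    grid: InterrogationGrid
    u: np.ndarray
    v: np.ndarray
    peak_quality: np.ndarray
    valid: np.ndarray
    units: str = "px_frame"
    n_pairs: int = 0
    planes: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        shape = (self.grid.n_rows, self.grid.n_cols)
        for name in ("u", "v", "peak_quality", "valid"):
            a = np.asarray(getattr(self, name))
            if a.shape != shape:
                raise ValueError(f"{name} must have grid shape {shape}")
            setattr(self, name, a)


def build_grid(frame_shape: tuple[int, int], window_size: int = 8, step: int = 4) -> InterrogationGrid:
    """Construct the interrogation grid for a frame shape."""
    return InterrogationGrid(window_size=window_size, step=step, frame_shape=tuple(frame_shape))


def _extract_windows(frame: np.ndarray, grid: InterrogationGrid) -> np.ndarray:
    """(n_rows, n_cols, w, w) view of the interrogation windows."""
    w = grid.window_size
    view = sliding_window_view(frame, (w, w))
    return view[:: grid.step, :: grid.step][: grid.n_rows, : grid.n_cols]


def _ensemble_planes(
    frames: np.ndarray, grid: InterrogationGrid, chunk: int = 16
) -> tuple[np.ndarray, np.ndarray]:
    """Average per-offset-normalized cross-covariance planes over pairs.

    For each frame pair and window the zero-padded linear correlation of the
    raw intensities is divided by the per-offset overlap count and reduced by
    the product of the per-offset overlap means — i.e. the sample
    cross-covariance at every displacement, normalized by the window standard
    deviations.  Naive circular or zero-padded correlation of mean-subtracted
    windows carries a triangular loss-of-pairs taper that drags broad speckle
    correlation peaks toward zero displacement; normalizing each offset by
    its own pair count and local means removes that bias.

    Returns (planes (n_rows, n_cols, 2w, 2w), pair_counts (n_rows, n_cols)).
    Planes are fftshifted: displacement (dr, dc) sits at index (w+dr, w+dc).
    Degenerate (zero-variance) windows in a pair contribute nothing.
    """
    w = grid.window_size
    size = 2 * w
    nr, nc = grid.n_rows, grid.n_cols
    acc = np.zeros((nr, nc, size, size))
    counts = np.zeros((nr, nc))
    T = frames.shape[0]
    wins = np.stack([_extract_windows(f, grid) for f in frames])  # (T, nr, nc, w, w)
    sd = wins.std(axis=(-2, -1))  # (T, nr, nc)

    # per-offset overlap count (fftshifted): (w - |dr|) * (w - |dc|)
    off = np.abs(np.arange(size) - w)
    n_axis = np.maximum(w - off, 0).astype(float)
    n_pairs = n_axis[:, None] * n_axis[None, :]
    n_safe = np.where(n_pairs > 0, n_pairs, 1.0)
    usable = n_pairs >= 4  # too few overlapping samples -> meaningless

    ones = np.ones((w, w))
    f_ones = np.fft.rfft2(ones, s=(size, size))

    def _corr(fa, fb):
        c = np.fft.irfft2(np.conj(fa) * fb, s=(size, size))
        return np.fft.fftshift(c, axes=(-2, -1))

    for s in range(0, T - 1, chunk):
        e = min(s + chunk, T - 1)
        a = wins[s:e]
        b = wins[s + 1 : e + 1]
        fa = np.fft.rfft2(a, s=(size, size))
        fb = np.fft.rfft2(b, s=(size, size))
        raw = _corr(fa, fb)  # sum of I_a * I_b over the overlap
        sum_a = _corr(fa, f_ones)  # per-offset partial sums
        sum_b = _corr(f_ones, fb)
        cov = raw / n_safe - (sum_a / n_safe) * (sum_b / n_safe)
        norm = sd[s:e] * sd[s + 1 : e + 1]
        good = norm > 1e-12
        plane = np.where(
            (good[..., None, None]) & usable,
            cov / np.where(good, norm, 1.0)[..., None, None],
            0.0,
        )
        acc += plane.sum(axis=0)
        counts += good.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        planes = np.where(counts[..., None, None] > 0, acc / np.maximum(counts, 1)[..., None, None], 0.0)
    return planes, counts


def _subpixel_offset(line: np.ndarray) -> float:
    """Three-point refinement from values (c_minus, c_0, c_plus)."""
    cm, c0, cp = line
    if cm > 0 and c0 > 0 and cp > 0 and (c0 >= cm and c0 >= cp):
        lm, l0, lp = math.log(cm), math.log(c0), math.log(cp)
        denom = lm - 2.0 * l0 + lp
        if denom < 0:
            return 0.5 * (lm - lp) / denom
    denom = cm - 2.0 * c0 + cp
    if denom < 0:
        return float(np.clip(0.5 * (cm - cp) / denom, -1.0, 1.0))
    return 0.0


def _locate_peak(plane: np.ndarray, w: int) -> tuple[float, float, float]:
    """Peak displacement (dr, dc) and primary/secondary ratio within +-w/2.

    Displacements beyond w/2 fall outside the search region and surface as
    low-quality vectors rather than aliased ones.
    """
    half = w // 2
    centre = w  # zero displacement index in the fftshifted 2w plane
    search = plane[centre - half : centre + half + 1, centre - half : centre + half + 1]
    m = search.max()
    cand = np.argwhere(search == m)
    # ties broken toward the smaller displacement magnitude
    offs = cand - half
    best = cand[np.argmin((offs ** 2).sum(axis=1))]
    pr, pc = int(best[0]), int(best[1])
    dr, dc = float(pr - half), float(pc - half)
    # sub-pixel refinement, skipped at the search border
    if 0 < pr < search.shape[0] - 1:
        dr += _subpixel_offset(search[pr - 1 : pr + 2, pc])
    if 0 < pc < search.shape[1] - 1:
        dc += _subpixel_offset(search[pr, pc - 1 : pc + 2])
    # secondary peak outside the 3x3 neighbourhood of the primary
    masked = search.copy()
    masked[max(0, pr - 1) : pr + 2, max(0, pc - 1) : pc + 2] = -np.inf
    second = masked.max()
    if not np.isfinite(second) or second <= 0:
        quality = np.inf if m > 0 else 0.0
    else:
        quality = m / second
    return dr, dc, float(quality)


def _median_outliers(u: np.ndarray, v: np.ndarray, valid: np.ndarray, nmad: float) -> np.ndarray:
    """Flag vectors deviating > nmad median absolute deviations from the
    3x3 neighbourhood median (computed over currently valid neighbours)."""
    nr, nc = u.shape
    bad = np.zeros_like(valid)
    eps = 0.1  # px floor so noiseless uniform fields are never flagged
    for comp in (u, v):
        for i in range(nr):
            for j in range(nc):
                if not valid[i, j]:
                    continue
                i0, i1 = max(0, i - 1), min(nr, i + 2)
                j0, j1 = max(0, j - 1), min(nc, j + 2)
                neigh = comp[i0:i1, j0:j1]
                mask = valid[i0:i1, j0:j1].copy()
                mask[i - i0, j - j0] = False
                vals = neigh[mask]
                if len(vals) < 3:
                    continue
                med = np.median(vals)
                mad = np.median(np.abs(vals - med))
                if abs(comp[i, j] - med) > nmad * mad + eps:
                    bad[i, j] = True
    return bad


def ensemble_piv(
    stack: Union[SpeckleStack, np.ndarray],
    grid: Optional[InterrogationGrid] = None,
    frame_range: Optional[tuple[int, int]] = None,
    peak_ratio_threshold: float = 1.3,
    mad_threshold: float = 3.0,
    keep_planes: bool = False,
) -> VectorField:
    """Ensemble-correlation PIV over consecutive frame pairs.

    Parameters
    ----------
    stack : SpeckleStack or (T, H, W) array
    grid : interrogation grid; defaults to 8-px windows at 4-px step
    frame_range : half-open [start, end) frame indices (default: all frames)
    peak_ratio_threshold : minimum primary/secondary peak ratio for validity
    mad_threshold : neighbourhood median-consistency threshold (MADs)
    keep_planes : store the ensemble correlation planes on the result

    Displacements larger than window_size/2 fall outside the search region
    and surface as low-quality (invalid) vectors rather than aliased ones.
    """
    frames = stack.frames if isinstance(stack, SpeckleStack) else np.asarray(stack, dtype=float)
    if frames.ndim != 3:
        raise ValueError("expected a (T, H, W) stack")
    if frame_range is not None:
        s, e = frame_range
        frames = frames[s:e]
    if frames.shape[0] < 2:
        raise ValueError("frame range must contain at least 2 frames")
    if grid is None:
        grid = build_grid(frames.shape[1:])
    frames = frames.astype(np.float64, copy=False)

    planes, counts = _ensemble_planes(frames, grid)
    nr, nc = grid.n_rows, grid.n_cols
    u = np.zeros((nr, nc))
    v = np.zeros((nr, nc))
    quality = np.zeros((nr, nc))
    valid = counts > 0
    w = grid.window_size
    for i in range(nr):
        for j in range(nc):
            if not valid[i, j]:
                continue
            dr, dc, q = _locate_peak(planes[i, j], w)
            v[i, j] = dr
            u[i, j] = dc
            quality[i, j] = q
    valid &= quality >= peak_ratio_threshold
    bad = _median_outliers(u, v, valid, mad_threshold)
    valid &= ~bad
    u = np.where(valid, u, np.nan)
    v = np.where(valid, v, np.nan)
    return VectorField(
        grid=grid,
        u=u,
        v=v,
        peak_quality=quality,
        valid=valid,
        units="px_frame",
        n_pairs=frames.shape[0] - 1,
        planes=planes if keep_planes else None,
    )


def phase_resolved_piv(
    stack: SpeckleStack,
    grid: Optional[InterrogationGrid] = None,
    phase_intervals: Sequence[tuple[float, float]] = (),
    **kwargs,
) -> list[VectorField]:
    """Run ensemble PIV restricted to each [start_s, end_s) time interval.

    Typical use: the power-stroke interval, the recovery-stroke interval
    (taken from beat-cycle timing), and the full record.
    """
    fields = []
    fps = stack.frame_rate
    for t0, t1 in phase_intervals:
        f0 = int(math.ceil(t0 * fps - 1e-9))
        f1 = int(math.ceil(t1 * fps - 1e-9))
        f0 = max(0, f0)
        f1 = min(stack.n_frames, f1)
        if f1 - f0 < 2:
            raise ValueError(f"interval [{t0}, {t1}) maps to fewer than 2 frames")
        fields.append(ensemble_piv(stack, grid=grid, frame_range=(f0, f1), **kwargs))
    return fields


def vectors_to_velocity(
    field: VectorField, effective_pixel_size: float, frame_rate: float
) -> VectorField:
    """Convert px/frame displacements to um/s velocities."""
    if effective_pixel_size <= 0 or frame_rate <= 0:
        raise ValueError("effective_pixel_size and frame_rate must be positive")
    if field.units != "px_frame":
        raise ValueError("field is not in px/frame units")
    scale = effective_pixel_size * frame_rate
    return replace(field, u=field.u * scale, v=field.v * scale, units="um_s")
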