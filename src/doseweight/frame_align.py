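"""Iterative rigid alignment of movie frames.

Beam-induced motion shifts the specimen between movie frames, largest in
the early frames and plateauing later.  The alignment algorithm here
iterates over frames, cross-correlating each frame against the current
best sum of all *other* frames (leaving the frame being aligned out of
the sum so it cannot "find itself"), then fits a smoothing spline to the
X and Y shift trajectories to suppress noise, repeating until the
largest per-frame shift change drops below a convergence threshold.

Cross-correlations are band-passed (very low frequencies carry gradient
artifacts, high frequencies are noise-dominated for this purpose) and
damped with a Gaussian B-factor; the correlation peak is located to
sub-pixel precision by parabolic interpolation.

The same routine aligns whole micrographs, boxed particles, or small
sub-sums of frames -- they are all just stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import interpolate

from .movie_io import MovieStack, shift_image

__all__ = [
    "AlignmentConfig",
    "ShiftTrajectory",
    "cross_correlate",
    "align_frames",
    "smooth_trajectory",
    "motion_plateau_onset",
    "apply_and_sum",
    "rotation_per_subsum",
    "rotational_surface_shift",
]


@dataclass
class AlignmentConfig:
    """Tunables of the frame alignment.

    Frequencies are in 1/A.  Defaults: pass 1/200 to 1/8 A^-1 with a
    1500 A^2 Gaussian B-factor on the correlation; converge when no
    frame's shift changes by more than 0.1 px, up to 20 iterations.
    """

    low_cutoff: float = 1.0 / 200.0
    high_cutoff: float = 1.0 / 8.0
    bfactor: float = 1500.0
    max_iterations: int = 20
    convergence_px: float = 0.1
    smoothing_dof: Optional[int] = None  # default: n_frames // 4, >= 4
    max_shift_px: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 <= self.low_cutoff < self.high_cutoff:
            raise ValueError("need 0 <= low_cutoff < high_cutoff")
        if self.convergence_px <= 0 or self.max_iterations < 1:
            raise ValueError("convergence threshold and iterations must be > 0")


@dataclass
class ShiftTrajectory:
    """Per-frame (dx, dy) correction shifts, in pixels.

    Applying ``shift_image(frame_i, dx_i, dy_i)`` aligns the frames.
    Trajectories are gauge-fixed to mean shift zero over frames: only
    relative motion is observable.  ``shifts_ang`` converts to A.
    """

    shifts_px: np.ndarray  # (n_frames, 2) as (dx, dy)
    pixel_size: float
    smoothed: bool = False
    converged: bool = True
    convergence_history: List[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.shifts_px = np.asarray(self.shifts_px, dtype=float)
        if self.shifts_px.ndim != 2 or self.shifts_px.shape[1] != 2:
            raise ValueError("shifts_px must have shape (n_frames, 2)")
        if not np.all(np.isfinite(self.shifts_px)):
            raise ValueError("shifts must be finite")

    @property
    def n_frames(self) -> int:
        return len(self.shifts_px)

    @property
    def shifts_ang(self) -> np.ndarray:
        return self.shifts_px * self.pixel_size

    def centered(self) -> "ShiftTrajectory":
        """Return a copy with the mean shift removed."""
        out = ShiftTrajectory(
            self.shifts_px - self.shifts_px.mean(axis=0),
            self.pixel_size, self.smoothed, self.converged,
            list(self.convergence_history),
        )
        return out

    def per_frame_displacement_ang(self) -> np.ndarray:
        """|r_i - r_{i-1}| in A for each frame (0 for the first frame)."""
        ang = self.shifts_ang
        disp = np.zeros(self.n_frames)
        if self.n_frames > 1:
            disp[1:] = np.linalg.norm(np.diff(ang, axis=0), axis=1)
        return disp

    def save(self, path: Union[str, Path], comment: str = "") -> None:
        """Write a plain-text shifts file: 'frame dx_A dy_A' per line."""
        lines = [
            "# doseweight shift trajectory",
            f"# pixel_size_A = {self.pixel_size}",
            f"# smoothed = {self.smoothed}  converged = {self.converged}",
        ]
        if comment:
            lines.append(f"# {comment}")
        lines.append("# frame dx_A dy_A")
        for i, (dx, dy) in enumerate(self.shifts_ang, start=1):
            lines.append(f"{i} {dx:.6f} {dy:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "ShiftTrajectory":
        pixel_size = None
        rows = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                if "pixel_size_A" in line:
                    pixel_size = float(line.split("=", 1)[1])
                continue
            if line.strip():
                idx, dx, dy = line.split()
                rows.append((int(idx), float(dx), float(dy)))
        if pixel_size is None or not rows:
            raise ValueError(f"{path}: not a doseweight shifts file")
        rows.sort()
        ang = np.array([(dx, dy) for _, dx, dy in rows])
        return cls(shifts_px=ang / pixel_size, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# Cross-correlation kernel
# ---------------------------------------------------------------------------


def _correlation_weights(
    shape: Tuple[int, int], pixel_size: float, config: AlignmentConfig
) -> np.ndarray:
    """Band-pass mask x Gaussian B-factor on the full FFT grid."""
    ky = np.fft.fftfreq(shape[0], d=pixel_size)
    kx = np.fft.fftfreq(shape[1], d=pixel_size)
    k2 = ky[:, None] ** 2 + kx[None, :] ** 2
    k = np.sqrt(k2)
    mask = (k >= config.low_cutoff) & (k <= config.high_cutoff)
    return mask * np.exp(-config.bfactor * k2 / 4.0)


def _parabolic_offset(ym: float, y0: float, yp: float) -> float:
    denom = ym - 2.0 * y0 + yp
    if denom >= 0:  # flat or non-concave: no reliable sub-pixel refinement
        return 0.0
    offset = 0.5 * (ym - yp) / denom
    return float(np.clip(offset, -0.5, 0.5))


def _locate_peak(
    cc: np.ndarray, prev_shift: Tuple[float, float]
) -> Tuple[float, float, float]:
    ny, nx = cc.shape
    peak = cc.max()
    candidates = np.argwhere(cc >= peak * (1 - 1e-12))
    # tie-break: wrap to signed shifts, take the candidate nearest the
    # previous iteration's shift
    sy = np.where(candidates[:, 0] > ny // 2, candidates[:, 0] - ny,
                  candidates[:, 0])
    sx = np.where(candidates[:, 1] > nx // 2, candidates[:, 1] - nx,
                  candidates[:, 1])
    d2 = (sx - prev_shift[0]) ** 2 + (sy - prev_shift[1]) ** 2
    iy, ix = candidates[np.argmin(d2)]
    dy = _parabolic_offset(cc[(iy - 1) % ny, ix], cc[iy, ix],
                           cc[(iy + 1) % ny, ix])
    dx = _parabolic_offset(cc[iy, (ix - 1) % nx], cc[iy, ix],
                           cc[iy, (ix + 1) % nx])
    sy0 = iy - ny if iy > ny // 2 else iy
    sx0 = ix - nx if ix > nx // 2 else ix
    return sx0 + dx, sy0 + dy, float(cc[iy, ix])


def cross_correlate(
    a: np.ndarray,
    b: np.ndarray,
    config: AlignmentConfig = AlignmentConfig(),
    pixel_size: float = 1.0,
    prev_shift: Tuple[float, float] = (0.0, 0.0),
    weights: Optional[np.ndarray] = None,
) -> Tuple[float, float, float]:
    """Locate the weighted cross-correlation peak of ``b`` against ``a``.

    Returns ``(dx, dy, peak)`` such that ``b ~ shift_image(a, dx, dy)``.
    The correlation is band-passed and B-factor damped per ``config``;
    the peak position is refined by 3x3 parabolic interpolation and is
    accurate to <= 0.1 px on noiseless shifted copies.
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    fa, fb = np.fft.fft2(a), np.fft.fft2(b)
    return _cross_correlate_ft(fa, fb, config, pixel_size, prev_shift, weights)


def _cross_correlate_ft(fa, fb, config, pixel_size, prev_shift=(0.0, 0.0),
                        weights=None):
    if weights is None:
        weights = _correlation_weights(fa.shape, pixel_size, config)
    cross = np.conj(fa) * fb * weights
    norm = np.abs(cross).sum()
    if norm == 0:
        raise ValueError(
            "cross-correlation undefined: no power in the pass band "
            "(all-zero or constant input?)"
        )
    cc = np.fft.ifft2(cross).real
    return _locate_peak(cc, prev_shift)


# ---------------------------------------------------------------------------
# Trajectory smoothing
# ---------------------------------------------------------------------------


def smooth_trajectory(
    shifts: np.ndarray, dof: Optional[int] = None
) -> np.ndarray:
    """Fit a least-squares cubic spline to each shift component.

    ``shifts`` is (n_frames,) or (n_frames, 2); ``dof`` is the effective
    number of degrees of freedom of the fit (default n_frames // 4, at
    least 4).  Inputs already expressible by the spline (e.g. linear
    drift) are reproduced exactly; i.i.d. jitter is averaged down.
    Fewer than 4 frames fall back to a lower-order polynomial fit.
    """
    arr = np.asarray(shifts, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[:, None]
    n = len(arr)
    if n < 4:
        x = np.arange(n)
        out = np.column_stack([
            np.polyval(np.polyfit(x, arr[:, j], deg=max(n - 1, 0)), x)
            for j in range(arr.shape[1])
        ])
        return out[:, 0] if squeeze else out
    if dof is None:
        dof = max(n // 4, 4)
    dof = int(np.clip(dof, 4, n))
    # cubic LSQ spline: dof = n_interior_knots + 4
    n_interior = dof - 4
    x = np.arange(n, dtype=float)
    if n_interior > 0:
        knots = np.linspace(0, n - 1, n_interior + 2)[1:-1]
    else:
        knots = np.array([])
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        spline = interpolate.LSQUnivariateSpline(x, arr[:, j], knots, k=3)
        out[:, j] = spline(x)
    return out[:, 0] if squeeze else out


# ---------------------------------------------------------------------------
# Main alignment loop
# ---------------------------------------------------------------------------


def align_frames(
    stack: MovieStack, config: AlignmentConfig = AlignmentConfig()
) -> ShiftTrajectory:
    """Estimate per-frame correction shifts for a movie.

    Iterates over frames, correlating each (currently shifted) frame
    with the leave-one-out sum of the others and updating its shift; a
    smoothing spline over frame index is applied to X(t) and Y(t) after
    each full pass, and shifts are re-centered to mean zero.  Stops when
    the maximum per-frame shift change falls below
    ``config.convergence_px`` or after ``config.max_iterations`` passes.
    Non-convergence returns the best trajectory flagged, never silently.
    """
    n = stack.n_frames
    if n < 3:
        raise ValueError(
            f"alignment needs >= 3 frames (leave-one-out sum), got {n}"
        )
    px = stack.pixel_size
    weights = _correlation_weights(stack.shape, px, config)
    raw_fts = np.fft.fft2(stack.frames.astype(float))
    ky = np.fft.fftfreq(stack.shape[0])[:, None]
    kx = np.fft.fftfreq(stack.shape[1])[None, :]

    def ramp(dx: float, dy: float) -> np.ndarray:
        return np.exp(-2j * np.pi * (kx * dx + ky * dy))

    shifts = np.zeros((n, 2))
    shifted_fts = raw_fts.copy()
    history: List[float] = []
    converged = False
    for _ in range(config.max_iterations):
        prev = shifts.copy()
        total = shifted_fts.sum(axis=0)
        for i in range(n):
            reference = total - shifted_fts[i]
            ddx, ddy, _ = _cross_correlate_ft(
                shifted_fts[i], reference, config, px, weights=weights
            )
            new = shifts[i] + (ddx, ddy)
            if config.max_shift_px is not None:
                mag = np.hypot(*new)
                if mag > config.max_shift_px:
                    new *= config.max_shift_px / mag
            delta = new - shifts[i]
            shifts[i] = new
            updated = raw_fts[i] * ramp(*shifts[i])
            total += updated - shifted_fts[i]
            shifted_fts[i] = updated
        shifts = smooth_trajectory(shifts, config.smoothing_dof)
        shifts -= shifts.mean(axis=0)
        for i in range(n):
            shifted_fts[i] = raw_fts[i] * ramp(*shifts[i])
        change = float(np.abs(shifts - prev).max())
        history.append(change)
        if change < config.convergence_px:
            converged = True
            break
    if not converged:
        import warnings

        warnings.warn(
            f"frame alignment did not converge in {config.max_iterations} "
            f"iterations (last max shift change {history[-1]:.3f} px)"
        )
    return ShiftTrajectory(
        shifts_px=shifts - shifts.mean(axis=0),
        pixel_size=px,
        smoothed=True,
        converged=converged,
        convergence_history=history,
    )


def motion_plateau_onset(
    traj: ShiftTrajectory, per_frame_threshold_ang: float
) -> int:
    """First frame (1-based) from which motion stays below a threshold.

    Motion is the frame-to-frame displacement |r_i - r_{i-1}| in A (zero
    for frame 1).  Returns ``n_frames + 1`` if the motion never settles.
    """
    disp = traj.per_frame_displacement_ang()
    below = disp < per_frame_threshold_ang
    for start in range(traj.n_frames):
        if below[start:].all():
            return start + 1
    return traj.n_frames + 1


def apply_and_sum(
    stack: MovieStack,
    traj: ShiftTrajectory,
    frame_range: Optional[Tuple[int, int]] = None,
) -> np.ndarray:
    """Shift each selected frame by its trajectory entry and sum.

    ``frame_range`` is a 1-based inclusive (first, last); default all
    frames.  No exposure weighting is applied here -- this is the plain
    aligned sum (see :mod:`doseweight.exposure_filter` for weighting).
    """
    if traj.n_frames != stack.n_frames:
        raise ValueError(
            f"trajectory covers {traj.n_frames} frames, movie has "
            f"{stack.n_frames}"
        )
    first, last = frame_range if frame_range else (1, stack.n_frames)
    if not (1 <= first <= last <= stack.n_frames):
        raise ValueError(
            f"invalid frame range {first}:{last} for {stack.n_frames} frames"
        )
    out = np.zeros(stack.shape)
    for i in range(first - 1, last):
        dx, dy = traj.shifts_px[i]
        if dx == 0 and dy == 0:
            out += stack.frames[i]
        else:
            out += shift_image(stack.frames[i], dx, dy)
    return out


# ---------------------------------------------------------------------------
# Residual-rotation arithmetic
# ---------------------------------------------------------------------------


def rotation_per_subsum(
    total_rotation_deg: float, n_frames: int, frames_per_subsum: int = 3
) -> float:
    """Average rotation (deg) accrued over one sub-sum of frames.

    Particles slowly rotate under the beam; dividing the total rotation
    over a movie by the number of frames gives the mean per-frame rate,
    and per-sub-sum rotation scales with the frames per sub-sum.
    """
    if n_frames < 1 or frames_per_subsum < 1:
        raise ValueError("frame counts must be >= 1")
    return total_rotation_deg * frames_per_subsum / n_frames


def rotational_surface_shift(rotation_deg: float, radius_ang: float) -> float:
    """Arc length (A) traced at ``radius_ang`` by a small rotation.

    Used to judge whether residual rotation blurs the periphery of a
    particle: e.g. 0.02 degrees at a 350 A radius is ~0.12 A, negligible
    next to per-frame translations.
    """
    if radius_ang < 0:
        raise ValueError("radius must be >= 0")
    return float(np.deg2rad(rotation_deg) * radius_ang)
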