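"""Movie stacks, exposure bookkeeping and Fourier-domain primitives.

A cryo-EM *movie* is a stack of low-exposure frames recorded during one
exposure.  This module holds the in-memory container (:class:`MovieStack`),
the exposure ledger (:class:`ExposureSchedule`) that converts frame
indices to accumulated exposures N_i in e-/A^2, and the small set of
Fourier operations every other module builds on: radial shell indexing,
Fourier cropping (exact band-limited downsampling), sub-pixel shifting
via phase ramps, and per-shell averaging.

Frame indices are 1-based in every user-facing interface, matching how
microscopists speak of "frames 4-21"; internal arrays are 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage

from .mrc import read_mrc, write_mrc

__all__ = [
    "MovieStack",
    "ExposureSchedule",
    "ShellIndex",
    "read_movie",
    "write_movie",
    "accumulated_exposure",
    "fourier_crop",
    "fourier_resample",
    "shift_image",
    "shell_average",
]


@dataclass
class MovieStack:
    """Ordered stack of equally sized 2D frames with a pixel size (A)."""

    frames: np.ndarray  # (n_frames, ny, nx), float
    pixel_size: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be (n, ny, nx), got shape {self.frames.shape}"
            )
        if self.n_frames < 1:
            raise ValueError("a movie needs at least one frame")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> Tuple[int, int]:
        """Shape (ny, nx) of a single frame."""
        return self.frames.shape[1:]

    def frame(self, index: int) -> np.ndarray:
        """Return frame by 1-based index."""
        if not 1 <= index <= self.n_frames:
            raise IndexError(
                f"frame index {index} out of range 1..{self.n_frames}"
            )
        return self.frames[index - 1]


@dataclass
class ExposureSchedule:
    """Maps frame indices to accumulated exposure N (e-/A^2).

    ``per_frame`` is either a scalar (uniform exposure rate) or one
    value per frame.  ``convention`` states which point within a frame
    its accumulated exposure refers to: ``"end"`` (default; a frame's
    signal reflects the damage sustained while it was recorded) or
    ``"mid"``.
    """

    per_frame: Union[float, Sequence[float]]
    pre_exposure: float = 0.0
    convention: str = "end"

    def __post_init__(self) -> None:
        if self.pre_exposure < 0:
            raise ValueError("pre_exposure must be >= 0")
        if self.convention not in ("end", "mid"):
            raise ValueError("convention must be 'end' or 'mid'")
        if np.ndim(self.per_frame) > 0:
            self.per_frame = np.asarray(self.per_frame, dtype=float)
            if np.any(self.per_frame <= 0):
                raise ValueError("per-frame exposures must be > 0")
        elif not self.per_frame > 0:
            raise ValueError("per_frame exposure must be > 0")

    def _rates(self, n_frames: int) -> np.ndarray:
        if np.ndim(self.per_frame) > 0:
            rates = np.asarray(self.per_frame, dtype=float)
            if len(rates) < n_frames:
                raise ValueError(
                    f"schedule lists {len(rates)} frames, need {n_frames}"
                )
            return rates[:n_frames]
        return np.full(n_frames, float(self.per_frame))

    def accumulated(self, frame_index: int) -> float:
        """Accumulated exposure at the convention point of ``frame_index``."""
        if frame_index < 1:
            raise IndexError(f"frame index must be >= 1, got {frame_index}")
        rates = self._rates(frame_index)
        n = self.pre_exposure + rates.sum()
        if self.convention == "mid":
            n -= rates[-1] / 2.0
        return float(n)

    def accumulated_all(self, n_frames: int) -> np.ndarray:
        """Accumulated exposures for frames 1..n_frames (strictly increasing)."""
        rates = self._rates(n_frames)
        n = self.pre_exposure + np.cumsum(rates)
        if self.convention == "mid":
            n -= rates / 2.0
        return n

    @classmethod
    def from_file(cls, path: Union[str, Path], pre_exposure: float = 0.0
                  ) -> "ExposureSchedule":
        """Read a sidecar text file with one per-frame exposure per line."""
        values = [
            float(line.split("#", 1)[0])
            for line in Path(path).read_text().splitlines()
            if line.split("#", 1)[0].strip()
        ]
        if not values:
            raise ValueError(f"{path}: no exposures found")
        return cls(per_frame=values, pre_exposure=pre_exposure)


def accumulated_exposure(schedule: ExposureSchedule, frame_index: int) -> float:
    """Accumulated exposure (e-/A^2) at frame ``frame_index`` (1-based)."""
    return schedule.accumulated(frame_index)


def read_movie(
    path: Union[str, Path], pixel_size_override: Optional[float] = None
) -> MovieStack:
    """Read an MRC/MRCS movie into a :class:`MovieStack`.

    The pixel size comes from the header unless ``pixel_size_override``
    is given; a disagreement between the two is resolved in favor of the
    override with a warning.
    """
    data, header_px = read_mrc(path)
    pixel_size = header_px
    if pixel_size_override is not None:
        if header_px > 0 and not np.isclose(header_px, pixel_size_override,
                                            rtol=1e-3):
            warnings.warn(
                f"{path}: header pixel size {header_px:.4f} A differs from "
                f"override {pixel_size_override:.4f} A; using the override"
            )
        pixel_size = float(pixel_size_override)
    if pixel_size <= 0:
        raise ValueError(
            f"{path}: header defines no pixel size; pass pixel_size_override"
        )
    return MovieStack(frames=data, pixel_size=pixel_size)


def write_movie(path: Union[str, Path], stack: MovieStack) -> None:
    """Write a :class:`MovieStack` as a mode-2 MRC stack."""
    write_mrc(path, stack.frames, stack.pixel_size)


# ---------------------------------------------------------------------------
# Fourier primitives
# ---------------------------------------------------------------------------


@dataclass
class ShellIndex:
    """Partition of a square/cubic Fourier grid into radial shells.

    Shell s collects voxels whose radial frequency, in grid units,
    rounds to s; shells run from 0 (DC) to n//2 (Nyquist).  Corner
    voxels beyond Nyquist belong to no shell (label -1).  The center
    frequency of shell s is ``s / (n * pixel_size)`` in 1/A.
    """

    shape: Tuple[int, ...]
    pixel_size: float
    labels: np.ndarray = field(repr=False)
    frequencies: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)

    @classmethod
    def for_shape(cls, shape: Sequence[int], pixel_size: float) -> "ShellIndex":
        shape = tuple(int(s) for s in shape)
        n = shape[0]
        if any(s != n for s in shape):
            raise ValueError(
                f"shell indexing requires a square/cubic grid, got {shape}"
            )
        if not pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        grids = np.meshgrid(
            *[np.fft.fftfreq(n) * n for _ in shape], indexing="ij"
        )
        radius = np.sqrt(sum(g * g for g in grids))
        labels = np.rint(radius).astype(np.int64)
        n_shells = n // 2 + 1
        labels[labels > n // 2] = -1
        counts = np.bincount(labels[labels >= 0].ravel(), minlength=n_shells)
        freqs = np.arange(n_shells) / (n * pixel_size)
        return cls(shape=shape, pixel_size=pixel_size, labels=labels,
                   frequencies=freqs, counts=counts)

    @property
    def n_shells(self) -> int:
        return len(self.frequencies)

    @property
    def nyquist(self) -> float:
        """Nyquist frequency in 1/A."""
        return 1.0 / (2.0 * self.pixel_size)

    def sum_per_shell(self, voxelwise: np.ndarray) -> np.ndarray:
        if voxelwise.shape != self.shape:
            raise ValueError(
                f"grid mismatch: data {voxelwise.shape} vs shells {self.shape}"
            )
        valid = self.labels >= 0
        return np.bincount(
            self.labels[valid].ravel(),
            weights=voxelwise[valid].ravel(),
            minlength=self.n_shells,
        )

    def mean_per_shell(self, voxelwise: np.ndarray) -> np.ndarray:
        return self.sum_per_shell(voxelwise) / np.maximum(self.counts, 1)


def shell_average(
    fourier_image: np.ndarray,
    shells: ShellIndex,
    statistic: str = "power",
) -> np.ndarray:
    """Per-shell mean of ``power`` (|F|^2), ``amplitude`` (|F|), or the
    raw voxel values (``statistic="value"``, for real voxelwise data)."""
    if statistic == "power":
        voxelwise = np.abs(fourier_image) ** 2
    elif statistic == "amplitude":
        voxelwise = np.abs(fourier_image)
    elif statistic == "value":
        voxelwise = np.real(fourier_image)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return shells.mean_per_shell(voxelwise)


def radial_frequency_grid(
    shape: Sequence[int], pixel_size: float, fill_dc: bool = True
) -> np.ndarray:
    """|k| in 1/A for every voxel of a full FFT grid.

    With ``fill_dc`` the DC voxel is assigned the smallest nonzero grid
    frequency, so damage-model weights at DC equal those of the first
    shell and the mean is never amplified relative to its neighbors.
    """
    freqs = [np.fft.fftfreq(n, d=pixel_size) for n in shape]
    grids = np.meshgrid(*freqs, indexing="ij")
    k = np.sqrt(sum(g * g for g in grids))
    if fill_dc:
        k_min = 1.0 / (max(shape) * pixel_size)
        k[k == 0] = k_min
    return k


def _resample_axis(ft: np.ndarray, axis: int, n_new: int) -> np.ndarray:
    """Crop or pad one axis of an fftshifted spectrum.

    Even grids carry a single unpaired Nyquist row: cropping folds the
    +Nyquist row into the -Nyquist row and padding splits it in half,
    which keeps the spectrum Hermitian for real inputs and makes
    crop(pad(x)) the identity on band-limited content.
    """
    n_old = ft.shape[axis]
    if n_new == n_old:
        return ft
    ft = np.moveaxis(ft, axis, 0)
    if n_new < n_old:
        start = n_old // 2 - n_new // 2
        block = ft[start:start + n_new].copy()
        if n_new % 2 == 0 and start + n_new < n_old:
            block[0] = block[0] + ft[start + n_new]
    else:
        shape = (n_new,) + ft.shape[1:]
        block = np.zeros(shape, dtype=ft.dtype)
        dst = n_new // 2 - n_old // 2
        block[dst:dst + n_old] = ft
        if n_old % 2 == 0:
            block[dst] = 0.5 * ft[0]
            block[dst + n_old] = 0.5 * ft[0]
    return np.moveaxis(block, 0, axis)


def fourier_resample(image: np.ndarray, new_shape: Sequence[int]) -> np.ndarray:
    """Resample by centered cropping/padding of the Fourier transform.

    Preserves the real-space mean and, for band-limited content below
    the smaller Nyquist, the signal itself (up to the sampling change).
    """
    new_shape = tuple(int(s) for s in new_shape)
    if len(new_shape) != image.ndim:
        raise ValueError("new_shape rank must match image rank")
    ft = np.fft.fftshift(np.fft.fftn(image))
    for axis, n_new in enumerate(new_shape):
        ft = _resample_axis(ft, axis, n_new)
    scale = np.prod(new_shape) / np.prod(image.shape)
    resampled = np.fft.ifftn(np.fft.ifftshift(ft)) * scale
    return np.ascontiguousarray(resampled.real)


def fourier_crop(image: np.ndarray, factor: int) -> np.ndarray:
    """Downsample ``image`` by an integer factor via Fourier cropping.

    All dimensions must be divisible by ``factor`` (no silent padding).
    The caller's pixel size is multiplied by ``factor``.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    if factor == 1:
        return np.asarray(image, dtype=float).copy()
    for n in image.shape:
        if n % factor:
            raise ValueError(
                f"dimension {n} is not divisible by crop factor {factor}"
            )
    return fourier_resample(image, [n // factor for n in image.shape])


def shift_image(image: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """Shift an image by (dx, dy) pixels with a Fourier phase ramp.

    Positive dx moves content toward larger x (column index), positive
    dy toward larger y (row index); integer shifts equal circular rolls.
    """
    if not (np.isfinite(dx) and np.isfinite(dy)):
        raise ValueError(f"shifts must be finite, got ({dx}, {dy})")
    ft = np.fft.fft2(image)
    shifted = ndimage.fourier_shift(ft, (dy, dx))
    return np.fft.ifft2(shifted).real
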