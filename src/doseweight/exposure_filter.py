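"""SNR-optimal exposure weighting of movie frames.

Radiation damage attenuates Fourier amplitudes by q(k, N) =
exp(-N / (2 Ne(k))), so late frames carry progressively less
high-resolution signal while contributing the same noise.  The matched
filter that maximizes the SNR of the frame sum in every resolution
shell therefore weights frame i at frequency k by q(k, N_i):

    F_filtered(k) = sum_i q_i(k) F_i(k) / sqrt(sum_i q_i(k)^2)

The square-root normalization keeps the noise variance of the output
equal to that of a single frame at every frequency, so the filter
reshapes only the signal, never the noise floor (a ``nosqrt`` variant
without the root is available for comparison).  When a per-shell
estimate of the unattenuated single-frame SNR (the particle spectral
SNR, PSSNR) is available, the full Wiener combination

    F_W(k) = sum_i q_i F_i / (sum_i q_i^2 + 1/SNR(k))

is provided, and a CTF-aware generalization for per-frame (or
per-image) reconstruction weighting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .dose_model import DEFAULT_PARAMS, DoseModelParams, attenuation_factor
from .movie_io import (
    ExposureSchedule,
    MovieStack,
    ShellIndex,
    radial_frequency_grid,
)

__all__ = [
    "FrameFourier",
    "frame_weights",
    "filtered_sum",
    "wiener_filtered_sum",
    "reconstruction_weights",
    "relative_snr_of_plain_sum",
    "filter_movie",
    "per_shell_weight_table",
]


@dataclass
class FrameFourier:
    """Fourier transform of one aligned frame plus its exposure.

    ``ft`` is the full (numpy-layout) FFT of the frame; ``exposure`` is
    the accumulated exposure N_i (e-/A^2) at this frame; ``ctf`` holds
    externally computed CTF values on the same grid when reconstruction
    weighting is used.  For a pre-summed input (e.g. a 3-frame sub-sum)
    use the sub-sum's mean accumulated exposure.
    """

    ft: np.ndarray
    exposure: float
    ctf: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.exposure < 0:
            raise ValueError("accumulated exposure must be >= 0")
        if self.ctf is not None and self.ctf.shape != self.ft.shape:
            raise ValueError("CTF grid must match the frame grid")


def _validate_set(frames: Sequence[FrameFourier], need_ctf: bool = False
                  ) -> None:
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    shape = frames[0].ft.shape
    exposures = [f.exposure for f in frames]
    for f in frames:
        if f.ft.shape != shape:
            raise ValueError("all frames must share one Fourier grid")
        if need_ctf and f.ctf is None:
            raise ValueError("reconstruction weighting needs a CTF per frame")
    if len(frames) > 1 and np.any(np.diff(exposures) < 0):
        raise ValueError("frame exposures must be non-decreasing")


def frame_weights(
    k: np.ndarray,
    exposures: Sequence[float],
    params: DoseModelParams = DEFAULT_PARAMS,
) -> np.ndarray:
    """Attenuation weights q_i(k) for each exposure, stacked on axis 0.

    ``k`` may be a 1D array of shell frequencies or a full radial
    frequency grid (see :func:`radial_frequency_grid`); every entry
    must be positive (substitute the first shell's frequency for DC).
    """
    exposures = np.asarray(exposures, dtype=float)
    if np.any(exposures < 0):
        raise ValueError("exposures must be >= 0")
    k = np.asarray(k, dtype=float)
    return attenuation_factor(
        k[None, ...], exposures.reshape((-1,) + (1,) * k.ndim), params
    )


def _q_stack(frames: Sequence[FrameFourier], params: DoseModelParams,
             pixel_size: float) -> np.ndarray:
    k = radial_frequency_grid(frames[0].ft.shape, pixel_size)
    return frame_weights(k, [f.exposure for f in frames], params)


def filtered_sum(
    frames: Sequence[FrameFourier],
    pixel_size: float,
    params: DoseModelParams = DEFAULT_PARAMS,
    variant: str = "sqrt",
) -> np.ndarray:
    """Matched-filter (exposure-weighted) sum, inverse-transformed.

    ``variant="sqrt"`` (default) normalizes by sqrt(sum q^2), which
    preserves the per-frequency noise variance of a single frame;
    ``"nosqrt"`` divides by sum q^2 instead.  With identical exposures
    the output is proportional to the plain sum; a single frame passes
    through unchanged.
    """
    _validate_set(frames)
    if variant not in ("sqrt", "nosqrt"):
        raise ValueError("variant must be 'sqrt' or 'nosqrt'")
    q = _q_stack(frames, params, pixel_size)
    num = sum(qi * f.ft for qi, f in zip(q, frames))
    denom = (q ** 2).sum(axis=0)
    if variant == "sqrt":
        denom = np.sqrt(denom)
    return np.fft.ifft2(num / denom).real


def _resolve_snr(snr, k_grid: np.ndarray, shells: Optional[ShellIndex]
                 ) -> np.ndarray:
    """Broadcast a per-shell SNR curve (or scalar/callable) onto a grid."""
    if callable(snr):
        return np.asarray(snr(k_grid), dtype=float)
    snr = np.asarray(snr, dtype=float)
    if snr.ndim == 0:
        return np.full(k_grid.shape, float(snr))
    if snr.shape == k_grid.shape:
        return snr
    if shells is None:
        raise ValueError(
            "per-shell SNR requires a ShellIndex matching the data grid"
        )
    if len(snr) != shells.n_shells:
        raise ValueError(
            f"SNR curve has {len(snr)} shells, grid has {shells.n_shells}"
        )
    return np.interp(k_grid, shells.frequencies, snr)


def _wiener_combine(num: np.ndarray, q2sum: np.ndarray, snr: np.ndarray
                    ) -> np.ndarray:
    """num / (q2sum + 1/snr), stable at snr = 0 and snr = inf."""
    out = np.empty(num.shape, dtype=complex)
    inf = np.isinf(snr)
    # finite SNR: multiply through by SNR -> snr*num / (snr*q2sum + 1);
    # at snr = 0 this is exactly the low-SNR limit (zero output there,
    # proportional to snr * num nearby)
    fin = ~inf
    out[fin] = snr[fin] * num[fin] / (snr[fin] * q2sum[fin] + 1.0)
    out[inf] = num[inf] / q2sum[inf]
    return out


def wiener_filtered_sum(
    frames: Sequence[FrameFourier],
    pixel_size: float,
    snr,
    params: DoseModelParams = DEFAULT_PARAMS,
    shells: Optional[ShellIndex] = None,
) -> np.ndarray:
    """Wiener-weighted frame sum using a known per-shell PSSNR.

    ``snr`` may be a scalar, a callable of frequency, a full-grid array,
    or a per-shell curve (then pass the matching ``shells``).  As
    SNR -> inf the result tends to sum(q F)/sum(q^2); as SNR -> 0 it
    tends, per shell, to SNR * sum(q F) (the low-exposure limit), with
    zero SNR handled exactly rather than dividing by zero.
    """
    _validate_set(frames)
    k_grid = radial_frequency_grid(frames[0].ft.shape, pixel_size)
    q = _q_stack(frames, params, pixel_size)
    num = sum(qi * f.ft for qi, f in zip(q, frames))
    q2sum = (q ** 2).sum(axis=0)
    snr_grid = _resolve_snr(snr, k_grid, shells)
    if np.any(snr_grid < 0):
        raise ValueError("SNR values must be >= 0")
    return np.fft.ifft2(_wiener_combine(num, q2sum, snr_grid)).real


def reconstruction_weights(
    frames: Sequence[FrameFourier],
    pixel_size: float,
    snr,
    params: DoseModelParams = DEFAULT_PARAMS,
    shells: Optional[ShellIndex] = None,
) -> np.ndarray:
    """Damage- and CTF-aware Wiener combination of frame transforms.

    Returns the combined Fourier grid
    ``sum_i CTF_i* q_i F_i / (sum_i (|CTF_i| q_i)^2 + 1/SNR)`` -- a
    generic per-voxel weighted combine usable on 2D or 3D grids, not a
    reconstruction engine.  With CTF identically 1 the inverse transform
    equals :func:`wiener_filtered_sum`.
    """
    _validate_set(frames, need_ctf=True)
    k_grid = radial_frequency_grid(frames[0].ft.shape, pixel_size)
    q = _q_stack(frames, params, pixel_size)
    num = sum(np.conj(f.ctf) * qi * f.ft for qi, f in zip(q, frames))
    den = sum((np.abs(f.ctf) * qi) ** 2 for qi, f in zip(q, frames))
    snr_grid = _resolve_snr(snr, k_grid, shells)
    return _wiener_combine(num, den, snr_grid)


def relative_snr_of_plain_sum(
    exposures: Sequence[float],
    k: float,
    params: DoseModelParams = DEFAULT_PARAMS,
) -> float:
    """Model SNR of the unweighted n-frame sum relative to the matched filter.

    At frequency ``k`` the matched-filter sum attains SNR proportional
    to sum(q_i^2); the plain sum attains (sum q_i)^2 / n.  Their ratio,

        (sum q_i)^2 / (n * sum q_i^2),

    lies in (0, 1] with equality iff all q_i are equal (Cauchy-Schwarz).
    E.g. for 38 frames totalling 53 e-/A^2, at 1/3 A^-1 the plain sum
    retains only about a third of the filtered sum's SNR.
    """
    exposures = np.asarray(exposures, dtype=float)
    if exposures.size == 0:
        raise ValueError("need at least one frame")
    q = attenuation_factor(float(k), exposures, params)
    q = np.atleast_1d(q)
    return float(q.sum() ** 2 / (len(q) * (q ** 2).sum()))


# ---------------------------------------------------------------------------
# Movie-level convenience
# ---------------------------------------------------------------------------


def frames_from_stack(
    stack: MovieStack,
    schedule: ExposureSchedule,
    traj=None,
    frame_range: Optional[Tuple[int, int]] = None,
) -> List[FrameFourier]:
    """Build :class:`FrameFourier` objects from an (optionally aligned) stack.

    Alignment shifts, when given, are applied as Fourier phase ramps;
    shifting and exposure weighting are both linear diagonal operators
    in Fourier space, so their order is immaterial.
    """
    first, last = frame_range if frame_range else (1, stack.n_frames)
    if not (1 <= first <= last <= stack.n_frames):
        raise ValueError(f"invalid frame range {first}:{last}")
    exposures = schedule.accumulated_all(stack.n_frames)
    ky = np.fft.fftfreq(stack.shape[0])[:, None]
    kx = np.fft.fftfreq(stack.shape[1])[None, :]
    out = []
    for i in range(first - 1, last):
        ft = np.fft.fft2(stack.frames[i].astype(float))
        if traj is not None:
            dx, dy = traj.shifts_px[i]
            ft = ft * np.exp(-2j * np.pi * (kx * dx + ky * dy))
        out.append(FrameFourier(ft=ft, exposure=float(exposures[i])))
    return out


def filter_movie(
    stack: MovieStack,
    schedule: ExposureSchedule,
    params: DoseModelParams = DEFAULT_PARAMS,
    traj=None,
    frame_range: Optional[Tuple[int, int]] = None,
    variant: str = "sqrt",
) -> np.ndarray:
    """Aligned, exposure-filtered sum of a movie in one call."""
    frames = frames_from_stack(stack, schedule, traj, frame_range)
    return filtered_sum(frames, stack.pixel_size, params, variant)


def per_shell_weight_table(
    shells: ShellIndex,
    exposures: Sequence[float],
    params: DoseModelParams = DEFAULT_PARAMS,
):
    """Per-shell q_i diagnostics as a pandas DataFrame.

    Rows are shells (column ``frequency_invA``); one column per frame.
    The DC shell reuses the first nonzero shell's frequency, mirroring
    the grid-level convention.
    """
    import pandas as pd

    freqs = shells.frequencies.copy()
    if freqs[0] == 0:
        freqs[0] = freqs[1] if len(freqs) > 1 else 1.0 / (2 * shells.pixel_size)
    q = frame_weights(freqs, exposures, params)
    table = pd.DataFrame(
        q.T, columns=[f"q_frame_{i + 1}" for i in range(len(q))]
    )
    table.insert(0, "frequency_invA", shells.frequencies)
    return table
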