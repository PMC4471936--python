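"""Critical-exposure estimation from exposure-resolved FSC curves.

The measurement chain: reconstructions (or 2D averages) computed from
narrow exposure windows yield one half-map pair per accumulated
exposure N.  Each pair gives a Fourier shell correlation curve, which
converts to a spectral SNR via

    SNR(k) = 2 FSC(k) / (1 - FSC(k)).

Because damage attenuates amplitudes as exp(-N / (2 Ne(k))), the SNR
decays as exp(-N / Ne(k)); a plot of ln SNR vs N is linear per shell
with slope -1/Ne(k).  Per-shell ordinary least squares, censoring
points whose FSC is indistinguishable from pure noise, yields Ne(k)
estimates, and a nonlinear fit of Ne(k) = a k^b + c condenses them into
portable :class:`~doseweight.dose_model.DoseModelParams`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dose_model import DoseModelParams
from .movie_io import ShellIndex

__all__ = [
    "FSCCurve",
    "SNRSeries",
    "CriticalExposureFit",
    "PowerLawFit",
    "compute_fsc",
    "fsc_to_snr",
    "snr_to_fsc",
    "resolution_at_threshold",
    "estimate_critical_exposure",
    "fit_power_law",
    "estimate_dose_model",
]


@dataclass
class FSCCurve:
    """Per-shell correlation between two half maps at one exposure."""

    frequencies: np.ndarray  # 1/A, strictly increasing
    fsc: np.ndarray
    n_voxels: np.ndarray  # voxels per shell (both Friedel mates counted)
    exposure: float = np.nan  # accumulated exposure label, e-/A^2

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.fsc = np.asarray(self.fsc, dtype=float)
        self.n_voxels = np.asarray(self.n_voxels)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("shell frequencies must be strictly increasing")
        if np.any(self.n_voxels <= 0):
            raise ValueError("shell voxel counts must be positive")

    def to_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write(f"# exposure = {self.exposure}\n")
            pd.DataFrame({
                "shell_frequency_invA": self.frequencies,
                "fsc": self.fsc,
                "n_voxels": self.n_voxels,
            }).to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "FSCCurve":
        exposure = np.nan
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                if "exposure" in first:
                    exposure = float(first.split("=", 1)[1])
                table = pd.read_csv(fh)
            else:
                fh.seek(0)
                table = pd.read_csv(fh)
        return cls(
            frequencies=table["shell_frequency_invA"].to_numpy(),
            fsc=table["fsc"].to_numpy(),
            n_voxels=table["n_voxels"].to_numpy(),
            exposure=exposure,
        )


def compute_fsc(
    map_a: np.ndarray,
    map_b: np.ndarray,
    pixel_size: float,
    mask: Optional[np.ndarray] = None,
    exposure: float = np.nan,
    skip_dc: bool = True,
) -> FSCCurve:
    """Fourier shell correlation between two equally gridded maps.

    Per shell: Re(sum A conj(B)) / sqrt(sum |A|^2 sum |B|^2).  A real-
    valued soft mask in [0, 1] may be applied to both maps first.  Works
    for 2D images and 3D volumes on square/cubic grids.  The DC shell is
    dropped by default (it compares the means, not structure).
    """
    if map_a.shape != map_b.shape:
        raise ValueError(f"grid mismatch: {map_a.shape} vs {map_b.shape}")
    if mask is not None:
        if mask.shape != map_a.shape:
            raise ValueError("mask grid must match the maps")
        if mask.min() < 0 or mask.max() > 1:
            raise ValueError("mask values must lie in [0, 1]")
        map_a = map_a * mask
        map_b = map_b * mask
    fa = np.fft.fftn(map_a)
    fb = np.fft.fftn(map_b)
    shells = ShellIndex.for_shape(map_a.shape, pixel_size)
    cross = shells.sum_per_shell((fa * np.conj(fb)).real)
    pa = shells.sum_per_shell(np.abs(fa) ** 2)
    pb = shells.sum_per_shell(np.abs(fb) ** 2)
    denom = np.sqrt(pa * pb)
    sl = slice(1, None) if skip_dc else slice(None)
    if np.any(denom[sl] == 0):
        raise ValueError("empty shell: a shell has no power in one map")
    fsc = np.divide(cross, denom, out=np.zeros_like(cross),
                    where=denom > 0)
    return FSCCurve(
        frequencies=shells.frequencies[sl],
        fsc=fsc[sl],
        n_voxels=shells.counts[sl],
        exposure=exposure,
    )


def fsc_to_snr(fsc):
    """Convert FSC to spectral SNR: ``2 FSC / (1 - FSC)``.

    Monotone increasing, 0 at 0, 2 at 0.5.  FSC >= 1 maps to infinity
    with a warning (perfect correlation carries no noise information);
    FSC <= -1 is a domain error.  Accepts scalars or arrays.
    """
    arr = np.asarray(fsc, dtype=float)
    if np.any(arr <= -1):
        raise ValueError("FSC must be > -1")
    out = np.empty_like(arr)
    saturated = arr >= 1
    if np.any(saturated):
        warnings.warn("FSC >= 1 encountered; SNR reported as infinity")
    out[saturated] = np.inf
    out[~saturated] = 2.0 * arr[~saturated] / (1.0 - arr[~saturated])
    return float(out) if np.isscalar(fsc) else out


def snr_to_fsc(snr):
    """Inverse of :func:`fsc_to_snr`: ``FSC = SNR / (SNR + 2)``."""
    arr = np.asarray(snr, dtype=float)
    out = np.where(np.isinf(arr), 1.0, arr / (arr + 2.0))
    return float(out) if np.isscalar(snr) else out


def resolution_at_threshold(curve: FSCCurve, threshold: float) -> float:
    """Resolution (A) where the FSC first drops below ``threshold``.

    The crossing frequency is linearly interpolated between the last
    shell above and the first shell below the threshold; conventional
    thresholds are 0.143 (half maps) and 0.5 (map vs model).  If the
    curve never drops below the threshold the Nyquist resolution is
    returned with a warning.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    fsc, freq = curve.fsc, curve.frequencies
    below = np.nonzero(fsc < threshold)[0]
    if len(below) == 0:
        warnings.warn(
            "FSC never drops below the threshold; reporting Nyquist"
        )
        return 1.0 / freq[-1]
    j = below[0]
    if j == 0:
        return 1.0 / freq[0]
    f0, f1 = fsc[j - 1], fsc[j]
    k0, k1 = freq[j - 1], freq[j]
    k_cross = k0 + (f0 - threshold) / (f0 - f1) * (k1 - k0)
    return float(1.0 / k_cross)


# ---------------------------------------------------------------------------
# Exposure series and per-shell regression
# ---------------------------------------------------------------------------


@dataclass
class SNRSeries:
    """SNR matrix indexed by (shell, accumulated exposure).

    ``snr[i, j]`` is the SNR of shell ``frequencies[i]`` measured at
    exposure ``exposures[j]``.  ``n_voxels`` feeds the pure-noise FSC
    floor used to censor unreliable points; ``symmetry_factor`` divides
    the voxel counts when the maps were symmetry averaged (symmetry
    copies are not independent).
    """

    frequencies: np.ndarray
    exposures: np.ndarray
    snr: np.ndarray  # (n_shells, n_exposures)
    n_voxels: Optional[np.ndarray] = None
    symmetry_factor: float = 1.0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.exposures = np.asarray(self.exposures, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        if self.snr.shape != (len(self.frequencies), len(self.exposures)):
            raise ValueError(
                f"snr shape {self.snr.shape} does not match "
                f"{len(self.frequencies)} shells x {len(self.exposures)} "
                "exposures"
            )
        # negative entries (FSC below zero, pure noise) are legal here;
        # they are censored by the noise floor before any regression

    @classmethod
    def from_fsc_curves(cls, curves: Sequence[FSCCurve],
                        symmetry_factor: float = 1.0) -> "SNRSeries":
        if len(curves) < 2:
            raise ValueError("need at least two exposure points")
        curves = sorted(curves, key=lambda c: c.exposure)
        freqs = curves[0].frequencies
        for c in curves:
            if not np.allclose(c.frequencies, freqs):
                raise ValueError("FSC curves are on different shell grids")
            if not np.isfinite(c.exposure):
                raise ValueError("every FSC curve needs an exposure label")
        snr = np.column_stack([fsc_to_snr(c.fsc) for c in curves])
        return cls(
            frequencies=freqs,
            exposures=np.array([c.exposure for c in curves]),
            snr=snr,
            n_voxels=curves[0].n_voxels,
            symmetry_factor=symmetry_factor,
        )

    def noise_floor_snr(self, sigma_mult: float = 3.0) -> np.ndarray:
        """Per-shell SNR floor: sigma_mult x the pure-noise FSC sigma.

        For a shell of n independent voxels the FSC of pure noise has
        standard deviation ~ 1/sqrt(n/2); points whose FSC falls below
        ``sigma_mult`` times that cannot be distinguished from noise.
        """
        if self.n_voxels is None:
            return np.zeros(len(self.frequencies))
        n_indep = np.asarray(self.n_voxels, dtype=float) / self.symmetry_factor
        sigma = 1.0 / np.sqrt(np.maximum(n_indep, 2.0) / 2.0)
        floor_fsc = np.minimum(sigma_mult * sigma, 0.999)
        return 2.0 * floor_fsc / (1.0 - floor_fsc)


@dataclass
class PowerLawFit:
    a: float
    b: float
    c: float
    r_squared: float
    degenerate: bool = False

    def to_params(self, voltage_kv: float = 300.0,
                  optimal_ratio: float = 2.5) -> DoseModelParams:
        return DoseModelParams(a=self.a, b=self.b, c=self.c,
                               voltage_kv=voltage_kv,
                               optimal_ratio=optimal_ratio)


@dataclass
class CriticalExposureFit:
    """Per-shell critical exposures plus the condensed power law."""

    shells: pd.DataFrame  # frequency, ne, slope, intercept, n_points, ...
    power_law: Optional[PowerLawFit] = None
    dropped: List[str] = field(default_factory=list)

    @property
    def frequencies(self) -> np.ndarray:
        kept = self.shells[self.shells["retained"]]
        return kept["frequency_invA"].to_numpy()

    @property
    def ne(self) -> np.ndarray:
        kept = self.shells[self.shells["retained"]]
        return kept["ne"].to_numpy()

    def to_csv(self, path: Union[str, Path]) -> None:
        self.shells.to_csv(path, index=False)


def estimate_critical_exposure(
    series: SNRSeries,
    start_exposure: float = 0.0,
    noise_sigma_mult: float = 3.0,
    min_points: int = 3,
    weighted: bool = False,
    freq_range: Optional[Tuple[float, float]] = None,
) -> CriticalExposureFit:
    """Per-shell Ne from linear regression of ln SNR on exposure.

    For every shell, points with exposure >= ``start_exposure`` (to skip
    the motion-dominated early frames) and SNR above the pure-noise
    floor enter an OLS fit of ln SNR vs N; the slope is -1/Ne.  Shells
    with fewer than ``min_points`` usable points or a non-negative slope
    are dropped with a reason.  ``weighted=True`` weights points by
    SNR-propagated inverse variance instead of plain OLS.
    ``freq_range`` restricts the shells considered (low-frequency shells
    are typically too noisy: their FSC saturates near 1).
    """
    floors = series.noise_floor_snr(noise_sigma_mult)
    rows = []
    dropped: List[str] = []
    for i, k in enumerate(series.frequencies):
        if freq_range is not None and not (freq_range[0] <= k <= freq_range[1]):
            dropped.append(f"shell {k:.5f}: outside frequency range")
            rows.append(_shell_row(k, reason="outside frequency range"))
            continue
        snr_row = series.snr[i]
        usable = (
            (series.exposures >= start_exposure)
            & np.isfinite(snr_row)
            & (snr_row > floors[i])
            & (snr_row > 0)
        )
        n_pts = int(usable.sum())
        if n_pts < min_points:
            dropped.append(f"shell {k:.5f}: only {n_pts} usable points")
            rows.append(_shell_row(k, n_points=n_pts,
                                   reason="too few usable points"))
            continue
        x = series.exposures[usable]
        y = np.log(snr_row[usable])
        if weighted:
            # var(ln SNR) ~ var(SNR)/SNR^2; with shell-count-limited FSC
            # noise, weight ~ SNR^2 is the propagated inverse variance
            slope, intercept, slope_se, r2 = _wls_line(x, y,
                                                      snr_row[usable] ** 2)
        else:
            res = stats.linregress(x, y)
            slope, intercept, r2 = res.slope, res.intercept, res.rvalue ** 2
            slope_se = res.stderr if res.stderr else np.nan
        if slope >= 0:
            dropped.append(f"shell {k:.5f}: non-negative slope {slope:.3g}")
            rows.append(_shell_row(k, slope=slope, intercept=intercept,
                                   n_points=n_pts,
                                   reason="non-negative slope"))
            continue
        ne_val = -1.0 / slope
        # delta method: Ne = -1/slope, so se(Ne) = se(slope) / slope^2
        ne_se = slope_se / slope ** 2 if np.isfinite(slope_se) else np.nan
        rows.append(_shell_row(k, ne=ne_val, ne_stderr=ne_se, slope=slope,
                               intercept=intercept, n_points=n_pts, r2=r2,
                               retained=True))
    shells = pd.DataFrame(rows)
    if not shells["retained"].any():
        raise ValueError(
            "no shell yielded a usable regression; diagnostics: "
            + "; ".join(dropped)
        )
    return CriticalExposureFit(shells=shells, dropped=dropped)


def _shell_row(k, ne=np.nan, ne_stderr=np.nan, slope=np.nan,
               intercept=np.nan, n_points=0, r2=np.nan, retained=False,
               reason=""):
    return {
        "frequency_invA": k, "ne": ne, "ne_stderr": ne_stderr,
        "slope": slope, "intercept": intercept, "n_points": n_points,
        "r_squared": r2, "retained": retained, "reason": reason,
    }


def _wls_line(x, y, w):
    """Weighted least-squares line; returns slope, intercept, se(slope), R^2."""
    X = np.column_stack([x, np.ones_like(x)])
    xtwx = X.T @ (w[:, None] * X)
    beta = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ beta
    dof = len(x) - 2
    sigma2 = float(np.sum(w * resid ** 2)) / dof if dof > 0 else np.nan
    cov = np.linalg.inv(xtwx) * sigma2
    ybar = np.average(y, weights=w)
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 - float(np.sum(w * resid ** 2)) / ss_tot if ss_tot > 0 else np.nan
    return float(beta[0]), float(beta[1]), float(np.sqrt(cov[0, 0])), r2


def fit_power_law(
    frequencies: Sequence[float],
    ne: Sequence[float],
    sigma: Optional[Sequence[float]] = None,
    max_iterations: int = 20000,
) -> PowerLawFit:
    """Nonlinear least squares of Ne(k) = a k^b + c with a>0, b<0, c>0.

    Initialized from the data (offset from the smallest Ne, exponent
    -1.5, prefactor from the highest-frequency point).  ``sigma`` gives
    per-shell standard errors of the Ne estimates; when supplied, shells
    are inverse-variance weighted (the three parameters are strongly
    correlated, so downweighting noisy shells stabilizes all of them).
    R^2 is computed unweighted on the Ne values directly, not on a log
    transform.  A fit collapsing to a constant (a ~ 0) is flagged
    ``degenerate``.
    """
    k = np.asarray(frequencies, dtype=float)
    y = np.asarray(ne, dtype=float)
    if len(k) < 4:
        raise ValueError("power-law fit needs at least 4 shells")
    if np.any(k <= 0) or np.any(y <= 0):
        raise ValueError("frequencies and Ne values must be positive")

    def model(kk, a, b, c):
        return a * kk ** b + c

    sig = None
    if sigma is not None:
        sig = np.asarray(sigma, dtype=float)
        if sig.shape != y.shape:
            raise ValueError("sigma must match the Ne values")
        if np.any(~np.isfinite(sig)) or np.any(sig <= 0):
            raise ValueError("sigma entries must be finite and positive")
    c0 = 0.9 * float(y.min())
    b0 = -1.5
    a0 = max((y[np.argmax(k)] - c0) / k.max() ** b0, 1e-6)
    tiny = 1e-12
    try:
        popt, _ = optimize.curve_fit(
            model, k, y, p0=(a0, b0, c0), sigma=sig,
            bounds=([tiny, -10.0, tiny], [np.inf, -tiny, np.inf]),
            maxfev=max_iterations,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"power-law fit did not converge (start a={a0:.4g}, b={b0}, "
            f"c={c0:.4g}): {err}"
        ) from err
    a, b, c = (float(v) for v in popt)
    resid = y - model(k, a, b, c)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else np.nan
    # degenerate when the power-law term barely varies over the fitted
    # range (b ~ 0 or a ~ 0): the prefactor is then unidentifiable
    variation = a * abs(k.min() ** b - k.max() ** b)
    degenerate = variation < 1e-3 * np.abs(y).max()
    return PowerLawFit(a=a, b=b, c=c, r_squared=r2, degenerate=degenerate)


def estimate_dose_model(
    curves: Sequence[FSCCurve],
    start_exposure: float = 0.0,
    noise_sigma_mult: float = 3.0,
    freq_range: Optional[Tuple[float, float]] = None,
    weighted: bool = False,
    symmetry_factor: float = 1.0,
    law_min_points: int = 6,
) -> CriticalExposureFit:
    """Full pipeline: FSC curves -> SNR series -> per-shell Ne -> power law.

    All shells with at least 3 usable exposure points are reported, but
    only shells whose regression used at least ``law_min_points`` points
    (and has a finite standard error) enter the power-law fit: slope
    standard errors from 3-4 point regressions are unreliable, and
    shells censored down to a handful of points carry a selection bias
    toward flat slopes.  The fit is inverse-variance weighted by the
    propagated per-shell Ne standard errors.
    """
    series = SNRSeries.from_fsc_curves(curves, symmetry_factor)
    fit = estimate_critical_exposure(
        series, start_exposure=start_exposure,
        noise_sigma_mult=noise_sigma_mult, weighted=weighted,
        freq_range=freq_range,
    )
    kept = fit.shells[fit.shells["retained"]]
    good = kept[
        (kept["n_points"] >= law_min_points)
        & np.isfinite(kept["ne_stderr"])
        & (kept["ne_stderr"] > 0)
    ]
    if len(good) >= 4:
        fit.power_law = fit_power_law(
            good["frequency_invA"].to_numpy(),
            good["ne"].to_numpy(),
            sigma=good["ne_stderr"].to_numpy(),
        )
    elif len(fit.frequencies) >= 4:
        fit.power_law = fit_power_law(fit.frequencies, fit.ne)
    return fit
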