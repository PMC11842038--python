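"""DPOAE growth-function fitting and threshold (TH_DP) extraction.

A distortion-product otoacoustic emission growth function relates the level
of the cubic distortion component L_DC (dB SPL) to the primary level L2
(dB SPL, primaries following the Scissors rule ``L1 = 0.4 L2 + 39``).
Because L_DC grows monotonically (or saturates) with L2, each bootstrap
draw resamples the measured points within their confidence intervals,
prunes non-monotone points from the ends of the function only, fits a
monotonicity-constrained cubic, and extrapolates it down to the -25 dB SPL
criterion. The threshold TH_DP is the median crossing level over valid
draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DPGrowthFunction",
    "DPFit",
    "DPThreshold",
    "FitFailure",
    "scissors_l1",
    "lsf_component_level",
    "enforce_monotonicity",
    "fit_adapted_cubic",
    "bootstrap_dp_threshold",
    "winsorize_low_thresholds",
]

P_REF = 20e-6  # Pa RMS, dB SPL reference


class FitFailure(Exception):
    """A bootstrap draw could not produce a monotone growth fit."""


@dataclass
class DPGrowthFunction:
    """Measured L_DC growth points with per-point uncertainty."""

    L2: np.ndarray
    ldc_mean: np.ndarray
    ldc_sd: np.ndarray
    f2: float = 4000.0
    ratio: float = 1.2
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.L2 = np.asarray(self.L2, dtype=float)
        self.ldc_mean = np.asarray(self.ldc_mean, dtype=float)
        self.ldc_sd = np.asarray(self.ldc_sd, dtype=float)
        if not (len(self.L2) == len(self.ldc_mean) == len(self.ldc_sd)):
            raise ValueError("L2, ldc_mean and ldc_sd must have equal length")
        if len(self.L2) < 4:
            raise ValueError("growth function needs at least 4 points")
        if np.any(np.diff(self.L2) <= 0):
            raise ValueError("L2 must be strictly increasing")
        if np.any(self.ldc_sd < 0):
            raise ValueError("per-point SDs must be non-negative")


@dataclass
class DPFit:
    """A fitted cubic ``L_DC(L2)``, highest-order coefficient first."""

    coefficients: np.ndarray
    retained_idx: np.ndarray
    monotone: bool

    def __call__(self, L2):
        return np.polyval(self.coefficients, L2)


@dataclass
class DPThreshold:
    """Bootstrapped DPOAE threshold estimate."""

    th_dp: float
    sd: float
    n_valid: int
    n_boot: int
    criterion: float = -25.0
    seed: int | None = None

    def to_dict(self) -> dict:
        return {"th_dp_db_spl": self.th_dp, "sd_db": self.sd,
                "n_valid": self.n_valid, "n_boot": self.n_boot,
                "criterion_db_spl": self.criterion, "seed": self.seed}


def scissors_l1(L2):
    """Scissors paradigm primary-level rule: ``L1 = 0.4 L2 + 39`` (dB SPL)."""
    return 0.4 * np.asarray(L2, dtype=float) + 39.0


def lsf_component_level(pressure: np.ndarray, fs: float, target_freq: float,
                        bandwidth: float = 2.0) -> float:
    """Narrow-band component level via a least-squares sine fit (dB SPL).

    The recording is split into sliding windows of length ``1 / bandwidth``
    seconds (half-window hop); in each window the amplitude of the best
    least-squares ``a cos + b sin`` fit at ``target_freq`` is computed, and
    the mean amplitude across windows is converted to dB SPL re 20 uPa RMS.
    The finite window acts as a sharp filter of the given bandwidth around
    the target frequency.
    """
    pressure = np.asarray(pressure, dtype=float)
    if target_freq >= fs / 2:
        raise ValueError("target frequency must be below Nyquist")
    win_len = int(round(fs / bandwidth))
    if len(pressure) < win_len:
        raise ValueError("record shorter than one analysis window "
                         f"({win_len} samples for {bandwidth} Hz bandwidth)")
    hop = max(1, win_len // 2)
    amps = []
    t = np.arange(win_len) / fs
    design = np.column_stack([np.cos(2 * np.pi * target_freq * t),
                              np.sin(2 * np.pi * target_freq * t)])
    pinv = np.linalg.pinv(design)
    for start in range(0, len(pressure) - win_len + 1, hop):
        a, b = pinv @ pressure[start:start + win_len]
        amps.append(np.hypot(a, b))
    amp = float(np.mean(amps))
    rms = amp / np.sqrt(2)
    if rms <= 0:
        return -np.inf
    return float(20 * np.log10(rms / P_REF))


def enforce_monotonicity(L2: np.ndarray, ldc: np.ndarray) -> np.ndarray:
    """Indices of a non-decreasing subsequence obtained by end-point pruning.

    Adjacent decreasing pairs are resolved by removing the outermost point
    of whichever end participates in a violation; interior points are never
    removed. Raises :class:`FitFailure` if an interior dip remains or fewer
    than 3 points survive.
    """
    L2 = np.asarray(L2, dtype=float)
    ldc = np.asarray(ldc, dtype=float)
    idx = list(range(len(ldc)))
    while True:
        vals = ldc[idx]
        dec = np.flatnonzero(np.diff(vals) < 0)
        if len(dec) == 0:
            break
        if len(idx) <= 3:
            raise FitFailure("fewer than 3 monotone points remain")
        if dec[0] == 0:
            idx.pop(0)
        elif dec[-1] == len(idx) - 2:
            idx.pop()
        else:
            raise FitFailure("interior non-monotonicity cannot be pruned "
                             "from the ends")
    if len(idx) < 3:
        raise FitFailure("fewer than 3 monotone points remain")
    return np.asarray(idx)


def _is_nondecreasing(coeffs: np.ndarray, lo: float, hi: float,
                      n_grid: int = 201) -> bool:
    deriv = np.polyder(coeffs)
    grid = np.linspace(lo, hi, n_grid)
    return bool(np.all(np.polyval(deriv, grid) >= -1e-9))


def fit_adapted_cubic(L2: np.ndarray, ldc: np.ndarray) -> DPFit:
    """Least-squares cubic through (L2, L_DC), rejected if non-monotone.

    End points violating monotonicity are pruned first; the cubic (degree
    limited by the number of retained points) must be non-decreasing over
    the retained L2 range, otherwise :class:`FitFailure` is raised.
    """
    L2 = np.asarray(L2, dtype=float)
    ldc = np.asarray(ldc, dtype=float)
    if len(L2) < 3:
        raise FitFailure("need at least 3 points")
    keep = enforce_monotonicity(L2, ldc)
    x, y = L2[keep], ldc[keep]
    deg = min(3, len(x) - 1)
    coeffs = np.polyfit(x, y, deg)
    coeffs = np.r_[np.zeros(3 - deg), coeffs]  # always cubic-shaped
    monotone = _is_nondecreasing(coeffs, x[0], x[-1])
    if not monotone:
        raise FitFailure("fitted cubic is not non-decreasing over the "
                         "retained range")
    return DPFit(coefficients=coeffs, retained_idx=keep, monotone=True)


def _threshold_from_fit(fit: DPFit, L2: np.ndarray, criterion: float,
                        max_extrapolation: float = 30.0) -> float:
    """L2 where the monotone continuation of the fit reaches the criterion.

    The fitted cubic is extrapolated downward from the retained range only
    as far as it remains non-decreasing (and never more than
    ``max_extrapolation`` dB below the lowest retained level); within that
    interval the criterion crossing is unique. A cubic tail that turns over
    before reaching the criterion is a fit failure, which keeps spurious
    far-left roots of the cubic from masquerading as thresholds.
    """
    x = L2[fit.retained_idx]
    lo, hi = x[0] - max_extrapolation, x[-1]
    deriv_roots = np.roots(np.polyder(fit.coefficients))
    turning = deriv_roots[(np.abs(deriv_roots.imag) < 1e-8)
                          & (deriv_roots.real < x[0])].real
    if len(turning):
        lo = max(lo, float(turning.max()))
    poly = fit.coefficients.copy()
    poly[-1] -= criterion
    roots = np.roots(poly)
    real = roots[np.abs(roots.imag) < 1e-8].real
    in_range = real[(real >= lo - 1e-9) & (real <= hi + 1e-9)]
    if len(in_range) == 0:
        raise FitFailure("fitted curve never reaches the criterion level "
                         "within its monotone extrapolation range")
    return float(in_range.max() if len(in_range) > 1 else in_range[0])


def bootstrap_dp_threshold(growth: DPGrowthFunction, n_boot: int = 500,
                           criterion: float = -25.0, seed: int | None = None,
                           ci_truncation: float = 1.96) -> DPThreshold:
    """Bootstrapped TH_DP: median criterion-crossing level over valid draws.

    Each draw resamples every L_DC point from a Gaussian with its measured
    mean and SD, truncated at ``+/- ci_truncation`` SD (draws constrained to
    the confidence interval); non-monotone draws are repaired by end-point
    pruning or rejected; the constrained cubic is extrapolated to the
    criterion level. When all SDs are zero the draw is deterministic and
    the bootstrap SD is zero.
    """
    rng = np.random.default_rng(seed)
    thresholds = []
    sds = growth.ldc_sd
    for _ in range(n_boot):
        if np.all(sds == 0):
            draw = growth.ldc_mean.copy()
        else:
            z = stats.truncnorm.rvs(-ci_truncation, ci_truncation,
                                    size=len(sds), random_state=rng)
            draw = growth.ldc_mean + z * sds
        try:
            fit = fit_adapted_cubic(growth.L2, draw)
            thresholds.append(_threshold_from_fit(fit, growth.L2, criterion))
        except FitFailure:
            continue
    n_valid = len(thresholds)
    if n_valid == 0:
        return DPThreshold(th_dp=np.nan, sd=np.nan, n_valid=0, n_boot=n_boot,
                           criterion=criterion, seed=seed)
    arr = np.asarray(thresholds)
    sd = float(arr.std(ddof=1)) if n_valid > 1 else 0.0
    return DPThreshold(th_dp=float(np.median(arr)), sd=sd, n_valid=n_valid,
                       n_boot=n_boot, criterion=criterion, seed=seed)


def winsorize_low_thresholds(values) -> tuple[np.ndarray, int]:
    """Replace low-outlier thresholds by the lower Tukey fence.

    Values below ``Q1 - 1.5 IQR`` (quartiles via linear-interpolation
    percentiles) are set to the fence value; returns the adjusted array and
    the number of replacements.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValueError("need at least 4 values for a quartile fence")
    q1, q3 = np.percentile(values, [25, 75])
    fence = q1 - 1.5 * (q3 - q1)
    out = values.copy()
    mask = out < fence
    out[mask] = fence
    return out, int(mask.sum())
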