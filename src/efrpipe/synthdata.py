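"""Synthetic inputs with known ground truth for the full pipeline.

This module generates every data modality the pipeline consumes:

* EEG-like epoch sets — a multi-harmonic phase-locked response at ``fm`` and
  its first four harmonics, buried in white + 1/f^alpha Gaussian noise with
  per-epoch gain jitter and alternating stimulus polarity;
* DPOAE growth functions — a monotone distortion-component level curve with
  additive Gaussian measurement noise and per-point SDs;
* adaptive speech-reception-threshold tracks — a psychometric listener
  scored word-by-word under a 1-up/1-down rule with decaying step size;
* multivariate cohorts — three groups (yNH / oNH / oHI) with configurable
  means, SDs and a Spearman-targeted correlation structure realised through
  a Gaussian copula.

All generators are deterministic given a seed and stamp their provenance
(seed, parameters) into the objects they return.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.special import expit

__all__ = [
    "EFRGroundTruth",
    "NoiseModel",
    "EpochSet",
    "ListenerModel",
    "GroupParams",
    "CohortParams",
    "generate_epochs",
    "generate_dp_growth",
    "simulate_word_scores",
    "run_adaptive_track",
    "generate_cohort",
    "fir_bandsplit",
    "spearman_to_pearson",
    "COHORT_VARIABLES",
    "default_cohort_params",
]


@dataclass(frozen=True)
class EFRGroundTruth:
    """True harmonic content of a simulated envelope-following response.

    ``harmonic_amplitudes[k-1]`` is the amplitude in uV of the cosine
    component at ``k * fm`` for k = 1..5.
    """

    fm: float = 120.0
    harmonic_amplitudes: tuple = (0.1, 0.05, 0.02, 0.01, 0.005)
    harmonic_phases: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.harmonic_amplitudes) != 5 or len(self.harmonic_phases) != 5:
            raise ValueError("exactly 5 harmonics (k*fm, k=1..5) are required")
        if any(a < 0 for a in self.harmonic_amplitudes):
            raise ValueError("harmonic amplitudes must be non-negative")


@dataclass(frozen=True)
class NoiseModel:
    """Additive EEG-like noise: white + 1/f^alpha components (uV RMS) plus a
    per-epoch multiplicative gain jitter on the phase-locked signal."""

    white_sd: float = 1.0
    pink_sd: float = 0.5
    pink_exponent: float = 1.0
    epoch_gain_jitter: float = 0.05

    def __post_init__(self) -> None:
        if min(self.white_sd, self.pink_sd, self.epoch_gain_jitter) < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.pink_exponent < 0:
            raise ValueError("pink exponent must be non-negative")


@dataclass
class EpochSet:
    """Epochs-by-samples matrix in uV with per-epoch polarity labels."""

    data: np.ndarray
    sample_rate: float
    polarity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.polarity = np.asarray(self.polarity)
        if len(self.polarity) != self.data.shape[0]:
            raise ValueError("one polarity label per epoch required")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def epoch_duration(self) -> float:
        return self.data.shape[1] / self.sample_rate


def _pink_noise(shape: tuple, alpha: float, rng: np.random.Generator
                ) -> np.ndarray:
    """Unit-RMS Gaussian noise with a 1/f^alpha amplitude spectrum."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    shaping = np.ones_like(f)
    shaping[1:] = f[1:] ** (-alpha / 2)
    shaping[0] = 0.0
    out = np.fft.irfft(spec * shaping, n=n, axis=-1)
    rms = out.std(axis=-1, keepdims=True)
    rms[rms == 0] = 1.0
    return out / rms


def generate_epochs(truth: EFRGroundTruth, noise: NoiseModel, n_epochs: int,
                    fs: float = 16384.0, epoch_dur: float = 0.5,
                    seed: int | None = None) -> EpochSet:
    """Simulate an epoched EEG recording containing a known EFR.

    Each epoch is ``g_e * sum_k A_k cos(2 pi k fm t + theta_k)`` plus
    independent white and 1/f^alpha noise, where ``g_e`` is a per-epoch gain
    ``1 + N(0, jitter)``. Polarity labels alternate (the envelope-locked
    response does not invert with stimulus polarity). The defaults
    (fs = 16384 Hz, 0.5 s epochs -> 8192 samples, 2 Hz bins) put ``k * fm``
    for fm = 120 Hz on exact bins.
    """
    n_samp = int(round(epoch_dur * fs))
    ks = np.arange(1, 6)
    if truth.fm * 5 >= fs / 2:
        raise ValueError("5th harmonic exceeds Nyquist frequency")
    rng = np.random.default_rng(seed)
    t = np.arange(n_samp) / fs
    amps = np.asarray(truth.harmonic_amplitudes)
    phases = np.asarray(truth.harmonic_phases)
    sig = (amps[:, None] * np.cos(2 * np.pi * np.outer(ks * truth.fm, t)
                                  + phases[:, None])).sum(axis=0)
    gains = 1.0 + noise.epoch_gain_jitter * rng.standard_normal(n_epochs)
    data = gains[:, None] * sig
    if noise.white_sd > 0:
        data = data + noise.white_sd * rng.standard_normal((n_epochs, n_samp))
    if noise.pink_sd > 0:
        data = data + noise.pink_sd * _pink_noise(
            (n_epochs, n_samp), noise.pink_exponent, rng)
    polarity = np.where(np.arange(n_epochs) % 2 == 0, 1, -1)
    meta = {"seed": seed, "fm": truth.fm, "fs": fs,
            "harmonic_amplitudes": list(truth.harmonic_amplitudes),
            "noise": {"white_sd": noise.white_sd, "pink_sd": noise.pink_sd,
                      "pink_exponent": noise.pink_exponent,
                      "epoch_gain_jitter": noise.epoch_gain_jitter}}
    return EpochSet(data, fs, polarity, meta=meta)


def generate_dp_growth(true_curve, L2_levels, noise_sd: float = 1.0,
                       point_sd: float | None = None,
                       seed: int | None = None):
    """Synthetic DPOAE growth function with known underlying curve.

    ``true_curve`` maps L2 (dB SPL) to the distortion-component level L_DC
    (dB SPL); measured means are ``true_curve(L2) + N(0, noise_sd)`` and the
    recorded per-point SD is ``point_sd`` (defaults to ``noise_sd``).
    Returns a :class:`~efrpipe.dpoae_threshold.DPGrowthFunction`.
    """
    from .dpoae_threshold import DPGrowthFunction

    L2 = np.asarray(L2_levels, dtype=float)
    if len(L2) < 4:
        raise ValueError("at least 4 primary levels are required for fitting")
    if np.any(np.diff(L2) <= 0):
        raise ValueError("L2 levels must be strictly increasing")
    rng = np.random.default_rng(seed)
    mean = np.asarray([true_curve(v) for v in L2], dtype=float)
    if noise_sd > 0:
        mean = mean + noise_sd * rng.standard_normal(len(L2))
    sd = np.full(len(L2), noise_sd if point_sd is None else point_sd)
    return DPGrowthFunction(L2=L2, ldc_mean=mean, ldc_sd=sd,
                            meta={"seed": seed, "noise_sd": noise_sd})


@dataclass(frozen=True)
class ListenerModel:
    """Psychometric listener for matrix-sentence word scoring.

    Probability correct at presentation level L:
    ``p = guess + (1 - guess) * logistic(4 * slope * (L - srt50))``
    so the psychometric slope at the midpoint is ``slope`` (proportion per
    dB) when ``guess = 0``, and ``p(srt50) = 0.5`` for ``guess = 0``.
    """

    srt50: float = 45.0
    slope: float = 0.15
    guess_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not 0 <= self.guess_rate < 0.5:
            raise ValueError("guess rate must be in [0, 0.5)")

    def p_correct(self, level: float) -> float:
        core = expit(4 * self.slope * (np.asarray(level, dtype=float)
                                       - self.srt50))
        return self.guess_rate + (1 - self.guess_rate) * core


def simulate_word_scores(listener: ListenerModel, level: float,
                         n_words: int = 5, seed=None) -> int:
    """Number of correctly repeated words in one sentence at ``level`` dB."""
    if n_words < 1:
        raise ValueError("need at least one word")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return int(rng.binomial(n_words, listener.p_correct(level)))


def run_adaptive_track(listener: ListenerModel, start_level: float = 70.0,
                       n_sentences: int = 20, n_words: int = 5,
                       initial_step: float = 5.0, step_decay: float = 0.8,
                       n_trailing: int = 10, seed=None,
                       return_track: bool = False):
    """1-up/1-down adaptive SRT track with word scoring and decaying steps.

    After each sentence the level moves by ``step * (p_hat - 0.5) / 0.5``
    downwards, where ``p_hat`` is the proportion of words repeated
    correctly; the step size decays by ``step_decay`` at every reversal of
    track direction. The SRT estimate is the mean presentation level of the
    last ``n_trailing`` sentences.
    """
    if n_sentences < 5:
        raise ValueError("need at least 5 sentences")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    level = float(start_level)
    step = float(initial_step)
    levels = np.empty(n_sentences)
    last_dir = 0
    for i in range(n_sentences):
        levels[i] = level
        n_corr = simulate_word_scores(listener, level, n_words, rng)
        p_hat = n_corr / n_words
        delta = -step * (p_hat - 0.5) / 0.5
        direction = int(np.sign(delta))
        if direction != 0 and last_dir != 0 and direction != last_dir:
            step *= step_decay
        if direction != 0:
            last_dir = direction
        level += delta
    srt = float(levels[-n_trailing:].mean())
    if return_track:
        return srt, levels
    return srt


# ---------------------------------------------------------------------------
# cohort generation

COHORT_VARIABLES = [
    "age", "th_a_4k", "th_dp", "efr_sam", "efr_ram",
    "srt_siq_bb", "srt_siq_lp", "srt_siq_hp",
    "srt_sin_bb", "srt_sin_lp", "srt_sin_hp",
]


@dataclass(frozen=True)
class GroupParams:
    """Per-group sample size and marginal mean/SD for each cohort variable."""

    n: int
    means: dict
    sds: dict

    def __post_init__(self) -> None:
        for v in COHORT_VARIABLES:
            if v not in self.means or v not in self.sds:
                raise ValueError(f"missing mean/SD for variable {v!r}")
            if self.sds[v] < 0:
                raise ValueError(f"negative SD for variable {v!r}")


@dataclass(frozen=True)
class CohortParams:
    """Cohort recipe: per-group marginals plus a shared Spearman correlation
    target applied within each group via a Gaussian copula."""

    groups: dict
    spearman_targets: dict = field(default_factory=dict)

    def correlation_matrix(self) -> np.ndarray:
        """Latent (Pearson) correlation matrix realising the Spearman targets."""
        p = len(COHORT_VARIABLES)
        corr = np.eye(p)
        idx = {v: i for i, v in enumerate(COHORT_VARIABLES)}
        for (a, b), rho_s in self.spearman_targets.items():
            r = spearman_to_pearson(rho_s)
            corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
        eig = np.linalg.eigvalsh(corr)
        if eig.min() < -1e-10:
            raise ValueError("Spearman targets yield a non-PSD correlation "
                             f"matrix (min eigenvalue {eig.min():.3g})")
        return corr


def spearman_to_pearson(rho_s: float) -> float:
    """Latent Gaussian Pearson correlation giving Spearman ``rho_s``:
    ``r = 2 sin(pi rho_s / 6)`` for bivariate normal marginals."""
    return float(2 * np.sin(np.pi * rho_s / 6))


def default_cohort_params() -> CohortParams:
    """Three-group cohort defaults.

    EFR, audiometric and age marginals follow the reported group statistics
    (yNH RAM 0.239 +/- 0.076 uV, SAM 0.065 +/- 0.022 uV; oNH RAM
    0.155 +/- 0.062, oHI RAM 0.095 +/- 0.028; 4-kHz thresholds
    3.3 +/- 3.5, 11.3 +/- 3.5 and 36 +/- 8.4 dB HL). SRT means/SDs are not
    tabulated numerically anywhere and are configuration: plausible matrix
    -sentence values with quiet SRTs in dB SPL and noise SRTs in dB SNR.
    The within-group Spearman target couples the RAM EFR to the high-pass
    speech-in-noise SRT at -0.73 and the two hearing-sensitivity metrics at
    0.84.
    """
    def g(n, age, age_sd, th_a, th_a_sd, th_dp, th_dp_sd, sam, sam_sd,
          ram, ram_sd, siq, sin):
        means = {"age": age, "th_a_4k": th_a, "th_dp": th_dp,
                 "efr_sam": sam, "efr_ram": ram,
                 "srt_siq_bb": siq[0], "srt_siq_lp": siq[1],
                 "srt_siq_hp": siq[2], "srt_sin_bb": sin[0],
                 "srt_sin_lp": sin[1], "srt_sin_hp": sin[2]}
        sds = {"age": age_sd, "th_a_4k": th_a_sd, "th_dp": th_dp_sd,
               "efr_sam": sam_sd, "efr_ram": ram_sd,
               "srt_siq_bb": 2.0, "srt_siq_lp": 2.5, "srt_siq_hp": 3.0,
               "srt_sin_bb": 1.0, "srt_sin_lp": 1.5, "srt_sin_hp": 2.0}
        return GroupParams(n=n, means=means, sds=sds)

    groups = {
        "yNH": g(15, 24.5, 2.2, 3.3, 3.5, 2.0, 8.0, 0.065, 0.022,
                 0.239, 0.076, (21.0, 25.0, 33.0), (-7.1, -5.0, -2.0)),
        "oNH": g(15, 64.2, 1.9, 11.3, 3.5, 15.0, 9.0, 0.063, 0.030,
                 0.155, 0.062, (25.0, 29.0, 40.0), (-5.5, -3.5, 1.5)),
        "oHI": g(14, 65.2, 1.7, 36.0, 8.4, 36.0, 10.0, 0.059, 0.031,
                 0.095, 0.028, (35.0, 38.0, 48.0), (-4.8, -3.0, 2.0)),
    }
    spearman = {
        ("efr_ram", "srt_sin_hp"): -0.73,
        ("efr_ram", "srt_siq_hp"): -0.55,
        ("efr_ram", "th_a_4k"): -0.25,
        ("efr_ram", "th_dp"): -0.25,
        ("efr_ram", "efr_sam"): 0.5,
        ("efr_sam", "srt_sin_hp"): -0.35,
        ("efr_sam", "srt_siq_hp"): -0.30,
        ("efr_sam", "th_a_4k"): -0.15,
        ("efr_sam", "th_dp"): -0.15,
        ("th_a_4k", "th_dp"): 0.84,
        ("th_a_4k", "srt_siq_hp"): 0.45,
        ("th_a_4k", "srt_sin_hp"): 0.30,
        ("th_dp", "srt_siq_hp"): 0.40,
        ("th_dp", "srt_sin_hp"): 0.30,
        ("srt_sin_hp", "srt_siq_hp"): 0.65,
    }
    return CohortParams(groups=groups, spearman_targets=spearman)


def generate_cohort(params: CohortParams | None = None,
                    seed: int | None = None,
                    n_per_group: int | None = None) -> pd.DataFrame:
    """Draw a synthetic cohort table.

    Within each group, variables are drawn from a multivariate Gaussian
    whose latent correlation realises the Spearman targets (Gaussian
    marginals preserve ranks, so the copula step is the latent correlation
    adjustment ``r = 2 sin(pi rho_s / 6)``), then scaled to the group
    mean/SD. ``n_per_group`` overrides every group's sample size (used for
    convergence checks).
    """
    params = default_cohort_params() if params is None else params
    rng = np.random.default_rng(seed)
    corr = params.correlation_matrix()
    # guard against exactly-singular targets
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(corr)))
    rows = []
    for gname, gp in params.groups.items():
        n = n_per_group if n_per_group is not None else gp.n
        z = rng.standard_normal((n, len(COHORT_VARIABLES))) @ chol.T
        df = pd.DataFrame(z, columns=COHORT_VARIABLES)
        for v in COHORT_VARIABLES:
            df[v] = gp.means[v] + gp.sds[v] * df[v]
        df.insert(0, "group", gname)
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    out.insert(0, "id", [f"S{i:05d}" for i in range(len(out))])
    out.attrs["seed"] = seed
    return out


def fir_bandsplit(x: np.ndarray, fs: float, mode: str, cutoff: float,
                  order: int = 1024) -> np.ndarray:
    """Linear-phase FIR low-/high-pass used to band-limit speech material.

    ``order`` is the filter order (taps = order + 1); the default mirrors a
    1024th-order filter. The delay is compensated so the output is aligned
    with the input.
    """
    if cutoff >= fs / 2:
        raise ValueError("cutoff must be below Nyquist")
    if order < 2:
        raise ValueError("order must be >= 2")
    if mode not in ("LP", "HP"):
        raise ValueError("mode must be 'LP' or 'HP'")
    ntaps = order + 1
    if mode == "HP" and ntaps % 2 == 0:
        ntaps += 1  # high-pass needs odd tap count (type I)
    taps = signal.firwin(ntaps, cutoff, fs=fs, pass_zero=(mode == "LP"),
                         window=("kaiser", 9.0))
    padded = np.r_[np.asarray(x, dtype=float), np.zeros(ntaps - 1)]
    y = signal.lfilter(taps, 1.0, padded)
    delay = (ntaps - 1) // 2
    return y[delay:delay + len(x)]
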