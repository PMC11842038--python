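"""Synthesis of SAM and RAM tones for envelope-following-response recordings.

Two amplitude-modulated pure tones share a carrier and modulation frequency
and differ only in envelope shape:

* SAM — sinusoidal modulator, ``x(t) = [1 + md sin(2 pi fm t + phi)] sin(2 pi f t)``
* RAM — rectangular modulator with duty cycle ``tau``,
  ``y(t) = [2 + 2 md m(t)] sin(2 pi f t)`` with ``m(t)`` a +/-1 square wave
  that is high during a fraction ``tau`` of each modulation period.

The rectangular envelope sharpens the onset of each modulation cycle, which
increases the synchrony of the evoked neural response; the RAM tone is
presented at the same waveform peak-to-peak amplitude as the SAM tone, which
lowers its RMS level by about 1.8 dB.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal.windows import tukey

__all__ = [
    "StimulusSpec",
    "Stimulus",
    "synthesize",
    "synthesize_sam",
    "synthesize_ram",
    "apply_taper",
    "match_peak_to_peak",
    "make_stimulus_train",
    "modulation_depth_db",
    "write_wav",
    "read_wav",
]

#: Reference sound pressure (Pa RMS) for dB SPL.
P_REF = 20e-6


@dataclass(frozen=True)
class StimulusSpec:
    """Parametric description of a SAM or RAM tone.

    Parameters
    ----------
    f : float
        Carrier frequency in Hz.
    fm : float
        Modulation frequency in Hz.
    md : float
        Modulation depth, dimensionless in [0, 1].
    phi : float
        Modulator start phase in radians (default ``3 pi / 2``).
    duty : float
        Duty cycle of the rectangular modulator, fraction in (0, 1].
        Ignored for SAM.
    duration : float
        Stimulus duration in seconds.
    fs : float
        Sampling rate in Hz.
    level_db_spl : float
        Presentation level in dB SPL re 20 uPa RMS.
    taper_fraction : float
        Fraction of samples covered by the tapered-cosine window ramps.
    kind : {"SAM", "RAM"}
    """

    f: float = 4000.0
    fm: float = 120.0
    md: float = 0.95
    phi: float = 3 * np.pi / 2
    duty: float = 0.25
    duration: float = 0.4
    fs: float = 48000.0
    level_db_spl: float = 70.0
    taper_fraction: float = 0.025
    kind: str = "SAM"

    def __post_init__(self) -> None:
        if not 0.0 <= self.md <= 1.0:
            raise ValueError(f"modulation depth must be in [0, 1], got {self.md}")
        if not 0.0 < self.duty <= 1.0:
            raise ValueError(f"duty cycle must be in (0, 1], got {self.duty}")
        if not self.fm < self.f:
            raise ValueError(f"need fm < f, got fm={self.fm}, f={self.f}")
        if not self.f < self.fs / 2:
            raise ValueError(f"carrier {self.f} Hz violates Nyquist at fs={self.fs}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0.0 <= self.taper_fraction <= 1.0:
            raise ValueError("taper_fraction must be in [0, 1]")
        if self.kind not in ("SAM", "RAM"):
            raise ValueError(f"kind must be 'SAM' or 'RAM', got {self.kind!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


@dataclass
class Stimulus:
    """A rendered stimulus waveform.

    ``samples`` are dimensionless (pre-calibration); ``scale`` is the linear
    factor mapping one unit of dimensionless amplitude to pascals, set so the
    waveform RMS corresponds to ``spec.level_db_spl``.
    """

    samples: np.ndarray
    sample_rate: float
    spec: StimulusSpec
    scale: float = field(default=np.nan)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if np.isnan(self.scale):
            self.scale = _calibration_scale(self.samples, self.spec.level_db_spl)

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    @property
    def peak_to_peak(self) -> float:
        return float(self.samples.max() - self.samples.min())


def _calibration_scale(samples: np.ndarray, level_db_spl: float) -> float:
    rms = np.sqrt(np.mean(samples**2))
    if rms == 0:
        return np.nan
    target_pa = P_REF * 10 ** (level_db_spl / 20)
    return float(target_pa / rms)


def modulation_depth_db(md: float) -> float:
    """Modulation depth re. 100% in dB: ``20 log10(md)`` (0.95 -> -0.45 dB)."""
    if md <= 0:
        raise ValueError("modulation depth must be positive for dB conversion")
    return 20 * np.log10(md)


def _time_grid(spec: StimulusSpec) -> np.ndarray:
    return np.arange(spec.n_samples) / spec.fs


def synthesize_sam(spec: StimulusSpec) -> Stimulus:
    """Render a sinusoidally amplitude-modulated tone (before windowing)."""
    if spec.kind != "SAM":
        raise ValueError(f"expected a SAM spec, got kind={spec.kind!r}")
    t = _time_grid(spec)
    env = 1.0 + spec.md * np.sin(2 * np.pi * spec.fm * t + spec.phi)
    return Stimulus(env * np.sin(2 * np.pi * spec.f * t), spec.fs, spec)


def square_modulator(t: np.ndarray, fm: float, phi: float, duty: float) -> np.ndarray:
    """Ideal +/-1 rectangular modulator evaluated pointwise at sample times.

    High (+1) during the first ``duty`` fraction of each modulation period,
    with the cycle origin shifted by ``phi`` radians (phi/2pi periods), as a
    sum of unit-step on/off transitions per period.
    """
    phase_cycles = np.mod(t * fm + phi / (2 * np.pi), 1.0)
    return np.where(phase_cycles < duty, 1.0, -1.0)


def synthesize_ram(spec: StimulusSpec) -> Stimulus:
    """Render a rectangularly amplitude-modulated tone (before windowing).

    The envelope alternates between ``2 + 2 md`` (for a fraction ``duty`` of
    each modulation period) and ``2 - 2 md``.
    """
    if spec.kind != "RAM":
        raise ValueError(f"expected a RAM spec, got kind={spec.kind!r}")
    t = _time_grid(spec)
    m = square_modulator(t, spec.fm, spec.phi, spec.duty)
    env = 2.0 + 2.0 * spec.md * m
    return Stimulus(env * np.sin(2 * np.pi * spec.f * t), spec.fs, spec)


def synthesize(spec: StimulusSpec, windowed: bool = False) -> Stimulus:
    """Render a stimulus from its spec; optionally apply its taper window."""
    stim = synthesize_sam(spec) if spec.kind == "SAM" else synthesize_ram(spec)
    if windowed and spec.taper_fraction > 0:
        stim = apply_taper(stim, spec.taper_fraction)
    return stim


def apply_taper(stim: Stimulus, fraction: float) -> Stimulus:
    """Apply a tapered-cosine (Tukey) window covering ``fraction`` of samples.

    ``fraction=0`` is the identity; ``fraction=1`` is a full Hann window.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("taper fraction must be in [0, 1]")
    win = tukey(len(stim.samples), alpha=fraction)
    out = Stimulus(stim.samples * win, stim.sample_rate, stim.spec, scale=stim.scale)
    return out


def match_peak_to_peak(reference: Stimulus, target: Stimulus) -> tuple[Stimulus, float]:
    """Scale ``target`` so its waveform peak-to-peak equals the reference's.

    Returns the scaled stimulus and the level offset
    ``20 log10(RMS_scaled_target / RMS_reference)`` in dB: the presentation
    level of the matched target is ``reference level + offset``. Matching the
    RAM tone (md=0.95, duty=0.25) to a 70 dB SPL SAM tone gives 68 dB SPL
    after integer rounding.
    """
    pp_ref = reference.peak_to_peak
    pp_tgt = target.peak_to_peak
    if pp_ref == 0 or pp_tgt == 0:
        raise ValueError("cannot peak-to-peak match a silent stimulus")
    k = pp_ref / pp_tgt
    scaled_samples = target.samples * k
    level_offset = 20 * np.log10(np.sqrt(np.mean(scaled_samples**2)) / reference.rms)
    new_level = reference.spec.level_db_spl + level_offset
    new_spec = replace(target.spec, level_db_spl=new_level)
    scaled = Stimulus(scaled_samples, target.sample_rate, new_spec)
    return scaled, float(level_offset)


def make_stimulus_train(
    stim: Stimulus,
    n_reps: int,
    isi_mean: float = 0.1,
    isi_halfwidth: float = 0.01,
    seed: int | None = None,
    balanced_polarity: bool = True,
) -> dict:
    """Event schedule for repeated presentation with jittered silent gaps.

    Inter-stimulus silences are drawn uniformly from
    ``[isi_mean - isi_halfwidth, isi_mean + isi_halfwidth]`` and polarities
    alternate so that exactly half the repetitions are inverted.

    Returns a dict with ``onsets`` (s), ``polarity`` (+1/-1 per repetition),
    ``seed`` and the generating parameters.
    """
    if balanced_polarity and n_reps % 2:
        raise ValueError("n_reps must be even for balanced polarity")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    isis = rng.uniform(isi_mean - isi_halfwidth, isi_mean + isi_halfwidth, n_reps)
    dur = len(stim.samples) / stim.sample_rate
    onsets = np.concatenate([[0.0], np.cumsum(dur + isis)[:-1]])
    if balanced_polarity:
        polarity = np.where(np.arange(n_reps) % 2 == 0, 1, -1)
    else:
        polarity = np.ones(n_reps, dtype=int)
    return {
        "onsets": onsets,
        "polarity": polarity,
        "seed": seed,
        "isi_mean": isi_mean,
        "isi_halfwidth": isi_halfwidth,
        "n_reps": n_reps,
    }


def write_wav(path: str | Path, stim: Stimulus) -> None:
    """Write a stimulus as float32 WAV with a JSON sidecar of its spec."""
    path = Path(path)
    wavfile.write(path, int(stim.sample_rate), stim.samples.astype(np.float32))
    sidecar = {"spec": asdict(stim.spec), "scale_pa_per_unit": stim.scale}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_wav(path: str | Path) -> Stimulus:
    """Read a stimulus written by :func:`write_wav` (requires the sidecar)."""
    path = Path(path)
    fs, samples = wavfile.read(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec = StimulusSpec(**meta["spec"])
    return Stimulus(samples.astype(float), float(fs), spec,
                    scale=meta["scale_pa_per_unit"])
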