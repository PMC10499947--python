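"""Synthetic single-lead ECG generator.

Produces labeled voltage traces with the statistical structure an
AF-vs-non-AF detector has to learn:

* normal sinus rhythm (NSR): near-regular RR intervals, visible P waves;
* atrial fibrillation (AF): highly irregular RR intervals, absent P waves,
  and a low-amplitude fibrillatory oscillation of the baseline;
* the three classic contaminants of ambulatory ECG — baseline wander,
  power-frequency (mains) interference and broadband myoelectric noise;
* class imbalance of roughly 1:5 AF:non-AF, as seen in public
  single-lead screening datasets.

Every output is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy import stats

__all__ = [
    "RhythmClass",
    "BeatMorphology",
    "ECGSynthConfig",
    "ECGRecord",
    "sample_rr_intervals",
    "render_waveform",
    "add_noise",
    "generate_dataset",
]


class RhythmClass(str, Enum):
    """Rhythm label.

    Binary mode uses {NSR, AF}; four-class scoring mode adds OTHER and
    NOISE (the N/A/O/~ categories of challenge-style scoring).  AF is the
    positive class (1); everything else is negative (0).
    """

    NSR = "NSR"
    AF = "AF"
    OTHER = "OTHER"
    NOISE = "NOISE"

    @property
    def binary_label(self) -> int:
        return 1 if self is RhythmClass.AF else 0

    @property
    def short(self) -> str:
        return {"NSR": "N", "AF": "A", "OTHER": "O", "NOISE": "~"}[self.value]


# (amplitude mV, offset s relative to the R peak, Gaussian width s)
_DEFAULT_BUMPS: dict[str, tuple[float, float, float]] = {
    "P": (0.15, -0.13, 0.022),
    "Q": (-0.10, -0.030, 0.010),
    "R": (1.00, 0.0, 0.012),
    "S": (-0.18, 0.030, 0.011),
    "T": (0.30, 0.26, 0.055),
}


@dataclass(frozen=True)
class BeatMorphology:
    """Amplitudes/offsets/widths (mV, s) of the five Gaussian bumps P,Q,R,S,T."""

    bumps: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_BUMPS)
    )

    def without_p(self) -> "BeatMorphology":
        bumps = dict(self.bumps)
        amp, off, width = bumps["P"]
        bumps["P"] = (0.0, off, width)
        return BeatMorphology(bumps)


@dataclass(frozen=True)
class ECGSynthConfig:
    """Generator parameters; defaults are the study conditions.

    RR statistics: NSR beats come from a truncated normal
    (mean 0.8 s, sd 0.03 s, floor 0.3 s); AF beats are i.i.d. gamma with
    mean 0.7 s and coefficient of variation 0.25, i.e. strictly more
    irregular than NSR.
    """

    fs: float = 500.0
    duration_s: float = 10.0
    nsr_rr_mean: float = 0.8
    nsr_rr_sd: float = 0.03
    af_rr_mean: float = 0.7
    af_rr_cv: float = 0.25
    morphology: BeatMorphology = field(default_factory=BeatMorphology)
    fib_wave_freq: float = 6.0
    fib_wave_amp: float = 0.05
    noise_amplitudes: tuple[float, float, float] = (0.10, 0.05, 0.03)
    powerline_freq: float = 50.0
    baseline_wander_freq: float = 0.3
    af_fraction: float = 1.0 / 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        for name in ("nsr_rr_mean", "nsr_rr_sd", "af_rr_mean", "af_rr_cv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.af_rr_cv <= self.nsr_rr_sd / self.nsr_rr_mean:
            raise ValueError(
                "af_rr_cv must exceed the NSR coefficient of variation "
                f"({self.nsr_rr_sd / self.nsr_rr_mean:.4f}); AF must be more irregular"
            )
        if not 4.0 <= self.fib_wave_freq <= 9.0:
            raise ValueError(f"fib_wave_freq must lie in [4, 9] Hz, got {self.fib_wave_freq}")
        if any(a < 0 for a in self.noise_amplitudes):
            raise ValueError("noise amplitudes must be non-negative")
        if not 0.0 < self.af_fraction < 1.0:
            raise ValueError(f"af_fraction must lie in (0, 1), got {self.af_fraction}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass
class ECGRecord:
    """A labeled single-lead voltage trace with sampling rate."""

    record_id: str
    samples: np.ndarray  # mV
    fs: float
    lead: str
    label: RhythmClass

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")


_RR_FLOOR_S = 0.3  # truncation point of the NSR RR distribution


def sample_rr_intervals(
    rhythm: RhythmClass,
    n_beats: int,
    config: ECGSynthConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n_beats`` RR intervals (s) for the given rhythm.

    NSR: truncated normal (left-truncated at 0.3 s).  AF: i.i.d. gamma with
    mean ``af_rr_mean`` and coefficient of variation ``af_rr_cv`` — the
    irregularity cue the recurrent stage of the detector exploits.
    """
    if n_beats < 1:
        raise ValueError(f"n_beats must be >= 1, got {n_beats}")
    if rhythm is RhythmClass.AF:
        cv = config.af_rr_cv
        shape = 1.0 / cv**2
        scale = config.af_rr_mean * cv**2
        rr = rng.gamma(shape, scale, size=n_beats)
        # gamma support is (0, inf); clip pathological near-zero draws
        return np.maximum(rr, 1e-3)
    a = (_RR_FLOOR_S - config.nsr_rr_mean) / config.nsr_rr_sd
    rr = stats.truncnorm.rvs(
        a, np.inf, loc=config.nsr_rr_mean, scale=config.nsr_rr_sd,
        size=n_beats, random_state=rng,
    )
    return np.asarray(rr)


def _place_bumps(
    t: np.ndarray, r_times: np.ndarray, morphology: BeatMorphology
) -> np.ndarray:
    out = np.zeros_like(t)
    for amp, off, width in morphology.bumps.values():
        if amp == 0.0:
            continue
        centers = r_times + off
        # each bump decays within ~4 widths; evaluate only nearby samples
        for c in centers:
            lo = np.searchsorted(t, c - 5 * width)
            hi = np.searchsorted(t, c + 5 * width)
            out[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - c) / width) ** 2)
    return out


def render_waveform(
    rr: np.ndarray,
    rhythm: RhythmClass,
    config: ECGSynthConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render a beat train as a sum of Gaussian PQRST bumps (mV).

    R peaks sit at the cumulative RR times.  AF beats are rendered with the
    P bump suppressed and a fibrillatory sinusoid at ``fib_wave_freq``
    (random phase) added — the morphological cue for the convolutional
    backbone.  Output length is ``round(sum(rr) * fs)``.
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size == 0:
        raise ValueError("rr must be non-empty")
    if np.any(rr <= 0):
        raise ValueError("all RR intervals must be positive")

    total = float(rr.sum())
    n = int(round(total * config.fs))
    t = np.arange(n) / config.fs
    r_times = np.cumsum(rr) - rr[0] * 0.5  # first R centred in its interval

    morph = config.morphology
    if rhythm is RhythmClass.AF:
        morph = morph.without_p()
    x = _place_bumps(t, r_times, morph)
    if rhythm is RhythmClass.AF:
        phase = rng.uniform(0, 2 * math.pi)
        x = x + config.fib_wave_amp * np.sin(2 * math.pi * config.fib_wave_freq * t + phase)
    return x


def add_noise(
    samples: np.ndarray,
    fs: float,
    config: ECGSynthConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Add the three classic ECG contaminants.

    baseline wander: sinusoid at ``baseline_wander_freq`` (default 0.3 Hz);
    powerline: sinusoid at ``powerline_freq``; myoelectric (EMG) noise:
    white Gaussian.  Phases are random; amplitudes come from
    ``config.noise_amplitudes`` = (baseline_mV, powerline_mV, emg_mV).
    """
    samples = np.asarray(samples, dtype=float)
    if not np.all(np.isfinite(samples)):
        raise ValueError("samples must be finite")
    bw_amp, pl_amp, emg_sd = config.noise_amplitudes
    if bw_amp < 0 or pl_amp < 0 or emg_sd < 0:
        raise ValueError("noise amplitudes must be non-negative")
    n = samples.size
    t = np.arange(n) / fs
    out = samples.copy()
    if bw_amp > 0:
        out += bw_amp * np.sin(2 * math.pi * config.baseline_wander_freq * t + rng.uniform(0, 2 * math.pi))
    if pl_amp > 0:
        out += pl_amp * np.sin(2 * math.pi * config.powerline_freq * t + rng.uniform(0, 2 * math.pi))
    if emg_sd > 0:
        out += rng.normal(0.0, emg_sd, size=n)
    return out


def _render_record(
    record_id: str,
    rhythm: RhythmClass,
    config: ECGSynthConfig,
    rng: np.random.Generator,
) -> ECGRecord:
    rr_mean = config.af_rr_mean if rhythm is RhythmClass.AF else config.nsr_rr_mean
    n_beats = int(math.ceil(config.duration_s / rr_mean)) + 8
    if rhythm is RhythmClass.NOISE:
        clean = np.zeros(config.n_samples)
        noisy = add_noise(clean, config.fs, config, rng)
        noisy += rng.normal(0.0, 0.2, size=noisy.size)  # dominated by broadband noise
        return ECGRecord(record_id, noisy, config.fs, "II", rhythm)
    render_as = rhythm
    cfg = config
    if rhythm is RhythmClass.OTHER:
        # generic "other rhythm": sinus morphology with shifted rate and
        # amplitude jitter — distinguishable from both NSR and AF
        render_as = RhythmClass.NSR
        cfg = replace(
            config,
            nsr_rr_mean=float(rng.uniform(0.45, 0.6)),
            nsr_rr_sd=config.nsr_rr_sd * 2,
        )
        n_beats = int(math.ceil(config.duration_s / 0.45)) + 8
    rr = sample_rr_intervals(render_as, n_beats, cfg, rng)
    clean = render_waveform(rr, render_as, cfg, rng)
    if rhythm is RhythmClass.OTHER:
        clean *= rng.uniform(0.6, 1.4)
    noisy = add_noise(clean, config.fs, config, rng)
    n = config.n_samples
    if noisy.size >= n:
        noisy = noisy[:n]
    else:  # pragma: no cover - margin of 8 beats makes this unreachable
        noisy = np.pad(noisy, (0, n - noisy.size))
    return ECGRecord(record_id, noisy, config.fs, "II", rhythm)


def generate_dataset(
    n_records: int,
    config: ECGSynthConfig,
    four_class: bool = False,
    other_fraction: float = 0.15,
    noise_fraction: float = 0.05,
) -> list[ECGRecord]:
    """Generate a labeled dataset, fully determined by ``config.seed``.

    Exactly ``round(n_records * af_fraction)`` records are AF; with
    ``four_class`` a further slice of the non-AF records is rendered as
    OTHER (distorted sinus) and NOISE (no cardiac activity).
    """
    if n_records < 2:
        raise ValueError(f"n_records must be >= 2, got {n_records}")
    n_af = int(round(n_records * config.af_fraction))
    labels = [RhythmClass.AF] * n_af
    n_rest = n_records - n_af
    if four_class:
        n_other = int(round(n_records * other_fraction))
        n_noise = int(round(n_records * noise_fraction))
        if n_other + n_noise > n_rest:
            raise ValueError("other_fraction + noise_fraction leave no NSR records")
        labels += [RhythmClass.OTHER] * n_other
        labels += [RhythmClass.NOISE] * n_noise
        labels += [RhythmClass.NSR] * (n_rest - n_other - n_noise)
    else:
        labels += [RhythmClass.NSR] * n_rest

    root = np.random.SeedSequence(config.seed)
    order_rng = np.random.default_rng(root.spawn(1)[0])
    order = order_rng.permutation(n_records)
    seeds = root.spawn(n_records + 1)[1:]

    records = []
    for i in range(n_records):
        rng = np.random.default_rng(seeds[i])
        rhythm = labels[order[i]]
        records.append(_render_record(f"rec{i:05d}", rhythm, config, rng))
    return records
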