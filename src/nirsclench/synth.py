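"""Synthetic prefrontal fNIRS cohort generator.

Simulates the hemoglobin time series the downstream pipeline expects: a
15-subject cohort, 22 channels at 10 Hz, 300 s rest / 60 s tooth clench /
60 s rest, with a task-evoked hemodynamic response (oxy-Hb rises, deoxy-Hb
falls in active channels), superimposed physiological oscillations
(cardiac ~1.2 Hz, respiratory ~0.3 Hz, Mayer wave ~0.1 Hz), slow drift,
white noise and sparse spike artifacts.

The per-channel task effect defaults follow a reference clench-minus-rest
change profile for this 22-channel prefrontal probe (units m(mol/L)·mm);
the between-subject spread defaults to the reference across-subject SD
scaled by 1/sqrt(n_subjects).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

N_CHANNELS = 22

# Mean clench-minus-rest change and across-subject SD per channel,
# oxy-Hb and deoxy-Hb, in m(mol/L)·mm (reference channel table, Ch1..Ch22).
OXY_EFFECT_MEAN = np.array([
    0.038, -0.021, -0.006, 0.027, 0.057, -0.006, -0.044, -0.033,
    0.097, 0.128, -0.032, -0.043, 0.092, 0.084, 0.080, -0.040,
    -0.098, 0.179, 0.305, 0.093, 0.061, 0.132,
])
OXY_EFFECT_SD = np.array([
    0.134, 0.151, 0.125, 0.104, 0.200, 0.124, 0.229, 0.242,
    0.095, 0.158, 0.221, 0.360, 0.252, 0.553, 0.182, 0.306,
    0.540, 0.196, 0.247, 0.356, 0.293, 0.320,
])
DEOXY_EFFECT_MEAN = np.array([
    -0.029, -0.025, -0.027, -0.042, 0.043, -0.030, -0.045, -0.036,
    -0.021, 0.016, -0.028, -0.023, -0.013, 0.240, -0.041, -0.074,
    -0.119, 0.078, 0.068, -0.037, -0.028, -0.068,
])
DEOXY_EFFECT_SD = np.array([
    0.041, 0.053, 0.047, 0.087, 0.190, 0.052, 0.039, 0.048,
    0.112, 0.108, 0.051, 0.054, 0.059, 0.515, 0.079, 0.108,
    0.288, 0.180, 0.126, 0.123, 0.093, 0.240,
])


class ConfigurationError(ValueError):
    """Raised for physically impossible generator configurations."""


@dataclass(frozen=True)
class EffectProfile:
    """Per-channel task effect sizes and their between-subject spread."""

    oxy_effect: np.ndarray = field(default_factory=lambda: OXY_EFFECT_MEAN.copy())
    deoxy_effect: np.ndarray = field(default_factory=lambda: DEOXY_EFFECT_MEAN.copy())
    oxy_subject_sd: np.ndarray = field(
        default_factory=lambda: OXY_EFFECT_SD / np.sqrt(15.0)
    )
    deoxy_subject_sd: np.ndarray = field(
        default_factory=lambda: DEOXY_EFFECT_SD / np.sqrt(15.0)
    )

    def __post_init__(self) -> None:
        for name in ("oxy_effect", "deoxy_effect", "oxy_subject_sd", "deoxy_subject_sd"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_CHANNELS,):
                raise ConfigurationError(
                    f"{name} must have shape ({N_CHANNELS},), got {arr.shape}"
                )
            object.__setattr__(self, name, arr)
        if (self.oxy_subject_sd < 0).any() or (self.deoxy_subject_sd < 0).any():
            raise ConfigurationError("between-subject SDs must be non-negative")

    @classmethod
    def null(cls) -> "EffectProfile":
        """No task effect and no between-subject spread (chance-level cohort)."""
        z = np.zeros(N_CHANNELS)
        return cls(oxy_effect=z, deoxy_effect=z, oxy_subject_sd=z, deoxy_subject_sd=z)


@dataclass(frozen=True)
class NoiseProfile:
    """Amplitudes (m(mol/L)·mm) and frequencies (Hz) of the nuisance signal.

    Oscillation phases are randomised per subject, channel and species.
    Spike artifacts are additive bipolar pulses of 1-3 samples whose
    amplitude is drawn uniformly from ``spike_amp_range`` multiples of
    ``white_sd``.
    """

    white_sd: float = 0.03
    # Session drift is modelled but off by default: with a single pre-task
    # baseline, any drift whose timescale is comparable to the session makes
    # time-from-baseline (and hence the class label) partially decodable even
    # with no task effect, so a null-calibrated cohort must exclude it.
    drift_amp: float = 0.0
    drift_timescale_s: float = 300.0
    cardiac_amp: float = 0.01
    cardiac_freq: float = 1.2
    resp_amp: float = 0.01
    resp_freq: float = 0.3
    mayer_amp: float = 0.015
    mayer_freq: float = 0.1
    spike_rate_per_min: float = 2.0
    spike_amp_range: tuple[float, float] = (6.0, 12.0)

    def __post_init__(self) -> None:
        amps = (self.white_sd, self.drift_amp, self.cardiac_amp,
                self.resp_amp, self.mayer_amp, self.spike_rate_per_min)
        if any(a < 0 for a in amps):
            raise ConfigurationError("noise amplitudes and rates must be >= 0")
        freqs = (self.cardiac_freq, self.resp_freq, self.mayer_freq)
        if any(f <= 0 for f in freqs) or self.drift_timescale_s <= 0:
            raise ConfigurationError("frequencies and timescales must be > 0")

    @classmethod
    def silent(cls) -> "NoiseProfile":
        return cls(white_sd=0.0, drift_amp=0.0, cardiac_amp=0.0,
                   resp_amp=0.0, mayer_amp=0.0, spike_rate_per_min=0.0)


@dataclass(frozen=True)
class HrfKernel:
    """Double-gamma hemodynamic response kernel.

    Normalised to unit area so a sustained boxcar plateaus at the configured
    effect amplitude; peak ~6 s, undershoot ~16 s.
    """

    peak_s: float = 6.0
    undershoot_s: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0
    duration_s: float = 32.0

    def sample(self, fs: float) -> np.ndarray:
        t = np.arange(0.0, self.duration_s, 1.0 / fs)
        pos = gamma_dist.pdf(t, a=self.peak_s, scale=1.0)
        neg = gamma_dist.pdf(t, a=self.undershoot_s, scale=1.0)
        h = pos - self.undershoot_ratio * neg
        area = h.sum() / fs
        return h / (area * fs)  # discrete sum == 1


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to regenerate a cohort bit-identically."""

    n_subjects: int = 15
    n_channels: int = N_CHANNELS
    fs: float = 10.0
    rest_s: float = 300.0
    clench_s: float = 60.0
    post_rest_s: float = 60.0
    effects: EffectProfile = field(default_factory=EffectProfile)
    noise: NoiseProfile = field(default_factory=NoiseProfile)
    hrf: HrfKernel = field(default_factory=HrfKernel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")
        if min(self.rest_s, self.clench_s, self.post_rest_s) <= 0:
            raise ConfigurationError("window durations must be positive")
        if self.n_subjects < 1:
            raise ConfigurationError("need at least one subject")
        if self.n_channels != N_CHANNELS:
            raise ConfigurationError(f"channel count is fixed at {N_CHANNELS}")

    @property
    def duration_s(self) -> float:
        return self.rest_s + self.clench_s + self.post_rest_s

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    @property
    def clench_onset_s(self) -> float:
        return self.rest_s

    @property
    def clench_offset_s(self) -> float:
        return self.rest_s + self.clench_s

    def null_effects(self) -> "CohortConfig":
        return replace(self, effects=EffectProfile.null())


@dataclass
class HbRecording:
    """One subject's oxy/deoxy series (time x channel) plus event timeline."""

    subject_id: str
    fs: float
    oxy: np.ndarray
    deoxy: np.ndarray
    clench_onset_s: float
    clench_offset_s: float

    def __post_init__(self) -> None:
        self.oxy = np.asarray(self.oxy, dtype=float)
        self.deoxy = np.asarray(self.deoxy, dtype=float)
        if self.oxy.shape != self.deoxy.shape:
            raise ValueError("oxy and deoxy series must have identical shape")
        if self.oxy.ndim != 2 or self.oxy.shape[1] != N_CHANNELS:
            raise ValueError(f"series must be time x {N_CHANNELS} channels")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.oxy.shape[0]

    def species(self, name: str) -> np.ndarray:
        if name == "oxy":
            return self.oxy
        if name == "deoxy":
            return self.deoxy
        raise KeyError(name)


def _subject_rng(config: CohortConfig, subject_index: int) -> np.random.Generator:
    """Deterministic per-subject substream of the cohort seed."""
    children = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    return np.random.default_rng(children[subject_index])


def task_response(config: CohortConfig) -> np.ndarray:
    """Unit-amplitude task regressor: clench boxcar convolved with the HRF."""
    n = config.n_samples
    t = np.arange(n) / config.fs
    boxcar = ((t >= config.clench_onset_s) & (t < config.clench_offset_s)).astype(float)
    kernel = config.hrf.sample(config.fs)
    return np.convolve(boxcar, kernel)[:n]


def _spikes(rng: np.random.Generator, n: int, noise: NoiseProfile,
            fs: float) -> np.ndarray:
    out = np.zeros(n)
    lam = noise.spike_rate_per_min * (n / fs) / 60.0
    count = rng.poisson(lam)
    lo, hi = noise.spike_amp_range
    for _ in range(count):
        start = rng.integers(0, n)
        width = rng.integers(1, 4)
        amp = rng.uniform(lo, hi) * noise.white_sd * rng.choice([-1.0, 1.0])
        out[start:start + width] += amp
    return out


def _noise_series(rng: np.random.Generator, n: int, fs: float,
                  noise: NoiseProfile) -> np.ndarray:
    t = np.arange(n) / fs
    out = rng.normal(0.0, noise.white_sd, size=n) if noise.white_sd > 0 else np.zeros(n)
    for amp, freq in ((noise.cardiac_amp, noise.cardiac_freq),
                      (noise.resp_amp, noise.resp_freq),
                      (noise.mayer_amp, noise.mayer_freq)):
        if amp > 0:
            out += amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
    if noise.drift_amp > 0:
        # slow drift: random linear trend plus one slow sinusoid
        a, b = rng.normal(size=2)
        out += noise.drift_amp * (
            a * (t - t[-1] / 2) / t[-1]
            + b * np.sin(2 * np.pi * t / noise.drift_timescale_s + rng.uniform(0, 2 * np.pi))
        )
    if noise.spike_rate_per_min > 0 and noise.white_sd > 0:
        out += _spikes(rng, n, noise, fs)
    return out


def generate_recording(config: CohortConfig, subject_index: int) -> HbRecording:
    """Simulate one subject's 22-channel oxy/deoxy recording.

    The per-channel effect is the profile mean plus a subject-level Gaussian
    perturbation, multiplied by the boxcar-convolved HRF regressor.
    Reproducible: the same (config, subject_index) always yields the same
    arrays.
    """
    if not 0 <= subject_index < config.n_subjects:
        raise IndexError(f"subject_index {subject_index} outside cohort of "
                         f"{config.n_subjects}")
    rng = _subject_rng(config, subject_index)
    n = config.n_samples
    response = task_response(config)

    eff = config.effects
    oxy_eff = eff.oxy_effect + rng.normal(0.0, 1.0, N_CHANNELS) * eff.oxy_subject_sd
    deoxy_eff = eff.deoxy_effect + rng.normal(0.0, 1.0, N_CHANNELS) * eff.deoxy_subject_sd

    oxy = np.empty((n, N_CHANNELS))
    deoxy = np.empty((n, N_CHANNELS))
    for ch in range(N_CHANNELS):
        oxy[:, ch] = oxy_eff[ch] * response + _noise_series(rng, n, config.fs, config.noise)
    for ch in range(N_CHANNELS):
        deoxy[:, ch] = deoxy_eff[ch] * response + _noise_series(rng, n, config.fs, config.noise)

    return HbRecording(
        subject_id=f"sub-{subject_index + 1:02d}",
        fs=config.fs,
        oxy=oxy,
        deoxy=deoxy,
        clench_onset_s=config.clench_onset_s,
        clench_offset_s=config.clench_offset_s,
    )


def generate_cohort(config: CohortConfig) -> list[HbRecording]:
    """One recording per subject, independent subject-level perturbations."""
    return [generate_recording(config, i) for i in range(config.n_subjects)]


# ---------------------------------------------------------------------------
# on-disk CSV dialect: one CSV per subject plus a JSON sidecar with events

def _columns() -> list[str]:
    return (["time_s"]
            + [f"ch{c + 1:02d}_oxy" for c in range(N_CHANNELS)]
            + [f"ch{c + 1:02d}_deoxy" for c in range(N_CHANNELS)])


def write_recording(rec: HbRecording, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame(
        np.column_stack([t, rec.oxy, rec.deoxy]), columns=_columns()
    )
    csv_path = directory / f"{rec.subject_id}.csv"
    df.to_csv(csv_path, index=False, float_format="%.6f")
    sidecar = {
        "subject_id": rec.subject_id,
        "fs": rec.fs,
        "clench_onset_s": rec.clench_onset_s,
        "clench_offset_s": rec.clench_offset_s,
    }
    (directory / f"{rec.subject_id}.json").write_text(json.dumps(sidecar, indent=2))
    return csv_path


def read_recording(csv_path: str | Path) -> HbRecording:
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    df = pd.read_csv(csv_path)
    oxy = df[[f"ch{c + 1:02d}_oxy" for c in range(N_CHANNELS)]].to_numpy()
    deoxy = df[[f"ch{c + 1:02d}_deoxy" for c in range(N_CHANNELS)]].to_numpy()
    return HbRecording(
        subject_id=meta["subject_id"],
        fs=float(meta["fs"]),
        oxy=oxy,
        deoxy=deoxy,
        clench_onset_s=float(meta["clench_onset_s"]),
        clench_offset_s=float(meta["clench_offset_s"]),
    )


def write_cohort(cohort: list[HbRecording], directory: str | Path) -> list[Path]:
    return [write_recording(rec, directory) for rec in cohort]


def read_cohort(directory: str | Path) -> list[HbRecording]:
    paths = sorted(Path(directory).glob("sub-*.csv"))
    return [read_recording(p) for p in paths]
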