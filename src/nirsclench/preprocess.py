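"""Filtering, window extraction, baseline referencing and artifact masking.

The analysis time course, anchored at the clench onset: a 10 s baseline
window immediately before a 60 s pre-task rest window; the first 5 s of the
clench are excluded (hemodynamics lag the motor act); the remaining 55 s
form the clench window. All windows are half-open ``[start, end)`` in
seconds from recording start, so sample counts are exact (100 / 600 / 550
at 10 Hz).

Artifact masking follows the 2-SD rule: within each window, species and
channel, samples whose baseline-referenced delta deviates from the window
mean by more than twice the window SD are treated as missing. Mean and SD
are computed once on the unmasked data (single pass, no re-iteration), so
the rule is idempotent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .synth import HbRecording, N_CHANNELS

SPECIES = ("oxy", "deoxy")
WINDOWS = ("rest", "clench")


class ParameterError(ValueError):
    pass


class WindowError(ValueError):
    pass


def lowpass_filter(series: np.ndarray, cutoff: float, fs: float,
                   order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass.

    Zero-phase filtering keeps window boundaries aligned with events; the
    effective attenuation is the squared magnitude response of the
    single-pass filter.
    """
    nyquist = fs / 2.0
    if not 0 < cutoff < nyquist:
        raise ParameterError(f"cutoff must lie in (0, {nyquist}) Hz, got {cutoff}")
    series = np.asarray(series, dtype=float)
    sos = butter(order, cutoff, btype="low", fs=fs, output="sos")
    return sosfiltfilt(sos, series, axis=0)


def filter_recording(rec: HbRecording, cutoff: float = 0.2,
                     order: int = 4) -> HbRecording:
    return HbRecording(
        subject_id=rec.subject_id,
        fs=rec.fs,
        oxy=lowpass_filter(rec.oxy, cutoff, rec.fs, order),
        deoxy=lowpass_filter(rec.deoxy, cutoff, rec.fs, order),
        clench_onset_s=rec.clench_onset_s,
        clench_offset_s=rec.clench_offset_s,
    )


@dataclass(frozen=True)
class TimeCourse:
    """Analysis windows in seconds from recording start.

    Derived from the clench onset: rest is the 60 s immediately before it,
    baseline the 10 s immediately before rest, and the clench window skips
    the first ``exclusion_s`` seconds of the task.
    """

    baseline_start: float
    baseline_end: float
    rest_start: float
    rest_end: float
    clench_start: float
    clench_end: float

    def __post_init__(self) -> None:
        edges = (self.baseline_start, self.baseline_end, self.rest_start,
                 self.rest_end, self.clench_start, self.clench_end)
        if any(b < a for a, b in zip(edges, edges[1:])):
            raise WindowError(f"windows must be ordered and non-overlapping: {edges}")
        if self.baseline_end != self.rest_start:
            raise WindowError("baseline must end where rest starts")

    @classmethod
    def from_events(cls, clench_onset_s: float, clench_offset_s: float,
                    baseline_s: float = 10.0, rest_s: float = 60.0,
                    exclusion_s: float = 5.0) -> "TimeCourse":
        return cls(
            baseline_start=clench_onset_s - rest_s - baseline_s,
            baseline_end=clench_onset_s - rest_s,
            rest_start=clench_onset_s - rest_s,
            rest_end=clench_onset_s,
            clench_start=clench_onset_s + exclusion_s,
            clench_end=clench_offset_s,
        )


def _slice(series: np.ndarray, fs: float, start_s: float, end_s: float) -> np.ndarray:
    i0 = int(round(start_s * fs))
    i1 = int(round(end_s * fs))
    if i0 < 0 or i1 > series.shape[0]:
        raise WindowError(
            f"window [{start_s}, {end_s}) s outside recording of "
            f"{series.shape[0] / fs} s"
        )
    return series[i0:i1]


def extract_windows(rec: HbRecording, tc: TimeCourse) -> dict[str, dict[str, np.ndarray]]:
    """Cut baseline / rest / clench segments for both Hb species.

    Returns ``{species: {"baseline": ..., "rest": ..., "clench": ...}}``;
    the exclusion period between rest and clench is dropped.
    """
    out: dict[str, dict[str, np.ndarray]] = {}
    for sp in SPECIES:
        series = rec.species(sp)
        out[sp] = {
            "baseline": _slice(series, rec.fs, tc.baseline_start, tc.baseline_end),
            "rest": _slice(series, rec.fs, tc.rest_start, tc.rest_end),
            "clench": _slice(series, rec.fs, tc.clench_start, tc.clench_end),
        }
    return out


def baseline_means(baseline_segment: np.ndarray) -> np.ndarray:
    """Per-channel mean of the baseline segment."""
    baseline_segment = np.asarray(baseline_segment, dtype=float)
    if baseline_segment.shape[0] == 0:
        raise WindowError("baseline segment is empty")
    return baseline_segment.mean(axis=0)


@dataclass
class EpochDeltas:
    """Baseline-referenced per-sample deltas with a missing-value mask.

    ``deltas[species][window]`` is a (samples x channels) float array;
    ``mask`` has the same shape, True where the sample was flagged as an
    artifact. ``stats`` holds the per-window per-channel mean/SD used by the
    masking rule.
    """

    subject_id: str
    fs: float
    deltas: dict[str, dict[str, np.ndarray]]
    mask: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    stats: dict[str, dict[str, dict[str, np.ndarray]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mask:
            self.mask = {
                sp: {w: np.zeros_like(a, dtype=bool) for w, a in wins.items()}
                for sp, wins in self.deltas.items()
            }

    def n_masked(self) -> int:
        return int(sum(m.sum() for wins in self.mask.values() for m in wins.values()))


def compute_deltas(segments: dict[str, dict[str, np.ndarray]],
                   means: dict[str, np.ndarray], *, subject_id: str = "",
                   fs: float = 10.0) -> EpochDeltas:
    """Subtract the per-channel baseline mean from rest and clench samples."""
    deltas: dict[str, dict[str, np.ndarray]] = {}
    for sp in SPECIES:
        mean = np.asarray(means[sp], dtype=float)
        deltas[sp] = {}
        for w in WINDOWS:
            seg = np.asarray(segments[sp][w], dtype=float)
            if seg.shape[1] != mean.shape[0]:
                raise ValueError("channel count mismatch between segment and baseline")
            deltas[sp][w] = seg - mean
    return EpochDeltas(subject_id=subject_id, fs=fs, deltas=deltas)


def mask_artifacts(epoch: EpochDeltas, n_sd: float = 2.0) -> EpochDeltas:
    """Flag samples deviating more than ``n_sd`` SDs from their window mean.

    Applied independently per window, species and channel; a zero-variance
    channel masks nothing (strict inequality). Single pass: statistics are
    not recomputed on the masked data.
    """
    mask: dict[str, dict[str, np.ndarray]] = {}
    stats: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    for sp, wins in epoch.deltas.items():
        mask[sp] = {}
        stats[sp] = {}
        for w, arr in wins.items():
            if arr.shape[0] < 2:
                raise WindowError("need >= 2 samples per window to compute an SD")
            mu = arr.mean(axis=0)
            sd = arr.std(axis=0, ddof=1)
            mask[sp][w] = np.abs(arr - mu) > n_sd * sd
            stats[sp][w] = {"mean": mu, "sd": sd}
    return EpochDeltas(subject_id=epoch.subject_id, fs=epoch.fs,
                       deltas=epoch.deltas, mask=mask, stats=stats)


def save_epoch(epoch: EpochDeltas, path) -> None:
    """Write deltas+mask as compressed arrays with a JSON manifest sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    arrays = {}
    masked_counts = {}
    for sp, wins in epoch.deltas.items():
        for w, arr in wins.items():
            arrays[f"deltas_{sp}_{w}"] = arr
            arrays[f"mask_{sp}_{w}"] = epoch.mask[sp][w]
            masked_counts[f"{sp}_{w}"] = epoch.mask[sp][w].sum(axis=0).tolist()
    np.savez_compressed(path, **arrays)
    manifest = {"subject_id": epoch.subject_id, "fs": epoch.fs,
                "masked_counts_per_channel": masked_counts}
    Path(str(path) + ".json").write_text(json.dumps(manifest, indent=2))


def load_epoch(path) -> EpochDeltas:
    import json
    from pathlib import Path

    path = Path(path)
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as z:
        deltas: dict[str, dict[str, np.ndarray]] = {}
        mask: dict[str, dict[str, np.ndarray]] = {}
        for key in z.files:
            kind, sp, w = key.split("_")
            (deltas if kind == "deltas" else mask).setdefault(sp, {})[w] = z[key]
    manifest = json.loads(Path(str(path) + ".json").read_text())
    return EpochDeltas(subject_id=manifest["subject_id"], fs=manifest["fs"],
                       deltas=deltas, mask=mask)


def preprocess_recording(rec: HbRecording, *, cutoff: float = 0.2,
                         filter_order: int = 4, baseline_s: float = 10.0,
                         rest_s: float = 60.0, exclusion_s: float = 5.0,
                         n_sd: float = 2.0, apply_filter: bool = True) -> EpochDeltas:
    """Full stage: filter, window, baseline-reference, mask."""
    if apply_filter:
        rec = filter_recording(rec, cutoff=cutoff, order=filter_order)
    tc = TimeCourse.from_events(rec.clench_onset_s, rec.clench_offset_s,
                                baseline_s=baseline_s, rest_s=rest_s,
                                exclusion_s=exclusion_s)
    segments = extract_windows(rec, tc)
    means = {sp: baseline_means(segments[sp]["baseline"]) for sp in SPECIES}
    epoch = compute_deltas(segments, means, subject_id=rec.subject_id, fs=rec.fs)
    return mask_artifacts(epoch, n_sd=n_sd)
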