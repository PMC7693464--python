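"""Conventional per-channel Hb analysis.

For each subject the mean oxy-Hb / deoxy-Hb over the full 1-min rest
window and the full 1-min clench window are computed (n = 600 at 10 Hz;
this stage deliberately uses the complete clench minute, unlike the
image pipeline's 55 s window). The per-channel change is the clench mean
minus the rest mean; across subjects a two-sided paired t-test compares
clench vs rest means, and the Bonferroni-adjusted p is the raw p times the
number of channels, deliberately uncapped (adjusted values may exceed 1,
as conventionally printed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .imaging import ChannelLayout
from .preprocess import _slice, filter_recording
from .synth import HbRecording, N_CHANNELS


class StatisticsError(ValueError):
    pass


@dataclass
class ChannelChangeTable:
    """Across-subject change summary per channel, one table per Hb species."""

    species: str
    frame: pd.DataFrame  # channel, change_mean, change_sd, p_raw, p_adj, region


def _window_means(rec: HbRecording, species: str, rest_s: float,
                  clench_s: float) -> tuple[np.ndarray, np.ndarray]:
    series = rec.species(species)
    onset = rec.clench_onset_s
    rest = _slice(series, rec.fs, onset - rest_s, onset)
    clench = _slice(series, rec.fs, onset, onset + clench_s)
    return rest.mean(axis=0), clench.mean(axis=0)


def channel_changes(cohort: list[HbRecording], *, rest_s: float = 60.0,
                    clench_s: float = 60.0, apply_filter: bool = True,
                    cutoff: float = 0.2,
                    layout: ChannelLayout | None = None,
                    n_comparisons: int = N_CHANNELS
                    ) -> dict[str, ChannelChangeTable]:
    """Per-channel clench-minus-rest changes with paired t-tests.

    Returns one table per Hb species with across-subject mean +/- SD of the
    change, the raw paired-t p-value, and the uncapped Bonferroni-adjusted
    p (raw x 22). Channels with zero change variance get NaN p-values
    (flagged, not zero).
    """
    if len(cohort) < 2:
        raise StatisticsError("need >= 2 subjects for a paired t-test")
    regions = (layout or ChannelLayout.default()).regions
    out: dict[str, ChannelChangeTable] = {}
    for sp in ("oxy", "deoxy"):
        rest_means = []
        clench_means = []
        for rec in cohort:
            if apply_filter:
                rec = filter_recording(rec, cutoff=cutoff)
            r, c = _window_means(rec, sp, rest_s, clench_s)
            rest_means.append(r)
            clench_means.append(c)
        rest_arr = np.vstack(rest_means)     # subjects x channels
        clench_arr = np.vstack(clench_means)
        change = clench_arr - rest_arr
        mean = change.mean(axis=0)
        sd = change.std(axis=0, ddof=1)
        p_raw = np.full(N_CHANNELS, np.nan)
        for ch in range(N_CHANNELS):
            diffs = change[:, ch]
            if np.allclose(diffs, diffs[0]):
                continue  # zero variance: t undefined, leave NaN
            p_raw[ch] = stats.ttest_rel(clench_arr[:, ch], rest_arr[:, ch]).pvalue
        frame = pd.DataFrame({
            "channel": np.arange(1, N_CHANNELS + 1),
            "change_mean": mean,
            "change_sd": sd,
            "p_raw": p_raw,
            "p_adj": p_raw * n_comparisons,  # uncapped by convention
            "region": [regions[ch] for ch in range(1, N_CHANNELS + 1)],
        })
        out[sp] = ChannelChangeTable(species=sp, frame=frame)
    return out
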