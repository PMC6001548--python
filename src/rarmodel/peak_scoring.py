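"""Model-free peak-scoring baselines for respiration amplitude responses.

Single trials are epoched in an 11-s window from CS onset and
baseline-corrected by the mean amplitude over the 4 s preceding the onset.
Three classical statistics summarize each epoch:

    P1  maximum (positive) peak in the 2-11 s window,
    P2  signed maximal deviation from baseline in the 2-11 s window,
    P3  mean amplitude in the 2-7 s window.

On all-negative windows P1 returns the (negative) maximum, keeping the
statistic total and continuous. Window endpoints are inclusive at
sample-grid resolution. Trial scores aggregate to condition level by the
unweighted trial mean.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

from .rar_glm import EventSchedule, RESPONSE_WINDOW_S
from .resp_preproc import AmplitudeTimeseries

__all__ = [
    "TrialEpoch",
    "epoch_trials",
    "score_p1_max_peak",
    "score_p2_max_variation",
    "score_p3_mean",
    "conditionwise_scores",
    "PEAK_SCORERS",
    "BASELINE_WINDOW_S",
]

#: pre-CS baseline window length (s); about one respiratory cycle
BASELINE_WINDOW_S = 4.0

_P12_WINDOW_S = (2.0, 11.0)
_P3_WINDOW_S = (2.0, 7.0)


@dataclass
class TrialEpoch:
    """Baseline-corrected single-trial response over [0, 11] s from CS onset."""

    values: np.ndarray
    condition: str
    baseline_value: float
    sampling_rate: float
    onset: float

    def window(self, start: float, end: float) -> np.ndarray:
        i0 = int(round(start * self.sampling_rate))
        i1 = int(round(end * self.sampling_rate))
        return self.values[i0 : i1 + 1]


def epoch_trials(ts: AmplitudeTimeseries, events: EventSchedule) -> list[TrialEpoch]:
    """Epoch the amplitude series around each CS onset.

    The baseline is the mean over [-4, 0) s before the onset and is
    subtracted from the 11-s window. Trials without 4 s of preceding or
    11 s of following data are excluded with a warning.
    """
    sr = ts.sampling_rate
    n = len(ts)
    n_pre = int(round(BASELINE_WINDOW_S * sr))
    n_win = int(round(RESPONSE_WINDOW_S * sr))
    epochs: list[TrialEpoch] = []
    for onset, cond in zip(events.cs_onsets, events.conditions):
        i_on = int(round((onset - ts.t0) * sr))
        if i_on - n_pre < 0 or i_on + n_win >= n:
            warnings.warn(
                f"trial at {onset:g} s excluded: insufficient pre/post data",
                stacklevel=2,
            )
            continue
        baseline = float(ts.values[i_on - n_pre : i_on].mean())
        values = ts.values[i_on : i_on + n_win + 1] - baseline
        epochs.append(TrialEpoch(values, str(cond), baseline, sr, float(onset)))
    return epochs


def score_p1_max_peak(epoch: TrialEpoch) -> float:
    """P1: maximum peak in the 2-11 s window (may be negative)."""
    return float(epoch.window(*_P12_WINDOW_S).max())


def score_p2_max_variation(epoch: TrialEpoch) -> float:
    """P2: signed extremum of maximal absolute value in the 2-11 s window."""
    seg = epoch.window(*_P12_WINDOW_S)
    return float(seg[np.argmax(np.abs(seg))])


def score_p3_mean(epoch: TrialEpoch) -> float:
    """P3: mean amplitude in the 2-7 s window."""
    return float(epoch.window(*_P3_WINDOW_S).mean())


PEAK_SCORERS: dict[str, Callable[[TrialEpoch], float]] = {
    "P1": score_p1_max_peak,
    "P2": score_p2_max_variation,
    "P3": score_p3_mean,
}


def conditionwise_scores(
    epochs: Iterable[TrialEpoch],
    scorer: Callable[[TrialEpoch], float],
    expected_conditions: Iterable[str] | None = None,
) -> dict[str, float]:
    """Mean trial score per condition.

    If ``expected_conditions`` is given and one of them has no epochs, it
    is reported missing with a warning and omitted from the result (the
    caller then excludes the subject).
    """
    by_cond: dict[str, list[float]] = defaultdict(list)
    for epoch in epochs:
        by_cond[epoch.condition].append(scorer(epoch))
    if expected_conditions is not None:
        for cond in expected_conditions:
            if cond not in by_cond:
                warnings.warn(f"no trials for condition {cond!r}", stacklevel=2)
    return {cond: float(np.mean(scores)) for cond, scores in sorted(by_cond.items())}
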