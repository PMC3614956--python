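"""Discrete gating-state assignment from order-parameter series.

An order parameter is mapped to a categorical state by a band (cutoff)
lookup, optionally preceded by a running-median smoothing and stabilized by
hysteresis: once in a state, the (smoothed) value must pass the relevant
cutoff by the hysteresis width before the label changes.

State sets used downstream:
  selectivity filter  : narrow / wide         (one cutoff, default 6.0 Å)
  cytoplasmic end     : closed / intermediate / open
                        (cutoffs 6.5 / 7.5 Å; the intermediate band is the
                        printed 6.5-7.5 Å range)
Joint labels combine a first letter for the filter state with a second for
the cytoplasmic state, e.g. "WO", "NI".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .errors import ParameterError, StructureError
from .order_params import OPSeries

#: Default cytoplasmic-end D2 cutoffs (Å): closed < 6.5 <= intermediate <= ... < open
DEFAULT_CE_CUTOFFS = (6.5, 7.5)
DEFAULT_CE_STATES = ("closed", "intermediate", "open")
#: Default selectivity-filter D1 cutoff (Å); figure-derived, must be echoed in reports.
DEFAULT_SF_CUTOFF = 6.0
DEFAULT_SF_STATES = ("narrow", "wide")

STATE_LETTERS = {
    "wide": "W", "narrow": "N",
    "open": "O", "intermediate": "I", "closed": "C",
}


@dataclass
class StateSeries:
    labels: np.ndarray  # per-frame categorical (str)
    states: tuple[str, ...]
    cutoffs: tuple[float, ...]
    hysteresis: float
    smoothing_window: int
    source_op: str
    times: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        bad = set(self.labels) - set(self.states)
        if bad:
            raise StructureError(f"labels {bad} outside declared state set")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class Segment:
    """Maximal run of one state over the half-open frame range [start, end)."""

    state: str
    start: int
    end: int
    duration_ns: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise StructureError("segment end must exceed start")

    @property
    def n_frames(self) -> int:
        return self.end - self.start


def band_of(value: float, cutoffs: Sequence[float]) -> int:
    """Index of the half-open band [c_i, c_{i+1}) containing value."""
    return int(np.searchsorted(np.asarray(cutoffs), value, side="right"))


def classify(
    op: OPSeries,
    cutoffs: Sequence[float],
    states: Sequence[str],
    hysteresis: float = 0.0,
    smoothing_window: int = 1,
) -> StateSeries:
    """Assign a per-frame state label by banded lookup of the smoothed value.

    With ``hysteresis=0`` and ``smoothing_window=1`` this is a pure band
    lookup.  Otherwise a label change toward a higher band requires the value
    to exceed the crossed cutoff by ``hysteresis`` (and symmetrically for
    lower bands); the smoothing is a centered running median.
    """
    cutoffs = tuple(float(c) for c in cutoffs)
    if list(cutoffs) != sorted(cutoffs) or len(set(cutoffs)) != len(cutoffs):
        raise ParameterError(f"cutoffs must be strictly increasing: {cutoffs}")
    if len(states) != len(cutoffs) + 1:
        raise ParameterError(
            f"need {len(cutoffs) + 1} state names for {len(cutoffs)} cutoffs")
    if smoothing_window < 1:
        raise ParameterError("smoothing_window must be >= 1 frame")
    if hysteresis < 0:
        raise ParameterError("hysteresis must be non-negative")

    values = op.values
    if smoothing_window > 1:
        values = median_filter(values, size=smoothing_window, mode="nearest")

    n = len(values)
    labels = np.empty(n, dtype=object)
    if n == 0:
        return StateSeries(labels, tuple(states), cutoffs, hysteresis,
                           smoothing_window, op.name, op.times)

    cur = band_of(values[0], cutoffs)
    labels[0] = states[cur]
    for i in range(1, n):
        v = values[i]
        target = band_of(v, cutoffs)
        if target > cur:
            # must clear the first cutoff above the current band, plus margin
            if v >= cutoffs[cur] + hysteresis:
                # move up only as far as the hysteresis-cleared cutoffs allow
                while cur < target and v >= cutoffs[cur] + hysteresis:
                    cur += 1
        elif target < cur:
            if v < cutoffs[cur - 1] - hysteresis:
                while cur > target and v < cutoffs[cur - 1] - hysteresis:
                    cur -= 1
        labels[i] = states[cur]
    return StateSeries(labels, tuple(states), cutoffs, hysteresis,
                       smoothing_window, op.name, op.times)


def _runs(labels: np.ndarray) -> list[tuple[str, int, int]]:
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((labels[start], start, i))
            start = i
    return runs


def segments(
    states: StateSeries,
    min_dwell_ns: float = 0.0,
    frame_stride_ns: float | None = None,
) -> list[Segment]:
    """Maximal constant-label runs; runs shorter than ``min_dwell_ns`` are
    merged into the longer flanking run (ties go to the preceding one).

    The output tiles the trajectory: segment durations sum to the total.
    """
    if min_dwell_ns < 0:
        raise ParameterError("min_dwell_ns must be >= 0")
    labels = np.array(states.labels, dtype=object)
    n = len(labels)
    if n == 0:
        return []
    if frame_stride_ns is None:
        t = states.times
        frame_stride_ns = float(t[1] - t[0]) if len(t) > 1 else 1.0

    def dur(run):
        return (run[2] - run[1]) * frame_stride_ns

    runs = _runs(labels)
    changed = True
    while changed and len(runs) > 1:
        changed = False
        # merge the shortest sub-threshold run first for determinism
        short = [i for i, r in enumerate(runs) if dur(r) < min_dwell_ns]
        if not short:
            break
        i = min(short, key=lambda j: (dur(runs[j]), j))
        state, s, e = runs[i]
        left = runs[i - 1] if i > 0 else None
        right = runs[i + 1] if i < len(runs) - 1 else None
        if left is None and right is None:
            break
        if right is None or (left is not None and dur(left) >= dur(right)):
            absorber = "left"
        else:
            absorber = "right"
        if absorber == "left":
            runs[i - 1] = (left[0], left[1], e)
            del runs[i]
        else:
            runs[i + 1] = (right[0], s, right[2])
            del runs[i]
        # coalesce now-adjacent equal labels
        j = 0
        while j < len(runs) - 1:
            if runs[j][0] == runs[j + 1][0]:
                runs[j] = (runs[j][0], runs[j][1], runs[j + 1][2])
                del runs[j + 1]
            else:
                j += 1
        changed = True

    return [Segment(state, s, e, (e - s) * frame_stride_ns)
            for state, s, e in runs]


def joint_states(sf: StateSeries, ce: StateSeries) -> StateSeries:
    """Two-letter joint labels, e.g. wide+open -> "WO", narrow+intermediate -> "NI"."""
    if len(sf) != len(ce):
        raise StructureError(
            f"state series lengths differ: {len(sf)} vs {len(ce)}")
    try:
        labels = np.array(
            [STATE_LETTERS[a] + STATE_LETTERS[b]
             for a, b in zip(sf.labels, ce.labels)], dtype=object)
    except KeyError as exc:
        raise ParameterError(f"no joint letter for state {exc}") from exc
    all_joint = tuple(sorted({STATE_LETTERS[a] + STATE_LETTERS[b]
                              for a in sf.states for b in ce.states}))
    return StateSeries(labels, all_joint, (), 0.0, 1,
                       f"{sf.source_op}x{ce.source_op}", sf.times)


def dwell_summary(segs: Sequence[Segment]) -> pd.DataFrame:
    """Per-state dwell statistics: visit count, total and mean dwell time."""
    rows = {}
    for s in segs:
        r = rows.setdefault(s.state, {"state": s.state, "n_visits": 0,
                                      "total_ns": 0.0})
        r["n_visits"] += 1
        r["total_ns"] += s.duration_ns
    df = pd.DataFrame(list(rows.values()))
    if not df.empty:
        df["mean_dwell_ns"] = df["total_ns"] / df["n_visits"]
    return df
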