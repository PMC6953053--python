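"""Finite-state matching of ventricular arrhythmia patterns on beat labels.

The four categories, on a sequence of per-beat labels (sinus ``N`` / ventricular
premature beat ``V``):

* ventricular tachycardia (VT): a run of four or more consecutive VPBs;
* salvo: a run of exactly two or three consecutive VPBs;
* bigeminy: strict V,N alternation containing at least three VPBs
  (minimum V N V N V);
* trigeminy: strict V,N,N cycling containing at least three VPBs
  (minimum V N N V N N V);
* isolated VPB: a single VPB matching none of the above.

Matching is greedy left-to-right with precedence
VT > salvo > trigeminy > bigeminy > isolated, maximal matches, and each beat
consumed by at most one event, so category tallies are disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RhythmEvent",
    "PatternConfig",
    "detect_runs",
    "classify_patterns",
    "count_by_type",
    "EVENT_TYPES",
]

EVENT_TYPES = ("vpb_isolated", "bigeminy", "trigeminy", "salvo", "vt")

_VPB_LABELS = {"vpb", "V", "v", 1, True}


@dataclass(frozen=True)
class RhythmEvent:
    """A classified arrhythmia occurrence.

    ``start_beat``/``end_beat`` are inclusive beat indices; ``n_vpb`` counts
    the VPB beats inside the event; ``onset_time_s`` is the time of the first
    beat (NaN when no times were supplied).
    """

    etype: str
    start_beat: int
    end_beat: int
    n_vpb: int
    onset_time_s: float = float("nan")

    def __post_init__(self) -> None:
        if self.etype not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.etype!r}")
        if self.end_beat < self.start_beat:
            raise ValueError("end_beat before start_beat")


@dataclass
class PatternConfig:
    """``min_alternation_vpbs`` is the minimum number of VPBs required for a
    bigeminy/trigeminy call (default 3: the minimal repeating reading of the
    definition); stricter readings raise it."""

    min_alternation_vpbs: int = 3


def _to_bool(labels) -> np.ndarray:
    arr = np.asarray(labels, dtype=object)
    return np.array([lab in _VPB_LABELS for lab in arr.ravel()], dtype=bool)


def detect_runs(labels) -> list[tuple[int, int]]:
    """Maximal runs of consecutive VPB labels as (start, length) pairs."""
    v = _to_bool(labels)
    if v.size == 0:
        return []
    padded = np.concatenate([[False], v, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def _chain(runs: list[tuple[int, int]], j: int, gap: int, n_labels: int) -> int:
    """Length of the maximal single-VPB chain starting at run ``j`` whose
    consecutive VPBs are separated by exactly ``gap`` sinus beats."""
    count = 1
    while True:
        s, ln = runs[j]
        if ln != 1:
            # chains are built from isolated-VPB runs only
            return count - 1 if count > 1 else 0
        if j + 1 >= len(runs):
            return count
        s2, ln2 = runs[j + 1]
        if s2 - (s + 1) != gap or ln2 != 1:
            return count
        j += 1
        count += 1


def classify_patterns(labels, times=None, config: PatternConfig | None = None) -> list[RhythmEvent]:
    """Scan a classified label sequence and emit non-overlapping rhythm events.

    ``times``: optional per-beat onset times in seconds (same length as
    ``labels``); used to stamp ``onset_time_s`` on each event.
    """
    cfg = config or PatternConfig()
    v = _to_bool(labels)
    runs = detect_runs(v)
    if times is not None:
        times = np.asarray(times, dtype=float)
        if times.size != v.size:
            raise ValueError("times and labels differ in length")

    def t(idx: int) -> float:
        return float(times[idx]) if times is not None else float("nan")

    events: list[RhythmEvent] = []
    j = 0
    while j < len(runs):
        start, length = runs[j]
        if length >= 4:
            events.append(RhythmEvent("vt", start, start + length - 1, length, t(start)))
            j += 1
        elif length >= 2:
            events.append(RhythmEvent("salvo", start, start + length - 1, length, t(start)))
            j += 1
        else:
            # single VPB: try trigeminy (gap 2) then bigeminy (gap 1)
            matched = False
            for gap, etype in ((2, "trigeminy"), (1, "bigeminy")):
                n = _chain(runs, j, gap, v.size)
                if n >= cfg.min_alternation_vpbs:
                    last_start, _ = runs[j + n - 1]
                    events.append(RhythmEvent(etype, start, last_start, n, t(start)))
                    j += n
                    matched = True
                    break
            if not matched:
                events.append(RhythmEvent("vpb_isolated", start, start, 1, t(start)))
                j += 1
    return events


def count_by_type(events: list[RhythmEvent], mode: str = "exclusive") -> dict:
    """Tally events per category, merging bigeminy+trigeminy into ``bg_tg``.

    Counts are event counts, not beat counts; ``total_vpb_beats`` additionally
    sums the VPB beats across all events.  In ``mode="inclusive"`` the ``vpb``
    entry counts every VPB complex (pattern members included) instead of
    isolated VPBs only.
    """
    if mode not in ("exclusive", "inclusive"):
        raise ValueError("mode must be 'exclusive' or 'inclusive'")
    total_vpb = sum(e.n_vpb for e in events)
    counts = {
        "vpb": sum(1 for e in events if e.etype == "vpb_isolated"),
        "bg_tg": sum(1 for e in events if e.etype in ("bigeminy", "trigeminy")),
        "salvo": sum(1 for e in events if e.etype == "salvo"),
        "vt": sum(1 for e in events if e.etype == "vt"),
        "total_vpb_beats": total_vpb,
    }
    if mode == "inclusive":
        counts["vpb"] = total_vpb
    return counts
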