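"""Per-beat and per-timepoint ECG interval metrics, including the murine
rate-corrected QT.

Mice beat near RR = 100 ms, so the human Bazett normalisation (RR/1 s) is
replaced by a normalisation to 100 ms:

    QTc = QT / sqrt(RR / 100)      (QT, RR in ms)

At RR = 100 ms the correction is the identity; QTc scales linearly in QT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["qtc_correct", "summarize_timepoint", "TimepointSummary"]


def qtc_correct(qt_ms, rr_ms):
    """Murine rate-corrected QT: ``qt_ms / sqrt(rr_ms / 100)``.

    Accepts scalars or arrays; raises ``ValueError`` on non-positive inputs.
    """
    qt = np.asarray(qt_ms, dtype=float)
    rr = np.asarray(rr_ms, dtype=float)
    if np.any(qt <= 0) or np.any(rr <= 0):
        raise ValueError("qt_ms and rr_ms must be positive")
    out = qt / np.sqrt(rr / 100.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TimepointSummary:
    """Mean interval parameters over the beats of one analysis window."""

    timepoint_id: str
    mean_rr_ms: float
    mean_qrs_ms: float
    mean_qt_ms: float
    mean_qtc_ms: float
    n_beats: int


def summarize_timepoint(
    beats: pd.DataFrame,
    window_s: tuple,
    timepoint_id: str = "",
    sinus_only: bool = True,
    rr_mode: str = "per_beat",
) -> TimepointSummary:
    """Average RR/QRS/QT/QTc over the beats inside ``window_s`` (seconds,
    half-open, on the ``r_time_s`` axis).

    QTc is computed per beat from the RR preceding that beat (``rr_mode=
    "per_beat"``), or from the window-mean RR (``rr_mode="window_mean"``).
    Beats with a missing T end (no measurable QT) are dropped; ectopic beats
    are excluded by default since they distort QRS/QT means.  Raises
    ``ValueError`` when no eligible beat remains.
    """
    if rr_mode not in ("per_beat", "window_mean"):
        raise ValueError("rr_mode must be 'per_beat' or 'window_mean'")
    start, end = window_s
    sel = (beats["r_time_s"] >= start) & (beats["r_time_s"] < end)
    if sinus_only:
        sel &= beats["label"] == "sinus"
    sub = beats.loc[sel].dropna(subset=["rr_ms", "qt_ms"])
    if len(sub) == 0:
        raise ValueError(f"no eligible beats in window {window_s}")
    rr = sub["rr_ms"].to_numpy(dtype=float)
    qt = sub["qt_ms"].to_numpy(dtype=float)
    if rr_mode == "per_beat":
        qtc = qtc_correct(qt, rr)
    else:
        qtc = qtc_correct(qt, float(rr.mean()))
    return TimepointSummary(
        timepoint_id=timepoint_id,
        mean_rr_ms=float(rr.mean()),
        mean_qrs_ms=float(sub["qrs_ms"].mean()),
        mean_qt_ms=float(qt.mean()),
        mean_qtc_ms=float(np.mean(qtc)),
        n_beats=int(len(sub)),
    )
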