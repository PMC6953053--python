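"""Ventricular premature beat (VPB) labelling.

A beat is a VPB when it (a) deviates in morphology — R amplitude or QRS
duration — from the reference formed by preceding non-VPB beats, (b) occurs
prematurely relative to the reference RR, and (c) lacks a preceding P wave or
shows a shortened PR interval.  The reference is a running median over the
last ``reference_window`` sinus-labelled beats (window 1 reproduces the
literal previous-beat rule).  Classification is causal: a beat's label
depends only on beats before it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ClassifierConfig", "classify_beats", "reference_profile"]


@dataclass
class ClassifierConfig:
    morph_dev_frac: float = 0.20    # min relative deviation in R amp OR QRS width
    prematurity_frac: float = 0.80  # VPB iff rr < prematurity_frac * ref RR
    pr_short_frac: float = 0.75     # shortened PR iff pr < pr_short_frac * ref PR
    reference_window: int = 10      # running-median span (preceding sinus beats)
    criterion_mode: str = "and"     # "and": morphology AND prematurity; "or": either

    def __post_init__(self) -> None:
        for name in ("morph_dev_frac", "prematurity_frac", "pr_short_frac"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.reference_window < 1:
            raise ValueError("reference_window must be >= 1")
        if self.criterion_mode not in ("and", "or"):
            raise ValueError("criterion_mode must be 'and' or 'or'")


def _median(values: list[float]) -> float:
    vals = [v for v in values if not np.isnan(v)]
    return float(np.median(vals)) if vals else np.nan


def reference_profile(
    beats: pd.DataFrame,
    upto_index: int,
    config: ClassifierConfig | None = None,
    labels: np.ndarray | None = None,
) -> tuple[float, float, float, float]:
    """Running-median reference (r_amplitude, qrs, rr, pr) before a beat.

    Medians are taken over the last ``reference_window`` beats strictly
    before ``upto_index`` that are labelled sinus (``labels`` overrides the
    table's own label column, which lets the classifier pass its in-progress
    labels).  Raises ``ValueError`` with fewer than 3 preceding sinus beats.
    """
    cfg = config or ClassifierConfig()
    if labels is None:
        labels = beats["label"].to_numpy()
    idx = [i for i in range(upto_index) if labels[i] == "sinus"]
    if len(idx) < 3:
        raise ValueError("need >= 3 preceding sinus beats for a reference")
    idx = idx[-cfg.reference_window:]
    sub = beats.iloc[idx]
    return (
        _median(list(sub["r_amplitude_mv"])),
        _median(list(sub["qrs_ms"])),
        _median(list(sub["rr_ms"])),
        _median(list(sub["pr_ms"])),
    )


def classify_beats(beats: pd.DataFrame, config: ClassifierConfig | None = None) -> pd.DataFrame:
    """Label every beat ``sinus`` or ``vpb``; adds a ``bootstrap`` flag column.

    The first ``reference_window`` beats are provisionally sinus (flagged) to
    seed the reference; raises ``ValueError`` when the table is too short to
    seed at all.
    """
    cfg = config or ClassifierConfig()
    n = len(beats)
    seed_n = max(cfg.reference_window, 3)
    if n <= seed_n:
        raise ValueError(f"need more than {seed_n} beats to seed the reference")

    labels = np.array(["sinus"] * n, dtype=object)
    bootstrap = np.zeros(n, dtype=bool)
    bootstrap[:seed_n] = True

    r_amp = beats["r_amplitude_mv"].to_numpy(dtype=float)
    qrs = beats["qrs_ms"].to_numpy(dtype=float)
    rr = beats["rr_ms"].to_numpy(dtype=float)
    pr = beats["pr_ms"].to_numpy(dtype=float)
    has_p = ~beats["p_onset"].isna().to_numpy()

    for i in range(seed_n, n):
        ref_amp, ref_qrs, ref_rr, ref_pr = reference_profile(beats, i, cfg, labels)
        morph = False
        if ref_amp and not np.isnan(ref_amp) and ref_amp != 0:
            morph |= abs(r_amp[i] - ref_amp) / abs(ref_amp) >= cfg.morph_dev_frac
        if ref_qrs and not np.isnan(ref_qrs) and ref_qrs != 0:
            morph |= abs(qrs[i] - ref_qrs) / ref_qrs >= cfg.morph_dev_frac
        premature = (
            not np.isnan(rr[i])
            and not np.isnan(ref_rr)
            and rr[i] < cfg.prematurity_frac * ref_rr
        )
        no_p_or_short_pr = (not has_p[i]) or (
            not np.isnan(pr[i])
            and not np.isnan(ref_pr)
            and pr[i] < cfg.pr_short_frac * ref_pr
        )
        if cfg.criterion_mode == "and":
            is_vpb = morph and premature and no_p_or_short_pr
        else:
            is_vpb = (morph or premature) and no_p_or_short_pr
        labels[i] = "vpb" if is_vpb else "sinus"

    out = beats.copy()
    out["label"] = labels
    out["bootstrap"] = bootstrap
    return out
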