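"""Time-window stratification, Table-1-style count tables, and group
comparisons.

Arrhythmia events are binned by onset time into post-intervention windows
(acute 0-15 min, 15-45 min, delayed 45 min-12 h; the 0-12 h row is always
their derived union, never independently tallied).  Per-group cells report
mean +/- sample SD; pairwise group contrasts use the two-sided Mann-Whitney
U test with significance at p <= 0.05 and no multiplicity adjustment (an
optional Holm adjustment is available).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "WindowScheme",
    "CountTable",
    "GroupComparison",
    "assign_windows",
    "build_count_table",
    "mann_whitney",
    "compare_all",
    "holm_adjust",
]

UNION_LABEL = "0-12h"
DEFAULT_WINDOWS = (
    ("0-15min", 0.0, 900.0),
    ("15-45min", 900.0, 2700.0),
    ("45min-12h", 2700.0, 43200.0),
)


@dataclass
class WindowScheme:
    """Ordered, non-overlapping half-open [start, end) windows in seconds
    post intervention, plus a derived union window covering all of them."""

    windows: tuple = DEFAULT_WINDOWS
    union_label: str = UNION_LABEL

    def __post_init__(self) -> None:
        w = sorted(self.windows, key=lambda t: t[1])
        for (la, a0, a1), (lb, b0, b1) in zip(w, w[1:]):
            if a1 > b0:
                raise ValueError(f"windows {la!r} and {lb!r} overlap")
        for la, a0, a1 in w:
            if a1 <= a0:
                raise ValueError(f"window {la!r} is empty or reversed")
        self.windows = tuple(w)

    @property
    def labels(self) -> list[str]:
        return [w[0] for w in self.windows]

    @property
    def span(self) -> tuple:
        return (self.windows[0][1], self.windows[-1][2])


def assign_windows(
    events: pd.DataFrame,
    intervention_time_s: float = 0.0,
    scheme: WindowScheme | None = None,
) -> pd.DataFrame:
    """Tag each event with the sub-window containing its onset time.

    ``events`` needs an ``onset_time_s`` column (seconds on the same clock as
    ``intervention_time_s``).  Events before the intervention are excluded
    with a warning; events after the last window end are silently excluded.
    The union window is never assigned here — it is derived when counting.
    """
    scheme = scheme or WindowScheme()
    rel = events["onset_time_s"].to_numpy(dtype=float) - intervention_time_s
    n_early = int((rel < scheme.span[0]).sum())
    if n_early:
        warnings.warn(f"{n_early} event(s) before the intervention excluded", stacklevel=2)
    out = events.copy()
    window = np.full(len(events), None, dtype=object)
    for label, start, end in scheme.windows:
        window[(rel >= start) & (rel < end)] = label
    out["window"] = window
    return out[out["window"].notna()].reset_index(drop=True)


@dataclass
class CountTable:
    """Per-animal, per-window, per-event-type counts with group structure.

    ``data`` is long-form with columns (animal_id, group, intervention,
    window, etype, count); the union window is always the sum of the
    sub-window rows (checked by :meth:`check_additivity`).
    """

    data: pd.DataFrame
    scheme: WindowScheme = field(default_factory=WindowScheme)

    def check_additivity(self, atol: float = 1e-9) -> bool:
        """Union-window value equals the sum over sub-windows for every
        (animal, intervention, etype)."""
        sub = self.data[self.data["window"] != self.scheme.union_label]
        uni = self.data[self.data["window"] == self.scheme.union_label]
        keys = ["animal_id", "intervention", "etype"]
        s = sub.groupby(keys)["count"].sum()
        u = uni.set_index(keys)["count"]
        s, u = s.align(u, fill_value=0.0)
        return bool(np.allclose(s, u, atol=atol))

    def group_summary(self, flag_single: bool = True) -> pd.DataFrame:
        """Mean and sample SD (n-1) per (group, intervention, window, etype).

        A single-animal group gets SD 0 with ``single_animal=True``.
        """
        keys = ["group", "intervention", "window", "etype"]
        rows = []
        for key, sub in self.data.groupby(keys):
            vals = sub["count"].to_numpy(dtype=float)
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
            rows.append(
                dict(
                    zip(keys, key),
                    mean=float(vals.mean()),
                    sd=sd,
                    n=int(vals.size),
                    single_animal=bool(vals.size == 1) if flag_single else False,
                )
            )
        return pd.DataFrame(rows)


def build_count_table(
    tagged_events: pd.DataFrame,
    animals: pd.DataFrame,
    intervention: str = "second_ligation",
    scheme: WindowScheme | None = None,
    merge_bg_tg: bool = True,
    mode: str = "exclusive",
) -> CountTable:
    """Count events per animal, window and type, zero-filling empty cells.

    ``tagged_events`` columns: animal_id, etype, window (from
    :func:`assign_windows`), n_vpb; ``animals`` columns: animal_id, group
    (every animal appears, with zero counts if event-free).  Bigeminy and
    trigeminy are merged into ``bg_tg`` to mirror published tallies.  In
    ``mode="inclusive"`` the ``vpb`` row counts all VPB beats (pattern
    members included) instead of isolated-VPB events.
    """
    scheme = scheme or WindowScheme()
    ev = tagged_events.copy()
    if merge_bg_tg:
        ev["etype"] = ev["etype"].replace({"bigeminy": "bg_tg", "trigeminy": "bg_tg"})
        etypes = ["vpb_isolated", "bg_tg", "salvo", "vt"]
    else:
        etypes = ["vpb_isolated", "bigeminy", "trigeminy", "salvo", "vt"]

    if mode == "inclusive" and "n_vpb" in ev.columns:
        ev["weight"] = np.where(ev["etype"] == "vpb_isolated", ev["n_vpb"], 1)
        # pattern members also count toward the VPB row
        extra = ev[ev["etype"] != "vpb_isolated"].copy()
        extra["etype"] = "vpb_isolated"
        extra["weight"] = extra["n_vpb"]
        ev = pd.concat([ev, extra], ignore_index=True)
    else:
        ev["weight"] = 1

    counts = (
        ev.groupby(["animal_id", "window", "etype"])["weight"].sum().rename("count")
    )
    idx = pd.MultiIndex.from_product(
        [animals["animal_id"], scheme.labels, etypes],
        names=["animal_id", "window", "etype"],
    )
    counts = counts.reindex(idx, fill_value=0).reset_index()
    union = (
        counts.groupby(["animal_id", "etype"], as_index=False)["count"]
        .sum()
        .assign(window=scheme.union_label)
    )
    full = pd.concat([counts, union], ignore_index=True)
    full = full.merge(animals[["animal_id", "group"]], on="animal_id")
    full["intervention"] = intervention
    cols = ["animal_id", "group", "intervention", "window", "etype", "count"]
    return CountTable(data=full[cols], scheme=scheme)


@dataclass(frozen=True)
class GroupComparison:
    """One pairwise Mann-Whitney contrast (two-sided, alpha = 0.05)."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    significant: bool
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    method: str
    etype: str = ""
    window: str = ""
    intervention: str = ""


def mann_whitney(a, b, etype: str = "", window: str = "", intervention: str = "") -> GroupComparison:
    """Two-sided Mann-Whitney U test between two samples of counts.

    Uses the exact null distribution when n_a + n_b <= 12 and the pooled
    sample is tie-free, otherwise the normal approximation with continuity
    and tie correction.  Significance at p <= 0.05.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= 12 and tie_free) else "asymptotic"
    res = sstats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(min(1.0, res.pvalue))
    sd_a = float(np.std(a, ddof=1))
    sd_b = float(np.std(b, ddof=1))
    return GroupComparison(
        group_a="a", group_b="b", n_a=int(a.size), n_b=int(b.size),
        u_statistic=float(res.statistic), p_value=p, significant=p <= 0.05,
        mean_a=float(a.mean()), sd_a=sd_a, mean_b=float(b.mean()), sd_b=sd_b,
        method=method, etype=etype, window=window, intervention=intervention,
    )


def compare_all(table: CountTable, groups: tuple = ("URI", "SRI", "MIC")) -> pd.DataFrame:
    """All pairwise group contrasts for every (etype, window, intervention).

    No multiple-testing correction is applied (raw p <= 0.05); use
    :func:`holm_adjust` on the result for a corrected view.
    """
    df = table.data
    rows = []
    for (etype, window, intervention), sub in df.groupby(["etype", "window", "intervention"]):
        for ga, gb in itertools.combinations(groups, 2):
            a = sub.loc[sub["group"] == ga, "count"].to_numpy(dtype=float)
            b = sub.loc[sub["group"] == gb, "count"].to_numpy(dtype=float)
            if a.size < 2 or b.size < 2:
                continue
            cmp_ = mann_whitney(a, b, etype=etype, window=window, intervention=intervention)
            d = cmp_.__dict__.copy()
            d["group_a"], d["group_b"] = ga, gb
            rows.append(d)
    return pd.DataFrame(rows)


def holm_adjust(comparisons: pd.DataFrame) -> pd.DataFrame:
    """Holm step-down adjusted p values (optional, off the main path)."""
    out = comparisons.copy()
    p = out["p_value"].to_numpy(dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    out["p_holm"] = adj
    out["significant_holm"] = out["p_holm"] <= 0.05
    return out
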