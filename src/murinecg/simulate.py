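"""Synthetic murine telemetry ECG with known ground truth.

The generator emits (a) beat-label sequences with injected arrhythmia events
(isolated VPB, bigeminy, trigeminy, salvo, VT), (b) voltage traces built from
per-beat waveform templates, and (c) overdispersed per-animal event-count
tables with group structure.  Everything is seeded and deterministic, so the
downstream detector/classifier/pattern stages can be scored against exact
truth.

Waveform model
--------------
Each beat is a sum of raised-cosine (Hann) bumps, one per wave (P, Q, R, S, T)
plus a wide ST bump between the end of S and the end of T.  Hann bumps have
compact support, so every fiducial (P onset, Q onset, R peak, S end, T end)
is an exact sample position, unlike Gaussian templates whose tails never
reach zero.  Infarction-stage morphology is expressed through the ST offset,
T-amplitude scale and Q/S depths of a :class:`MorphologyStage`.

Ectopic (VPB) beats are rendered without a P wave, with the QRS time-scaled
by ``vpb_qrs_scale`` and amplitude-scaled, and occur prematurely at
``prematurity_factor`` of the sinus RR; the sinus beat after an isolated VPB
carries a full compensatory pause (RR scaled by ``2 - prematurity_factor``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .delineate import EcgTrace, _region_end, _region_start, _t_region_end
from .patterns import RhythmEvent

__all__ = [
    "MorphologyStage",
    "ArrhythmiaSpec",
    "SimulationTruth",
    "STAGES",
    "CapacityError",
    "generate_label_sequence",
    "synthesize_trace",
    "simulate_count_table",
]


class CapacityError(ValueError):
    """Requested events cannot be placed in the available number of beats."""


@dataclass(frozen=True)
class MorphologyStage:
    """Stage-dependent waveform parameters.

    ``st_offset_mv`` shifts the ST segment relative to the isoelectric line
    (positive = elevation); ``t_amplitude_scale`` multiplies the T wave
    (hyperacute T during occlusion); ``q_depth_mv``/``s_depth_mv`` are the
    (non-positive) Q and S amplitudes.
    """

    stage_id: str
    st_offset_mv: float
    t_amplitude_scale: float
    q_depth_mv: float
    s_depth_mv: float

    def __post_init__(self) -> None:
        if self.q_depth_mv > 0 or self.s_depth_mv > 0:
            raise ValueError("q_depth_mv and s_depth_mv must be <= 0")


#: Morphology presets for the infarction/reinfarction time course:
#: acute occlusion shows ST elevation with hyperacute T; reperfusion and the
#: 12 h post-reinfarction stage develop deep Q waves; 7 days after the first
#: ischemia-reperfusion the trace shows deep S waves with ST depression.
STAGES: dict[str, MorphologyStage] = {
    s.stage_id: s
    for s in (
        MorphologyStage("baseline", 0.00, 1.0, -0.05, -0.10),
        MorphologyStage("occlusion", 0.30, 1.8, -0.05, -0.10),
        MorphologyStage("reperfusion", 0.00, 1.1, -0.20, -0.10),
        MorphologyStage("day7_prereinfarct", -0.15, 1.0, -0.10, -0.40),
        MorphologyStage("reinfarct_acute", 0.35, 1.5, -0.10, -0.25),
        MorphologyStage("reinfarct_12h", 0.20, 1.2, -0.25, -0.15),
    )
}


@dataclass
class ArrhythmiaSpec:
    """What to inject into a label sequence.

    ``vpb_rate`` is the expected number of *isolated* VPBs per minute
    (Poisson-distributed, converted at the nominal 600 beats/min);
    ``vt_run_lengths`` (each >= 4) and ``salvo_run_lengths`` (each 2 or 3)
    give the exact run lengths of the injected VT and salvo events;
    bigeminy/trigeminy events are injected in their minimal 3-VPB form.
    ``prematurity_factor`` is the VPB coupling interval as a fraction of the
    sinus RR and ``vpb_qrs_scale`` widens the ectopic QRS.
    """

    vpb_rate: float = 0.0
    n_bigeminy: int = 0
    n_trigeminy: int = 0
    vt_run_lengths: tuple = ()
    salvo_run_lengths: tuple = ()
    prematurity_factor: float = 0.65
    vpb_qrs_scale: float = 1.6
    vpb_r_scale: float = 1.3

    def __post_init__(self) -> None:
        self.vt_run_lengths = tuple(int(v) for v in self.vt_run_lengths)
        self.salvo_run_lengths = tuple(int(v) for v in self.salvo_run_lengths)
        if self.vpb_rate < 0:
            raise ValueError("vpb_rate must be >= 0")
        if self.n_bigeminy < 0 or self.n_trigeminy < 0:
            raise ValueError("event counts must be >= 0")
        if any(v < 4 for v in self.vt_run_lengths):
            raise ValueError("every VT run length must be >= 4")
        if any(v not in (2, 3) for v in self.salvo_run_lengths):
            raise ValueError("every salvo run length must be 2 or 3")
        if not 0.0 < self.prematurity_factor < 1.0:
            raise ValueError("prematurity_factor must be in (0, 1)")
        if self.vpb_qrs_scale <= 1.0:
            raise ValueError("vpb_qrs_scale must be > 1")

    @property
    def n_vt(self) -> int:
        return len(self.vt_run_lengths)

    @property
    def n_salvo(self) -> int:
        return len(self.salvo_run_lengths)


@dataclass
class SimulationTruth:
    """Ground truth emitted by the generator.

    ``labels`` is the per-beat sequence ("sinus"/"vpb"); ``events`` the
    injected :class:`RhythmEvent` list (beat spans, sorted by onset);
    ``fiducials`` the exact per-beat template landmarks (filled by
    :func:`synthesize_trace`).  ``spec`` records the rendering parameters.
    """

    labels: np.ndarray
    events: list[RhythmEvent]
    spec: ArrhythmiaSpec
    fiducials: pd.DataFrame | None = None

    @property
    def n_beats(self) -> int:
        return int(self.labels.size)


# beats occupied by each minimal alternation pattern: V N V N V / V N N V N N V
_PATTERN_SPAN = {"bigeminy": 5, "trigeminy": 7}


def generate_label_sequence(
    n_beats: int,
    spec: ArrhythmiaSpec,
    seed: int,
    min_gap: int = 3,
    lead_in: int = 10,
) -> SimulationTruth:
    """Place the requested events into ``n_beats`` beats, all else sinus.

    Events are separated by at least ``min_gap`` sinus beats (3 by default:
    a 2-beat gap would let two neighbouring events read as one longer
    alternation pattern) and preceded by ``lead_in`` sinus beats so the beat
    classifier can bootstrap its reference profile.  Raises
    :class:`CapacityError` when the requested events cannot fit.
    Deterministic for a fixed seed.
    """
    if n_beats <= 0:
        raise ValueError("n_beats must be positive")
    rng = np.random.default_rng(seed)

    events: list[tuple[str, int, int]] = []  # (etype, span, n_vpb)
    for ln in spec.vt_run_lengths:
        events.append(("vt", ln, ln))
    for ln in spec.salvo_run_lengths:
        events.append(("salvo", ln, ln))
    events += [("bigeminy", 5, 3)] * spec.n_bigeminy
    events += [("trigeminy", 7, 3)] * spec.n_trigeminy
    n_isolated = int(rng.poisson(spec.vpb_rate * n_beats / 600.0))
    events += [("vpb_isolated", 1, 1)] * n_isolated

    k = len(events)
    span_total = sum(s for _, s, _ in events)
    required = span_total + (lead_in if k else 0) + max(0, k - 1) * min_gap
    if required > n_beats:
        raise CapacityError(
            f"{k} events spanning {span_total} beats need >= {required} beats "
            f"(lead-in {lead_in}, gap {min_gap}); got {n_beats}"
        )

    order = rng.permutation(k)
    events = [events[i] for i in order]
    slack = n_beats - required
    # distribute the spare sinus beats uniformly over the k+1 gaps
    extra = rng.multinomial(slack, np.full(k + 1, 1.0 / (k + 1))) if k else [0]

    labels = np.full(n_beats, "sinus", dtype=object)
    placed: list[RhythmEvent] = []
    pos = (lead_in if k else 0) + int(extra[0])
    for i, (etype, span, n_vpb) in enumerate(events):
        if etype in _PATTERN_SPAN:
            offs = range(0, span, 2) if etype == "bigeminy" else range(0, span, 3)
            for o in offs:
                labels[pos + o] = "vpb"
        else:
            labels[pos: pos + span] = "vpb"
        placed.append(RhythmEvent(etype, pos, pos + span - 1, n_vpb))
        pos += span + min_gap + int(extra[i + 1])
    placed.sort(key=lambda e: e.start_beat)
    return SimulationTruth(labels=labels, events=placed, spec=spec)


# ---------------------------------------------------------------------------
# waveform templates


def _hann_bump(t_ms: np.ndarray, center: float, half_width: float, amp: float) -> np.ndarray:
    """Raised-cosine bump with compact support [center-half_width, center+half_width]."""
    d = t_ms - center
    inside = np.abs(d) < half_width
    out = np.zeros_like(t_ms)
    out[inside] = amp * 0.5 * (1.0 + np.cos(np.pi * d[inside] / half_width))
    return out


def _beat_bumps(stage: MorphologyStage, spec: ArrhythmiaSpec, ectopic: bool):
    """(center, half_width, amplitude) of each bump, in ms relative to R."""
    if not ectopic:
        bumps = [
            ("p", -28.0, 9.0, 0.15),
            ("q", -6.0, 4.5, stage.q_depth_mv),
            ("r", 0.0, 6.0, 1.0),
            ("s", 6.0, 4.5, stage.s_depth_mv),
            ("st", 28.75, 14.25, stage.st_offset_mv),  # support [14.5, 43]
            ("t", 28.0, 15.0, 0.25 * stage.t_amplitude_scale),
        ]
    else:
        g, a = spec.vpb_qrs_scale, spec.vpb_r_scale
        bumps = [
            ("q", -6.0 * g, 4.5 * g, stage.q_depth_mv * a),
            ("r", 0.0, 6.0 * g, 1.0 * a),
            ("s", 6.0 * g, 4.5 * g, stage.s_depth_mv * a),
            ("t", 30.0, 9.0, 0.30),  # compact T so in-run beats never overlap
        ]
    return bumps


#: amplitude floor defining wave onset/offset landmarks (mV); matches the
#: noiseless delineation threshold so truth and measurement share one
#: definition of "where the wave departs the isoelectric line".
LANDMARK_EPS_MV = 0.01


def _crossing_halfspan(half_width: float, amp: float, eps: float) -> float | None:
    """Distance from a Hann bump's centre at which |bump| crosses ``eps``."""
    a = abs(amp)
    if a <= eps:
        return None
    c = np.clip(2.0 * eps / a - 1.0, -1.0, 1.0)
    return half_width * math.acos(c) / math.pi


def _template(stage, spec, ectopic, fs_hz):
    """Render one beat template on the integer sample grid.

    Returns (waveform, r_index, landmarks): landmarks are sample offsets
    relative to the R peak at the points where the template departs from /
    returns to within ``LANDMARK_EPS_MV`` of the isoelectric line (onsets =
    first supra-threshold sample, ends = one past the last; half-open).
    """
    bumps = _beat_bumps(stage, spec, ectopic)
    by = {name: (c, w, a) for name, c, w, a in bumps}
    lo = min(c - w for _, c, w, _ in bumps) - 1.0
    hi = max(c + w for _, c, w, _ in bumps) + 1.0
    i0 = int(math.floor(lo * fs_hz / 1000.0))
    i1 = int(math.ceil(hi * fs_hz / 1000.0))
    idx = np.arange(i0, i1 + 1)
    t_ms = idx * 1000.0 / fs_hz
    wave = np.zeros_like(t_ms)
    for _, c, w, a in bumps:
        wave += _hann_bump(t_ms, c, w, a)

    # landmarks are measured on the summed template with the same region
    # rules the delineator uses, so truth and measurement share one
    # definition even when waves partially cancel (e.g. ST depression vs T)
    eps = LANDMARK_EPS_MV
    k = 3
    supra = np.abs(wave) > eps
    r_idx = -i0
    q_onset = _region_start(supra, r_idx, k)
    s_end = _region_end(supra, r_idx, k)
    t_end = _t_region_end(
        supra, wave, 0.0, s_end, supra.size - 1, k,
        min_width=max(1, int(round(3.0 * fs_hz / 1000.0))),
        min_peak=1.5 * eps,
    )
    if "p" in by:
        pc = by["p"][0]
        p_onset = _region_start(supra, int(round(pc * fs_hz / 1000.0)) - i0, k)
    else:
        p_onset = None
    landmarks = {
        "q_onset": q_onset + i0,
        "s_end": s_end + i0,
        "t_end": None if math.isnan(t_end) else int(t_end) + i0,
        "p_onset": None if p_onset is None else p_onset + i0,
    }
    return wave, -i0, landmarks


def synthesize_trace(
    truth: SimulationTruth,
    stage: MorphologyStage | str = "baseline",
    hr_bpm: float = 600.0,
    fs_hz: float = 1000.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    baseline_wander_mv: float = 0.0,
    t0_s: float = 0.0,
) -> tuple[EcgTrace, pd.DataFrame]:
    """Render a voltage trace for a label sequence; returns (trace, fiducials).

    The default noise (0.02 mV against a 1 mV R wave, signal RMS ~0.2 mV)
    corresponds to an SNR of roughly 20 dB.  ``baseline_wander_mv`` adds a
    0.5 Hz respiratory-like sine (off by default).  The fiducial table holds
    the exact template landmarks per beat and is also attached to
    ``truth.fiducials``.
    """
    if isinstance(stage, str):
        try:
            stage = STAGES[stage]
        except KeyError:
            raise ValueError(f"unknown stage {stage!r}") from None
    if not 300.0 <= hr_bpm <= 900.0:
        raise ValueError("hr_bpm must be in the murine-plausible 300-900 range")
    if fs_hz < 500.0:
        raise ValueError("fs_hz must be >= 500")

    spec = truth.spec
    rr = 60.0 / hr_bpm * fs_hz  # samples
    labels = truth.labels
    n = labels.size

    # R-peak times: VPBs arrive prematurely; a sinus beat following a VPB
    # carries the compensatory pause.
    r_samples = np.empty(n)
    r_samples[0] = 0.3 * fs_hz
    for i in range(1, n):
        if labels[i] == "vpb":
            step = spec.prematurity_factor * rr
        elif labels[i - 1] == "vpb":
            step = (2.0 - spec.prematurity_factor) * rr
        else:
            step = rr
        r_samples[i] = r_samples[i - 1] + step
    r_samples = np.round(r_samples).astype(int)

    sin_wave, sin_r, sin_marks = _template(stage, spec, False, fs_hz)
    vpb_wave, vpb_r, vpb_marks = _template(stage, spec, True, fs_hz)

    n_samples = int(r_samples[-1] + max(sin_wave.size, vpb_wave.size) + 0.3 * fs_hz)
    x = np.zeros(n_samples)
    rows = []
    for i, r in enumerate(r_samples):
        ect = labels[i] == "vpb"
        wave, r_off, marks = (vpb_wave, vpb_r, vpb_marks) if ect else (sin_wave, sin_r, sin_marks)
        a = r - r_off
        x[a: a + wave.size] += wave
        rows.append(
            dict(
                beat=i,
                label=labels[i],
                p_onset=np.nan if marks["p_onset"] is None else float(r + marks["p_onset"]),
                q_onset=float(r + marks["q_onset"]),
                r_peak=int(r),
                s_end=float(r + marks["s_end"]),
                t_end=float(r + marks["t_end"]),
            )
        )

    rng = np.random.default_rng(seed)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=n_samples)
    if baseline_wander_mv > 0:
        t = np.arange(n_samples) / fs_hz
        x = x + baseline_wander_mv * np.sin(2 * np.pi * 0.5 * t + rng.uniform(0, 2 * np.pi))

    fiducials = pd.DataFrame(rows)
    truth.fiducials = fiducials
    meta = dict(stage=stage.stage_id, hr_bpm=hr_bpm, noise_sd=noise_sd, seed=seed)
    trace = EcgTrace(samples=x, fs_hz=fs_hz, t0_s=t0_s, meta=meta)

    # stamp event onset times now that beat times exist
    t_beat = t0_s + r_samples / fs_hz
    truth.events = [replace(e, onset_time_s=float(t_beat[e.start_beat])) for e in truth.events]
    return trace, fiducials


def simulate_count_table(
    group_means: dict,
    n_animals: dict,
    dispersion: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-animal event counts per group and cell (Table-1-shaped).

    ``group_means`` maps group -> {cell_label: mean count}; cells with mean 0
    yield exact zeros.  Counts follow a negative binomial with the given mean
    and dispersion ``k`` (variance = m + m^2/k), matching the overdispersion
    of telemetry arrhythmia counts, whose SDs typically exceed their means.
    Returns a long DataFrame (animal_id, group, cell, count), reproducible
    for a fixed seed.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for group in group_means:
        n = int(n_animals[group])
        if n < 2:
            raise ValueError(f"group {group!r} needs >= 2 animals")
        for a in range(n):
            animal = f"{group}_{a + 1:02d}"
            for cell, mean in group_means[group].items():
                if mean < 0:
                    raise ValueError("means must be >= 0")
                if mean == 0:
                    count = 0
                else:
                    p = dispersion / (dispersion + mean)
                    count = int(rng.negative_binomial(dispersion, p))
                rows.append(dict(animal_id=animal, group=group, cell=cell, count=count))
    return pd.DataFrame(rows)
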