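"""R-peak detection and per-beat fiducial delineation for murine single-lead ECG.

Murine telemetry ECG runs at 300--900 bpm, so the detector uses a short
(30 ms) refractory period and a 5--60 Hz band for QRS energy.  Fiducials
(start of P, start of Q, R peak, end of S, end of T) are located by a
threshold-crossing search around each R peak; onsets are the first sample of
the supra-threshold region containing the wave, ends are the first sample
after it (half-open [onset, end) convention, 0-based sample indices).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "EcgTrace",
    "DetectorConfig",
    "DelineationConfig",
    "detect_r_peaks",
    "delineate_beats",
    "compute_intervals",
    "annotate_trace",
    "BEAT_COLUMNS",
]

#: Columns of the per-beat annotation table.  Fiducials are sample indices
#: (NaN when absent), intervals are milliseconds, ``r_amplitude_mv`` is the
#: R-peak voltage above the isoelectric baseline and ``label`` is one of
#: ``{"sinus", "vpb", "unclassified"}``.
BEAT_COLUMNS = [
    "p_onset", "q_onset", "r_peak", "s_end", "t_end",
    "rr_ms", "pr_ms", "qrs_ms", "qt_ms",
    "r_amplitude_mv", "r_time_s", "label",
]


@dataclass
class EcgTrace:
    """Uniformly sampled single-lead voltage series.

    Parameters
    ----------
    samples : ndarray
        Voltage in mV.
    fs_hz : float
        Sampling rate in Hz.
    t0_s : float
        Recording start offset in seconds relative to the intervention
        (e.g. LAD-ligation) time; 0 means recording starts at intervention.
    """

    samples: np.ndarray
    fs_hz: float
    t0_s: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.samples.size == 0:
            raise ValueError("trace has no samples")
        if np.isnan(self.samples).any():
            raise ValueError("trace contains NaN after cleaning")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz

    def time_s(self) -> np.ndarray:
        """Time axis in seconds relative to the intervention."""
        return self.t0_s + np.arange(self.samples.size) / self.fs_hz


@dataclass
class DetectorConfig:
    """Pan--Tompkins-style R detector settings (murine defaults)."""

    band_hz: tuple = (5.0, 60.0)
    refractory_ms: float = 30.0
    integration_ms: float = 15.0
    threshold_frac: float = 0.25   # of the 99.5th percentile of QRS energy
    min_duration_s: float = 2.0


@dataclass
class DelineationConfig:
    """Threshold-crossing fiducial search settings.

    ``eps_mv`` is the noiseless amplitude floor; the working threshold is
    ``max(eps_mv, noise_mult * noise_sd_est)``.  ``k_consecutive`` sub- or
    supra-threshold samples are required to open/close a wave region, which
    makes the search robust to single-sample zero crossings inside the QRS.
    Search windows are scaled for mice (QRS ~20 ms, QT ~50 ms at 600 bpm).
    """

    eps_mv: float = 0.01
    noise_mult: float = 3.0
    k_consecutive: int = 3
    q_window_ms: float = 45.0   # Q onset searched within this span before R
    s_window_ms: float = 45.0   # S end searched within this span after R
    t_frac_of_rr: float = 0.6   # T end searched up to this fraction of RR after R
    p_window_ms: float = 40.0   # P searched within this span before Q onset
    t_min_width_ms: float = 3.0     # minimum supra width for a T region
    t_min_peak_mult: float = 1.5    # minimum T peak as a multiple of the threshold


def _bandpass(x: np.ndarray, fs: float, band: tuple) -> np.ndarray:
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _noise_sd(x: np.ndarray) -> float:
    """Robust noise estimate from the second difference (MAD-based).

    Smooth ECG waveforms have small curvature per sample, so the second
    difference is noise-dominated; for white noise its SD is sqrt(6) times
    the noise SD.
    """
    d = np.diff(x, n=2)
    if d.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d))) / np.sqrt(6.0)


def _baseline(x: np.ndarray, noise_sd: float) -> float:
    """Isoelectric level as the mode of the voltage histogram.

    At murine rates the waveform occupies most of the cycle, so the median is
    biased; the isoelectric samples are still the single most common voltage.
    """
    width = max(noise_sd / 2.0, 2e-3)
    lo, hi = np.percentile(x, [1, 99])
    if hi <= lo:
        return float(lo)
    nbins = max(10, int(np.ceil((hi - lo) / width)))
    counts, edges = np.histogram(x, bins=nbins, range=(lo, hi))
    k = int(np.argmax(counts))
    a, b = edges[max(0, k - 1)], edges[min(nbins, k + 2)]
    sel = x[(x >= a) & (x <= b)]
    return float(np.median(sel)) if sel.size else float(0.5 * (a + b))


def detect_r_peaks(trace: EcgTrace, config: DetectorConfig | None = None) -> np.ndarray:
    """Detect R peaks; returns strictly increasing sample indices.

    An all-flat trace yields an empty array with a warning; a trace shorter
    than ``config.min_duration_s`` raises ``ValueError``.
    """
    cfg = config or DetectorConfig()
    if trace.duration_s < cfg.min_duration_s:
        raise ValueError(
            f"trace of {trace.duration_s:.2f} s is shorter than the "
            f"{cfg.min_duration_s} s minimum"
        )
    x = trace.samples
    if np.ptp(x) == 0.0:
        warnings.warn("flat trace: no R peaks detected", stacklevel=2)
        return np.array([], dtype=int)

    fs = trace.fs_hz
    filt = _bandpass(x, fs, cfg.band_hz)
    energy = np.gradient(filt) ** 2
    win = max(1, int(round(cfg.integration_ms * fs / 1000.0)))
    energy = np.convolve(energy, np.ones(win) / win, mode="same")

    height = cfg.threshold_frac * np.percentile(energy, 99.5)
    if height <= 0:
        warnings.warn("no QRS energy above threshold", stacklevel=2)
        return np.array([], dtype=int)
    distance = max(1, int(round(cfg.refractory_ms * fs / 1000.0)))
    locs, _ = sps.find_peaks(energy, height=height, distance=distance)

    # refine each energy peak to the local extremum of the band-passed signal
    half = max(1, int(round(10 * fs / 1000.0)))
    r_peaks = []
    for loc in locs:
        a, b = max(0, loc - half), min(x.size, loc + half + 1)
        r_peaks.append(a + int(np.argmax(filt[a:b])))
    r_peaks = np.unique(np.asarray(r_peaks, dtype=int))
    # unique() may merge refinements closer than the refractory period
    if r_peaks.size > 1:
        keep = np.concatenate([[True], np.diff(r_peaks) >= distance])
        r_peaks = r_peaks[keep]
    return r_peaks


def _region_start(supra: np.ndarray, end_idx: int, k: int) -> int:
    """Walk left from ``end_idx`` to the start of its supra-threshold region,
    tolerating gaps shorter than ``k`` samples."""
    i = end_idx
    gap = 0
    start = end_idx
    while i >= 0:
        if supra[i]:
            start = i
            gap = 0
        else:
            gap += 1
            if gap >= k:
                break
        i -= 1
    return start


def _region_end(supra: np.ndarray, start_idx: int, k: int) -> int:
    """Walk right from ``start_idx`` to one past the end of its region."""
    i = start_idx
    gap = 0
    end = start_idx
    while i < supra.size:
        if supra[i]:
            end = i
            gap = 0
        else:
            gap += 1
            if gap >= k:
                break
        i += 1
    return end + 1


def _t_region_end(
    supra: np.ndarray,
    x: np.ndarray,
    baseline: float,
    start: int,
    stop: int,
    k: int,
    min_width: int,
    min_peak: float,
) -> float:
    """End of the T wave: first supra region after the post-QRS notch that is
    at least ``min_width`` samples wide with peak >= ``min_peak``; NaN if none.

    Shared by the delineator and the synthetic-truth landmark computation so
    both sides use one definition of "end of T".
    """
    j = start
    while j <= stop - k + 1 and not np.all(~supra[j: j + k]):
        j += 1
    while j <= stop - k + 1:
        if np.all(supra[j: j + k]):
            end = _region_end(supra, j, k)
            width = end - j
            peak = float(np.max(np.abs(x[j:end] - baseline))) if end > j else 0.0
            if width >= min_width and peak >= min_peak:
                return min(float(end), float(stop + 1))
            j = end + k
        else:
            j += 1
    return float("nan")


def delineate_beats(
    trace: EcgTrace,
    r_peaks: np.ndarray,
    config: DelineationConfig | None = None,
) -> pd.DataFrame:
    """Delineate one beat per R peak; returns a beat table (labels unclassified).

    ``p_onset`` is NaN when no P deflection exceeds the presence threshold in
    the P search window; ``t_end`` is NaN when no T wave is found (such beats
    are excluded from QT statistics downstream).
    """
    r_peaks = np.asarray(r_peaks, dtype=int)
    if r_peaks.size < 1:
        raise ValueError("need at least one R peak")
    cfg = config or DelineationConfig()
    x = trace.samples
    fs = trace.fs_hz
    noise = _noise_sd(x)
    baseline = _baseline(x, noise)
    thresh = max(cfg.eps_mv, cfg.noise_mult * noise)
    supra = np.abs(x - baseline) > thresh
    k = cfg.k_consecutive

    q_win = int(round(cfg.q_window_ms * fs / 1000.0))
    s_win = int(round(cfg.s_window_ms * fs / 1000.0))
    p_win = int(round(cfg.p_window_ms * fs / 1000.0))

    n = r_peaks.size

    # pass 1: QRS bounds (independent of neighbours)
    q_onsets = np.empty(n, dtype=int)
    s_ends = np.empty(n, dtype=int)
    for i, r in enumerate(r_peaks):
        lo = max(0, r - q_win)
        q_onsets[i] = max(lo, _region_start(supra, r, k))
        hi = min(x.size - 1, r + s_win)
        s_ends[i] = min(hi + 1, _region_end(supra, r, k))

    # pass 2: T end — end of the first supra run after the QRS (the ST-T
    # complex), searched up to a fraction of the beat's own (preceding) RR
    # and never into the next beat's QRS
    t_ends = np.full(n, np.nan)
    for i, r in enumerate(r_peaks):
        if i > 0:
            rr_samp = r - r_peaks[i - 1]
        elif n > 1:
            rr_samp = r_peaks[1] - r
        else:
            rr_samp = x.size - r
        t_stop = min(x.size - 1, r + int(round(cfg.t_frac_of_rr * rr_samp)))
        if i + 1 < n:
            t_stop = min(t_stop, q_onsets[i + 1] - 1)
        # cross the isoelectric notch first (>= k sub-threshold samples) so a
        # residual QRS tail after an underestimated S end is not taken for T,
        # then take the first qualifying supra region (wide enough and with a
        # real peak — rejects single-sample noise blips before the T wave)
        t_ends[i] = _t_region_end(
            supra, x, baseline, s_ends[i], t_stop, k,
            min_width=max(1, int(round(cfg.t_min_width_ms * fs / 1000.0))),
            min_peak=cfg.t_min_peak_mult * thresh,
        )

    # pass 3: P onset — last supra run before the QRS onset, never reaching
    # into the previous beat's T wave
    p_onsets = np.full(n, np.nan)
    for i in range(n):
        q_onset = q_onsets[i]
        p_lo = max(0, q_onset - p_win)
        if i > 0 and not np.isnan(t_ends[i - 1]):
            p_lo = max(p_lo, int(t_ends[i - 1]) + 1)
        j = q_onset - 1 - k
        while j >= p_lo:
            if supra[j] and np.all(supra[j: j + k]):
                start = _region_start(supra, j, k)
                if start >= p_lo:
                    p_onsets[i] = float(start)
                break
            j -= 1

    rows = [
        dict(
            p_onset=p_onsets[i],
            q_onset=float(q_onsets[i]),
            r_peak=int(r_peaks[i]),
            s_end=float(s_ends[i]),
            t_end=t_ends[i],
            r_amplitude_mv=float(x[r_peaks[i]] - baseline),
        )
        for i in range(n)
    ]
    beats = pd.DataFrame(rows)
    beats["label"] = "unclassified"
    return compute_intervals(beats, trace)


def compute_intervals(beats: pd.DataFrame, trace: EcgTrace) -> pd.DataFrame:
    """Fill rr_ms, pr_ms, qrs_ms, qt_ms (and r_time_s) from the fiducials.

    RR is measured from the previous beat's R peak, so the first beat has no
    RR; PR is absent for beats without a P onset.
    """
    beats = beats.copy()
    fs = trace.fs_hz
    ms = 1000.0 / fs
    r = beats["r_peak"].to_numpy(dtype=float)
    beats["rr_ms"] = np.concatenate([[np.nan], np.diff(r) * ms])
    beats["pr_ms"] = (beats["q_onset"] - beats["p_onset"]) * ms
    beats["qrs_ms"] = (beats["s_end"] - beats["q_onset"]) * ms
    beats["qt_ms"] = (beats["t_end"] - beats["q_onset"]) * ms
    beats["r_time_s"] = trace.t0_s + r / fs
    return beats[[c for c in BEAT_COLUMNS if c in beats.columns]]


def annotate_trace(
    trace: EcgTrace,
    detector: DetectorConfig | None = None,
    delineation: DelineationConfig | None = None,
) -> pd.DataFrame:
    """Convenience: detect R peaks and delineate in one call."""
    r_peaks = detect_r_peaks(trace, detector)
    if r_peaks.size == 0:
        return pd.DataFrame(columns=BEAT_COLUMNS)
    return delineate_beats(trace, r_peaks, delineation)
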