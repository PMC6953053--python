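# Methods

## Scope and model

`murinecg` quantifies ventricular arrhythmias in single-lead murine telemetry
ECG. The unit of analysis is the beat label sequence: each delineated beat is
either a normally conducted sinus beat or a ventricular premature beat (VPB),
and arrhythmia events are pattern matches on that sequence. Group-level
output is a per-animal count table over post-intervention time windows with
nonparametric pairwise contrasts.

## Synthetic ECG generator

### Beat labels and event placement

`generate_label_sequence` places the requested events (isolated VPBs at a
Poisson-distributed per-minute rate, bigeminy and trigeminy in their minimal
three-VPB form `V N V N V` / `V N N V N N V`, salvos of 2–3 beats, VT runs of
≥4 beats) into an otherwise sinus sequence, uniformly at random over the
feasible gaps. Events are separated by at least **3** sinus beats and preceded
by a 10-beat sinus lead-in. Three, not two: with a 2-beat gap two isolated
VPBs read as a trigeminy prefix and a 1- or 2-beat gap can extend an
alternation pattern, so the injected event list would no longer be the unique
parse of the label sequence. With the 3-beat guard the pattern grammar's
output equals the placement log exactly (tested over 100 seeds).

### Waveform model

Each beat is a sum of raised-cosine (Hann) bumps, one per wave. Hann bumps
have compact support, so landmark positions are well defined; Gaussian bumps
were rejected because their tails never reach zero and every "onset" would be
threshold-fuzzy. Sinus template (ms relative to R, amplitude mV):

| wave | centre | half-width | amplitude |
|------|--------|-----------|-----------|
| P | −28 | 9 | 0.15 |
| Q | −6 | 4.5 | stage `q_depth` (−0.05 baseline) |
| R | 0 | 6 | 1.0 |
| S | +6 | 4.5 | stage `s_depth` (−0.10 baseline) |
| ST | +28.75 | 14.25 | stage `st_offset` |
| T | +28 | 15 | 0.25 × stage `t_scale` |

The ST bump starts 4 ms after the S support ends, leaving an isoelectric
notch so the QRS end is identifiable even under ST displacement. Ectopic
(VPB) beats have no P wave, QRS time-scaled by `vpb_qrs_scale` (default 1.6)
and amplitude-scaled by 1.3, and a compact T (centre +30, half-width 9,
amplitude 0.30) chosen so that consecutive VPBs in a run never overlap.

Six morphology presets follow the infarction time course: `baseline`;
`occlusion` (ST +0.30 mV, hyperacute T ×1.8); `reperfusion` (Q deepened to
−0.20); `day7_prereinfarct` (deep S −0.40 with ST −0.15 depression);
`reinfarct_acute` (ST +0.35, T ×1.5); `reinfarct_12h` (Q −0.25, ST +0.20).
Amplitudes are arbitrary-but-consistent mV (telemetry lead conventions and
gains are device-specific); only their signs and relative changes carry
meaning.

### Timing

Defaults: 600 bpm (RR 100 ms), fs 1000 Hz, chosen so printed murine
QRS (~15–21 ms) and QTc (~50–70 ms) magnitudes are reproducible and the QTc
normalisation RR/100 is the identity at the default rate. VPBs arrive at a
coupling interval of `prematurity_factor` × RR (default 0.65); the sinus beat
after a VPB carries a full compensatory pause ((2 − 0.65) × RR), so a
bigeminy cycle spans exactly 2 RR. Consecutive VPBs in runs follow each other
at the coupling interval (the run is genuinely tachycardic).

Coupling 0.65 (not shorter) keeps the previous beat's T wave clear of the
next beat's QRS at the default rate; every inter-wave gap in any legal beat
sequence is ≥4 samples at 1 kHz, which the delineator's 3-sample region
hysteresis (below) relies on.

### Truth fiducials

Ground-truth landmarks are measured **numerically on the rendered isolated
beat template** with exactly the same region rules the delineator uses
(threshold 0.01 mV, 3-sample hysteresis, T = first qualifying post-QRS
region). One definition on both sides means a noiseless round trip is
sample-exact even where waves partially cancel (ST depression under the
T wave shifts the real crossing inward of any per-bump support edge).

### Noise

Additive white Gaussian noise, default SD 0.02 mV against a 1 mV R wave and
~0.2 mV signal RMS, i.e. SNR ≈ 20 dB — typical of a clean implanted
telemetry channel. Optional 0.5 Hz baseline wander (off by default). Not
emulated: electrode motion artefacts, muscle noise bursts, QRS morphology
drift, heart-rate variability, fusion beats, atrial ectopy, heart block. A
green recovery test therefore establishes correctness of the algorithm
chain under stationary noise, not detector performance on degraded field
recordings.

### Count-table simulator

Per-animal event counts are negative binomial with mean m and dispersion k
(variance m + m²/k). Published per-group SDs exceed their means throughout,
so Poisson noise would be badly underdispersed; the NB dispersion can be fit
from a printed mean ± SD as k = m²/(SD² − m).

## Delineation

R detection: zero-phase Butterworth band-pass 5–60 Hz, squared derivative,
15 ms moving-average integration, threshold at 0.25 × the 99.5th percentile
of the energy envelope, 30 ms refractory (a mouse at 900 bpm has RR ≈ 67 ms),
peak refined to the band-passed extremum. Flat traces return an empty list
with a warning; traces shorter than 2 s are rejected.

Fiducials are found on the raw trace relative to a baseline and threshold:

- **baseline** — mode of the voltage histogram, not the median: at murine
  rates the waveform occupies ~80 % of the cycle, so the median is biased off
  the isoelectric line; the isoelectric samples remain the most common value.
- **threshold** — max(0.01 mV, 3 × noise SD). Noise is estimated from the
  MAD of the second difference (÷√6), which smooth waveforms barely excite.
- **regions** — supra-threshold runs with 3-sample hysteresis
  (`k_consecutive`): a region opens/closes only on 3 consecutive samples,
  which bridges the 1-sample zero crossing inside the QRS and resists
  noise-induced splits.
- **QRS** — the region containing the R peak, bounded to ±45 ms.
- **T end** — the first post-QRS region after an isoelectric notch that is
  ≥3 ms wide with peak ≥1.5 × threshold, searched up to 0.6 × the preceding
  RR and never past the next beat's QRS onset. The notch requirement rejects
  residual QRS tails; the width/peak requirements reject noise blips. Beats
  with no qualifying region get `t_end = NaN` and are excluded from QT
  statistics.
- **P onset** — last qualifying region in the 40 ms before the QRS onset,
  never reaching into the previous beat's T wave (a premature beat's P window
  otherwise lands on the preceding T). Absent P ⇒ `p_onset = NaN`.

Conventions: 0-based sample indices, half-open [onset, end) intervals, RR
from the previous R peak (first beat has none), intervals in ms.

## VPB classification

The definition is conjunctive: morphology deviation AND prematurity AND the
conduction clause (no P, or PR < 0.75 × reference). Thresholds (20 %
morphology, 0.8 prematurity, 0.75 PR) are package defaults — the underlying
verbal definition carries no numbers — and are configurable, as is an
`"or"` mode joining morphology/prematurity disjunctively for users who read
the definition permissively. The reference is a running median over the last
10 preceding sinus-labelled beats (window 1 reproduces the literal
"preceding non-VPB complex" rule); the first 10 beats are provisionally
sinus and flagged `bootstrap`. Classification is causal: truncating the
recording never changes earlier labels.

## Rhythm-pattern grammar

Greedy left-to-right with precedence VT > salvo > trigeminy > bigeminy >
isolated VPB, maximal matches, each beat consumed at most once — so the four
tallies are disjoint, matching published tables that report them as separate
rows. "Repeated at least three times" for alternation patterns is read as
≥3 VPBs inside the pattern (minimum `V N V N V` / `V N N V N N V`);
`min_alternation_vpbs` raises that for stricter readings. Runs truncated by
the recording edge count if they meet their minimum length. No rate
criterion is applied to VT (none is defined for these models). The tally
helper merges bigeminy+trigeminy into one BG/TG category; the VPB row counts
isolated VPBs only by default (`mode="inclusive"` counts pattern members
too — published tables do not state which convention their software used).
Correctness is established against an independent regex-backtracking oracle
over every label sequence of length 14.

## Interval metrics

QTc = QT/√(RR/100) with both in ms — the murine normalisation to RR = 100 ms
(a human Bazett correction normalised to 1 s would be meaningless at 600
bpm). Per-beat QTc uses the RR preceding the measured beat (standard
convention; window-mean RR available via `rr_mode`). Timepoint summaries
average over sinus beats only by default, since ectopic QRS/QT distort the
means; beats without a measurable T are excluded. The default averaging
window is 60 s, configurable — the published protocol averaged "many
subsequent beats" without stating a duration.

## Windows and statistics

Windows are half-open [start, end) on event onset time relative to the
intervention: 0–15 min, 15–45 min, 45 min–12 h. The 0–12 h row is always the
derived union — computed as the sum of the sub-windows, never tallied
independently — which makes additivity a structural invariant
(`CountTable.check_additivity`). Events before the intervention are excluded
with a warning; an onset exactly at a boundary belongs to the later window.
Timing is taken from the intervention (ligation) time; a recording that
starts later sets `t0_s` accordingly.

Group cells report mean ± sample SD (n−1); single-animal groups report SD 0
with a flag. Pairwise contrasts use the two-sided Mann–Whitney U test: exact
null by enumeration when n₁+n₂ ≤ 12 and the pooled sample is tie-free,
otherwise the normal approximation with continuity and tie correction
(mid-ranks). Significance is raw p ≤ 0.05 with no multiplicity adjustment,
matching common practice in these studies; `holm_adjust` is provided for a
corrected view. Note the normal approximation's worst-case two-sided-p error
at n = 6+6 is ≈ 0.015 even with continuity correction; the exact route is
used automatically at these sizes.

## Known limitations

- Single-lead only; no ST-segment scoring for infarct staging (the stage
  presets are generative, not diagnostic).
- The classifier's bootstrap assumes the recording starts in sinus rhythm.
- Fiducial accuracy guarantees hold at fs ≥ 1000 Hz; at 500 Hz the 2-sample
  bound corresponds to 4 ms.
- The synthetic generator is a test harness, not a physiological model: no
  ionic/action-potential dynamics, no autonomic rate modulation, no lead
  geometry.
- Heart block and atrial arrhythmias are out of scope.
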