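import numpy as np
import pandas as pd
import pytest

import murinecg as m


@pytest.fixture(scope="session")
def mixed_spec():
    """An arrhythmia mix exercising every event type."""
    return m.ArrhythmiaSpec(
        vpb_rate=10.0,
        n_bigeminy=1,
        n_trigeminy=1,
        vt_run_lengths=(5,),
        salvo_run_lengths=(2, 3),
    )


@pytest.fixture(scope="session")
def noiseless_run(mixed_spec):
    """One noiseless 600-beat baseline trace with truth and annotations."""
    truth = m.generate_label_sequence(600, mixed_spec, seed=1)
    trace, fiducials = m.synthesize_trace(truth, stage="baseline", noise_sd=0.0, seed=1)
    r = m.detect_r_peaks(trace)
    beats = m.delineate_beats(trace, r)
    return truth, trace, fiducials, beats


def regular_beat_table(n=40, rr=100.0, qrs=20.0, qt=50.0, amp=1.0, fs=1000.0):
    """A perfectly regular synthetic sinus beat table (no trace behind it)."""
    r = np.arange(n) * rr * fs / 1000.0
    df = pd.DataFrame(
        dict(
            p_onset=r - 35,
            q_onset=r - 10,
            r_peak=r.astype(int),
            s_end=r - 10 + qrs,
            t_end=r - 10 + qt,
            rr_ms=np.concatenate([[np.nan], np.full(n - 1, rr)]),
            pr_ms=np.full(n, 25.0),
            qrs_ms=np.full(n, qrs),
            qt_ms=np.full(n, qt),
            r_amplitude_mv=np.full(n, amp),
            r_time_s=r / fs,
            label="unclassified",
        )
    )
    return df
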