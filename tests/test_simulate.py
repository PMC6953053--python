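import numpy as np
import pytest

import murinecg as m
from murinecg.simulate import CapacityError


class TestLabelGenerator:
    def test_all_zero_spec_is_pure_sinus(self):
        truth = m.generate_label_sequence(100, m.ArrhythmiaSpec(), seed=1)
        assert truth.n_beats == 100
        assert (truth.labels == "sinus").all()
        assert truth.events == []

    def test_single_vt_run_spans_five_vpb(self):
        spec = m.ArrhythmiaSpec(vt_run_lengths=(5,))
        truth = m.generate_label_sequence(50, spec, seed=7)
        assert len(truth.events) == 1
        (e,) = truth.events
        assert e.etype == "vt" and e.n_vpb == 5
        assert (truth.labels[e.start_beat: e.end_beat + 1] == "vpb").all()

    def test_capacity_error_when_events_cannot_fit(self):
        spec = m.ArrhythmiaSpec(vt_run_lengths=(10, 10, 10))
        with pytest.raises(CapacityError):
            m.generate_label_sequence(40, spec, seed=0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(vt_run_lengths=(3,)),          # VT must be >= 4 beats
            dict(salvo_run_lengths=(4,)),       # salvo is 2 or 3 beats
            dict(prematurity_factor=1.2),
            dict(vpb_qrs_scale=0.9),
            dict(vpb_rate=-1.0),
        ],
    )
    def test_spec_invariant_violations_raise(self, kwargs):
        with pytest.raises(ValueError):
            m.ArrhythmiaSpec(**kwargs)

    def test_deterministic_for_fixed_seed(self, mixed_spec):
        a = m.generate_label_sequence(500, mixed_spec, seed=3)
        b = m.generate_label_sequence(500, mixed_spec, seed=3)
        assert (a.labels == b.labels).all()
        assert a.events == b.events

    def test_pattern_detector_recovers_injected_events_100_seeds(self, mixed_spec):
        """The generator's placement log is the oracle: the rhythm-pattern
        scanner must reproduce it exactly for every seed."""
        for seed in range(100):
            truth = m.generate_label_sequence(900, mixed_spec, seed=seed)
            got = m.classify_patterns(truth.labels)
            want = truth.events
            assert [(e.etype, e.start_beat, e.end_beat, e.n_vpb) for e in got] == [
                (e.etype, e.start_beat, e.end_beat, e.n_vpb) for e in want
            ], f"seed {seed}"

    def test_event_labels_consistent_with_type(self, mixed_spec):
        truth = m.generate_label_sequence(900, mixed_spec, seed=11)
        for e in truth.events:
            seg = truth.labels[e.start_beat: e.end_beat + 1]
            assert (seg == "vpb").sum() == e.n_vpb
            if e.etype == "vt":
                assert e.n_vpb >= 4 and (seg == "vpb").all()
            if e.etype == "salvo":
                assert e.n_vpb in (2, 3) and (seg == "vpb").all()


class TestTraceSynthesis:
    def test_noiseless_sinus_rr_is_constant(self):
        truth = m.generate_label_sequence(100, m.ArrhythmiaSpec(), seed=2)
        trace, fid = m.synthesize_trace(truth, hr_bpm=600, fs_hz=1000, noise_sd=0.0, seed=2)
        rr = np.diff(fid["r_peak"].to_numpy())
        assert np.all(np.abs(rr - 100) <= 1)
        # and the detector sees the same constant rhythm
        det = np.diff(m.detect_r_peaks(trace))
        assert np.all(np.abs(det - 100) <= 1)

    def test_occlusion_elevates_st_segment(self):
        truth = m.generate_label_sequence(60, m.ArrhythmiaSpec(), seed=4)
        base, fid = m.synthesize_trace(truth, stage="baseline", noise_sd=0.0, seed=4)
        occl, _ = m.synthesize_trace(truth, stage="occlusion", noise_sd=0.0, seed=4)

        def mean_st(trace):
            vals = []
            for _, row in fid.iterrows():
                a, b = int(row.s_end), int(row.s_end) + 10
                vals.append(trace.samples[a:b].mean())
            return np.mean(vals)

        assert mean_st(occl) > mean_st(base)

    def test_vpb_qrs_width_scales_with_template(self):
        spec = m.ArrhythmiaSpec(vpb_rate=30.0, vpb_qrs_scale=1.6)
        truth = m.generate_label_sequence(300, spec, seed=5)
        assert (truth.labels == "vpb").any()
        _, fid = m.synthesize_trace(truth, noise_sd=0.0, seed=5)
        qrs = (fid["s_end"] - fid["q_onset"]).to_numpy()
        sinus_qrs = np.median(qrs[fid["label"] == "sinus"])
        vpb_qrs = np.median(qrs[fid["label"] == "vpb"])
        # landmark-based widths track the template time-scaling
        assert vpb_qrs / sinus_qrs == pytest.approx(1.6, rel=0.10)

    def test_vpb_rendered_without_p_wave(self):
        spec = m.ArrhythmiaSpec(vpb_rate=30.0)
        truth = m.generate_label_sequence(300, spec, seed=6)
        _, fid = m.synthesize_trace(truth, noise_sd=0.0, seed=6)
        assert fid.loc[fid["label"] == "vpb", "p_onset"].isna().all()
        assert fid.loc[fid["label"] == "sinus", "p_onset"].notna().all()

    def test_trace_is_bit_identical_for_fixed_seed(self, mixed_spec):
        truth = m.generate_label_sequence(200, mixed_spec, seed=9)
        t1, _ = m.synthesize_trace(truth, noise_sd=0.02, seed=9)
        t2, _ = m.synthesize_trace(truth, noise_sd=0.02, seed=9)
        assert np.array_equal(t1.samples, t2.samples)

    @pytest.mark.parametrize("kwargs", [dict(hr_bpm=100), dict(fs_hz=200), dict(stage="nope")])
    def test_invalid_rendering_args_raise(self, kwargs):
        truth = m.generate_label_sequence(30, m.ArrhythmiaSpec(), seed=0)
        with pytest.raises(ValueError):
            m.synthesize_trace(truth, **kwargs)


class TestCountTableSimulator:
    def test_zero_mean_cell_yields_all_zeros(self):
        df = m.simulate_count_table({"URI": {"vpb": 0.0}}, {"URI": 5}, dispersion=1.0, seed=1)
        assert (df["count"] == 0).all()

    def test_large_sample_mean_matches_target(self):
        df = m.simulate_count_table({"g": {"c": 5.0}}, {"g": 10_000}, dispersion=1.0, seed=2)
        assert df["count"].mean() == pytest.approx(5.0, rel=0.02)

    def test_equal_seeds_give_identical_tables(self):
        kw = dict(group_means={"a": {"x": 3.0}, "b": {"x": 7.0}}, n_animals={"a": 6, "b": 9})
        assert m.simulate_count_table(**kw, seed=5).equals(m.simulate_count_table(**kw, seed=5))

    def test_invalid_dispersion_raises(self):
        with pytest.raises(ValueError):
            m.simulate_count_table({"g": {"c": 1.0}}, {"g": 3}, dispersion=0.0, seed=0)
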