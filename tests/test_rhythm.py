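"""Rhythm classification rules on constructed and synthetic traces."""

import numpy as np
import pytest

from cardiotrial import (
    Abnormality,
    SynthConfig,
    Trace,
    classify_rhythm,
    detect_cycles,
    detect_dad,
    detect_ead,
    generate_label_suite,
    generate_trace,
)
from cardiotrial.rhythm import RhythmAssessment, RhythmConfig

ALL_KINDS = ("NORMAL", "EAD", "DAD", "RF", "IRR", "VT", "Q", "RESAC")


def flat_trace(vm, duration=20.0, dt=1e-3, cai=20.0):
    n = int(duration / dt) + 1
    t = np.arange(n) * dt
    return Trace(t, np.full(n, float(vm)), np.full(n, cai), dt)


class TestCessationRules:
    def test_constant_depolarized_vm_is_repolarization_failure(self):
        a = classify_rhythm(flat_trace(-20.0))
        assert a.labels == {"RF"}
        assert a.proarrhythmic

    def test_flat_resting_vm_is_quiescence(self):
        a = classify_rhythm(flat_trace(-70.0))
        assert a.labels == {"Q"}
        assert not a.proarrhythmic

    def test_subthreshold_peak_train_is_residual_activity(self):
        trace, truth, _ = generate_trace(
            SynthConfig(duration_s=30.0,
                        program=(Abnormality("RESAC", 0.0, -20.0),))
        )
        a = classify_rhythm(trace)
        assert a.labels == {"RESAC"}
        assert not a.proarrhythmic
        lo, hi = a.evidence["RESAC"]["peak_range_mV"]
        assert -40.0 < hi < 0.0

    def test_trace_shorter_than_window_raises(self):
        with pytest.raises(ValueError, match="15"):
            classify_rhythm(flat_trace(-70.0, duration=10.0))


class TestRateRules:
    def test_single_long_cycle_is_irregular(self):
        """Cycle lengths (1.0, 2.6, 1.0) s: the 160% jump exceeds the 150%
        irregularity threshold."""
        cfg = SynthConfig(rate_bpm=60.0, duration_s=30.0,
                          program=(Abnormality("IRR", 14.0, 2.6),))
        trace, _, _ = generate_trace(cfg)
        a = classify_rhythm(trace)
        assert a.labels == {"IRR"}
        ev = a.evidence["IRR"][0]
        ratio = abs(ev["lengths_s"][1] - ev["lengths_s"][0]) / min(ev["lengths_s"])
        assert ratio > 1.5

    def test_just_below_threshold_is_regular(self):
        # 2.4 s after 1.0 s is a 140% change: below the 150% rule
        cfg = SynthConfig(rate_bpm=60.0, duration_s=30.0,
                          program=(Abnormality("IRR", 14.0, 2.4),))
        trace, _, _ = generate_trace(cfg)
        assert "IRR" not in classify_rhythm(trace).labels

    def test_fast_rate_is_tachycardia_like(self):
        trace, _, _ = generate_trace(
            SynthConfig(duration_s=30.0, program=(Abnormality("VT", 0.0, 150.0),))
        )
        a = classify_rhythm(trace)
        assert a.labels == {"VT"}
        assert a.evidence["VT"]["rate_hz"] == pytest.approx(2.5, rel=0.02)


class TestEadDad:
    def test_monotone_repolarization_has_no_ead(self):
        trace, _, _ = generate_trace(SynthConfig(duration_s=30.0))
        assert detect_ead(trace) == []

    def test_one_ead_per_cycle_is_counted(self):
        trace, _, _ = generate_trace(
            SynthConfig(duration_s=30.0, program=(Abnormality("EAD", 0.0, 15.0),))
        )
        cyc = detect_cycles(trace, "vm")
        events = detect_ead(trace, cyc)
        vm_events = [e for e in events if e["signal"] == "vm"]
        assert len(vm_events) == len(cyc)
        assert classify_rhythm(trace).labels == {"EAD"}

    def test_tiny_bump_below_amplitude_threshold_ignored(self):
        trace, _, _ = generate_trace(
            SynthConfig(duration_s=30.0, program=(Abnormality("EAD", 0.0, 0.5),))
        )
        assert [e for e in detect_ead(trace) if e["signal"] == "vm"] == []

    def test_clean_diastole_has_no_dad(self):
        trace, _, _ = generate_trace(SynthConfig(duration_s=30.0))
        assert detect_dad(trace) == []

    def test_diastolic_hump_is_dad(self):
        trace, _, _ = generate_trace(
            SynthConfig(duration_s=30.0, program=(Abnormality("DAD", 0.0, 5.0),))
        )
        events = [e for e in detect_dad(trace) if e["signal"] == "vm"]
        assert len(events) >= 1
        assert all(e["amplitude"] < 10.0 for e in events)
        assert classify_rhythm(trace).labels == {"DAD"}

    def test_suprathreshold_hump_counts_as_new_ap_not_dad(self):
        """A diastolic hump reaching +10 mV crosses the AP threshold: the
        cycle detector claims it and the DAD detector must not."""
        normal, _, _ = generate_trace(SynthConfig(duration_s=30.0))
        big, _, _ = generate_trace(
            SynthConfig(duration_s=30.0, program=(Abnormality("DAD", 0.0, 85.0),))
        )
        n_normal = len(detect_cycles(normal, "vm"))
        n_big = len(detect_cycles(big, "vm"))
        assert n_big > n_normal
        assert [e for e in detect_dad(big) if e["signal"] == "vm"] == []


class TestAssessmentInvariants:
    def test_normal_is_exclusive(self):
        with pytest.raises(ValueError):
            RhythmAssessment(frozenset({"NORMAL", "EAD"}))

    def test_q_and_resac_are_exclusive(self):
        with pytest.raises(ValueError):
            RhythmAssessment(frozenset({"Q", "RESAC"}))

    def test_cessation_alone_is_not_proarrhythmic(self):
        for label in ("Q", "RESAC"):
            assert not RhythmAssessment(frozenset({label})).proarrhythmic
        assert RhythmAssessment(frozenset({"EAD", "Q"})).proarrhythmic

    def test_composite_renderings(self):
        assert RhythmAssessment(frozenset({"EAD", "DAD", "RF"})).composite() == "EDR"
        assert RhythmAssessment(frozenset({"EAD", "RF"})).composite() == "ER"
        assert RhythmAssessment(frozenset({"IRR", "Q"})).composite() == "IRR+Q"

    def test_labels_invariant_to_shift_and_small_offset(self):
        for program in ((), (Abnormality("EAD", 0.0),)):
            trace, _, _ = generate_trace(
                SynthConfig(duration_s=30.0, program=program)
            )
            ref = classify_rhythm(trace).labels
            shifted = Trace(trace.t + 50.0, trace.vm, trace.cai, trace.dt)
            offset = Trace(trace.t, trace.vm + 0.05, trace.cai, trace.dt)
            assert classify_rhythm(shifted).labels == ref
            assert classify_rhythm(offset).labels == ref


class TestLabelRecovery:
    def _per_label_stats(self, seeds, sigma_vm, sigma_cai):
        tp = {k: 0 for k in ALL_KINDS}
        fp = {k: 0 for k in ALL_KINDS}
        fn = {k: 0 for k in ALL_KINDS}
        for seed in seeds:
            suite = generate_label_suite(
                seed=seed, sigma_vm=sigma_vm, sigma_cai=sigma_cai
            )
            for _, (trace, truth, _) in suite.items():
                got = classify_rhythm(trace).labels
                for k in ALL_KINDS:
                    if k in truth.labels and k in got:
                        tp[k] += 1
                    elif k in got:
                        fp[k] += 1
                    elif k in truth.labels:
                        fn[k] += 1
        return tp, fp, fn

    def test_exact_recovery_on_noiseless_suite(self):
        """Per-label precision and recall are both 1 on the noiseless
        synthetic suite covering all eight labels."""
        tp, fp, fn = self._per_label_stats((0, 1, 2), 0.0, 0.0)
        for k in ALL_KINDS:
            assert fp[k] == 0, f"false positives for {k}"
            assert fn[k] == 0, f"false negatives for {k}"
            assert tp[k] > 0

    def test_f1_above_095_at_1mV_noise(self):
        tp, fp, fn = self._per_label_stats((0, 1, 2, 3), 1.0, 2.0)
        for k in ALL_KINDS:
            f1 = 2 * tp[k] / max(2 * tp[k] + fp[k] + fn[k], 1)
            assert f1 >= 0.95, f"F1 for {k} = {f1}"
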