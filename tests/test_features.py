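"""Feature extraction and elimination criteria on constructed traces."""

import numpy as np
import pytest

from is3screen.features import (CIP_CLASSES, MEASUREMENT_NAMES, EliminationResult,
                                REFERENCE, SpikeDetectionConfig, detect_spikes,
                                eliminate, measure_cip)
from is3screen.simulator import StimulusProtocol, Trace
from is3screen.screening import default_protocols

DT = 0.025


def make_trace(t, v):
    return Trace(("soma", 0.5), np.asarray(t, float), np.asarray(v, float), DT)


def flat_trace(duration=1300.0, level=-70.0):
    t = np.arange(0.0, duration + DT, DT)
    return t, np.full_like(t, level)


def add_spike(t, v, at, threshold=-44.0, peak=18.0, rise=0.5, fall=0.5):
    """Superimpose a triangular spike (linear rise/fall) at time ``at``."""
    up = (t >= at - rise) & (t <= at)
    down = (t > at) & (t <= at + fall)
    v[up] = np.maximum(v[up], threshold + (peak - threshold) * (t[up] - (at - rise)) / rise)
    v[down] = np.maximum(v[down], peak - (peak - threshold) * (t[down] - at) / fall)
    return v


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        t, v = flat_trace()
        assert len(detect_spikes(make_trace(t, v))) == 0

    def test_counts_twenty_eight_identical_spikes(self):
        t, v = flat_trace(1300.0, -70.0)
        onsets = 120.0 + 36.0 * np.arange(28)
        for at in onsets:
            v = add_spike(t, v, at)
        train = detect_spikes(make_trace(t, v))
        assert len(train) == 28

    def test_triangular_spike_geometry(self):
        """Threshold -44, peak +18: amplitude 62 mV, half-width at -13 mV.

        The membrane ramps slowly (below the slope criterion) from rest to
        -44 mV, then rises fast to the peak; threshold detection must land
        at the slope break.
        """
        t, v = flat_trace(100.0, -70.0)
        at, thr, peak, rise, fall = 50.0, -44.0, 18.0, 1.0, 1.0
        ramp = (t >= at - rise - 10.0) & (t < at - rise)  # 2.6 mV/ms approach
        v[ramp] = -70.0 + (thr + 70.0) * (t[ramp] - (at - rise - 10.0)) / 10.0
        up = (t >= at - rise) & (t <= at)
        v[up] = thr + (peak - thr) * (t[up] - (at - rise)) / rise
        down = (t > at) & (t <= at + fall)
        v[down] = peak - (peak - thr) * (t[down] - at) / fall
        settle_back = (t > at + fall) & (t <= at + fall + 5.0)
        v[settle_back] = thr + (-70.0 - thr) * (t[settle_back] - (at + fall)) / 5.0
        train = detect_spikes(make_trace(t, v))
        assert len(train) == 1
        assert train.thresholds[0] == pytest.approx(-44.0, abs=1.0)
        assert train.amplitudes[0] == pytest.approx(62.0, abs=1.0)
        # half-amplitude level -13 mV: triangle width at that level
        frac = (18.0 - (-13.0)) / 62.0
        assert train.half_widths[0] == pytest.approx((rise + fall) * frac, rel=0.05)

    def test_count_invariant_to_subthreshold_noise(self, s2_traces):
        trace = s2_traces["active_depol"]
        clean = len(detect_spikes(trace))
        rng = np.random.default_rng(11)
        noisy = Trace(trace.site, trace.t,
                      trace.v + rng.uniform(-0.5, 0.5, size=len(trace.v)), trace.dt)
        assert len(detect_spikes(noisy)) == clean


class TestMeasureCip:
    def test_measurement_count_contract(self):
        counts = {c: len(MEASUREMENT_NAMES[c]) for c in CIP_CLASSES}
        assert counts == {"hyperpolarizing": 5, "passive_depol": 1,
                          "active_depol": 10, "depol_block": 2}

    def test_constructed_hyperpolarizing_step(self):
        """Baseline -70, pulse plateau -105, no undershoot: Vm diff -35, sag 0."""
        prot = StimulusProtocol.cip(-100.0)
        t = np.arange(0.0, prot.duration + DT, DT)
        v = np.full_like(t, -70.0)
        v[(t >= 100.0) & (t < 1100.0)] = -105.0
        fv = measure_cip(make_trace(t, v), "hyperpolarizing", prot)
        assert fv.values["hyperpol_vm_difference"] == pytest.approx(-35.0)
        assert fv.values["potential_sag"] == pytest.approx(0.0, abs=1e-9)
        assert fv.values["minimum_potential"] == pytest.approx(-105.0)

    def test_sag_measured_from_minimum_to_plateau(self):
        prot = StimulusProtocol.cip(-100.0)
        t = np.arange(0.0, prot.duration + DT, DT)
        v = np.full_like(t, -70.0)
        pulse = (t >= 100.0) & (t < 1100.0)
        tp = t[pulse] - 100.0
        # ramp down to -112 over 60 ms, then relax to -105 with tau 15 ms
        v[pulse] = np.where(tp < 60.0, -70.0 - 42.0 * tp / 60.0,
                            -105.0 - 7.0 * np.exp(-(tp - 60.0) / 15.0))
        fv = measure_cip(make_trace(t, v), "hyperpolarizing", prot)
        assert fv.values["minimum_potential_time"] == pytest.approx(60.0, abs=1.0)
        assert fv.values["potential_sag"] == pytest.approx(7.0, abs=0.2)
        assert fv.values["sag_time_constant"] == pytest.approx(15.0, rel=0.1)

    def test_six_early_spikes_give_initial_rate_60(self):
        """Six spikes in the first 100 ms of the block step: 60 Hz initial rate."""
        prot = StimulusProtocol.cip(500.0)
        t = np.arange(0.0, prot.duration + DT, DT)
        v = np.full_like(t, -70.0)
        v[(t >= 100.0) & (t < 1100.0)] = -10.0
        for at in 100.0 + 15.0 * (1 + np.arange(6)):
            v = add_spike(t, v, at, threshold=-20.0, peak=30.0)
        fv = measure_cip(make_trace(t, v), "depol_block", prot)
        assert fv.values["initial_100ms_spike_rate"] == pytest.approx(60.0)
        assert fv.values["depol_block_vm_difference"] == pytest.approx(60.0, abs=0.5)

    def test_time_shift_invariance(self, s2_traces, protocols):
        for cip_class in CIP_CLASSES:
            trace = s2_traces[cip_class]
            shifted = Trace(trace.site, trace.t + 137.0, trace.v, trace.dt)
            a = measure_cip(trace, cip_class, protocols[cip_class]).as_array()
            b = measure_cip(shifted, cip_class, protocols[cip_class]).as_array()
            np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_reference_vector_names_match_contract(self):
        for cip_class in CIP_CLASSES:
            assert tuple(REFERENCE.for_class(cip_class)) == MEASUREMENT_NAMES[cip_class]
        assert REFERENCE.for_class("active_depol")["interspike_interval"] == 36.6898
        assert REFERENCE.for_class("active_depol")["number_of_spikes"] == 28.0

    def test_wrong_class_rejected(self, s2_traces, protocols):
        with pytest.raises(ValueError):
            measure_cip(s2_traces["active_depol"], "spiking", protocols["active_depol"])


def synth_traces(n50=6, late_spike=False, recovery_spike=False, spike20=False,
                 no_repol_50=False, no_repol_500=False):
    """Construct a full CIP trace set with controllable violations."""
    prots = default_protocols()
    out = {}
    for cip_class, prot in prots.items():
        t = np.arange(0.0, prot.duration + DT, DT)
        v = np.full_like(t, -70.0)
        pulse = (t >= 100.0) & (t < 1100.0)
        if cip_class == "hyperpolarizing":
            v[pulse] = -105.0
        elif cip_class == "passive_depol":
            v[pulse] = -58.0
            if spike20:
                v = add_spike(t, v, 400.0)
        elif cip_class == "active_depol":
            v[pulse] = -50.0
            for at in 140.0 + 36.0 * np.arange(n50):
                v = add_spike(t, v, at)
            if no_repol_50:
                v[t >= 1100.0] = -50.0
        else:
            v[pulse] = -15.0
            for at in (110.0, 130.0, 150.0):
                v = add_spike(t, v, at, threshold=-25.0, peak=25.0)
            if late_spike:
                v = add_spike(t, v, 950.0, threshold=-25.0, peak=25.0)
            if recovery_spike:
                v = add_spike(t, v, 1150.0)
            if no_repol_500:
                v[t >= 1100.0] = -30.0
        out[cip_class] = make_trace(t, v)
    return out, prots


class TestEliminate:
    def test_accepting_case(self):
        traces, prots = synth_traces()
        verdict = eliminate(traces, prots)
        assert verdict.passed and verdict.reasons == []

    @pytest.mark.parametrize("kwargs, reason", [
        (dict(spike20=True), "spikes_20pA"),
        (dict(n50=2), "few_spikes_50pA"),
        (dict(no_repol_50=True), "no_repolarization_50pA"),
        (dict(late_spike=True), "late_spikes_500pA"),
        (dict(recovery_spike=True), "recovery_spikes_500pA"),
        (dict(no_repol_500=True), "no_repolarization_500pA"),
    ])
    def test_each_failure_mode(self, kwargs, reason):
        traces, prots = synth_traces(**kwargs)
        verdict = eliminate(traces, prots)
        assert not verdict.passed
        assert verdict.reasons == [reason]

    def test_removing_late_spikes_only_helps(self):
        """Monotonicity: deleting late-window spikes cannot create a failure."""
        bad, prots = synth_traces(late_spike=True)
        good, _ = synth_traces(late_spike=False)
        r_bad = set(eliminate(bad, prots).reasons)
        r_good = set(eliminate(good, prots).reasons)
        assert r_good <= r_bad

    def test_missing_cip_rejected(self):
        traces, prots = synth_traces()
        del traces["depol_block"]
        with pytest.raises(ValueError, match="missing"):
            eliminate(traces, prots)

    def test_hyperpolarizing_step_never_eliminates(self):
        traces, prots = synth_traces()
        # corrupt the hyperpolarizing trace arbitrarily: still no elimination
        tr = traces["hyperpolarizing"]
        traces["hyperpolarizing"] = Trace(tr.site, tr.t, tr.v + 25.0, tr.dt)
        assert eliminate(traces, prots).passed

    def test_result_invariant_checked(self):
        with pytest.raises(ValueError):
            EliminationResult(passed=True, reasons=["late_spikes_500pA"])
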