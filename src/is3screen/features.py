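"""Signature-feature extraction from voltage traces and elimination criteria.

Four current-injection protocol (CIP) classes carry fixed measurement sets:

* hyperpolarizing (-100 pA, 5 measurements): membrane-potential difference,
  minimum-potential time and value, sag, sag time constant;
* passive depolarization (+20 pA, 1): membrane-potential difference;
* active depolarization (+50 pA, 10): depolarization height, interspike
  interval, first spike time, threshold/half-width/amplitude/AHP means,
  spike rate, spike count, frequency adaptation;
* depolarization block (+500 pA, 2): final-700-ms membrane-potential
  difference and initial-100-ms spike rate.

Elimination rejects models that spike in the passive step, spike fewer
than three times in the active step, fail to repolarize after either
depolarizing step, or keep spiking late in (or after) the block step.
The hyperpolarizing step never eliminates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .simulator import StimulusProtocol, Trace

__all__ = [
    "SpikeDetectionConfig",
    "SpikeTrain",
    "FeatureVector",
    "EliminationResult",
    "ReferenceMeasurements",
    "REFERENCE",
    "CIP_CLASSES",
    "MEASUREMENT_NAMES",
    "detect_spikes",
    "measure_cip",
    "eliminate",
]

CIP_CLASSES = ("hyperpolarizing", "passive_depol", "active_depol", "depol_block")

#: Measurement names per CIP class; counts are the contract {5, 1, 10, 2}.
MEASUREMENT_NAMES: dict[str, tuple[str, ...]] = {
    "hyperpolarizing": (
        "hyperpol_vm_difference",
        "minimum_potential_time",
        "minimum_potential",
        "potential_sag",
        "sag_time_constant",
    ),
    "passive_depol": ("passive_depol_vm_difference",),
    "active_depol": (
        "active_depol_vm_difference",
        "interspike_interval",
        "first_spike_time",
        "spike_threshold_mean",
        "spike_half_width_mean",
        "spike_amplitude_mean",
        "spike_rate",
        "spike_max_ahp_mean",
        "number_of_spikes",
        "spike_frequency_adaptation",
    ),
    "depol_block": ("depol_block_vm_difference", "initial_100ms_spike_rate"),
}


@dataclass(frozen=True)
class SpikeDetectionConfig:
    """Thresholds for spike detection.

    ``peak_level``: peaks must exceed this voltage (mV); ``dvdt_threshold``:
    spike threshold is where dV/dt first exceeds this slope (mV/ms) before
    the peak; ``min_amplitude``: peaks closer than this to the threshold
    are discarded as noise.
    """

    peak_level: float = 0.0
    dvdt_threshold: float = 20.0
    min_amplitude: float = 5.0


@dataclass
class SpikeTrain:
    """Per-spike times, thresholds, amplitudes, half-widths and AHP depths."""

    times: np.ndarray  # ms, at the peak
    thresholds: np.ndarray  # mV
    amplitudes: np.ndarray  # mV, peak - threshold
    half_widths: np.ndarray  # ms, at half amplitude
    ahp_depths: np.ndarray  # mV, threshold - post-spike minimum (>= 0 when AHP)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.times)


def detect_spikes(trace: Trace, config: Optional[SpikeDetectionConfig] = None) -> SpikeTrain:
    """Locate spikes and per-spike waveform measurements in a voltage trace.

    Peaks are local maxima above ``peak_level`` following an upward
    crossing; each spike's threshold is the last point before the peak
    where dV/dt crosses ``dvdt_threshold`` upward.  Half-width is measured
    at threshold + amplitude/2; AHP depth is threshold minus the minimum
    before the next spike's threshold crossing (or window end).
    """
    config = config or SpikeDetectionConfig()
    t, v = trace.t, trace.v
    if len(v) < 3:
        return SpikeTrain(*(np.zeros(0) for _ in range(5)))
    above = v >= config.peak_level
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    ends = np.flatnonzero(above[:-1] & ~above[1:]) + 1
    dvdt = np.gradient(v, t)

    peaks, thr_idx = [], []
    prev_end = 0
    for c in crossings:
        e_candidates = ends[ends > c]
        e = e_candidates[0] if len(e_candidates) else len(v)
        seg = slice(c, e)
        p = c + int(np.argmax(v[seg]))
        # threshold: last upward crossing of the slope criterion before the
        # peak, searched within this spike's own rise (past the previous
        # spike's end, so pulse-onset transients don't contaminate it)
        lo = max(prev_end, 1)
        window = dvdt[lo:p + 1]
        ups = np.flatnonzero((window >= config.dvdt_threshold)
                             & (dvdt[lo - 1:p] < config.dvdt_threshold))
        ti = lo + ups[-1] if len(ups) else prev_end + int(np.argmin(v[prev_end:p + 1]))
        if v[p] - v[ti] < config.min_amplitude:
            prev_end = e
            continue
        peaks.append(p)
        thr_idx.append(ti)
        prev_end = e

    n = len(peaks)
    times = np.array([t[p] for p in peaks])
    thresholds = np.array([v[i] for i in thr_idx])
    amplitudes = np.array([v[p] - v[i] for p, i in zip(peaks, thr_idx)])
    half_widths = np.zeros(n)
    ahp = np.zeros(n)
    for j, (p, ti) in enumerate(zip(peaks, thr_idx)):
        half_v = thresholds[j] + amplitudes[j] / 2.0
        # walk out from the peak to the half-amplitude crossings
        i0 = p
        while i0 > ti and v[i0] > half_v:
            i0 -= 1
        t0 = np.interp(half_v, [v[i0], v[i0 + 1]], [t[i0], t[i0 + 1]]) if v[i0 + 1] != v[i0] else t[i0]
        i1 = p
        end = peaks[j + 1] if j + 1 < n else len(v) - 1
        while i1 < end and v[i1] > half_v:
            i1 += 1
        t1 = np.interp(half_v, [v[i1], v[i1 - 1]], [t[i1], t[i1 - 1]]) if v[i1 - 1] != v[i1] else t[i1]
        half_widths[j] = t1 - t0
        # AHP: minimum between this peak and the next threshold crossing
        nxt = thr_idx[j + 1] if j + 1 < n else len(v) - 1
        if nxt > p:
            ahp[j] = thresholds[j] - np.min(v[p:nxt + 1])
    return SpikeTrain(times, thresholds, amplitudes, half_widths, ahp)


@dataclass
class FeatureVector:
    """Named measurements for one CIP class."""

    cip_class: str
    cip_amplitude_pA: float
    values: dict[str, float]

    def __post_init__(self) -> None:
        expected = MEASUREMENT_NAMES[self.cip_class]
        if tuple(self.values) != expected:
            raise ValueError(
                f"measurement set for {self.cip_class} must be {expected}, "
                f"got {tuple(self.values)}")

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.values)


def _exp_decay(t, a, tau, c):
    # clipped exponent keeps curve_fit's trial steps finite
    return a * np.exp(-np.clip(t / tau, -700.0, 700.0)) + c


def _sag_time_constant(t: np.ndarray, v: np.ndarray) -> float:
    """Single-exponential fit (least squares) from the minimum to the end."""
    if len(t) < 4 or np.ptp(v) < 1e-9:
        return 0.0
    t0 = t - t[0]
    a0 = v[0] - v[-1]
    try:
        popt, _ = curve_fit(_exp_decay, t0, v, p0=[a0, max(t0[-1] / 5, 1.0), v[-1]],
                            maxfev=2000)
        tau = abs(popt[1])
    except RuntimeError:
        tau = 0.0
    return float(tau)


def measure_cip(
    trace: Trace,
    cip_class: str,
    protocol: StimulusProtocol,
    spike_config: Optional[SpikeDetectionConfig] = None,
) -> FeatureVector:
    """Compute the measurement set of ``cip_class`` from a somatic trace.

    Vm differences are mean-during-pulse minus mean-during-baseline; the
    depolarization-block Vm difference uses only the final 700 ms of the
    pulse.  Times are reported relative to pulse onset.  Only relative
    timing matters: shifting the trace's time axis leaves results unchanged.
    """
    if cip_class not in CIP_CLASSES:
        raise ValueError(f"unknown CIP class {cip_class!r}")
    if len(protocol.pulses) != 1:
        raise ValueError("measure_cip expects a single-step protocol")
    onset, dur, amp = protocol.pulses[0]
    t_off = trace.t[0]  # tolerate shifted time axes
    t = trace.t - t_off
    v = trace.v
    base = v[(t >= onset - protocol.baseline) & (t < onset)]
    pulse_mask = (t >= onset) & (t < onset + dur)
    pulse_v = v[pulse_mask]
    pulse_t = t[pulse_mask]
    if len(base) == 0 or len(pulse_v) == 0:
        raise ValueError("trace does not cover the protocol window")
    vm_base = float(np.mean(base))
    vm_pulse = float(np.mean(pulse_v))

    if cip_class == "hyperpolarizing":
        imin = int(np.argmin(pulse_v))
        v_min = float(pulse_v[imin])
        t_min = float(pulse_t[imin] - onset)
        # steady state: mean of the last 10% of the pulse
        ss = float(np.mean(pulse_v[int(0.9 * len(pulse_v)):]))
        sag = max(ss - v_min, 0.0)
        tau_sag = _sag_time_constant(pulse_t[imin:], pulse_v[imin:]) if sag > 1e-9 else 0.0
        vals = {
            "hyperpol_vm_difference": vm_pulse - vm_base,
            "minimum_potential_time": t_min,
            "minimum_potential": v_min,
            "potential_sag": sag,
            "sag_time_constant": tau_sag,
        }
        return FeatureVector(cip_class, amp, vals)

    if cip_class == "passive_depol":
        return FeatureVector(cip_class, amp,
                             {"passive_depol_vm_difference": vm_pulse - vm_base})

    spikes = detect_spikes(Trace(trace.site, t, v, trace.dt), spike_config)
    in_pulse = (spikes.times >= onset) & (spikes.times < onset + dur)
    st = SpikeTrain(spikes.times[in_pulse] - onset, spikes.thresholds[in_pulse],
                    spikes.amplitudes[in_pulse], spikes.half_widths[in_pulse],
                    spikes.ahp_depths[in_pulse])

    if cip_class == "active_depol":
        n = len(st)
        isis = st.isis
        # adaptation: late ISIs over early ISIs (> 1 means slowing down)
        if len(isis) >= 4:
            adapt = float(np.mean(isis[-2:]) / np.mean(isis[:2]))
        elif len(isis) >= 2:
            adapt = float(isis[-1] / isis[0])
        else:
            adapt = 1.0
        vals = {
            "active_depol_vm_difference": vm_pulse - vm_base,
            "interspike_interval": float(np.mean(isis)) if len(isis) else 0.0,
            "first_spike_time": float(st.times[0]) if n else dur,
            "spike_threshold_mean": float(np.mean(st.thresholds)) if n else 0.0,
            "spike_half_width_mean": float(np.mean(st.half_widths)) if n else 0.0,
            "spike_amplitude_mean": float(np.mean(st.amplitudes)) if n else 0.0,
            "spike_rate": n / (dur * 1e-3),
            "spike_max_ahp_mean": float(np.mean(st.ahp_depths)) if n else 0.0,
            "number_of_spikes": float(n),
            "spike_frequency_adaptation": adapt,
        }
        return FeatureVector(cip_class, amp, vals)

    # depolarization block: final-700-ms Vm difference + initial 100 ms rate
    final_mask = (pulse_t >= onset + dur - 700.0)
    vm_final = float(np.mean(pulse_v[final_mask]))
    n_initial = int(np.sum(st.times < 100.0))
    vals = {
        "depol_block_vm_difference": vm_final - vm_base,
        "initial_100ms_spike_rate": n_initial / 0.1,
    }
    return FeatureVector(cip_class, amp, vals)


@dataclass(frozen=True)
class ReferenceMeasurements:
    """Reference measurement values per CIP class (immutable)."""

    values: tuple[tuple[str, tuple[tuple[str, float], ...]], ...]

    @classmethod
    def from_dict(cls, d: dict[str, dict[str, float]]) -> "ReferenceMeasurements":
        out = []
        for cip_class, meas in d.items():
            expected = MEASUREMENT_NAMES[cip_class]
            if set(meas) != set(expected):
                raise ValueError(f"bad measurement set for {cip_class}")
            out.append((cip_class, tuple((n, float(meas[n])) for n in expected)))
        return cls(tuple(out))

    def for_class(self, cip_class: str) -> dict[str, float]:
        for c, m in self.values:
            if c == cip_class:
                return dict(m)
        raise KeyError(cip_class)

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {c: dict(m) for c, m in self.values}


#: The selected experimental reference measurements used as the screening
#: target for the real cell (one value per measurement).  The spike-count /
#: rate / ISI triple is used verbatim in the distance metric, not recomputed.
REFERENCE = ReferenceMeasurements.from_dict({
    "hyperpolarizing": {
        "hyperpol_vm_difference": -34.2649,
        "minimum_potential_time": 58.9000,
        "minimum_potential": -112.6709,
        "potential_sag": 6.7865,
        "sag_time_constant": 14.3000,
    },
    "passive_depol": {"passive_depol_vm_difference": 12.4910},
    "active_depol": {
        "active_depol_vm_difference": 29.4174,
        "interspike_interval": 36.6898,
        "first_spike_time": 33.1000,
        "spike_threshold_mean": -44.3428,
        "spike_half_width_mean": 1.0301,
        "spike_amplitude_mean": 61.7296,
        "spike_rate": 35.0044,
        "spike_max_ahp_mean": 6.8820,
        "number_of_spikes": 28.0000,
        "spike_frequency_adaptation": 1.3305,
    },
    "depol_block": {
        "depol_block_vm_difference": 62.6461,
        "initial_100ms_spike_rate": 60.0000,
    },
})


@dataclass
class EliminationResult:
    """Screening verdict; ``passed`` iff ``reasons`` is empty."""

    passed: bool
    reasons: list[str]

    def __post_init__(self) -> None:
        if self.passed != (not self.reasons):
            raise ValueError("passed must equal (reasons empty)")


def _repolarizes(trace: Trace, protocol: StimulusProtocol,
                 tolerance_mV: float = 10.0, window_ms: float = 50.0) -> bool:
    """True if the final ``window_ms`` of recovery returns near baseline."""
    onset, dur, _ = protocol.pulses[0]
    t = trace.t - trace.t[0]
    base = trace.v[(t >= onset - protocol.baseline) & (t < onset)]
    tail = trace.v[t >= t[-1] - window_ms]
    return bool(abs(float(np.mean(tail)) - float(np.mean(base))) <= tolerance_mV)


def eliminate(
    traces: dict[str, Trace],
    protocols: dict[str, StimulusProtocol],
    spike_config: Optional[SpikeDetectionConfig] = None,
) -> EliminationResult:
    """Apply the elimination criteria across the four CIP classes.

    ``traces``/``protocols`` are keyed by CIP class.  Criteria: spikes
    during the passive step; fewer than three spikes in the active step;
    failure to repolarize after the active or block step; spikes in the
    final 700 ms of the block pulse; spikes during the block recovery.
    """
    missing = [c for c in CIP_CLASSES if c not in traces or c not in protocols]
    if missing:
        raise ValueError(f"missing CIP simulations: {missing}")
    reasons: list[str] = []

    def spikes_for(cip_class):
        tr = traces[cip_class]
        t = tr.t - tr.t[0]
        return detect_spikes(Trace(tr.site, t, tr.v, tr.dt), spike_config)

    # +20 pA: any spike eliminates
    onset20, dur20, _ = protocols["passive_depol"].pulses[0]
    sp20 = spikes_for("passive_depol")
    if len(sp20) > 0:
        reasons.append("spikes_20pA")

    # +50 pA: need >= 3 spikes in the pulse and repolarization afterwards
    onset50, dur50, _ = protocols["active_depol"].pulses[0]
    sp50 = spikes_for("active_depol")
    n50 = int(np.sum((sp50.times >= onset50) & (sp50.times < onset50 + dur50)))
    if n50 < 3:
        reasons.append("few_spikes_50pA")
    if not _repolarizes(traces["active_depol"], protocols["active_depol"]):
        reasons.append("no_repolarization_50pA")

    # +500 pA: block must hold through the last 700 ms, recovery silent
    onset500, dur500, _ = protocols["depol_block"].pulses[0]
    sp500 = spikes_for("depol_block")
    late = np.sum((sp500.times >= onset500 + dur500 - 700.0)
                  & (sp500.times < onset500 + dur500))
    if late > 0:
        reasons.append("late_spikes_500pA")
    post = np.sum(sp500.times >= onset500 + dur500)
    if post > 0:
        reasons.append("recovery_spikes_500pA")
    if not _repolarizes(traces["depol_block"], protocols["depol_block"]):
        reasons.append("no_repolarization_500pA")

    return EliminationResult(passed=not reasons, reasons=reasons)
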