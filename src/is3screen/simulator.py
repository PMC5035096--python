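"""Current-clamp simulation of biophysical models.

Wraps the numba cable kernel: builds protocols (current steps, pulse
trains), double-exponential synapses, optional Gaussian white-noise
injection, and returns voltage traces.  Each simulation is preceded by a
settle-to-steady-state pre-run (discarded) unless an explicit initial
state is supplied, so protocols start from the model's true resting
potential.

Internal unit contract: mV, ms, um, S/cm^2, uF/cm^2, Ohm cm; point
currents nA (protocol amplitudes are given in pA and converted once
here); synaptic weights uS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _kernel
from .biophysics import BiophysicalModel

__all__ = [
    "StimulusProtocol",
    "SynapseSpec",
    "NoiseSpec",
    "SimulationConfig",
    "Trace",
    "SimulationError",
    "simulate",
    "settle",
    "synaptic_conductance",
    "inject_noise",
]

Location = tuple[int, float]  # (section id, arc fraction)

SOMA = ("soma", 0.5)  # symbolic soma-midpoint location accepted everywhere


class SimulationError(RuntimeError):
    """Numerical failure (NaN/overflow) during integration."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Somatic (or dendritic) current injection protocol.

    ``pulses`` are (onset ms, duration ms, amplitude pA) with onsets
    measured from the start of the recorded window; ``baseline`` ms of
    zero current precede the first pulse and ``recovery`` ms follow the
    last.  Current-step protocols must not have overlapping pulses.
    """

    baseline: float = 100.0
    pulses: tuple[tuple[float, float, float], ...] = ()
    recovery: float = 200.0
    site: object = SOMA

    def __post_init__(self) -> None:
        for onset, dur, amp in self.pulses:
            if dur <= 0 or not math.isfinite(amp):
                raise ValueError("pulse duration must be > 0 and amplitude finite")
        spans = sorted((o, o + d) for o, d, _ in self.pulses)
        for (a0, a1), (b0, b1) in zip(spans[:-1], spans[1:]):
            if b0 < a1:
                raise ValueError("overlapping pulses")

    @classmethod
    def cip(cls, amplitude_pA: float, baseline: float = 100.0,
            pulse: float = 1000.0, recovery: float = 200.0) -> "StimulusProtocol":
        """A single current step: the standard screening protocol shape."""
        return cls(baseline, ((baseline, pulse, amplitude_pA),), recovery)

    @classmethod
    def pulse_train(cls, n: int, amplitude_pA: float, duration: float = 2.0,
                    interval: float = 20.0, baseline: float = 100.0,
                    recovery: float = 200.0) -> "StimulusProtocol":
        """n short pulses (onset-to-onset ``interval`` ms), e.g. a bAP train."""
        pulses = tuple((baseline + i * interval, duration, amplitude_pA) for i in range(n))
        return cls(baseline, pulses, recovery)

    @property
    def duration(self) -> float:
        if not self.pulses:
            return self.baseline + self.recovery
        return max(o + d for o, d, _ in self.pulses) + self.recovery

    def current_nA(self, t: np.ndarray) -> np.ndarray:
        out = np.zeros_like(t)
        for onset, dur, amp in self.pulses:
            out[(t >= onset) & (t < onset + dur)] += amp * 1e-3
        return out


@dataclass(frozen=True)
class SynapseSpec:
    """Double-exponential conductance synapse driven by presynaptic spikes.

    Peak conductance after a single spike equals ``weight`` (uS): the
    double exponential is scaled by the normalization factor
    1 / (exp(-tp/tau2) - exp(-tp/tau1)) with tp the analytic peak time.
    """

    location: Location
    weight: float
    spike_times: tuple[float, ...] = ()
    tau1: float = 0.2
    tau2: float = 2.0
    e: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.tau1 < self.tau2:
            raise ValueError("require 0 < tau1 < tau2")
        if self.weight < 0:
            raise ValueError("synaptic weight must be >= 0")

    @property
    def peak_time(self) -> float:
        """Time to peak after a spike: tau1*tau2/(tau2-tau1) * ln(tau2/tau1)."""
        return self.tau1 * self.tau2 / (self.tau2 - self.tau1) * math.log(self.tau2 / self.tau1)

    @property
    def factor(self) -> float:
        tp = self.peak_time
        return 1.0 / (math.exp(-tp / self.tau2) - math.exp(-tp / self.tau1))


def synaptic_conductance(spec: SynapseSpec, t) -> np.ndarray | float:
    """Conductance (uS) at time(s) ``t``, summed over presynaptic spikes."""
    t_arr = np.asarray(t, dtype=float)
    g = np.zeros_like(t_arr)
    f = spec.factor * spec.weight
    for ts in spec.spike_times:
        dt = t_arr - ts
        mask = dt >= 0
        g[mask] += f * (np.exp(-dt[mask] / spec.tau2) - np.exp(-dt[mask] / spec.tau1))
    return float(g) if np.isscalar(t) else g


@dataclass(frozen=True)
class NoiseSpec:
    """Zero-mean Gaussian white-noise current at the protocol site."""

    enabled: bool = True
    sd_pA: float = 0.0
    seed: int = 0


def inject_noise(noise: NoiseSpec, dt: float, n_steps: int) -> np.ndarray:
    """Per-step noise current samples in pA; identical for identical seeds."""
    if not noise.enabled or noise.sd_pA == 0:
        return np.zeros(n_steps)
    rng = np.random.default_rng(noise.seed)
    return rng.normal(0.0, noise.sd_pA, size=n_steps)


@dataclass(frozen=True)
class SimulationConfig:
    dt: float = 0.025
    method: str = "backward_euler"  # or "crank_nicolson"
    record: tuple = (SOMA,)
    settle_ms: float = 500.0
    record_all: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.method not in ("backward_euler", "crank_nicolson"):
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def theta(self) -> float:
        return 1.0 if self.method == "backward_euler" else 0.5


@dataclass
class Trace:
    """A recorded voltage time series at one site."""

    site: object
    t: np.ndarray
    v: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        if len(self.t) != len(self.v):
            raise ValueError("t and v must have equal length")

    def window(self, t0: float, t1: float) -> "Trace":
        mask = (self.t >= t0) & (self.t <= t1)
        return Trace(self.site, self.t[mask], self.v[mask], self.dt)

    def to_text(self, path) -> None:
        np.savetxt(path, np.column_stack([self.t, self.v]),
                   header="time_ms voltage_mV", fmt="%.6f")


# ---------------------------------------------------------------------------
# kernel packing


def _resolve(model: BiophysicalModel, location) -> int:
    if location == SOMA or location == "soma":
        return model.comp_model.soma_index()
    return model.comp_model.locate(location)


def _pack(model: BiophysicalModel):
    """Flatten a model into the kernel's array form (cached on the model)."""
    cached = getattr(model, "_packed", None)
    if cached is not None:
        return cached
    cm = model.comp_model
    # only channels with any nonzero density take part in the integration
    names = sorted(n for n, g in model.gbar_uS.items() if np.any(g > 0))
    chan_objs = [model.channels[n] for n in names]

    g_exp, g_vh, g_k, g_form, g_p = [], [], [], [], []
    chan_gate_ptr = [0]
    pair_ptr = [0]
    pair_comp: list[int] = []
    pair_gbar: list[float] = []
    erev = []
    form_code = {"constant": _kernel.TAU_CONSTANT, "bell": _kernel.TAU_BELL,
                 "sigmoid": _kernel.TAU_SIGMOID}
    for name, ch in zip(names, chan_objs):
        for gate in ch.gates:
            g_exp.append(gate.exponent)
            g_vh.append(gate.vhalf)
            g_k.append(gate.k)
            g_form.append(form_code[gate.tau_form])
            g_p.append(list(gate.tau_params) + [0.0] * (5 - len(gate.tau_params)))
        chan_gate_ptr.append(len(g_exp))
        active = np.flatnonzero(model.gbar_uS[name] > 0)
        pair_comp.extend(int(i) for i in active)
        pair_gbar.extend(float(model.gbar_uS[name][i]) for i in active)
        pair_ptr.append(len(pair_comp))
        erev.append(ch.reversal)

    n_gates = len(g_exp)
    packed = dict(
        parent=cm.parent_index.astype(np.int64),
        g_ax=cm.axial_g.astype(np.float64),
        cap=model.cap_nF.astype(np.float64),
        g_leak=model.g_leak_uS.astype(np.float64),
        e_leak=model.e_leak.astype(np.float64),
        gate_exp=np.array(g_exp, dtype=np.int64),
        gate_vhalf=np.array(g_vh, dtype=np.float64),
        gate_k=np.array(g_k, dtype=np.float64),
        gate_form=np.array(g_form, dtype=np.int64),
        gate_p=np.array(g_p, dtype=np.float64).reshape(n_gates, 5) if n_gates else np.zeros((0, 5)),
        chan_gate_ptr=np.array(chan_gate_ptr, dtype=np.int64),
        erev=np.array(erev, dtype=np.float64),
        pair_ptr=np.array(pair_ptr, dtype=np.int64),
        pair_comp=np.array(pair_comp, dtype=np.int64),
        pair_gbar=np.array(pair_gbar, dtype=np.float64),
        channel_names=names,
    )
    model._packed = packed
    return packed


def _initial_gates(model: BiophysicalModel, v: np.ndarray) -> np.ndarray:
    pk = _pack(model)
    n_gates = pk["gate_vhalf"].shape[0]
    gates = np.zeros((n_gates, model.n_comp))
    for gidx in range(n_gates):
        vh, k = pk["gate_vhalf"][gidx], pk["gate_k"][gidx]
        gates[gidx] = 1.0 / (1.0 + np.exp(-(v - vh) / k))
    return gates


def _run(model, v, gates, n_steps, dt, theta, inj_comp, inj_nA, syn_comp,
         syn_g, syn_e, rec_idx):
    pk = _pack(model)
    v_out = np.empty((len(rec_idx), n_steps + 1))
    fail = _kernel.integrate(
        v, gates, dt, n_steps, theta,
        pk["parent"], pk["g_ax"], pk["cap"], pk["g_leak"], pk["e_leak"],
        pk["gate_vhalf"], pk["gate_k"], pk["gate_exp"], pk["gate_form"],
        pk["gate_p"], pk["chan_gate_ptr"], pk["erev"],
        pk["pair_ptr"], pk["pair_comp"], pk["pair_gbar"],
        inj_comp, inj_nA, syn_comp, syn_g, syn_e,
        np.asarray(rec_idx, dtype=np.int64), v_out,
    )
    if fail >= 0:
        raise SimulationError(
            f"non-finite membrane state at step {fail} (t = {fail * dt:.3f} ms)")
    return v_out


def settle(model: BiophysicalModel, config: Optional[SimulationConfig] = None
           ) -> tuple[np.ndarray, np.ndarray]:
    """Settle to steady state with zero stimulus; returns (v, gates).

    The result can be passed to :func:`simulate` as ``init_state`` to skip
    the pre-run (useful when sweeping many protocols on one model).
    """
    config = config or SimulationConfig()
    v = np.full(model.n_comp, float(np.mean(model.e_leak)))
    gates = _initial_gates(model, v)
    n_steps = int(round(config.settle_ms / config.dt))
    none_i = np.zeros(0, dtype=np.int64)
    _run(model, v, gates, n_steps, config.dt, 1.0,
         none_i, np.zeros((0, n_steps)), none_i, np.zeros((0, n_steps)),
         np.zeros(0), np.zeros(0, dtype=np.int64))
    return v, gates


def simulate(
    model: BiophysicalModel,
    protocol: StimulusProtocol,
    synapses: Sequence[SynapseSpec] = (),
    noise: Optional[NoiseSpec] = None,
    config: Optional[SimulationConfig] = None,
    init_state: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> list[Trace]:
    """Run a protocol and return one :class:`Trace` per recorded site.

    The time axis starts at 0 at the beginning of the recorded window
    (after the settle pre-run).  Deterministic given the noise seed.
    """
    config = config or SimulationConfig()
    if init_state is None:
        v, gates = settle(model, config)
    else:
        v, gates = init_state[0].copy(), init_state[1].copy()

    dt = config.dt
    n_steps = int(round(protocol.duration / dt))
    t_edges = np.arange(n_steps) * dt

    inj_comp = np.array([_resolve(model, protocol.site)], dtype=np.int64)
    inj = protocol.current_nA(t_edges)[None, :].copy()
    if noise is not None and noise.enabled and noise.sd_pA > 0:
        inj = inj + inject_noise(noise, dt, n_steps)[None, :] * 1e-3

    if synapses:
        syn_comp = np.array([_resolve(model, s.location) for s in synapses], dtype=np.int64)
        syn_g = np.stack([synaptic_conductance(s, t_edges) for s in synapses])
        syn_e = np.array([s.e for s in synapses])
    else:
        syn_comp = np.zeros(0, dtype=np.int64)
        syn_g = np.zeros((0, n_steps))
        syn_e = np.zeros(0)

    if config.record_all:
        rec_sites = [ (c.section_id, 0.5 * (c.a + c.b)) for c in model.comp_model.compartments ]
        rec_idx = np.arange(model.n_comp, dtype=np.int64)
    else:
        rec_sites = list(config.record)
        rec_idx = np.array([_resolve(model, s) for s in rec_sites], dtype=np.int64)

    v_out = _run(model, v, gates, n_steps, dt, config.theta,
                 inj_comp, inj, syn_comp, syn_g, syn_e, rec_idx)
    t = np.arange(n_steps + 1) * dt
    return [Trace(site, t, v_out[i], dt) for i, site in enumerate(rec_sites)]
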