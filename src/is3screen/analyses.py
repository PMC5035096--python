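"""Downstream characterizations of accepted models.

* Electrotonic analysis: steady-state voltage attenuation of the passive
  model, expressed as the electrotonic distance L = log(A) with
  A = upstream voltage / downstream voltage for a 1 mV applied signal,
  in both directions (toward and away from the soma).
* Backpropagating action potential (bAP) profiles: spike amplitude versus
  path distance along a dendritic tree under a train of three brief
  somatic pulses (2 ms, 800 pA).
* Synaptic threshold-weight scans: the minimal double-exponential synapse
  weight that drives the soma past -20 mV from a single presynaptic
  spike, location by location along a tree, together with the local
  voltage deflection in the first millisecond (whose ceiling at the
  driving force marks synaptic current saturation).
* Point-conductance conversion from a density and a spherical-soma radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .biophysics import BiophysicalModel
from .morphology import CompartmentalModel, MorphologyError
from .simulator import (SimulationConfig, StimulusProtocol, SynapseSpec,
                        settle, simulate)

__all__ = [
    "AttenuationMap",
    "BapProfile",
    "ThresholdWeightScan",
    "electrotonic_map",
    "bap_profile",
    "threshold_weight_scan",
    "gmax_from_density",
    "path_locations",
]


# ---------------------------------------------------------------------------
# sampling helper


def path_locations(cm: CompartmentalModel, tree_label: str, spacing: float = 10.0
                   ) -> list[tuple[tuple[int, float], float]]:
    """Locations every ``spacing`` um along the root-to-most-distal-tip path.

    Returns [((section id, fraction), path distance um), ...] for the
    labelled tree, starting at its attachment to the soma.
    """
    morph = cm.morphology
    secs = [s for s in morph.sections if s.tree_label == tree_label]
    if not secs:
        raise MorphologyError(f"no tree with label {tree_label!r}")
    from .morphology import path_distance as pdist

    # most distal tip of the tree
    tips = [(s, pdist(morph, (s.id, 1.0))) for s in secs]
    tip_sec, tip_dist = max(tips, key=lambda t: t[1])
    # chain from tip back to the section attached outside the tree
    sec_ids = {s.id for s in secs}
    chain = [tip_sec]
    while chain[-1].parent is not None and chain[-1].parent[0] in sec_ids:
        chain.append(morph.section(chain[-1].parent[0]))
    chain.reverse()
    start_dist = pdist(morph, (chain[0].id, 0.0))

    out = []
    targets = np.arange(start_dist, tip_dist, spacing)
    for target in targets:
        d = start_dist
        for sec in chain:
            if target <= d + sec.length + 1e-9:
                frac = min(max((target - d) / sec.length, 0.0), 1.0)
                out.append(((sec.id, frac), float(pdist(morph, (sec.id, frac)))))
                break
            d += sec.length
    return out


# ---------------------------------------------------------------------------
# electrotonic analysis


@dataclass
class AttenuationMap:
    """Electrotonic distance per compartment of a passive model.

    ``direction``: 'away_from_soma' (signal at the soma, measured along
    the dendrites; V_out) or 'toward_soma' (signal at each dendritic site,
    measured at the soma; V_in).  L uses the configured log base (natural
    log by default) and is 0 at the reference point.
    """

    direction: str
    path_distances: np.ndarray  # um per compartment
    L: np.ndarray  # electrotonic distance per compartment
    regions: list[str]
    tree_labels: list[str]


def _passive_impedance(model: BiophysicalModel) -> np.ndarray:
    """Dense DC transfer-impedance matrix Z (MOhm) of the passive network."""
    cm = model.comp_model
    n = cm.n_comp
    G = np.zeros((n, n))
    G[np.diag_indices(n)] = model.g_leak_uS
    for i in range(1, n):
        ga = cm.axial_g[i]
        if ga <= 0:
            continue
        p = cm.parent_index[i]
        G[i, i] += ga
        G[p, p] += ga
        G[i, p] -= ga
        G[p, i] -= ga
    return np.linalg.inv(G)


def electrotonic_map(model: BiophysicalModel, direction: str = "away_from_soma",
                     log_base: float = math.e) -> AttenuationMap:
    """Steady-state electrotonic distances of a passive model.

    Uses the DC solution of the passive cable network: with a 1 mV signal
    applied at the upstream point, attenuation to a downstream point is
    A = 1 / V_downstream, and L = log(A).  By reciprocity of the passive
    network both directions come from one impedance matrix:
    away from soma, A(x) = Z_ss / Z_sx; toward the soma, A(x) = Z_xx / Z_xs.
    """
    if direction not in ("away_from_soma", "toward_soma"):
        raise ValueError(f"unknown direction {direction!r}")
    if not model.is_passive:
        raise ValueError("electrotonic analysis requires a passive model "
                         "(use model.as_passive())")
    cm = model.comp_model
    Z = _passive_impedance(model)
    s = cm.soma_index()
    if direction == "away_from_soma":
        A = Z[s, s] / Z[s, :]
    else:
        A = np.diag(Z) / Z[:, s]
    L = np.log(A) / math.log(log_base)
    labels = [cm.morphology.section(c.section_id).tree_label for c in cm.compartments]
    return AttenuationMap(direction, cm.path_distances.copy(), L, list(cm.regions), labels)


# ---------------------------------------------------------------------------
# backpropagating action potentials


@dataclass
class BapProfile:
    """Spike amplitude versus path distance along one dendritic tree."""

    tree_label: str
    path_distances: np.ndarray  # um
    amplitudes: np.ndarray  # mV, peak minus pre-train baseline, >= 0


def bap_profile(model: BiophysicalModel, tree_label: str, spacing: float = 10.0,
                *, n_pulses: int = 3, pulse_pA: float = 800.0,
                pulse_ms: float = 2.0, interval_ms: float = 20.0,
                config: Optional[SimulationConfig] = None) -> BapProfile:
    """Amplitude profile of backpropagating spikes along ``tree_label``.

    Injects the somatic pulse train (default three 2 ms, 800 pA pulses),
    records along the tree's distal-most path, and reports per-location
    peak minus pre-train baseline.
    """
    config = config or SimulationConfig()
    locs = path_locations(model.comp_model, tree_label, spacing)
    protocol = StimulusProtocol.pulse_train(n_pulses, pulse_pA, pulse_ms,
                                            interval_ms, baseline=20.0,
                                            recovery=30.0)
    from dataclasses import replace

    cfg = replace(config, record=tuple(loc for loc, _ in locs))
    traces = simulate(model, protocol, config=cfg)
    onset = protocol.pulses[0][0]
    amps = []
    for tr in traces:
        baseline = float(np.mean(tr.v[tr.t < onset]))
        amps.append(max(float(tr.v.max()) - baseline, 0.0))
    return BapProfile(tree_label, np.array([d for _, d in locs]), np.array(amps))


# ---------------------------------------------------------------------------
# synaptic threshold-weight scan


@dataclass
class ThresholdWeightScan:
    """Per-location minimal synaptic weight for a somatic spike.

    ``weights`` is NaN where no weight up to the schedule maximum reached
    the criterion ('unreachable'); ``local_dv`` is the site's max - min
    voltage in the first 1 ms after the presynaptic spike at the threshold
    weight (or at the schedule maximum where unreachable); ``saturated``
    flags locations where that deflection reaches the driving-force
    ceiling |V_rest - e_syn|.
    """

    tree_label: str
    path_distances: np.ndarray
    weights: np.ndarray  # uS, NaN = unreachable
    local_dv: np.ndarray  # mV
    saturated: np.ndarray  # bool
    unreachable: np.ndarray  # bool


def threshold_weight_scan(
    model: BiophysicalModel,
    tree_label: str,
    spacing: float = 10.0,
    *,
    w_min: float = 1e-4,
    w_max: float = 10.0,
    soma_criterion_mV: float = -20.0,
    saturation_fraction: float = 0.95,
    sig_figs: int = 3,
    config: Optional[SimulationConfig] = None,
) -> ThresholdWeightScan:
    """Scan synapse locations along a tree for the threshold weight.

    At each location a single presynaptic spike drives a double-exponential
    synapse; the weight is refined by bisection on a geometric schedule
    until the somatic potential surpasses ``soma_criterion_mV`` (resolution
    ~``sig_figs`` significant figures).  The first-millisecond local
    deflection at the synapse site is recorded at the threshold weight.
    """
    config = config or SimulationConfig()
    locs = path_locations(model.comp_model, tree_label, spacing)
    state = settle(model, config)
    v_rest = float(state[0][model.comp_model.soma_index()])

    from dataclasses import replace

    spike_t = 5.0
    window = StimulusProtocol(baseline=spike_t, pulses=(), recovery=60.0)

    def trial(loc, weight):
        syn = SynapseSpec(loc, weight, (spike_t,))
        cfg = replace(config, record=(("soma", 0.5), loc))
        soma_tr, site_tr = simulate(model, window, synapses=[syn],
                                    config=cfg, init_state=state)
        mask = (site_tr.t >= spike_t) & (site_tr.t <= spike_t + 1.0)
        dv = float(site_tr.v[mask].max() - site_tr.v[mask].min())
        return float(soma_tr.v.max()) >= soma_criterion_mV, dv

    dists, weights, dvs, sat, unreach = [], [], [], [], []
    ceiling = abs(v_rest - 0.0)  # e_syn = 0 mV
    for loc, dist in locs:
        ok_max, dv_max = trial(loc, w_max)
        if not ok_max:
            dists.append(dist)
            weights.append(np.nan)
            dvs.append(dv_max)
            sat.append(dv_max >= saturation_fraction * ceiling)
            unreach.append(True)
            continue
        lo, hi = math.log(w_min), math.log(w_max)
        ok_min, _ = trial(loc, w_min)
        if ok_min:
            hi = lo  # already suprathreshold at the schedule minimum
        n_iter = max(1, math.ceil(math.log2((hi - lo) / math.log(1 + 10 ** (1 - sig_figs))))) if hi > lo else 0
        for _ in range(n_iter):
            mid = 0.5 * (lo + hi)
            ok, _ = trial(loc, math.exp(mid))
            if ok:
                hi = mid
            else:
                lo = mid
        w_thr = math.exp(hi)
        _, dv = trial(loc, w_thr)
        dists.append(dist)
        weights.append(w_thr)
        dvs.append(dv)
        sat.append(dv >= saturation_fraction * ceiling)
        unreach.append(False)
    return ThresholdWeightScan(tree_label, np.array(dists), np.array(weights),
                               np.array(dvs), np.array(sat, dtype=bool),
                               np.array(unreach, dtype=bool))


# ---------------------------------------------------------------------------
# unit conversion


def gmax_from_density(density_S_cm2: float, radius_um: float) -> float:
    """Point conductance (nS) of a density spread over a spherical soma.

    G = density * 4 pi r^2, converted to nS: with r in um and density in
    S/cm^2 this is density * 4 pi r^2 * 10.  Linear in density, quadratic
    in radius.
    """
    if density_S_cm2 < 0:
        raise ValueError("density must be >= 0")
    if radius_um <= 0:
        raise ValueError("radius must be > 0")
    return density_S_cm2 * 4.0 * math.pi * radius_um ** 2 * 10.0
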