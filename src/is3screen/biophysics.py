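"""Passive membrane parameters, voltage-gated channel kinetics, spatial profiles.

Channel kinetics are data, not code: each channel is a set of Hodgkin-Huxley
gating variables whose steady states are Boltzmann sigmoids and whose time
constants come from a small family of voltage-dependence forms (constant,
bell, sigmoid).  The shipped parameter file
(``data/channels_synthetic.yaml``) is a synthetic transcription tuned so
that the published conductance-density grids reproduce the four signature
firing regimes on the bundled fixture morphology; see the file header.

Spatial distribution scenarios follow the standard labels: S.x (somatic
channels only), SD (uniform soma + dendrites), SDprox.x (soma + proximal
dendrites via a Boltzmann fall-off in path distance).  The persistent sodium
conductance is restricted to the soma in every scenario; in SDprox.2 the
A-type potassium conductance is soma-only as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
import yaml

from .morphology import CompartmentalModel

__all__ = [
    "PassiveParams",
    "RegionPassiveMap",
    "GatingVariable",
    "ChannelModel",
    "SpatialProfile",
    "DistributionScenario",
    "SCENARIOS",
    "BiophysicalModel",
    "boltzmann_density",
    "gating_rates",
    "load_channels",
    "build_model",
]

E_NA = 50.0  # mV, sodium reversal used in all simulations
E_K = -77.0  # mV, potassium reversal used in all simulations


@dataclass(frozen=True)
class PassiveParams:
    """Specific passive membrane parameters.

    C_m uF/cm^2, R_a Ohm cm, G_m S/cm^2, E_leak mV.  Defaults are the
    soma/dendrite values of the reference interneuron model (resting
    potential -69.7 mV).
    """

    C_m: float = 0.9
    R_a: float = 255.0
    G_m: float = 0.000019
    E_leak: float = -69.7

    def __post_init__(self) -> None:
        if self.C_m <= 0 or self.R_a <= 0 or self.G_m <= 0:
            raise ValueError("C_m, R_a and G_m must be positive")


#: Axon-stub override used when axonal branches are trimmed to a stub: the
#: remaining segment's passive load compensates for the removed arbor.
AXON_STUB_PASSIVE = PassiveParams(C_m=4.0, R_a=300.0, G_m=0.000185, E_leak=-69.7)


@dataclass(frozen=True)
class RegionPassiveMap:
    """Region -> passive parameters; every compartment region must resolve."""

    soma: PassiveParams = PassiveParams()
    dendrite: PassiveParams = PassiveParams()
    axon: PassiveParams = AXON_STUB_PASSIVE

    def for_region(self, region: str) -> PassiveParams:
        try:
            return getattr(self, region)
        except AttributeError:
            raise KeyError(f"no passive parameters for region {region!r}") from None

    def with_e_leak(self, e_leak: float) -> "RegionPassiveMap":
        from dataclasses import replace

        return RegionPassiveMap(
            soma=replace(self.soma, E_leak=e_leak),
            dendrite=replace(self.dendrite, E_leak=e_leak),
            axon=replace(self.axon, E_leak=e_leak),
        )


# ---------------------------------------------------------------------------
# gating kinetics

_TAU_FORMS = ("constant", "bell", "sigmoid")


@dataclass(frozen=True)
class GatingVariable:
    """One HH gating variable: sigmoid steady state, parametric time constant.

    steady state x_inf(V) = 1 / (1 + exp(-(V - vhalf) / k)); k < 0 encodes
    inactivation.  tau forms (ms):
      constant: tau0
      bell:     tau_min + amp / (exp((V-vt)/a) + exp(-(V-vt)/b))
      sigmoid:  tau_min + amp / (1 + exp((V-vt)/a))
    """

    name: str
    vhalf: float
    k: float
    exponent: int
    tau_form: str
    tau_params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.exponent < 1:
            raise ValueError("gate exponent must be >= 1")
        if self.tau_form not in _TAU_FORMS:
            raise ValueError(f"unknown tau form {self.tau_form!r}")
        if self.k == 0:
            raise ValueError("gate slope k must be nonzero")

    def steady_state(self, v):
        return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - self.vhalf) / self.k))

    def time_constant(self, v):
        v = np.asarray(v, dtype=float)
        if self.tau_form == "constant":
            return np.full_like(v, self.tau_params[0])
        if self.tau_form == "bell":
            tau_min, amp, vt, a, b = self.tau_params
            return tau_min + amp / (np.exp((v - vt) / a) + np.exp(-(v - vt) / b))
        tau_min, amp, vt, a = self.tau_params
        return tau_min + amp / (1.0 + np.exp((v - vt) / a))


@dataclass(frozen=True)
class ChannelModel:
    """A voltage-gated channel: gating variables and a reversal potential.

    Current density is density * prod(gate^exponent) * (V - reversal).
    """

    name: str
    gates: tuple[GatingVariable, ...]
    reversal: float

    def open_fraction(self, gate_values: np.ndarray) -> np.ndarray:
        out = np.ones_like(gate_values[0])
        for g, x in zip(self.gates, gate_values):
            out = out * x ** g.exponent
        return out


def gating_rates(channel: ChannelModel, v) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Steady states and time constants of every gate of ``channel`` at ``v``."""
    if not np.all(np.isfinite(np.asarray(v, dtype=float))):
        raise ValueError("voltage must be finite")
    infs = [g.steady_state(v) for g in channel.gates]
    taus = [g.time_constant(v) for g in channel.gates]
    return infs, taus


def load_channels(path=None) -> dict[str, ChannelModel]:
    """Load channel definitions from a YAML parameter file.

    Without ``path`` the packaged synthetic kinetics file is used.
    """
    if path is None:
        text = resources.files("is3screen.data").joinpath("channels_synthetic.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    channels = {}
    for name, spec in raw["channels"].items():
        gates = []
        for gname, g in spec.get("gates", {}).items():
            tau = g["tau"]
            form = tau["form"]
            if form == "constant":
                params = (float(tau["tau0"]),)
            elif form == "bell":
                params = tuple(float(tau[k]) for k in ("tau_min", "amp", "vt", "a", "b"))
            elif form == "sigmoid":
                params = tuple(float(tau[k]) for k in ("tau_min", "amp", "vt", "a"))
            else:
                raise ValueError(f"channel {name}: unknown tau form {form!r}")
            gates.append(
                GatingVariable(gname, float(g["vhalf"]), float(g["k"]),
                               int(g.get("exponent", 1)), form, params)
            )
        channels[name] = ChannelModel(name, tuple(gates), float(spec["reversal"]))
    return channels


# ---------------------------------------------------------------------------
# spatial conductance profiles


def boltzmann_density(G: float, k: float, d: float, p) -> np.ndarray | float:
    """Distance-dependent conductance density f(p) = G - G / (1 + exp(k (d - p))).

    Uniform at G through the proximal dendrite and falling sharply to zero
    around path distance ``d`` (um); ``k`` (um^-1, default 10 in the
    screening scenarios) sets the sharpness.
    """
    p_arr = np.asarray(p, dtype=float)
    if G < 0 or k <= 0 or d <= 0:
        raise ValueError("require G >= 0, k > 0, d > 0")
    if np.any(p_arr < 0):
        raise ValueError("path distance p must be >= 0")
    # G - G/(1+e^z) == G/(1+e^-z) == G*expit(z), overflow-safe via expit
    from scipy.special import expit

    out = G * expit(k * (d - p_arr))
    if np.isscalar(p):
        return float(out)
    return out


_PROFILE_KINDS = ("uniform_everywhere", "soma_only", "soma_and_dendrites", "boltzmann_proximal")


@dataclass(frozen=True)
class SpatialProfile:
    """Maps a compartment (region, path distance) to a conductance density."""

    kind: str
    G: float
    k: float = 10.0
    d: float = 75.0

    def __post_init__(self) -> None:
        if self.kind not in _PROFILE_KINDS:
            raise ValueError(f"unknown profile kind {self.kind!r}")
        if self.G < 0:
            raise ValueError("plateau density G must be >= 0")

    def density(self, region: str, p: float) -> float:
        if self.kind == "uniform_everywhere":
            return self.G
        if self.kind == "soma_only":
            return self.G if region == "soma" else 0.0
        if self.kind == "soma_and_dendrites":
            return self.G if region in ("soma", "dendrite") else 0.0
        # boltzmann_proximal: uniform in soma, Boltzmann fall-off in dendrites
        if region == "soma":
            return self.G
        if region == "dendrite":
            return float(boltzmann_density(self.G, self.k, self.d, p))
        return 0.0


@dataclass(frozen=True)
class DistributionScenario:
    """A labelled assignment of channels to regions.

    ``soma_channels``: channels present in the soma (uniform).
    ``dendrite_channels``: channels present in dendrites with the listed
    profile kind ('soma_and_dendrites' for uniform, 'boltzmann_proximal'
    for proximal-only).  The axon stub carries leak only in every scenario.
    """

    label: str
    soma_channels: tuple[str, ...]
    dendrite_channels: tuple[str, ...]
    dendrite_profile: str = "soma_and_dendrites"

    def profile_for(self, channel: str, G: float, d: float) -> SpatialProfile:
        if channel in self.dendrite_channels:
            return SpatialProfile(self.dendrite_profile, G, d=d)
        if channel in self.soma_channels:
            return SpatialProfile("soma_only", G)
        raise KeyError(f"channel {channel!r} not in scenario {self.label}")

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.soma_channels + self.dendrite_channels))


#: The five screening scenarios.  na_p is soma-only everywhere; SDprox.2
#: additionally keeps ka at the soma.
SCENARIOS: dict[str, DistributionScenario] = {
    "S.1": DistributionScenario(
        "S.1", ("na_p", "na_t", "ka", "kdrf", "kdrs"), ()),
    "S.2": DistributionScenario(
        "S.2", ("na_p", "na_t", "ka", "kdrf_faster"), ()),
    "SD": DistributionScenario(
        "SD", ("na_p", "na_t", "ka", "kdrf_faster"),
        ("na_t", "ka", "kdrf_faster"), "soma_and_dendrites"),
    "SDprox.1": DistributionScenario(
        "SDprox.1", ("na_p", "na_t", "ka", "kdrf_faster"),
        ("na_t", "ka", "kdrf_faster"), "boltzmann_proximal"),
    "SDprox.2": DistributionScenario(
        "SDprox.2", ("na_p", "na_t", "ka", "kdrf_faster"),
        ("na_t", "kdrf_faster"), "boltzmann_proximal"),
}


# ---------------------------------------------------------------------------
# model assembly


class BiophysicalModel:
    """A compartmental model with passive parameters and channel densities.

    All unit conversions from specific densities to per-compartment point
    values live here: capacitance nF, conductance uS, with areas in um^2.
    """

    def __init__(self, comp_model: CompartmentalModel, passive: RegionPassiveMap,
                 channels: dict[str, ChannelModel],
                 densities_by_comp: dict[str, np.ndarray],
                 scenario_label: str = "custom"):
        self.comp_model = comp_model
        self.passive = passive
        self.channels = channels
        self.densities_by_comp = densities_by_comp  # S/cm^2 per compartment
        self.scenario_label = scenario_label

        areas = comp_model.areas_um2
        regions = comp_model.regions
        pp = [passive.for_region(r) for r in regions]
        # cm (uF/cm^2) * area(um^2) * 1e-8 cm^2/um^2 -> uF; * 1e3 -> nF
        self.cap_nF = np.array([p.C_m for p in pp]) * areas * 1e-5
        # G_m (S/cm^2) * area_cm2 -> S; * 1e6 -> uS  => factor 1e-2
        self.g_leak_uS = np.array([p.G_m for p in pp]) * areas * 1e-2
        self.e_leak = np.array([p.E_leak for p in pp])
        self.gbar_uS = {name: dens * areas * 1e-2 for name, dens in densities_by_comp.items()}

    @property
    def n_comp(self) -> int:
        return self.comp_model.n_comp

    @property
    def is_passive(self) -> bool:
        return all(np.all(g == 0) for g in self.gbar_uS.values())

    def active_channel_names(self) -> list[str]:
        return [n for n, g in self.gbar_uS.items() if np.any(g > 0)]

    def as_passive(self) -> "BiophysicalModel":
        zero = {n: np.zeros(self.n_comp) for n in self.densities_by_comp}
        return BiophysicalModel(self.comp_model, self.passive, self.channels, zero,
                                scenario_label=f"{self.scenario_label}:passive")


def build_model(
    comp_model: CompartmentalModel,
    scenario: DistributionScenario | str,
    densities: dict[str, float],
    *,
    cutoff_d: float = 75.0,
    passive: Optional[RegionPassiveMap] = None,
    channels: Optional[dict[str, ChannelModel]] = None,
) -> BiophysicalModel:
    """Assemble a biophysical model from a scenario and per-channel densities.

    ``densities`` maps channel name -> plateau density in S/cm^2; channels
    missing from the scenario raise, channels of the scenario missing from
    ``densities`` default to zero.  ``cutoff_d`` is the Boltzmann midpoint
    for SDprox scenarios (ignored otherwise).
    """
    if isinstance(scenario, str):
        try:
            scenario = SCENARIOS[scenario]
        except KeyError:
            raise KeyError(f"unknown scenario label {scenario!r}") from None
    passive = passive or RegionPassiveMap()
    channels = channels or load_channels()
    for name, G in densities.items():
        if G < 0:
            raise ValueError(f"negative density for {name}")
        if name not in scenario.channels:
            raise KeyError(f"channel {name!r} not part of scenario {scenario.label}")

    regions = comp_model.regions
    pdist = comp_model.path_distances
    dens_by_comp = {}
    for name in scenario.channels:
        G = float(densities.get(name, 0.0))
        prof = scenario.profile_for(name, G, cutoff_d)
        dens_by_comp[name] = np.array(
            [prof.density(r, p) for r, p in zip(regions, pdist)]
        )
    return BiophysicalModel(comp_model, passive, channels, dens_by_comp,
                            scenario_label=scenario.label)
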