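"""Synthetic test morphologies and ground-truth screening references.

The real reconstruction behind the reference interneuron model is not
bundled, so every pipeline here runs on stylized synthetic morphologies:
a small bipolar cell with one long sparsely branched dendritic tree, two
shorter heavily branched trees, and a short axon stub.  Generators are
deterministic given their seed and emit valid SWC.

``make_reference`` simulates a known grid-member model over the four CIPs
and packages its features as the screening reference, so the whole
strategy can be validated by parameter recovery: screening must return
the generating model at rank 1 with distance 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .morphology import Morphology, MorphPoint, Section, compartmentalize
from .biophysics import (RegionPassiveMap, build_model,
                         DistributionScenario, BiophysicalModel)
from .simulator import SimulationConfig, StimulusProtocol
from .features import (MEASUREMENT_NAMES, ReferenceMeasurements, measure_cip,
                       SpikeDetectionConfig)

__all__ = [
    "TreeRecipe",
    "FixtureMorphologySpec",
    "GroundTruth",
    "make_fixture_morphology",
    "make_fixture_model",
    "make_reference",
    "recovery_harness",
    "DEFAULT_TRUTH_DENSITIES",
]


@dataclass(frozen=True)
class TreeRecipe:
    """A symmetric binary dendritic tree: a stem then ``depth`` bifurcations.

    ``child_lengths`` gives the section length at each level below the stem
    (len == depth).  Branch-point count is 2^depth - 1 for depth >= 1.
    """

    label: str
    stem_length: float
    child_lengths: tuple[float, ...]
    stem_diameter: float = 1.3
    tip_diameter: float = 0.4
    azimuth_deg: float = 0.0  # direction of the stem in the xy plane

    @property
    def depth(self) -> int:
        return len(self.child_lengths)

    @property
    def n_branch_points(self) -> int:
        return 2 ** self.depth - 1 if self.depth >= 1 else 0

    @property
    def total_length(self) -> float:
        return self.stem_length + sum(2 ** (i + 1) * L for i, L in enumerate(self.child_lengths))

    @property
    def max_distal_length(self) -> float:
        return self.stem_length + sum(self.child_lengths)


@dataclass(frozen=True)
class FixtureMorphologySpec:
    """Recipe for a synthetic interneuron-like morphology."""

    soma_length: float = 15.0
    soma_diameter: float = 12.0
    trees: tuple[TreeRecipe, ...] = (
        TreeRecipe("1", 200.0, (140.0, 80.0), 1.4, 0.5, 90.0),
        TreeRecipe("2A", 60.0, (50.0, 40.0, 30.0), 1.3, 0.4, -70.0),
        TreeRecipe("2B", 55.0, (45.0, 35.0, 25.0), 1.2, 0.4, -110.0),
    )
    axon_length: float = 90.0
    axon_diameter: float = 3.0
    jitter: float = 0.0  # relative length jitter (deterministic via seed)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.soma_length <= 0 or self.soma_diameter <= 0:
            raise ValueError("impossible soma geometry")
        for tr in self.trees:
            if tr.stem_length <= 0 or any(L <= 0 for L in tr.child_lengths):
                raise ValueError(f"impossible geometry for tree {tr.label}")


def make_fixture_morphology(spec: Optional[FixtureMorphologySpec] = None) -> Morphology:
    """Build the synthetic morphology described by ``spec``.

    Sections are laid out as 2D turtle walks per tree (branches fan +/-30
    degrees); geometry is deterministic given ``spec.seed``.
    """
    spec = spec or FixtureMorphologySpec()
    rng = np.random.default_rng(spec.seed)

    def jit(L: float) -> float:
        if spec.jitter <= 0:
            return L
        return float(L * (1.0 + spec.jitter * rng.uniform(-1, 1)))

    half = spec.soma_length / 2.0
    soma = Section(0, "soma", "soma",
                   [MorphPoint(-half, 0, 0, spec.soma_diameter),
                    MorphPoint(half, 0, 0, spec.soma_diameter)])
    sections = [soma]
    next_id = 1

    for tree in spec.trees:
        levels = tree.depth + 1
        diam_step = (tree.stem_diameter - tree.tip_diameter) / max(levels, 1)

        def grow(parent_id, attach_frac, origin, angle_deg, level, tree=tree,
                 diam_step=diam_step):
            nonlocal next_id
            if level == 0:
                length, d0 = jit(tree.stem_length), tree.stem_diameter
            else:
                length = jit(tree.child_lengths[level - 1])
                d0 = tree.stem_diameter - level * diam_step
            d1 = max(d0 - diam_step, tree.tip_diameter)
            rad = math.radians(angle_deg)
            end = (origin[0] + length * math.cos(rad), origin[1] + length * math.sin(rad))
            sec = Section(next_id, "dendrite", tree.label,
                          [MorphPoint(origin[0], origin[1], 0, d0),
                           MorphPoint(end[0], end[1], 0, d1)],
                          (parent_id, attach_frac))
            sections.append(sec)
            my_id = next_id
            next_id += 1
            if level < tree.depth:
                spread = 30.0 / (level + 1)
                grow(my_id, 1.0, end, angle_deg + spread, level + 1)
                grow(my_id, 1.0, end, angle_deg - spread, level + 1)

        # attach stems at the distal soma end (arc fraction 1)
        rad = math.radians(tree.azimuth_deg)
        grow(0, 1.0, (half, 0.0), tree.azimuth_deg, 0)

    if spec.axon_length > 0:
        sections.append(Section(next_id, "axon", "axon",
                                [MorphPoint(-half, 0, 0, spec.axon_diameter),
                                 MorphPoint(-half - spec.axon_length, 0, 0, spec.axon_diameter)],
                                (0, 0.0)))
    return Morphology(sections, name=f"fixture_seed{spec.seed}")


def make_fixture_model(
    spec: Optional[FixtureMorphologySpec] = None,
    scenario: str | DistributionScenario = "S.2",
    densities: Optional[dict[str, float]] = None,
    *,
    cutoff_d: float = 75.0,
    passive: Optional[RegionPassiveMap] = None,
    policy: str = "frequency",
) -> BiophysicalModel:
    """Morphology + compartments + channels in one call (test convenience)."""
    passive = passive or RegionPassiveMap()
    morph = make_fixture_morphology(spec)
    cm = compartmentalize(morph, policy, passive=passive)
    return build_model(cm, scenario, densities or {}, cutoff_d=cutoff_d, passive=passive)


#: Grid-member densities (S/cm^2) used as the default ground truth for the
#: somatic-channel scenario; drawn from the published final S.2 ranges.
DEFAULT_TRUTH_DENSITIES = {
    "na_t": 0.225, "na_p": 0.0001, "ka": 0.2, "kdrf_faster": 1.0,
}


@dataclass(frozen=True)
class GroundTruth:
    """A known generating model for recovery tests."""

    scenario: str = "S.2"
    densities: tuple[tuple[str, float], ...] = tuple(DEFAULT_TRUTH_DENSITIES.items())
    cutoff_d: float = 75.0
    morphology_spec: FixtureMorphologySpec = FixtureMorphologySpec()

    def densities_dict(self) -> dict[str, float]:
        return dict(self.densities)


def make_reference(
    truth: GroundTruth,
    protocols: Optional[dict[str, StimulusProtocol]] = None,
    config: Optional[SimulationConfig] = None,
    spike_config: Optional[SpikeDetectionConfig] = None,
) -> ReferenceMeasurements:
    """Simulate the ground-truth model over the four CIPs -> reference features.

    Raises if the generating model is eliminated by its own criteria (a
    fixture must itself be a valid model).
    """
    from .screening import default_protocols, run_cips
    from .features import eliminate

    protocols = protocols or default_protocols()
    config = config or SimulationConfig()
    model = make_fixture_model(truth.morphology_spec, truth.scenario,
                               truth.densities_dict(), cutoff_d=truth.cutoff_d)
    traces = run_cips(model, protocols, config)
    verdict = eliminate(traces, protocols, spike_config)
    if not verdict.passed:
        raise ValueError(f"ground-truth model eliminated: {verdict.reasons}")
    ref = {
        cip_class: measure_cip(traces[cip_class], cip_class, protocols[cip_class],
                               spike_config).values
        for cip_class in MEASUREMENT_NAMES
    }
    return ReferenceMeasurements.from_dict(ref)


def recovery_harness(grid, truth: GroundTruth, scenario: Optional[str] = None,
                     config: Optional[SimulationConfig] = None) -> dict:
    """Full screening run against a reference generated from ``truth``.

    Returns a report dict: whether the rank-1 parameters equal the truth,
    the truth model's distance, and the survivor count.
    """
    from .screening import generate_database, default_protocols

    scenario = scenario or truth.scenario
    config = config or SimulationConfig()
    reference = make_reference(truth, config=config)
    model = make_fixture_model(truth.morphology_spec, scenario, {})
    db = generate_database(model.comp_model, scenario, grid, reference,
                           config=config, passive=model.passive)
    best = db.top(1)[0]
    truth_params = dict(truth.densities)
    if "cutoff_d" in grid.names:
        truth_params["cutoff_d"] = truth.cutoff_d
    recovered = all(
        math.isclose(best.parameters[k], truth_params[k], rel_tol=1e-12)
        for k in grid.names
    )
    truth_rec = [r for r in db.records
                 if all(math.isclose(r.parameters[k], truth_params[k], rel_tol=1e-12)
                        for k in grid.names)]
    return {
        "recovered": recovered,
        "rank1_parameters": dict(best.parameters),
        "truth_distance": truth_rec[0].mean_distance if truth_rec else float("nan"),
        "n_survivors": db.n_survivors,
        "n_models": len(db.records),
    }
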