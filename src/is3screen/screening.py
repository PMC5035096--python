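"""Model-database screening over conductance grids and CBDR visualization.

The screening strategy: build one model per point of a Cartesian
conductance grid, run the four current-injection protocols, eliminate
models that miss the signature features, measure the survivors, score
each against the reference with the normalized distance metric, and rank.
Eliminated models carry the sentinel distance 100.  The resulting
database is visualized by clutter-based dimensional reordering (CBDR):
parameters are stacked onto two image axes in order of their impact on
the distance metric, so structure in conductance space reads as spatial
structure in the image.

The distance metric is implemented exactly as printed in its source,
d(x, y) = sum_i |x_i - y_i| / (N sigma_i) -- a sigma-scaled mean absolute
deviation (the literature name "normalized Euclidean distance" is kept
for the public alias, with an optional true-L2 variant behind a switch).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .biophysics import (BiophysicalModel, DistributionScenario, RegionPassiveMap,
                         SCENARIOS, build_model, load_channels)
from .features import (CIP_CLASSES, MEASUREMENT_NAMES, EliminationResult,
                       ReferenceMeasurements, SpikeDetectionConfig, eliminate,
                       measure_cip)
from .morphology import CompartmentalModel
from .simulator import (SimulationConfig, SimulationError, StimulusProtocol,
                        Trace, settle, simulate)

__all__ = [
    "ELIMINATED_DISTANCE",
    "CIP_AMPLITUDES",
    "ParameterGrid",
    "ModelRecord",
    "ModelDatabase",
    "CBDRLayout",
    "normalized_distance",
    "model_distance",
    "default_protocols",
    "run_cips",
    "generate_database",
    "cbdr_layout",
]

#: Sentinel distance assigned to eliminated (or failed) models.
ELIMINATED_DISTANCE = 100.0

#: Screening step amplitudes (pA) per CIP class.
CIP_AMPLITUDES = {
    "hyperpolarizing": -100.0,
    "passive_depol": 20.0,
    "active_depol": 50.0,
    "depol_block": 500.0,
}

#: Grid axis name reserved for the Boltzmann cutoff distance ("VGC Distance").
CUTOFF_AXIS = "cutoff_d"


def default_protocols(baseline: float = 100.0, pulse: float = 1000.0,
                      recovery: float = 200.0) -> dict[str, StimulusProtocol]:
    """The four screening steps: -100, +20, +50, +500 pA."""
    return {c: StimulusProtocol.cip(a, baseline, pulse, recovery)
            for c, a in CIP_AMPLITUDES.items()}


# ---------------------------------------------------------------------------
# distance metric


def normalized_distance(x, y, sigma=None, *, metric: str = "mean_abs") -> float:
    """Sigma-scaled distance between a measurement vector and the reference.

    Default 'mean_abs': sum_i |x_i - y_i| / (N sigma_i).  With all sigma 1
    this is the mean absolute deviation.  metric='l2' gives the true
    normalized Euclidean form sqrt(sum ((x-y)/sigma)^2 / N) for
    sensitivity checks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if sigma is None:
        sigma = np.ones_like(x)
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != x.shape:
        raise ValueError("sigma must match x in length")
    if np.any(sigma <= 0):
        raise ValueError("sigma values must be > 0")
    n = len(x)
    if metric == "mean_abs":
        return float(np.sum(np.abs(x - y) / (n * sigma)))
    if metric == "l2":
        return float(np.sqrt(np.sum(((x - y) / sigma) ** 2) / n))
    raise ValueError(f"unknown metric {metric!r}")


def model_distance(cip_distances) -> float:
    """Mean of the four per-CIP distances (equal weight per signature feature)."""
    if isinstance(cip_distances, dict):
        missing = [c for c in CIP_CLASSES if c not in cip_distances]
        if missing:
            raise ValueError(f"missing CIP distances: {missing}")
        vals = [cip_distances[c] for c in CIP_CLASSES]
    else:
        vals = list(cip_distances)
        if len(vals) != 4:
            raise ValueError("expected exactly 4 CIP distances")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# grids and databases


@dataclass(frozen=True)
class ParameterGrid:
    """Ordered per-parameter value lists; database size is their product."""

    axes: tuple[tuple[str, tuple[float, ...]], ...]

    @classmethod
    def from_dict(cls, d: dict[str, Sequence[float]]) -> "ParameterGrid":
        axes = tuple((k, tuple(float(v) for v in vals)) for k, vals in d.items())
        for name, vals in axes:
            if len(vals) < 1:
                raise ValueError(f"axis {name!r} needs >= 1 value")
        return cls(axes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.axes)

    def levels(self, name: str) -> tuple[float, ...]:
        for n, vals in self.axes:
            if n == name:
                return vals
        raise KeyError(name)

    @property
    def size(self) -> int:
        return int(np.prod([len(v) for _, v in self.axes]))

    def points(self) -> Iterator[dict[str, float]]:
        names = self.names
        for combo in itertools.product(*(vals for _, vals in self.axes)):
            yield dict(zip(names, combo))


@dataclass
class ModelRecord:
    """One grid point: parameters, verdict, distances, rank."""

    parameters: dict[str, float]
    eliminated: bool
    reasons: list[str]
    cip_distances: dict[str, float]
    mean_distance: float
    rank: int = 0
    features: Optional[dict[str, dict[str, float]]] = None

    def __post_init__(self) -> None:
        if self.mean_distance < 0:
            raise ValueError("mean distance must be >= 0")
        if self.eliminated != (self.mean_distance == ELIMINATED_DISTANCE):
            raise ValueError("eliminated flag must match the sentinel distance")


@dataclass
class ModelDatabase:
    """All records of one screening run over a grid."""

    grid: ParameterGrid
    scenario_label: str
    records: list[ModelRecord]
    reference: ReferenceMeasurements

    def __post_init__(self) -> None:
        if len(self.records) != self.grid.size:
            raise ValueError("record count must equal grid size")

    @property
    def n_survivors(self) -> int:
        return sum(1 for r in self.records if not r.eliminated)

    def top(self, n: int = 1) -> list[ModelRecord]:
        return sorted(self.records, key=lambda r: r.rank)[:n]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = dict(r.parameters)
            row.update(
                eliminated=r.eliminated,
                reasons=";".join(r.reasons),
                mean_distance=r.mean_distance,
                rank=r.rank,
            )
            for c in CIP_CLASSES:
                row[f"distance_{c}"] = r.cip_distances.get(c, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)

    def save_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def rescored(self, reference: ReferenceMeasurements, metric: str = "mean_abs"
                 ) -> "ModelDatabase":
        """Re-rank against a new reference using stored features.

        Requires the database to have been generated with
        ``keep_features=True``; elimination verdicts are reused (they do
        not depend on the reference).
        """
        records = []
        for r in self.records:
            if r.eliminated:
                records.append(ModelRecord(dict(r.parameters), True, list(r.reasons),
                                           dict(r.cip_distances), ELIMINATED_DISTANCE,
                                           features=r.features))
                continue
            if r.features is None:
                raise ValueError("rescoring needs stored features "
                                 "(generate_database(..., keep_features=True))")
            cip_d = {}
            for cip_class in CIP_CLASSES:
                names = MEASUREMENT_NAMES[cip_class]
                ref = reference.for_class(cip_class)
                x = np.array([r.features[cip_class][n] for n in names])
                y = np.array([ref[n] for n in names])
                cip_d[cip_class] = normalized_distance(x, y, metric=metric)
            records.append(ModelRecord(dict(r.parameters), False, [], cip_d,
                                       model_distance(cip_d), features=r.features))
        _assign_ranks(records)
        return ModelDatabase(self.grid, self.scenario_label, records, reference)


def _assign_ranks(records: list[ModelRecord]) -> None:
    """Unique 1-based ranks: survivors by distance, eliminated last.

    Ties break lexicographically on parameter values (deterministic).
    """
    def key(r: ModelRecord):
        return (r.eliminated, r.mean_distance, tuple(r.parameters.values()))

    for rank, rec in enumerate(sorted(records, key=key), start=1):
        rec.rank = rank


def run_cips(
    model: BiophysicalModel,
    protocols: Optional[dict[str, StimulusProtocol]] = None,
    config: Optional[SimulationConfig] = None,
) -> dict[str, Trace]:
    """Run the four CIPs from a single shared settle state; somatic traces."""
    protocols = protocols or default_protocols()
    config = config or SimulationConfig()
    state = settle(model, config)
    out = {}
    for cip_class, prot in protocols.items():
        out[cip_class] = simulate(model, prot, config=config, init_state=state)[0]
    return out


def score_model(
    traces: dict[str, Trace],
    protocols: dict[str, StimulusProtocol],
    reference: ReferenceMeasurements,
    spike_config: Optional[SpikeDetectionConfig] = None,
    metric: str = "mean_abs",
) -> tuple[EliminationResult, dict[str, float], float, dict[str, dict[str, float]]]:
    """Eliminate, measure, and score one model's CIP traces."""
    verdict = eliminate(traces, protocols, spike_config)
    features = {}
    cip_d = {}
    for cip_class in CIP_CLASSES:
        fv = measure_cip(traces[cip_class], cip_class, protocols[cip_class], spike_config)
        features[cip_class] = fv.values
        ref = reference.for_class(cip_class)
        cip_d[cip_class] = normalized_distance(
            fv.as_array(), np.array([ref[n] for n in fv.names]), metric=metric)
    mean_d = ELIMINATED_DISTANCE if not verdict.passed else model_distance(cip_d)
    return verdict, cip_d, mean_d, features


def generate_database(
    comp_model: CompartmentalModel,
    scenario: str | DistributionScenario,
    grid: ParameterGrid,
    reference: ReferenceMeasurements,
    *,
    protocols: Optional[dict[str, StimulusProtocol]] = None,
    config: Optional[SimulationConfig] = None,
    passive: Optional[RegionPassiveMap] = None,
    channels=None,
    spike_config: Optional[SpikeDetectionConfig] = None,
    default_cutoff_d: float = 75.0,
    metric: str = "mean_abs",
    keep_features: bool = False,
) -> ModelDatabase:
    """Screen every grid point: build, simulate, eliminate, measure, score, rank.

    Results are independent of iteration order (each grid point is
    self-contained); a simulation failure marks the record failed with the
    sentinel distance and the run continues.
    """
    if grid.size < 1:
        raise ValueError("empty parameter grid")
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    protocols = protocols or default_protocols()
    config = config or SimulationConfig()
    passive = passive or RegionPassiveMap()
    channels = channels or load_channels()

    records = []
    for point in grid.points():
        densities = {k: v for k, v in point.items() if k != CUTOFF_AXIS}
        cutoff = point.get(CUTOFF_AXIS, default_cutoff_d)
        model = build_model(comp_model, scenario, densities, cutoff_d=cutoff,
                            passive=passive, channels=channels)
        try:
            traces = run_cips(model, protocols, config)
            verdict, cip_d, mean_d, feats = score_model(
                traces, protocols, reference, spike_config, metric)
            records.append(ModelRecord(point, not verdict.passed,
                                       verdict.reasons, cip_d, mean_d,
                                       features=feats if keep_features else None))
        except SimulationError as exc:
            records.append(ModelRecord(point, True, [f"simulation_failure:{exc}"],
                                       {}, ELIMINATED_DISTANCE))
    _assign_ranks(records)
    return ModelDatabase(grid, scenario.label if hasattr(scenario, "label") else str(scenario),
                         records, reference)


# ---------------------------------------------------------------------------
# CBDR (clutter-based dimensional reordering)


@dataclass
class CBDRLayout:
    """Dimensional stacking of an N-D grid into a 2D distance image.

    Parameters are ordered by impact (range of per-level marginal mean
    distances, descending; ties break by name) and assigned alternately to
    the y then x axis, outermost first -- so the most influential
    parameter changes slowest along y.  ``image[0, 0]`` is the all-lowest
    corner (render with origin='lower' to put low conductances bottom
    left).  ``record_index`` maps each pixel bijectively to a record.
    """

    impact_order: tuple[str, ...]
    y_params: tuple[str, ...]
    x_params: tuple[str, ...]
    image: np.ndarray
    record_index: np.ndarray
    database: ModelDatabase

    def pixel_to_record(self, row: int, col: int) -> ModelRecord:
        return self.database.records[self.record_index[row, col]]

    def save_sidecar(self, path) -> None:
        """Pixel -> model mapping as delimited text (row, col, record, params)."""
        rows = []
        names = self.database.grid.names
        for r in range(self.image.shape[0]):
            for c in range(self.image.shape[1]):
                rec = self.pixel_to_record(r, c)
                rows.append([r, c, self.record_index[r, c]] + [rec.parameters[n] for n in names])
        pd.DataFrame(rows, columns=["row", "col", "record"] + list(names)).to_csv(
            path, sep="\t", index=False)

    def save_png(self, path, cmap: str = "viridis") -> None:
        """Render the distance image; eliminated pixels are black."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        img = np.ma.masked_equal(self.image, ELIMINATED_DISTANCE)
        cm = plt.get_cmap(cmap).copy()
        cm.set_bad("black")
        fig, ax = plt.subplots(figsize=(5, 4.5))
        shown = ax.imshow(img, origin="lower", cmap=cm, interpolation="nearest")
        fig.colorbar(shown, ax=ax, label="distance")
        ax.set_xlabel(" / ".join(self.x_params) or "-")
        ax.set_ylabel(" / ".join(self.y_params) or "-")
        ax.set_title(f"{self.database.scenario_label}: CBDR distance map")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def cbdr_layout(db: ModelDatabase) -> CBDRLayout:
    """Stack the grid into a 2D image ordered by parameter impact."""
    grid = db.grid
    names = grid.names
    dist = {tuple(r.parameters[n] for n in names): r for r in db.records}

    impacts = {}
    for name in names:
        marg = []
        for level in grid.levels(name):
            vals = [r.mean_distance for r in db.records if r.parameters[name] == level]
            marg.append(float(np.mean(vals)))
        impacts[name] = max(marg) - min(marg) if marg else 0.0
    order = tuple(sorted(names, key=lambda n: (-impacts[n], n)))

    y_params = tuple(order[0::2])
    x_params = tuple(order[1::2])

    def axis_size(params):
        return int(np.prod([len(grid.levels(p)) for p in params])) if params else 1

    ny, nx = axis_size(y_params), axis_size(x_params)
    image = np.zeros((ny, nx))
    record_index = np.zeros((ny, nx), dtype=int)
    rec_pos = {tuple(r.parameters[n] for n in names): i for i, r in enumerate(db.records)}

    def decode(idx, params):
        # outermost parameter is the most significant digit
        out = {}
        for p in reversed(params):
            k = len(grid.levels(p))
            out[p] = grid.levels(p)[idx % k]
            idx //= k
        return out

    for row in range(ny):
        yvals = decode(row, y_params)
        for col in range(nx):
            point = dict(yvals)
            point.update(decode(col, x_params))
            key = tuple(point[n] for n in names)
            image[row, col] = dist[key].mean_distance
            record_index[row, col] = rec_pos[key]
    return CBDRLayout(order, y_params, x_params, image, record_index, db)
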