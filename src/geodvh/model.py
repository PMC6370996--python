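"""Geometry-driven DVH prediction.

The model pools, over a training cohort, the prescription-normalized doses of
OAR voxels into 0.5-mm bins of signed distance-to-target (and optionally into
infield/outfield compartments).  For a new patient it assigns each OAR voxel
either the median of its bin's pooled dose-frequency histogram or a
deterministic quantile sample of the whole histogram, and accumulates the
assigned doses into a predicted DVH.  Prediction quality is summarized by the
sum of residuals (SR) and the sum of squared residuals (RSS) between actual
and predicted cumulative DVHs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .dvh import DVHCurve, compute_dvh, DEFAULT_BIN_WIDTH
from .geometry import DistanceMap, FieldLabelMap, StructureMask, VoxelGrid


class ModelError(ValueError):
    pass


class InsufficientTrainingCoverage(ModelError):
    """No training histogram is available for any queried cell."""


# ---------------------------------------------------------------------------
# Plan specification (SIB prescription levels)
# ---------------------------------------------------------------------------

PLAN_TYPES = ("InitPlan", "Boost1", "Boost2", "Boost3")

# prescriptions in Gy per target, and the outermost target whose prescription
# normalizes doses and anchors the distance maps
_PLAN_TABLE = {
    "InitPlan": ({"PTV1": 33.0}, "PTV1"),
    "Boost1": ({"PTV1": 33.0, "PTV2": 25.0}, "PTV2"),
    "Boost2": ({"boostCTV": 40.0, "PTV1": 33.0, "PTV2": 25.0}, "PTV2"),
    "Boost3": ({"PTV1": 33.0, "PTV3": 25.0}, "PTV3"),
}


@dataclass(frozen=True)
class PlanSpec:
    """Prescription structure of one SBRT/SIB-SBRT plan type."""

    plan_type: str
    prescriptions: dict[str, float]
    outermost_target: str

    @classmethod
    def standard(cls, plan_type: str) -> "PlanSpec":
        if plan_type not in _PLAN_TABLE:
            raise ModelError(f"unknown plan type {plan_type!r}; expected one of {PLAN_TYPES}")
        presc, outer = _PLAN_TABLE[plan_type]
        return cls(plan_type, dict(presc), outer)

    @property
    def outermost_prescription(self) -> float:
        return self.prescriptions[self.outermost_target]


@dataclass
class Case:
    """One patient/plan bundle: masks, per-plan dose grids, absence flags."""

    case_id: str
    grid: VoxelGrid
    masks: dict[str, StructureMask]
    doses: dict[str, np.ndarray] = field(default_factory=dict)  # plan type -> Gy grid
    absent: set[str] = field(default_factory=set)

    def oar_doses(self, plan_type: str, oar_label: str) -> np.ndarray:
        """Per-voxel Gy doses of one OAR under one plan (C-order voxel order)."""
        if plan_type not in self.doses:
            raise ModelError(f"case {self.case_id} has no dose for plan {plan_type}")
        return self.doses[plan_type][self.masks[oar_label].inside]


# ---------------------------------------------------------------------------
# Distance binning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceBinSpec:
    """Uniform distance bins; defaults 0.5 mm over [-10, 150) mm."""

    width_mm: float = 0.5
    lower_mm: float = -10.0
    upper_mm: float = 150.0

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.lower_mm >= self.upper_mm:
            raise ModelError(f"invalid bin spec {self}")
        n = (self.upper_mm - self.lower_mm) / self.width_mm
        if abs(n - round(n)) > 1e-9:
            raise ModelError("bin range must be an integer number of bin widths")

    @property
    def n_bins(self) -> int:
        return int(round((self.upper_mm - self.lower_mm) / self.width_mm))

    def centers(self) -> np.ndarray:
        return self.lower_mm + (np.arange(self.n_bins) + 0.5) * self.width_mm


def assign_bins(distances: np.ndarray | DistanceMap, spec: DistanceBinSpec) -> np.ndarray:
    """Bin index per voxel: floor((d - lower)/width), clamped to [0, n_bins)."""
    d = distances.distances if isinstance(distances, DistanceMap) else np.asarray(distances)
    idx = np.floor((d - spec.lower_mm) / spec.width_mm).astype(np.int64)
    return np.clip(idx, 0, spec.n_bins - 1)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

FIELD_LABELS = ("infield", "outfield")


@dataclass(frozen=True)
class ModelConfig:
    assignment_mode: str = "distribution"  # or "median"
    partition_mode: str = "separated"  # or "single"
    apex_interval_mm: float = 0.0  # 0, 5 or 10; ignored for "single"
    bins: DistanceBinSpec = field(default_factory=DistanceBinSpec)
    distance_limit_mm: float | None = None  # train only on bins fully within this distance

    def __post_init__(self) -> None:
        if self.assignment_mode not in ("median", "distribution"):
            raise ModelError(f"unknown assignment mode {self.assignment_mode!r}")
        if self.partition_mode not in ("single", "separated"):
            raise ModelError(f"unknown partition mode {self.partition_mode!r}")
        if self.partition_mode == "separated" and self.apex_interval_mm not in (0, 5, 10):
            raise ModelError("apex interval must be 0, 5 or 10 mm")


@dataclass
class GeoDVHModel:
    """Pooled dose-frequency histograms per (OAR, field label, distance bin)."""

    plan_type: str
    config: ModelConfig
    # (oar, field) -> {bin index -> sorted normalized doses}
    cells: dict[tuple[str, str], dict[int, np.ndarray]]
    training_ids: tuple[str, ...] = ()

    def sample_count(self) -> int:
        return sum(len(h) for cell in self.cells.values() for h in cell.values())

    def nonempty_bins(self, oar: str, fieldlab: str) -> np.ndarray:
        return np.array(sorted(self.cells.get((oar, fieldlab), {}).keys()), dtype=np.int64)


def _field_strings(labels: FieldLabelMap, partition_mode: str) -> np.ndarray:
    if partition_mode == "single":
        return np.full(labels.n_voxels, "infield")
    return np.where(labels.infield, "infield", "outfield")


def _check_limit(spec: DistanceBinSpec, limit_mm: float | None) -> None:
    if limit_mm is not None and limit_mm < spec.lower_mm + spec.width_mm:
        raise ModelError("distance limit below the first bin")


def build_model(
    training: list[tuple[Case, dict[str, DistanceMap], dict[str, FieldLabelMap]]],
    config: ModelConfig,
    plan_type: str,
    oar_labels: tuple[str, ...] | None = None,
) -> GeoDVHModel:
    """Pool normalized OAR voxel doses over a training cohort.

    Each training element carries one case plus its per-OAR distance maps and
    field-label maps (computed against the plan's outermost target).  Doses
    are divided by the outermost target's prescription before pooling.
    """
    if not training:
        raise ModelError("at least one training case is required")
    plan = PlanSpec.standard(plan_type)
    _check_limit(config.bins, config.distance_limit_mm)

    raw: dict[tuple[str, str], dict[int, list[np.ndarray]]] = {}
    ids = []
    for case, dmaps, fmaps in training:
        if plan_type not in case.doses:
            raise ModelError(f"case {case.case_id} lacks a dose grid for {plan_type}")
        ids.append(case.case_id)
        for oar, dmap in dmaps.items():
            if oar_labels is not None and oar not in oar_labels:
                continue
            if dmap.n_voxels == 0:
                continue
            ndose = case.oar_doses(plan_type, oar) / plan.outermost_prescription
            bins = assign_bins(dmap, config.bins)
            fields = _field_strings(fmaps[oar], config.partition_mode)
            within = np.ones(dmap.n_voxels, dtype=bool)
            if config.distance_limit_mm is not None:
                within = dmap.distances <= config.distance_limit_mm
            for flab in np.unique(fields):
                sel = (fields == flab) & within
                b, nd = bins[sel], ndose[sel]
                order = np.argsort(b, kind="stable")
                b, nd = b[order], nd[order]
                uniq, starts = np.unique(b, return_index=True)
                cell = raw.setdefault((oar, str(flab)), {})
                for u, chunk in zip(uniq, np.split(nd, starts[1:])):
                    cell.setdefault(int(u), []).append(chunk)

    cells = {
        key: {b: np.sort(np.concatenate(chunks)) for b, chunks in cell.items()}
        for key, cell in raw.items()
    }
    return GeoDVHModel(plan_type=plan_type, config=config, cells=cells, training_ids=tuple(ids))


def _quantile_sample(sorted_hist: np.ndarray, n: int) -> np.ndarray:
    """Deterministic n-point sample reproducing the histogram's shape.

    Returns the (i - 0.5)/n empirical quantiles, i = 1..n, using the
    inverted-CDF definition, so querying a histogram of its own size returns
    the histogram itself.
    """
    m = len(sorted_hist)
    q = (np.arange(1, n + 1) - 0.5) / n
    idx = np.minimum(np.ceil(q * m).astype(np.int64) - 1, m - 1)
    idx = np.maximum(idx, 0)
    return sorted_hist[idx]


def predict_voxel_doses(
    model: GeoDVHModel, dmap: DistanceMap, labels: FieldLabelMap
) -> np.ndarray:
    """Predicted normalized dose per OAR voxel (aligned with the distance map).

    A query bin with no training samples borrows the nearest nonempty bin with
    the same field label (falling back to the other field label if that
    compartment is entirely empty).  Voxels beyond a configured distance limit
    are assigned normalized dose 0.
    """
    cfg = model.config
    bins = assign_bins(dmap, cfg.bins)
    fields = _field_strings(labels, cfg.partition_mode)
    out = np.zeros(dmap.n_voxels)
    beyond = np.zeros(dmap.n_voxels, dtype=bool)
    if cfg.distance_limit_mm is not None:
        beyond = dmap.distances > cfg.distance_limit_mm

    if not any(model.cells.get((dmap.oar_label, f)) for f in FIELD_LABELS):
        raise InsufficientTrainingCoverage(
            f"insufficient training coverage for OAR {dmap.oar_label!r}"
        )

    for flab in np.unique(fields):
        nonempty = model.nonempty_bins(dmap.oar_label, str(flab))
        use_flab = str(flab)
        if len(nonempty) == 0:  # whole compartment untrained: borrow the other
            other = "outfield" if flab == "infield" else "infield"
            nonempty = model.nonempty_bins(dmap.oar_label, other)
            use_flab = other
        cell = model.cells[(dmap.oar_label, use_flab)]
        sel = (fields == flab) & ~beyond
        if not sel.any():
            continue
        b = bins[sel]
        # nearest nonempty bin per queried bin
        pos = np.searchsorted(nonempty, b)
        pos_lo = np.clip(pos - 1, 0, len(nonempty) - 1)
        pos_hi = np.clip(pos, 0, len(nonempty) - 1)
        lo, hi = nonempty[pos_lo], nonempty[pos_hi]
        nearest = np.where(np.abs(b - lo) <= np.abs(hi - b), lo, hi)
        sel_idx = np.flatnonzero(sel)
        for u in np.unique(nearest):
            grp = sel_idx[nearest == u]
            hist = cell[int(u)]
            if cfg.assignment_mode == "median":
                out[grp] = float(np.median(hist))
            else:
                out[grp] = _quantile_sample(hist, len(grp))
    return out


def predict_dvh(
    model: GeoDVHModel,
    dmap: DistanceMap,
    labels: FieldLabelMap,
    voxel_volume_mL: float,
    bin_width: float = DEFAULT_BIN_WIDTH,
    max_dose: float | None = None,
) -> DVHCurve:
    """Predicted cumulative DVH of one OAR on the normalized dose axis."""
    if dmap.n_voxels == 0:
        return compute_dvh(np.empty(0), voxel_volume_mL, bin_width, max_dose, normalized=True)
    pred = predict_voxel_doses(model, dmap, labels)
    return compute_dvh(pred, voxel_volume_mL, bin_width, max_dose, normalized=True)


# ---------------------------------------------------------------------------
# Residuals
# ---------------------------------------------------------------------------

def _check_axes(actual: DVHCurve, predicted: DVHCurve) -> None:
    if len(actual.edges) != len(predicted.edges) or not np.allclose(
        actual.edges, predicted.edges
    ):
        raise ModelError("DVH curves must share the same dose axis for residuals")


def sum_of_residuals(actual: DVHCurve, predicted: DVHCurve) -> float:
    """Signed SR = sum_D (DVH(D) - DVHpred(D)) * dD; positive means the model
    underpredicts dose-volume."""
    _check_axes(actual, predicted)
    dd = actual.bin_width
    return float(np.sum(actual.cumulative - predicted.cumulative) * dd)


def rss(actual: DVHCurve, predicted: DVHCurve) -> float:
    """RSS = sum_D ((DVH(D) - DVHpred(D)) * dD)^2 >= 0."""
    _check_axes(actual, predicted)
    dd = actual.bin_width
    diff = (actual.cumulative - predicted.cumulative) * dd
    return float(np.sum(diff * diff))


@dataclass
class ResidualReport:
    sr: float
    rss: float
    per_oar: dict[str, tuple[float, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Serialization (single .npz archive: JSON config + one array per cell)
# ---------------------------------------------------------------------------

def save_model(model: GeoDVHModel, path) -> None:
    cfg = {
        "plan_type": model.plan_type,
        "training_ids": list(model.training_ids),
        "assignment_mode": model.config.assignment_mode,
        "partition_mode": model.config.partition_mode,
        "apex_interval_mm": model.config.apex_interval_mm,
        "distance_limit_mm": model.config.distance_limit_mm,
        "bins": asdict(model.config.bins),
    }
    arrays = {"__config__": np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8)}
    for (oar, flab), cell in model.cells.items():
        for b, hist in cell.items():
            arrays[f"{oar}|{flab}|{b}"] = hist
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path) -> GeoDVHModel:
    with np.load(path) as data:
        cfg = json.loads(bytes(data["__config__"]).decode())
        cells: dict[tuple[str, str], dict[int, np.ndarray]] = {}
        for key in data.files:
            if key == "__config__":
                continue
            oar, flab, b = key.rsplit("|", 2)
            cells.setdefault((oar, flab), {})[int(b)] = data[key]
    config = ModelConfig(
        assignment_mode=cfg["assignment_mode"],
        partition_mode=cfg["partition_mode"],
        apex_interval_mm=cfg["apex_interval_mm"],
        bins=DistanceBinSpec(**cfg["bins"]),
        distance_limit_mm=cfg["distance_limit_mm"],
    )
    return GeoDVHModel(
        plan_type=cfg["plan_type"],
        config=config,
        cells=cells,
        training_ids=tuple(cfg["training_ids"]),
    )
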