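"""Evaluation machinery for the geometry-driven DVH model.

Covers four studies: self-consistency (train on the whole cohort, predict the
same cohort, summarize SR per model variant), repeated twofold
cross-validation with violation-prediction confusion metrics (PPV/NPV/AC),
the distance-limit experiment (how far from the target the dose-frequency
histograms must reach before prediction quality plateaus), and a Monte-Carlo
simulation placing virtual GI organs of varying volume and distance to map
planning feasibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dvh import (
    Constraint,
    ConstraintSet,
    DVHCurve,
    MetricKind,
    compute_dvh,
    dvh_metric,
    DEFAULT_BIN_WIDTH,
)
from .geometry import DistanceMap, FieldLabelMap, outfield_mask, signed_distance_field
from .model import (
    Case,
    GeoDVHModel,
    ModelConfig,
    PlanSpec,
    PLAN_TYPES,
    build_model,
    predict_dvh,
    rss,
    sum_of_residuals,
)

GI_OARS = ("stomach", "duodenum", "bowel")
GI_METRIC_THRESHOLDS = (1.0, 3.0, 9.0)  # D1mL, D3mL, D9mL

# Upper end of the prescription-normalized dose axis shared by all curves
# (hot spots reach ~1.6 x the outermost prescription under SIB plans).
NORM_AXIS_MAX = 2.5


# ---------------------------------------------------------------------------
# Cohort preparation: distance maps, field maps and actual DVHs per plan
# ---------------------------------------------------------------------------

@dataclass
class PreparedPlanCase:
    """Everything the model needs about one (case, plan) pair."""

    case: Case
    plan: PlanSpec
    dmaps: dict[str, DistanceMap]
    fmaps: dict[float, dict[str, FieldLabelMap]]  # apex interval -> per-OAR map
    actual_ndvh: dict[str, DVHCurve]  # normalized dose axis

    def fmap(self, oar: str, interval_mm: float) -> FieldLabelMap:
        return self.fmaps[interval_mm][oar]


def prepare_case(
    case: Case,
    plan_type: str,
    oar_labels: tuple[str, ...] = GI_OARS,
    intervals: tuple[float, ...] = (0.0,),
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> PreparedPlanCase:
    """Compute distance maps, cone partitions and actual normalized DVHs."""
    plan = PlanSpec.standard(plan_type)
    outer = case.masks[plan.outermost_target]
    sdf = signed_distance_field(outer)
    dmaps: dict[str, DistanceMap] = {}
    actual: dict[str, DVHCurve] = {}
    present = [o for o in oar_labels if o not in case.absent and o in case.masks]
    for oar in present:
        m = case.masks[oar]
        idx = np.argwhere(m.inside)
        dmaps[oar] = DistanceMap(
            oar_label=oar,
            target_label=plan.outermost_target,
            grid=case.grid,
            voxel_indices=idx,
            distances=sdf[m.inside.nonzero()] if idx.size else np.empty(0),
        )
        nd = case.oar_doses(plan_type, oar) / plan.outermost_prescription
        actual[oar] = compute_dvh(
            nd, case.grid.voxel_volume_mL, bin_width, max_dose=NORM_AXIS_MAX, normalized=True
        )
    fmaps: dict[float, dict[str, FieldLabelMap]] = {}
    for iv in intervals:
        out = outfield_mask(outer, iv)  # grid-wide cone, shared across OARs
        fmaps[iv] = {
            oar: FieldLabelMap(
                oar_label=oar,
                apex_interval_mm=float(iv),
                infield=~out[case.masks[oar].inside.nonzero()],
            )
            for oar in present
        }
    return PreparedPlanCase(case=case, plan=plan, dmaps=dmaps, fmaps=fmaps, actual_ndvh=actual)


def prepare_cohort(
    cases: list[Case],
    plan_types: tuple[str, ...] = PLAN_TYPES,
    oar_labels: tuple[str, ...] = GI_OARS,
    intervals: tuple[float, ...] = (0.0,),
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> dict[str, list[PreparedPlanCase]]:
    return {
        pt: [prepare_case(c, pt, oar_labels, intervals, bin_width) for c in cases]
        for pt in plan_types
    }


def _training_tuples(prepared: list[PreparedPlanCase], interval: float):
    return [(p.case, p.dmaps, p.fmaps[interval]) for p in prepared]


def _interval_of(config: ModelConfig) -> float:
    return config.apex_interval_mm if config.partition_mode == "separated" else 0.0


def _predict_case(
    model: GeoDVHModel, p: PreparedPlanCase, oar: str, bin_width: float = DEFAULT_BIN_WIDTH
) -> DVHCurve:
    return predict_dvh(
        model,
        p.dmaps[oar],
        p.fmap(oar, _interval_of(model.config)),
        p.case.grid.voxel_volume_mL,
        bin_width=bin_width,
        max_dose=NORM_AXIS_MAX,
    )


# ---------------------------------------------------------------------------
# Self-consistency
# ---------------------------------------------------------------------------

def self_consistency(
    prepared: dict[str, list[PreparedPlanCase]],
    model_configs: dict[str, ModelConfig],
    oar_labels: tuple[str, ...] = GI_OARS,
    return_raw: bool = False,
):
    """Train each model variant on all cases and predict the same cases.

    Returns per (plan, OAR, config) the mean and SD of the sum of residuals
    across cases, plus a flag for the self-consistency criterion
    |mean SR| < 0.5 * SD(SR).  With ``return_raw`` a second DataFrame carries
    one row per (config, plan, case, OAR).
    """
    rows = []
    raw_rows = []
    for pt, plist in prepared.items():
        if len(plist) < 2:
            raise ValueError("self-consistency requires at least 2 cases")
        for cname, cfg in model_configs.items():
            iv = _interval_of(cfg)
            model = build_model(_training_tuples(plist, iv), cfg, pt, oar_labels)
            srs: dict[str, list[float]] = {o: [] for o in oar_labels}
            for p in plist:
                for oar in oar_labels:
                    if oar not in p.dmaps:
                        continue
                    pred = _predict_case(model, p, oar)
                    sr = sum_of_residuals(p.actual_ndvh[oar], pred)
                    srs[oar].append(sr)
                    raw_rows.append(
                        {"config": cname, "plan": pt, "case": p.case.case_id,
                         "oar": oar, "sr": sr}
                    )
            for oar, vals in srs.items():
                if not vals:
                    continue
                mean = float(np.mean(vals))
                sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
                rows.append(
                    {
                        "plan": pt,
                        "oar": oar,
                        "config": cname,
                        "mean_sr": mean,
                        "sd_sr": sd,
                        "n": len(vals),
                        "self_consistent": bool(abs(mean) < 0.5 * sd) if np.isfinite(sd) else None,
                    }
                )
    if return_raw:
        return pd.DataFrame(rows), pd.DataFrame(raw_rows)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cross-validation and confusion metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossValConfig:
    repeats: int = 25
    folds: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repeats < 1 or self.folds != 2:
            raise ValueError("cross-validation is twofold with >= 1 repeats")


@dataclass
class ConfusionSummary:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def add(self, predicted: bool, actual: bool) -> None:
        if predicted and actual:
            self.tp += 1
        elif predicted and not actual:
            self.fp += 1
        elif not predicted and actual:
            self.fn += 1
        else:
            self.tn += 1

    def metrics(self) -> "ConfusionMetrics":
        return confusion_metrics(self.tp, self.fp, self.tn, self.fn)


@dataclass
class ConfusionMetrics:
    ppv: float | None
    npv: float | None
    ac: float | None

    @staticmethod
    def _pct(x: float | None) -> float | None:
        return None if x is None else round(100.0 * x)

    @property
    def ppv_pct(self):
        return self._pct(self.ppv)

    @property
    def npv_pct(self):
        return self._pct(self.npv)

    @property
    def ac_pct(self):
        return self._pct(self.ac)


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    """PPV, NPV and accuracy as exact ratios (None where undefined)."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be >= 0")
    total = tp + fp + tn + fn
    ppv = tp / (tp + fp) if tp + fp > 0 else None
    npv = tn / (tn + fn) if tn + fn > 0 else None
    ac = (tp + tn) / total if total > 0 else None
    return ConfusionMetrics(ppv=ppv, npv=npv, ac=ac)


def prediction_count(
    present_gi_counts: list[int], n_repeats: int, n_plans: int, n_metrics: int = 3
) -> int:
    """Bookkeeping identity for the total number of violation predictions.

    One prediction per (validation case x repeat x plan x present GI-OAR x
    metric); each case is validated exactly once per repeat.
    """
    return n_repeats * n_plans * n_metrics * sum(present_gi_counts)


def _gi_constraints(constraints: ConstraintSet, oar: str) -> list[Constraint]:
    cons = [
        c
        for c in constraints.for_structure(oar)
        if c.metric.kind is MetricKind.D_AT_VOLUME_ML
        and c.metric.threshold in GI_METRIC_THRESHOLDS
    ]
    return sorted(cons, key=lambda c: c.metric.threshold)


@dataclass
class CrossValResult:
    confusion: ConfusionSummary
    per_metric_confusion: dict[str, ConfusionSummary]
    residuals: pd.DataFrame  # one row per (repeat, plan, case, oar): sr, rss
    n_predictions: int = 0


def cross_validate(
    prepared: dict[str, list[PreparedPlanCase]],
    cv: CrossValConfig,
    model_config: ModelConfig,
    constraints: ConstraintSet,
    oar_labels: tuple[str, ...] = GI_OARS,
) -> CrossValResult:
    """Repeated twofold cross-validation of violation prediction.

    Per repeat the cohort is split at random into two halves; each half trains
    a model that predicts the other half's DVHs.  For every validation case,
    plan, present GI-OAR and hot-spot metric (D1/D3/D9mL) the predicted
    violation is compared with the actual one; counts pool over both folds and
    all repeats.  Absent organs are skipped from counting.
    """
    n = len(next(iter(prepared.values())))
    if n < 4:
        raise ValueError("need at least 2 cases per fold")
    rng = np.random.default_rng(cv.seed)
    iv = _interval_of(model_config)
    confusion = ConfusionSummary()
    per_metric = {f"D{int(t)}mL": ConfusionSummary() for t in GI_METRIC_THRESHOLDS}
    rows = []

    for rep in range(cv.repeats):
        perm = rng.permutation(n)
        half = n // 2
        folds = (perm[:half], perm[half:])
        for k in (0, 1):
            train_idx, valid_idx = folds[k], folds[1 - k]
            for pt, plist in prepared.items():
                model = build_model(
                    _training_tuples([plist[i] for i in train_idx], iv),
                    model_config,
                    pt,
                    oar_labels,
                )
                presc = plist[0].plan.outermost_prescription
                for i in valid_idx:
                    p = plist[i]
                    for oar in oar_labels:
                        if oar not in p.dmaps:
                            continue
                        pred_n = _predict_case(model, p, oar)
                        act_n = p.actual_ndvh[oar]
                        sr = sum_of_residuals(act_n, pred_n)
                        r2 = rss(act_n, pred_n)
                        rows.append(
                            {"repeat": rep, "plan": pt, "case": p.case.case_id,
                             "oar": oar, "sr": sr, "rss": r2}
                        )
                        pred_gy = pred_n.to_gy(presc)
                        act_gy = act_n.to_gy(presc)
                        for con in _gi_constraints(constraints, oar):
                            pv = dvh_metric(pred_gy, con.metric).value
                            av = dvh_metric(act_gy, con.metric).value
                            predicted_violation = not con.passes(pv)
                            actual_violation = not con.passes(av)
                            confusion.add(predicted_violation, actual_violation)
                            per_metric[f"D{int(con.metric.threshold)}mL"].add(
                                predicted_violation, actual_violation
                            )
    return CrossValResult(
        confusion=confusion,
        per_metric_confusion=per_metric,
        residuals=pd.DataFrame(rows),
        n_predictions=confusion.total,
    )


# ---------------------------------------------------------------------------
# Plan-validity pooling
# ---------------------------------------------------------------------------

def pooled_validity_ratio(violation_counts: dict[str, int], n_cases: int) -> float:
    """Fraction of valid plans pooled over the given plan types.

    ``violation_counts`` maps plan type -> number of cases with >= 1 constraint
    violation under that plan.
    """
    if any(v < 0 or v > n_cases for v in violation_counts.values()):
        raise ValueError("violation counts must lie in [0, n_cases]")
    valid = sum(n_cases - v for v in violation_counts.values())
    return valid / (n_cases * len(violation_counts))


def case_constraint_report(
    case: Case, plan_type: str, constraints: ConstraintSet, bin_width_gy: float = 0.1
):
    """Evaluate every dose constraint on one case's actual dose grid.

    The combined kidney is the union of the left and right kidney masks.
    Returns (DataFrame with one row per constraint, plan_valid flag).
    """
    from .dvh import check_constraints

    dvhs: dict[str, DVHCurve] = {}
    structures = {c.structure for c in constraints}
    vol = case.grid.voxel_volume_mL
    for s in structures:
        if s in case.absent:
            continue
        if s == "kidney" and "kidney" not in case.masks:
            inside = case.masks["kidney_L"].inside | case.masks["kidney_R"].inside
            doses = case.doses[plan_type][inside]
        elif s in case.masks:
            doses = case.oar_doses(plan_type, s)
        else:
            continue
        dvhs[s] = compute_dvh(doses, vol, bin_width=bin_width_gy)
    absent = {s for s in structures if s not in dvhs}
    validity = check_constraints(dvhs, constraints, absent=absent)
    rows = [
        {
            "structure": r.constraint.structure,
            "metric": str(r.constraint.metric),
            "value": r.value,
            "comparator": r.constraint.comparator,
            "limit": r.constraint.limit,
            "passed": r.passed,
            "undersized": r.undersized,
        }
        for r in validity.results
    ]
    return pd.DataFrame(rows), validity.plan_valid


# ---------------------------------------------------------------------------
# Distance-limit experiment
# ---------------------------------------------------------------------------

def distance_limit_experiment(
    prepared: dict[str, list[PreparedPlanCase]],
    model_config: ModelConfig,
    limits_mm: tuple[float, ...] = tuple(range(5, 55, 5)),
    oar_labels: tuple[str, ...] = GI_OARS,
) -> pd.DataFrame:
    """RSS as a function of the usable distance-to-target range.

    For each limit L the model is trained only on voxels within L of the
    target and, at prediction, voxels beyond L receive normalized dose 0, so
    RSS measures the information lost by truncating the dose-frequency
    histograms.  The output includes RSS normalized by its value at the
    smallest limit.
    """
    rows = []
    for limit in limits_mm:
        cfg = ModelConfig(
            assignment_mode=model_config.assignment_mode,
            partition_mode=model_config.partition_mode,
            apex_interval_mm=model_config.apex_interval_mm,
            bins=model_config.bins,
            distance_limit_mm=float(limit),
        )
        iv = _interval_of(cfg)
        vals = []
        for pt, plist in prepared.items():
            model = build_model(_training_tuples(plist, iv), cfg, pt, oar_labels)
            for p in plist:
                for oar in oar_labels:
                    if oar not in p.dmaps:
                        continue
                    pred = _predict_case(model, p, oar)
                    vals.append(rss(p.actual_ndvh[oar], pred))
        rows.append({"limit_mm": float(limit), "mean_rss": float(np.mean(vals))})
    df = pd.DataFrame(rows).sort_values("limit_mm", ignore_index=True)
    df["rss_ratio"] = df["mean_rss"] / df["mean_rss"].iloc[0]
    return df


# ---------------------------------------------------------------------------
# Virtual-OAR feasibility simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VirtualOARSpec:
    volumes_mL: tuple[float, ...] = tuple(range(5, 55, 5))
    distance_edges_mm: tuple[float, ...] = tuple(range(0, 65, 5))  # cells 0-5 ... 55-60
    n_draws: int = 250
    seed: int = 0
    placement_sd_mm: float = 1.25  # Gaussian SD of the blob-center distance
    grid_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.5)

    def __post_init__(self) -> None:
        if self.n_draws < 1 or min(self.volumes_mL) <= 0:
            raise ValueError("need >= 1 draw and positive volumes")


@dataclass
class VirtualOARResult:
    spec: VirtualOARSpec
    any_violation: pd.DataFrame  # index volumes, columns distance-cell labels
    per_metric: dict[str, pd.DataFrame]


def _nested_ball_offsets(spec: VirtualOARSpec) -> tuple[np.ndarray, np.ndarray]:
    """Voxel offsets of a digitized ball big enough for the largest volume.

    Returns (x-offsets mm sorted by radius, cumulative-count order) such that
    the first n voxels form the (deformed) ball of volume n * voxel volume;
    smaller volumes are nested inside larger ones.
    """
    sx, sy, sz = spec.grid_spacing_mm
    voxel_mL = sx * sy * sz / 1000.0
    n_max = int(round(max(spec.volumes_mL) / voxel_mL))
    r_mm = (3 * max(spec.volumes_mL) * 1000 / (4 * np.pi)) ** (1 / 3) * 1.5 + max(sx, sy, sz)
    nx, ny, nz = (int(np.ceil(r_mm / s)) for s in (sx, sy, sz))
    ox = np.arange(-nx, nx + 1) * sx
    oy = np.arange(-ny, ny + 1) * sy
    oz = np.arange(-nz, nz + 1) * sz
    gx, gy, gz = np.meshgrid(ox, oy, oz, indexing="ij")
    r = np.sqrt(gx**2 + gy**2 + gz**2).ravel()
    order = np.lexsort((gz.ravel(), gy.ravel(), gx.ravel(), r))[:n_max]
    return gx.ravel()[order], r[order]


def virtual_oar_simulation(
    model: GeoDVHModel,
    plan: PlanSpec,
    constraints: ConstraintSet,
    spec: VirtualOARSpec = VirtualOARSpec(),
    gi_label: str = "stomach",
) -> VirtualOARResult:
    """Monte-Carlo feasibility map over virtual GI-OAR volume and distance.

    For every (volume, distance-cell) pair, ``n_draws`` virtual organs are
    placed: a voxelized ball of the exact requested volume whose center
    distance to the target is drawn from a Gaussian around the cell midpoint;
    voxel distances vary across the ball along a lateral (infield) axis.  The
    model predicts each draw's DVH and the D1/D3/D9mL limits are checked; each
    cell reports the fraction of draws violating each metric and any metric.

    The same Gaussian deviates are reused across all cells (common random
    numbers), so cell-to-cell comparisons are paired.
    """
    sx, sy, sz = spec.grid_spacing_mm
    voxel_mL = sx * sy * sz / 1000.0
    offs_x, _ = _nested_ball_offsets(spec)
    cons = _gi_constraints(constraints, gi_label)
    rng = np.random.default_rng(spec.seed)
    z_draws = rng.standard_normal(spec.n_draws)  # shared across cells

    edges = spec.distance_edges_mm
    cells = list(zip(edges[:-1], edges[1:]))
    cell_labels = [f"{lo:g}-{hi:g}mm" for lo, hi in cells]
    metric_names = [f"D{int(c.metric.threshold)}mL" for c in cons]
    any_mat = np.zeros((len(spec.volumes_mL), len(cells)))
    per_metric = {m: np.zeros_like(any_mat) for m in metric_names}

    grid_stub = None  # DistanceMap.grid unused by prediction
    from .geometry import VoxelGrid

    grid_stub = VoxelGrid((1, 1, 1), spec.grid_spacing_mm)

    for vi, vol in enumerate(spec.volumes_mL):
        n_vox = int(round(vol / voxel_mL))
        if n_vox < 1 or n_vox > len(offs_x):
            raise ValueError(f"requested volume {vol} mL unachievable on grid")
        blob_x = offs_x[:n_vox]
        for ci, (lo, hi) in enumerate(cells):
            mean_d = 0.5 * (lo + hi)
            n_any = 0
            n_metric = {m: 0 for m in metric_names}
            for z in z_draws:
                d_center = mean_d + spec.placement_sd_mm * z
                d = d_center + blob_x
                dmap = DistanceMap(
                    oar_label=gi_label,
                    target_label=plan.outermost_target,
                    grid=grid_stub,
                    voxel_indices=np.empty((n_vox, 0)),
                    distances=d,
                )
                fmap = FieldLabelMap(
                    oar_label=gi_label,
                    apex_interval_mm=model.config.apex_interval_mm,
                    infield=np.ones(n_vox, dtype=bool),
                )
                pred = predict_dvh(
                    model, dmap, fmap, voxel_mL, max_dose=NORM_AXIS_MAX
                ).to_gy(plan.outermost_prescription)
                violated_any = False
                for con, mname in zip(cons, metric_names):
                    v = dvh_metric(pred, con.metric).value
                    if not con.passes(v):
                        n_metric[mname] += 1
                        violated_any = True
                n_any += violated_any
            any_mat[vi, ci] = n_any / spec.n_draws
            for m in metric_names:
                per_metric[m][vi, ci] = n_metric[m] / spec.n_draws

    idx = pd.Index(spec.volumes_mL, name="volume_mL")
    return VirtualOARResult(
        spec=spec,
        any_violation=pd.DataFrame(any_mat, index=idx, columns=cell_labels),
        per_metric={
            m: pd.DataFrame(v, index=idx, columns=cell_labels) for m, v in per_metric.items()
        },
    )
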