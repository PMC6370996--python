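"""Cumulative DVH computation, DVH-metric extraction and constraint checking.

A cumulative DVH gives, for each dose level D, the fraction of a structure's
volume receiving at least D.  Metrics follow clinical convention: DxmL / Dx%
is the minimum dose to the hottest x mL (or x %) of the structure, VxGy is
the volume (in % or mL) receiving at least x Gy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources

import numpy as np


class DVHError(ValueError):
    pass


# Default dose-axis bin width on the prescription-normalized axis; ~0.17 Gy
# at a 33 Gy prescription, fine enough that binning error is negligible
# relative to typical DVH-prediction residuals.
DEFAULT_BIN_WIDTH = 0.005


@dataclass
class DVHCurve:
    """Cumulative dose–volume curve on a uniform dose axis.

    ``edges`` are dose bin edges (uniform width); ``cumulative[i]`` is the
    fraction of the structure receiving >= ``edges[i]``.  ``normalized`` marks
    a prescription-normalized dose axis (vs absolute Gy).
    """

    edges: np.ndarray
    cumulative: np.ndarray
    volume_mL: float
    mean_dose: float = float("nan")
    normalized: bool = False
    empty: bool = False

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    def to_gy(self, prescription: float) -> "DVHCurve":
        """Denormalize a prescription-normalized curve to absolute Gy."""
        if not self.normalized:
            return self
        return DVHCurve(
            edges=self.edges * prescription,
            cumulative=self.cumulative.copy(),
            volume_mL=self.volume_mL,
            mean_dose=self.mean_dose * prescription,
            normalized=False,
            empty=self.empty,
        )


def compute_dvh(
    doses: np.ndarray,
    voxel_volume_mL: float,
    bin_width: float = DEFAULT_BIN_WIDTH,
    max_dose: float | None = None,
    normalized: bool = False,
) -> DVHCurve:
    """Cumulative DVH of a structure's per-voxel doses.

    The curve value at edge D is the fraction of voxels with dose >= D.  An
    empty voxel list yields an ``empty``-flagged curve with undefined metrics.
    ``max_dose`` fixes the upper end of the axis so curves from different
    structures share a common grid.
    """
    if bin_width <= 0:
        raise DVHError("bin_width must be > 0")
    doses = np.asarray(doses, dtype=float).ravel()
    if doses.size and doses.min() < 0:
        raise DVHError("negative doses rejected")
    top = max_dose if max_dose is not None else (doses.max() if doses.size else 0.0)
    n_bins = max(int(np.ceil(top / bin_width + 1e-9)) + 1, 2)
    edges = np.arange(n_bins) * bin_width
    if doses.size == 0:
        return DVHCurve(edges, np.zeros(n_bins), 0.0, normalized=normalized, empty=True)
    # fraction of voxels with dose >= edge, via a histogram tail sum
    counts, _ = np.histogram(doses, bins=np.append(edges, np.inf))
    cumulative = counts[::-1].cumsum()[::-1] / doses.size
    return DVHCurve(
        edges=edges,
        cumulative=cumulative,
        volume_mL=doses.size * voxel_volume_mL,
        mean_dose=float(doses.mean()),
        normalized=normalized,
    )


class MetricKind(str, Enum):
    D_AT_VOLUME_ML = "D_at_volume_mL"
    D_AT_VOLUME_PCT = "D_at_volume_pct"
    V_AT_DOSE_GY_PCT = "V_at_dose_Gy_pct"
    V_AT_DOSE_GY_ML = "V_at_dose_Gy_mL"
    DMEAN = "Dmean"


@dataclass(frozen=True)
class MetricSpec:
    kind: MetricKind
    threshold: float = float("nan")

    def __str__(self) -> str:
        if self.kind is MetricKind.DMEAN:
            return "Dmean"
        unit = {"D_at_volume_mL": "mL", "D_at_volume_pct": "%",
                "V_at_dose_Gy_pct": "Gy", "V_at_dose_Gy_mL": "Gy"}[self.kind.value]
        prefix = "D" if self.kind.value.startswith("D") else "V"
        t = self.threshold
        return f"{prefix}{t:g}{unit}"


@dataclass
class MetricValue:
    value: float
    undersized: bool = False  # mL threshold exceeded structure volume


def _dose_at_fraction(curve: DVHCurve, frac: float) -> float:
    """Largest dose edge whose cumulative volume is >= ``frac``.

    The step convention keeps the metric within one bin width of the exact
    order statistic and never overstates the dose of a mass concentration
    sitting exactly on a bin edge.
    """
    cum = curve.cumulative
    hits = np.flatnonzero(cum >= frac)
    if hits.size == 0:
        return float(curve.edges[0])
    return float(curve.edges[hits[-1]])


def dvh_metric(curve: DVHCurve, spec: MetricSpec) -> MetricValue:
    """Evaluate one DVH metric on a cumulative curve.

    D-at-volume is the largest dose edge whose cumulative volume reaches the
    threshold; V-at-dose interpolates the cumulative value at the query dose.
    An mL threshold larger than the structure volume returns the minimum dose
    edge with the ``undersized`` flag set.
    """
    if curve.empty:
        raise DVHError("metrics are undefined on an empty structure")
    if spec.kind is MetricKind.DMEAN:
        return MetricValue(curve.mean_dose)
    if spec.kind is MetricKind.D_AT_VOLUME_ML:
        if spec.threshold > curve.volume_mL:
            return MetricValue(float(curve.edges[0]), undersized=True)
        return MetricValue(_dose_at_fraction(curve, spec.threshold / curve.volume_mL))
    if spec.kind is MetricKind.D_AT_VOLUME_PCT:
        return MetricValue(_dose_at_fraction(curve, spec.threshold / 100.0))
    # V-at-dose: interpolated cumulative at the query dose
    d = spec.threshold
    if d <= curve.edges[0]:
        frac = float(curve.cumulative[0])
    elif d >= curve.edges[-1]:
        frac = float(curve.cumulative[-1])
    else:
        frac = float(np.interp(d, curve.edges, curve.cumulative))
    if spec.kind is MetricKind.V_AT_DOSE_GY_PCT:
        return MetricValue(100.0 * frac)
    return MetricValue(frac * curve.volume_mL)


# ---------------------------------------------------------------------------
# Constraint set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Constraint:
    structure: str
    metric: MetricSpec
    comparator: str  # "le" or "lt"
    limit: float

    def __post_init__(self) -> None:
        if self.comparator not in ("le", "lt"):
            raise DVHError(f"unknown comparator {self.comparator!r}")
        if self.limit <= 0:
            raise DVHError("constraint limits must be strictly positive")

    def passes(self, value: float) -> bool:
        return value <= self.limit if self.comparator == "le" else value < self.limit

    def __str__(self) -> str:
        op = "<=" if self.comparator == "le" else "<"
        return f"{self.structure} {self.metric} {op} {self.limit:g}"


GI_OARS = ("stomach", "duodenum", "bowel")

KNOWN_LABELS = GI_OARS + ("kidney", "kidney_L", "kidney_R", "liver", "cord")


@dataclass
class ConstraintSet:
    """The OAR dose limits driving violation prediction and plan validity."""

    constraints: tuple[Constraint, ...]
    version: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for c in self.constraints:
            key = (c.structure, c.metric)
            if key in seen:
                raise DVHError(f"duplicate constraint for {c.structure} {c.metric}")
            seen.add(key)
            if c.structure not in KNOWN_LABELS:
                raise DVHError(f"constraint references unknown structure {c.structure!r}")

    def __iter__(self):
        return iter(self.constraints)

    def for_structure(self, label: str) -> list[Constraint]:
        return [c for c in self.constraints if c.structure == label]

    @classmethod
    def from_json(cls, payload: dict) -> "ConstraintSet":
        cons = tuple(
            Constraint(
                structure=c["structure"],
                metric=MetricSpec(MetricKind(c["metric_kind"]), float(c["threshold"])),
                comparator=c["comparator"],
                limit=float(c["limit"]),
            )
            for c in payload["constraints"]
        )
        return cls(cons, version=payload.get("version", ""))

    @classmethod
    def default(cls) -> "ConstraintSet":
        """The shipped five-fraction pancreatic SBRT constraint set."""
        text = resources.files("geodvh.data").joinpath("constraints_v1.json").read_text()
        return cls.from_json(json.loads(text))


@dataclass
class ConstraintResult:
    constraint: Constraint
    value: float | None  # None when the structure is absent
    passed: bool | None  # None when skipped
    undersized: bool = False

    @property
    def evaluated(self) -> bool:
        return self.passed is not None


@dataclass
class PlanValidity:
    results: list[ConstraintResult]
    plan_valid: bool

    def violations(self) -> list[ConstraintResult]:
        return [r for r in self.results if r.passed is False]


def check_constraints(
    dvhs: dict[str, DVHCurve],
    constraints: ConstraintSet,
    absent: set[str] | frozenset[str] = frozenset(),
) -> PlanValidity:
    """Evaluate every constraint against per-structure DVHs (absolute Gy axis).

    Structures listed in ``absent`` (e.g. a surgically removed duodenum) are
    skipped, not failed; the plan is valid iff all evaluable constraints pass.
    """
    results = []
    for con in constraints:
        if con.structure in absent:
            results.append(ConstraintResult(con, None, None))
            continue
        if con.structure not in dvhs:
            raise DVHError(
                f"constraint structure {con.structure!r} neither present nor marked absent"
            )
        curve = dvhs[con.structure]
        if curve.normalized:
            raise DVHError("constraint checking requires absolute-Gy DVH curves")
        if curve.empty:
            results.append(ConstraintResult(con, None, None))
            continue
        mv = dvh_metric(curve, con.metric)
        results.append(
            ConstraintResult(con, mv.value, con.passes(mv.value), undersized=mv.undersized)
        )
    valid = all(r.passed for r in results if r.evaluated)
    return PlanValidity(results=results, plan_valid=valid)
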