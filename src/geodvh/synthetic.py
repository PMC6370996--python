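"""Synthetic pancreatic SBRT cohorts.

Generates voxelized cases whose statistical structure matches what the
distance-bin DVH model assumes: organ doses that are chiefly a function of
signed distance to the outermost target and of infield/outfield membership,
with multiplicative noise and mild case-to-case falloff variation.  The dose
engine is an analytic stand-in emulating SBRT falloff, not a treatment
planning system: dose equals the prescription inside targets and decays as a
sigmoid of distance outside, with a steeper scale in the outfield double cone.

Geometries follow the clinical construction rules: CTVgeom is a 10-mm
(15-mm posterior) expansion of the GTV, PTV1/2/3 are 3-mm expansions of
GTV/CTVgeom/CTVprop with GI-OAR overlaps subtracted, and a boost CTV excludes
tissue within 10 mm of the GI-OARs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import (
    Margins,
    StructureMask,
    VoxelGrid,
    expand_mask,
    outfield_mask,
    signed_distance_field,
    subtract_overlap,
)
from .model import Case, PlanSpec, PLAN_TYPES

GI_OARS = ("stomach", "duodenum", "bowel")


@dataclass(frozen=True)
class OARSpec:
    """Placement recipe for one synthetic organ."""

    label: str
    volume_range_mL: tuple[float, float]
    direction: tuple[float, float, float]  # unit-ish LPS direction from the GTV
    gap_mean_mm: float  # nearest-surface distance to the GTV, |Normal(mean, sd)|
    gap_sd_mm: float
    elongation: float = 1.0  # >1 stretches the blob along z (tubular organs)


def _default_oars() -> tuple[OARSpec, ...]:
    # GI organs close enough to populate every proximity regime; kidneys,
    # liver and cord sit far, as in the abdomen.
    return (
        OARSpec("stomach", (30, 80), (0.5, -0.7, 0.3), 10.0, 8.0),
        OARSpec("duodenum", (20, 60), (-0.9, 0.2, -0.2), 8.0, 7.0, elongation=1.6),
        OARSpec("bowel", (40, 100), (0.2, -0.6, -0.7), 12.0, 9.0),
        OARSpec("kidney_L", (80, 120), (0.85, 0.5, -0.15), 30.0, 5.0),
        OARSpec("kidney_R", (80, 120), (-0.85, 0.5, -0.15), 30.0, 5.0),
        OARSpec("liver", (150, 250), (-0.7, -0.4, 0.35), 25.0, 5.0),
        OARSpec("cord", (15, 25), (0.0, 1.0, 0.0), 45.0, 5.0, elongation=6.0),
    )


@dataclass(frozen=True)
class FalloffParams:
    """Analytic dose engine: dose = P / (1 + (d / d_half)^k) outside targets."""

    infield_half_mm: float = 20.0
    outfield_half_mm: float = 8.0
    sharpness: float = 3.0
    noise_sd: float = 0.1  # lognormal sigma of multiplicative voxel noise
    case_jitter_sd: float = 0.1  # lognormal sigma of per-case half-distance scaling

    def __post_init__(self) -> None:
        if self.outfield_half_mm >= self.infield_half_mm:
            raise ValueError("outfield falloff must be steeper than infield")
        if self.noise_sd < 0 or self.case_jitter_sd < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass(frozen=True)
class CohortParams:
    n_cases: int = 20
    gtv_volume_range_mL: tuple[float, float] = (4.0, 101.0)
    grid_dims: tuple[int, int, int] = (96, 96, 64)
    grid_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.5)
    ctvgeom_margin_mm: float = 10.0
    ctvgeom_posterior_mm: float = 15.0
    ctvprop_margin_mm: float = 15.0  # stand-in for the elective nodal CTV
    boost_margin_mm: float = 5.0
    boost_gi_clearance_mm: float = 10.0
    ptv_margin_mm: float = 3.0
    oars: tuple[OARSpec, ...] = field(default_factory=_default_oars)
    falloff: FalloffParams = field(default_factory=FalloffParams)
    n_duodenum_absent: int = 2  # emulates prior surgical resection
    master_seed: int = 0


@dataclass
class SyntheticCase:
    """A generated case plus its provenance."""

    case: Case
    gtv_volume_mL: float
    min_oar_distance_mm: dict[str, float]
    seed: int


# ---------------------------------------------------------------------------
# Blob construction
# ---------------------------------------------------------------------------

def _blob_mask(
    grid: VoxelGrid,
    center_mm: np.ndarray,
    volume_mL: float,
    rng: np.random.Generator,
    roughness_mm: float = 4.0,
    elongation: float = 1.0,
    smooth_sigma_mm: float = 8.0,
) -> np.ndarray:
    """Smooth organic blob with an exact voxel count.

    Scores every voxel by minus its (optionally z-compressed) radial distance
    from the center plus a smoothed noise field, and keeps exactly the top-n
    voxels; deterministic given the generator state.
    """
    n = int(round(volume_mL / grid.voxel_volume_mL))
    if n < 1 or n > np.prod(grid.dims):
        raise ValueError(f"requested volume {volume_mL} mL unachievable on grid")
    xs, ys, zs = grid.voxel_centers()
    dx = xs - center_mm[0]
    dy = ys - center_mm[1]
    dz = (zs - center_mm[2]) / elongation
    r = np.sqrt(
        dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
    )
    noise = rng.standard_normal(grid.dims)
    sigma_vox = [smooth_sigma_mm / s for s in grid.spacing]
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    score = -r + roughness_mm * smooth
    order = np.argsort(score.ravel(), kind="stable")[::-1][:n]
    mask = np.zeros(np.prod(grid.dims), dtype=bool)
    mask[order] = True
    return mask.reshape(grid.dims)


def _equivalent_radius_mm(volume_mL: float) -> float:
    return (3.0 * volume_mL * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def make_geometry(params: CohortParams, case_seed: int, case_id: str = "") -> SyntheticCase:
    """Build all target and OAR masks of one synthetic case."""
    rng = np.random.default_rng(case_seed)
    grid = VoxelGrid(params.grid_dims, params.grid_spacing_mm)
    center = np.array(
        [grid.axis_coords(a)[grid.dims[a] // 2] for a in range(3)]
    )

    lo, hi = params.gtv_volume_range_mL
    gtv_volume = float(rng.uniform(lo, hi))
    gtv = StructureMask(grid, _blob_mask(grid, center, gtv_volume, rng), "GTV")
    r_gtv = _equivalent_radius_mm(gtv_volume)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # large CTVprop stand-ins may clip at the border
        ctvgeom = expand_mask(
            gtv,
            Margins(
                left=params.ctvgeom_margin_mm,
                right=params.ctvgeom_margin_mm,
                anterior=params.ctvgeom_margin_mm,
                posterior=params.ctvgeom_posterior_mm,
                superior=params.ctvgeom_margin_mm,
                inferior=params.ctvgeom_margin_mm,
            ),
        )
        ctvgeom.label = "CTVgeom"
        ctvprop = expand_mask(gtv, Margins.isotropic(params.ctvprop_margin_mm))
        ctvprop.label = "CTVprop"

        # OARs
        oar_masks: dict[str, StructureMask] = {}
        min_dist: dict[str, float] = {}
        for spec in params.oars:
            vol = float(rng.uniform(*spec.volume_range_mL))
            gap = abs(float(rng.normal(spec.gap_mean_mm, spec.gap_sd_mm))) + 1.0
            direction = np.asarray(spec.direction, dtype=float)
            direction = direction / np.linalg.norm(direction)
            r_oar = _equivalent_radius_mm(vol / spec.elongation)
            c = center + direction * (r_gtv + gap + r_oar)
            oar_masks[spec.label] = StructureMask(
                grid,
                _blob_mask(grid, c, vol, rng, elongation=spec.elongation),
                spec.label,
            )

        gi = [oar_masks[g] for g in GI_OARS]

        boost = expand_mask(gtv, Margins.isotropic(params.boost_margin_mm))
        gi_union = StructureMask(
            grid, np.logical_or.reduce([m.inside for m in gi]), "GI"
        )
        clearance = expand_mask(
            gi_union, Margins.isotropic(params.boost_gi_clearance_mm)
        )
        boost = StructureMask(grid, boost.inside & ~clearance.inside, "boostCTV")
        if boost.is_empty():  # GTV fully inside the GI clearance zone
            boost = StructureMask(grid, gtv.inside.copy(), "boostCTV")

        ptv_m = Margins.isotropic(params.ptv_margin_mm)
        ptv1 = subtract_overlap(expand_mask(gtv, ptv_m), gi)
        ptv1.label = "PTV1"
        ptv2 = subtract_overlap(expand_mask(ctvgeom, ptv_m), gi)
        ptv2.label = "PTV2"
        ptv3 = subtract_overlap(expand_mask(ctvprop, ptv_m), gi)
        ptv3.label = "PTV3"

    masks = {
        "GTV": gtv, "CTVgeom": ctvgeom, "CTVprop": ctvprop, "boostCTV": boost,
        "PTV1": ptv1, "PTV2": ptv2, "PTV3": ptv3, **oar_masks,
    }
    sdf_gtv = signed_distance_field(gtv)
    for spec in params.oars:
        m = oar_masks[spec.label]
        min_dist[spec.label] = float(sdf_gtv[m.inside].min()) if m.voxel_count else np.nan

    case = Case(case_id=case_id or f"case{case_seed}", grid=grid, masks=masks)
    return SyntheticCase(
        case=case, gtv_volume_mL=gtv.volume_mL, min_oar_distance_mm=min_dist, seed=case_seed
    )


# ---------------------------------------------------------------------------
# Analytic dose engine
# ---------------------------------------------------------------------------

def analytic_dose(
    case: Case,
    plan: PlanSpec,
    falloff: FalloffParams,
    noise_seed: int,
) -> np.ndarray:
    """SBRT-like dose grid (Gy, float32) for one plan.

    Voxels inside a prescribed target receive the highest applicable
    prescription; outside, dose decays as ``P / (1 + (d/d_half)^k)`` of signed
    distance to the outermost target, with a steeper half-distance in the
    outfield double cone, times lognormal voxel noise.  Noise-free dose is
    continuous across the target boundary (both sides equal the outermost
    prescription at d = 0).
    """
    rng = np.random.default_rng(noise_seed)
    outer = case.masks[plan.outermost_target]
    if outer.is_empty():
        raise ValueError("outermost target is empty")

    jitter = float(np.exp(rng.normal(0.0, falloff.case_jitter_sd))) if falloff.case_jitter_sd else 1.0
    half_in = falloff.infield_half_mm * jitter
    half_out = falloff.outfield_half_mm * jitter

    d = signed_distance_field(outer)
    out = outfield_mask(outer, interval_mm=0)
    half = np.where(out, half_out, half_in)
    p_out = plan.outermost_prescription
    dose = p_out / (1.0 + (np.clip(d, 0.0, None) / half) ** falloff.sharpness)

    # nested prescriptions: highest applicable wins
    target_dose = np.zeros(case.grid.dims)
    inside_any = np.zeros(case.grid.dims, dtype=bool)
    for label, presc in plan.prescriptions.items():
        m = case.masks[label].inside
        target_dose = np.where(m, np.maximum(target_dose, presc), target_dose)
        inside_any |= m

    if falloff.noise_sd > 0:
        noise = np.exp(rng.normal(0.0, falloff.noise_sd, size=case.grid.dims))
        dose = dose * noise
    dose = np.where(inside_any, target_dose, dose)
    return dose.astype(np.float32)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def make_cohort(
    params: CohortParams,
    plan_types: tuple[str, ...] = PLAN_TYPES,
) -> list[SyntheticCase]:
    """Generate ``n_cases`` independent cases with doses for every plan type.

    Case seeds derive from the master seed via a seed sequence, so the whole
    cohort is bit-identical on regeneration.
    """
    ss = np.random.SeedSequence(params.master_seed)
    children = ss.spawn(params.n_cases)
    cohort: list[SyntheticCase] = []
    for i, child in enumerate(children):
        seeds = child.generate_state(1 + len(plan_types)) % (2**31)
        sc = make_geometry(params, int(seeds[0]), case_id=f"case{i:02d}")
        if i < params.n_duodenum_absent:
            sc.case.absent.add("duodenum")
            empty = np.zeros(sc.case.grid.dims, dtype=bool)
            sc.case.masks["duodenum"] = StructureMask(sc.case.grid, empty, "duodenum")
            sc.min_oar_distance_mm["duodenum"] = float("nan")
        for j, pt in enumerate(plan_types):
            plan = PlanSpec.standard(pt)
            sc.case.doses[pt] = analytic_dose(sc.case, plan, params.falloff, int(seeds[1 + j]))
        cohort.append(sc)
    return cohort


def cohort_summary(cohort: list[SyntheticCase]) -> pd.DataFrame:
    """Per-case volumes and nearest GTV-to-OAR distances (mm)."""
    rows = []
    for sc in cohort:
        row = {
            "case_id": sc.case.case_id,
            "gtv_mL": round(sc.gtv_volume_mL, 2),
            "ctvgeom_mL": round(sc.case.masks["CTVgeom"].volume_mL, 2),
            "ptv1_mL": round(sc.case.masks["PTV1"].volume_mL, 2),
            "ptv2_mL": round(sc.case.masks["PTV2"].volume_mL, 2),
            "ptv3_mL": round(sc.case.masks["PTV3"].volume_mL, 2),
        }
        for oar, dist in sc.min_oar_distance_mm.items():
            row[f"dist_{oar}_mm"] = round(dist, 2) if np.isfinite(dist) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
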