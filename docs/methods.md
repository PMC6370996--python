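# Methods

## The prediction model

`geodvh` implements a knowledge-based DVH prediction model for pancreatic
SBRT and simultaneous-integrated-boost (SIB) SBRT. The model's single
assumption is that the dose an organ-at-risk (OAR) voxel receives is chiefly
determined by two geometric facts: its minimal Euclidean distance to the
outermost target structure, and whether the voxel is reachable by the
treatment beams (infield) or lies in the superior/inferior double cone the
beams cannot enter (outfield).

Training pools, over a cohort of prior plans, the prescription-normalized
voxel doses of each OAR into 0.5-mm distance bins spanning −10 mm to +150 mm
(320 bins; negative distances are inside the target). Each (OAR, field label,
bin) cell keeps the full empirical dose-frequency histogram. Prediction for a
new geometry assigns each OAR voxel a dose from its cell in one of two modes:

- **median** — every voxel in the bin receives the histogram median (even
  sizes: mean of the two central order statistics);
- **distribution** — the *n* voxels falling in a bin receive the
  (i − 0.5)/n empirical quantiles of the histogram (inverted-CDF definition),
  a deterministic sample that reproduces the training distribution's shape.
  Querying a histogram with its own sample size returns the histogram itself,
  which gives the model its self-prediction closure property.

The predicted voxel doses are accumulated into a cumulative DVH on the
normalized dose axis and denormalized with the new plan's outermost-target
prescription. Agreement with a planned DVH is summarized by the sum of
residuals SR = Σ_D (DVH(D) − DVH_pred(D))·ΔD (signed; positive means the
model underpredicts dose-volume) and the sum of squared residuals
RSS = Σ_D ((DVH(D) − DVH_pred(D))·ΔD)².

### Numerical choices

- **Dose axis**: ΔD = 0.005 in normalized units (≈0.17 Gy at a 33 Gy
  prescription), axis 0–2.5 so all plan types share one grid. Binning error
  is far below typical SR magnitudes (~0.01–0.05).
- **DVH metrics**: D-at-volume uses the step convention — the largest dose
  edge whose cumulative volume reaches the threshold — which stays within one
  bin width of the exact order statistic and never overstates the dose of
  mass concentrated on a bin edge. V-at-dose interpolates the cumulative
  curve linearly. An mL threshold exceeding the structure volume returns the
  minimum dose edge with an `undersized` flag rather than silently passing.
- **Signed distances** are voxel-center-to-voxel-center (Euclidean distance
  transform with anisotropic sampling): outside voxels take the distance to
  the nearest target voxel center, inside voxels the negative distance to the
  nearest non-target voxel center. Distances beyond +150 mm clamp into the
  last bin; sub-voxel surface meshes are out of scope.
- **Empty prediction cells** borrow the nearest nonempty bin with the same
  field label (falling back to the other field compartment if one is entirely
  untrained). This keeps prediction volume-preserving; assigning zero would
  bias near-target DVHs low. An OAR with no training coverage at all is
  rejected.
- **Field partition**: beams lie within ±30° of the axial plane, so the
  outfield region is the double cone with half-angle 60° about the
  superior–inferior axis. The apex sits at the (x, y) centroid of the
  extreme target slice, pushed 0/5/10 mm beyond the target; a voxel whose
  elevation angle from the nearer apex exceeds 30° is outfield, and the exact
  30° boundary counts as infield.
- **Margin expansion** combines per-direction margins with an
  ellipsoidal-per-octant metric (a 10 mm isotropic / 15 mm posterior margin
  blends smoothly rather than forming a box), evaluated on voxel centers and
  clipped at the grid boundary with a warning.

## Plans and constraints

Four plan types are built in: InitPlan (33 Gy to PTV1), Boost1 (33/25 Gy to
PTV1/PTV2), Boost2 (40/33/25 Gy to boostCTV/PTV1/PTV2) and Boost3 (33/25 Gy
to PTV1/PTV3). The outermost target (PTV1, PTV2, PTV2, PTV3 respectively)
anchors the distance maps and normalizes doses.

The shipped five-fraction constraint set: stomach/duodenum/bowel
D1mL ≤ 33 Gy, D3mL ≤ 20 Gy, D9mL ≤ 15 Gy; combined kidney (union of left and
right masks) V12Gy ≤ 75 %; liver D50 % ≤ 12 Gy; spinal cord V23Gy < 0.35 mL.
The GI, kidney and liver limits are inclusive; the cord limit is strict. A
plan is valid iff every evaluable constraint passes; structures flagged
absent (e.g. a surgically removed duodenum) are skipped, not failed.

## Evaluation machinery

- **Self-consistency**: train on the whole cohort, predict the same cohort;
  a sound model family must give |mean SR| well below SD(SR) across cases
  (the flag uses |mean| < 0.5·SD).
- **Cross-validation**: repeated (default 25×) twofold splits; each half
  trains a model scored on the other. Violation predictions for the GI
  hot-spot metrics (D1/D3/D9mL) are pooled over
  (case × repeat × plan × OAR × metric) into TP/FP/TN/FN, from which
  PPV = TP/(TP+FP), NPV = TN/(TN+FN) and accuracy AC = (TP+TN)/total follow.
- **Distance-limit experiment**: the model may use only dose-frequency
  histograms within L ∈ {5, …, 50} mm of the target; query voxels beyond L
  receive normalized dose 0 (dropping them would change the DVH denominator),
  so RSS(L) measures the information lost to truncation.
- **Virtual-OAR simulation**: for each (volume, mean-distance) cell, 250
  virtual GI organs are placed — a digitized ball of the exact requested
  voxel count whose center distance is drawn from a Gaussian around the cell
  midpoint (SD 1.25 mm, recorded in output metadata); voxel distances vary
  across the ball along a lateral, infield axis (locally-planar target
  approximation). Each draw's predicted DVH is checked against the GI
  hot-spot limits and the cell reports per-metric and any-metric violation
  fractions. Two variance-reduction choices make cell-to-cell comparisons
  paired: one shared set of Gaussian deviates across all cells (common random
  numbers), and nested balls (volume v is the first n_v voxels of one
  radius-sorted ball), so a larger organ is a strict superset of a smaller
  one at the same draw.

## The synthetic cohort generator

No clinical data ship with the package; `geodvh.synthetic` generates cohorts
with the statistical structure the model assumes so the whole pipeline is
testable end to end.

- **Geometry**: the GTV is a smooth random blob (radially tapered smoothed
  Gaussian field, top-n voxels, hence an exact volume) with volume drawn
  uniformly from 4–101 mL on a 2×2×2.5 mm grid (96×96×64 voxels by default,
  20 cases). CTVgeom is the 10 mm (15 mm posterior) expansion, a CTVprop
  stand-in for the elective-nodal volume is a 15 mm isotropic expansion,
  boostCTV is a 5 mm expansion excluding tissue within 10 mm of the GI
  organs, and PTV1/2/3 are 3 mm expansions with GI overlaps subtracted —
  all built through the public geometry operations. Seven organs (stomach,
  duodenum, bowel, both kidneys, liver, cord) are blob/tube stand-ins placed
  along anatomically-motivated directions; the GI organs draw their
  nearest-surface gap from |N(8–12, 7–9)| mm + 1 so every proximity regime is
  populated, while kidneys, liver and cord sit 25–45 mm away. Two of twenty
  cases are generated without a duodenum, emulating prior surgical resection.
- **Dose engine**: an analytic stand-in for the treatment planning system,
  not a beam model. Voxels inside a prescribed target receive the highest
  applicable prescription (SIB behavior); outside,
  dose = P·(1 + (d/d_half)^k)⁻¹ of signed distance d to the outermost
  target, with d_half = 20 mm infield and 8 mm in the outfield double cone,
  k = 3, times lognormal voxel noise (σ = 0.1); each case additionally scales
  both half-distances by a lognormal factor (σ = 0.1), so cases differ the
  way plans of different patients do. The shape parameters were chosen to
  reproduce clinical five-fraction SBRT dose statistics: a high shoulder
  (GI hot-spot doses of ~20–30 Gy within 10 mm of the target), a steep distal
  fall (organ mean doses of a few Gy), negligible cord dose at 45 mm and
  kidney V12 of a few percent. Noise-free, the engine is strictly decreasing
  in distance within each field compartment, continuous across the target
  boundary, and covers D95 of the outermost PTV at its prescription.
- **What it does not emulate**: optimizer trade-offs (real plans push dose
  away from nearby OARs, so real dose is not a pure function of geometry),
  beam/arc fluence structure, tissue heterogeneity, and realistic organ
  shapes. Passing tests on synthetic cohorts therefore demonstrate the
  pipeline's correctness and the model's behavior *when its core assumption
  holds*, not clinical accuracy; cross-validated accuracy on synthetic data
  (~97 %) exceeds what mixed clinical cohorts can achieve.

## Problem sizes and determinism

The default study conditions are 20 cases × 4 plan types on the
96×96×64 grid; the distance-limit study uses a 10-case noise-free cohort and
the feasibility simulation 250 draws per cell. All randomness flows from
explicit integer seeds through `numpy` seed sequences (case seeds are spawned
from a master seed), so cohorts, cross-validation splits, and simulations are
bit-identical under a fixed seed; the distribution assignment mode is
deterministic by construction (quantile mapping, no sampling).

## Known limitations

- The model predicts DVHs, not spatial dose: it cannot render a predicted
  3-D dose distribution.
- Whether clinical distance maps should use the pre- or post-subtraction PTV
  is ambiguous; the package uses the subtracted PTV (the structure the
  optimizer actually targets), so an OAR voxel can sit at positive distance
  even where it overlapped the unsubtracted PTV.
- SR/RSS are computed on the prescription-normalized dose axis; absolute-Gy
  residuals scale by the outermost prescription.
- DICOM-RT support assumes axis-aligned orientation, uniform frame offsets
  and rasterization onto the dose grid; the bundled RTSTRUCT/RTDOSE writer
  exists for round-trip testing of synthetic cases, not clinical transfer.
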