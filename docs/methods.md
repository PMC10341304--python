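# Methods

This note documents the models, conventions and deliberate simplifications
behind `hypofx`, in the order the pipeline runs.

## Linear-quadratic iso-effect conversion

Constraint tables published for conventionally fractionated treatment are
re-expressed for a five-fraction schedule through the plain linear-quadratic
model,

    BED(D; n, α/β) = D · (1 + (D/n) / (α/β)),

with no repair-kinetics or repopulation time factors. Two schedules are
taken as iso-effective when their BEDs agree; the target-schedule total dose
is the positive root of `D²/(n·α/β) + D − BED_ref = 0`, solved in closed
form. A bisection solver of the same fixed-point equation is kept in the
test suite as an independent oracle; the two agree to better than 1e−6 Gy
over doses up to 100 Gy, 1–40 fractions and α/β ∈ {1, 3, 10} Gy.

Conventions that matter:

* **Reference schedule.** Published constraints are treated as delivered in
  28 fractions — dose per fraction `D/28` for *every* constraint, including
  sub-prescription thresholds such as the bowel V15. This is the only
  reading that reproduces all printed five-fraction equivalents
  (45 → 25.55, 37 → 21.75, …).
* **α/β = 3.0 Gy for all OARs**, the late-responding-tissue value; a
  distinct tumour α/β is out of scope because the conversion is applied to
  OAR constraints only.
* **Rounding.** Converted doses are rounded to the nearest 0.05 Gy. The
  source tables do not state their rounding rule; nearest-0.05 is the
  convention inferred from the printed values (it reproduces all of them)
  and should be read as a package convention, not an external statement.
* **RBE.** Proton physical dose is weighted by a constant RBE of 1.1
  (GyE = Gy × 1.1); LET-dependent variable-RBE models are out of scope.

## Volumes and mask algebra

All volumes of a plan share one grid geometry (shape, per-axis spacing in
mm, origin at the first voxel center). A voxel belongs to a structure iff
its center does, and every distance is a physical center-to-center
Euclidean distance, so anisotropic spacing is handled exactly. Margin
expansion and skin cropping are built on `scipy.ndimage`'s exact Euclidean
distance transform with physical sampling. There is no resampling between
geometries: the synthetic generator controls both dose and masks, so a
resampling layer would be dead weight. Masks and dose grids round-trip
through NIfTI (masks as 0/1 uint8, dose as float32).

## DVH endpoints

Endpoints are computed from raw masked voxel doses, never from the binned
cumulative curve; the exported curve (default bin 0.05 GyE) is for plotting
only, which keeps binning error out of every reported metric. Conventions:
`V_d` counts voxels with dose ≥ d (closed DVH convention); `D_p%` is the
`ceil(p·N/100)`-th hottest voxel, i.e. the largest dose received by at
least p % of the volume, with ties broken toward the higher dose (for
D50% this is a median-type statistic; no ICRU near-median smoothing is
attempted). Maximum dose is the single hottest voxel — no 0.03 cc
point-dose convention. Integral dose assumes water density (1.0 g/cc):
energy (J) = mean dose (J/kg) × mass (kg). Empty masks are rejected with
the structure's name in the message.

## Constraint evaluation

Each constraint yields exactly one finding; nothing is dropped silently.
Comparators are exact at the boundary (observed = limit fails "<", passes
"≤"). Margins are signed in the constraint's native units with negative
meaning violation. The liver rule "spare at least 700 cc below 15 GyE" is
encoded as a first-class `spare_volume` constraint kind and evaluated as
`total volume − V15(cc) ≥ 700 cc`. Kidney constraints carry a
`both_remain` / `one_resected` condition resolved by a per-run switch
(default `both_remain`); non-matching constraints are reported as
`not_applicable` so finding counts stay exhaustive. The global
maximum-point-dose ceiling (108 % of the prescription) is not tied to a
named structure in the source tables; it is applied to the body's hottest
voxel relative to the highest prescription (the 30 GyE boost), as a
documented convention.

## Cohort statistics

Endpoints are compared with classical Student t-tests, **paired and
two-sided by default**: both plans exist for every patient and a single
p-value is reported per endpoint. Pairing and sidedness are not externally
fixed, so both are config flags; no mode is claimed to reproduce any
specific published p-value. Unpaired mode uses the pooled-variance
statistic. Zero-variance conventions: identical paired samples give
p = 1; a constant nonzero paired difference gives p = 0; endpoints constant
and equal in both arms (e.g. 100 % GTV coverage everywhere) are reported
with p = "N/A". p-values are displayed to three decimals with values below
0.0005 rendered "0.000"; significance is declared at p < 0.050 with no
multiple-testing correction (deliberately, to mirror the workflow this
package emulates). Sample SDs use the n−1 denominator.

## Synthetic phantom cohort

Each patient is an ellipsoidal body (semi-axes 165 × 108 × 122 mm) with a
large lateralised tumour (GTV semi-axes ≈ 44 × 38 × 50 mm before jitter)
and geometric-primitive OARs: stomach, duodenum, bowel, liver, paired
kidneys, paired femoral heads, a vertebral column with spinal canal, skin,
and the derived Body−CTV. Structure derivation follows the planning rules:
CTV = GTV + 15 mm inside the body; PTV = CTV + 5 mm cropped 3 mm from the
skin; the boost CTV is the posterior cap of the CTV behind the tumour
midline (a stand-in — real margin-at-risk placement is clinical judgment);
bone is truncated 10 mm cranio-caudal of the CTV. The skin structure is
undefined in the source workflow; here it is the outermost body shell
(3 mm or one voxel, whichever is thicker).

Dose models are phenomenological, not transport physics, because the
analysis under test consumes dose grids and only the photon-bath vs.
proton-falloff contrast must be faithful:

* **Photon-like**: 16 equispaced coplanar beams (an arc steered at the PTV
  centroid), each attenuated exponentially with radiological depth
  (0.0045 /mm, ≈6 MV in water) and confined laterally to the target
  aperture plus a Gaussian penumbra. Every beam deposits entrance *and*
  exit dose — the low-dose bath.
* **Proton-like**: 4 beams entering from the tumour side (lateral +
  posterior-ipsilateral obliques, emulating angle selection that avoids
  bowel and spares the spinal canal and uninvolved kidney), with a reduced
  entrance plateau (0.32 of target dose), a short proximal ramp, and a
  Gaussian distal falloff (4 mm length) to ≈0 beyond the target.
* A conformal target component (smoothed, saturated target indicator)
  carries the prescription: photon plans target the **PTV**, proton plans
  the **CTV**, mirroring how the two modalities handle setup uncertainty
  (robust optimisation itself is not simulated; proton plans are evaluated
  on nominal geometry only). This margin difference is what makes the
  photon plan's high-dose spill (e.g. bone V25) systematically larger.
* A `bath_scale` factor (photon 0.35, proton 0.7) crudely stands in for
  inverse-optimised OAR sparing; without it the unmodulated beam
  superposition overestimates out-of-field dose.
* Smooth multiplicative noise (1.5 % photon, 0.8 % proton) provides dose
  texture; each plan is then globally scaled so the CTV's 1st-percentile
  dose reaches 25 GyE (V25 ≥ 99 %) and the boost's 4th percentile reaches
  30 GyE, and clipped at 108 % of the boost prescription (hot-spot
  suppression, standing in for a max-dose objective). A scaling factor
  above 1.5 raises an error with diagnostics instead of silently failing
  coverage.

Per-patient variability: tumour side (±x), size scale U(0.85, 1.15) and
center jitter (±8 mm transverse, ±12 mm longitudinal), drawn from
`master_seed + patient_index`; plan noise seeds derive from the same
stream. Identical seeds give bit-identical cohorts.

**Problem sizes.** The default grid is 96 × 96 × 64 voxels at 4 mm
isotropic — chosen so a full 10-patient paired cohort generates and
analyzes in well under a minute on one CPU while the 5 mm PTV margin still
rasterises. The 100-replicate significance-recovery property runs on a
64 × 64 × 44 grid at 6 mm covering the same physical extent; at that
spacing the PTV margin no longer grows the CTV, so per-patient *high-dose*
(V25-level) directional contrasts are only guaranteed on the default grid,
while mean-dose and integral-dose contrasts — which drive the replicate
t-tests — are grid-robust.

**What passing tests do and do not show.** The generator guarantees, by
construction, the directional structure of the real comparison (higher
photon integral dose, bath-driven bowel/kidney/bone dose, sparing of the
contralateral kidney) with generator-controlled effect sizes. Passing the
directional and significance-recovery suites therefore validates the
analysis machinery, not the clinical magnitudes: synthetic organ doses are
not calibrated to any patient cohort, real per-endpoint means/SDs/p-values
derive from commercial treatment-planning-system plans on real anatomy and
are not reproducible here.

## Known limitations

* No DICOM RT support; volumes are NIfTI only (no NRRD writer installed).
* No contour-to-mask rasterisation, dose resampling, differential DVHs,
  BED-weighted DVH curves, or NTCP modelling.
* The beam models ignore heterogeneity, scatter, range uncertainty and
  robust optimisation; proton RBE is constant.
* The `D_at_volume_percent` constraint kind is declared but not
  convertible/evaluable as a table constraint (no shipped table uses it);
  D50% is available as a DVH endpoint.
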