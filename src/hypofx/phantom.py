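"""Synthetic phantom cohorts: anatomy plus paired photon-like and
proton-like dose distributions.

The generator emulates the study conditions of a paired in-silico plan
comparison for retroperitoneal sarcoma: each synthetic patient is an
ellipsoidal body with a large lateralised tumour, the surrounding
abdominal organs at risk as geometric primitives, and two dose
distributions covering the CTV at 25 GyE and a posterior boost
sub-volume at 30 GyE in five fractions.

Dose models are deliberately phenomenological, not physical transport:

* the photon-like plan superposes many coplanar exponentially attenuated
  beams aimed at the target — every beam deposits entrance **and exit**
  dose, producing the characteristic low-dose bath;
* the proton-like plan uses 4 lateral/posterior-oblique beams with a
  reduced entrance plateau and dose falling to ~0 within a few mm beyond
  the distal target edge (Bragg-peak behaviour), so the contralateral
  side of the patient is essentially unirradiated.

Only this bath-versus-sharp-falloff contrast — which drives every
downstream comparison — is meant to be faithful; absolute organ doses
are not calibrated to any clinical dataset. Photon plans target the PTV
(CTV + 5 mm setup margin, cropped 3 mm from the skin) while proton plans
target the CTV directly, mirroring how the two modalities handle setup
uncertainty and giving the photon plan its wider high-dose spill.

All randomness flows from explicit integer seeds; per-patient seeds are
``master_seed + patient_index``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .dvh import Plan
from .radiobiology import LQParameters, rbe_weight
from .volumes import (
    DoseGrid,
    GridGeometry,
    StructureMask,
    StructureSet,
    crop_from_surface,
    expand_mask,
    exterior_distance,
    intersect_mask,
    subtract_mask,
    union_mask,
)

__all__ = [
    "Ellipsoid",
    "Sphere",
    "ZCylinder",
    "PhantomSpec",
    "BeamParams",
    "Phantom",
    "PatientPlans",
    "default_geometry",
    "coarse_geometry",
    "generate_phantom",
    "simulate_photon_dose",
    "simulate_proton_dose",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

PRESCRIPTION_CTV_GYE = 25.0
PRESCRIPTION_BOOST_GYE = 30.0
MAX_POINT_PCT = 108.0

CTV_MARGIN_MM = 15.0
PTV_MARGIN_MM = 5.0
SKIN_CROP_MM = 3.0
BONE_CRANIOCAUDAL_MM = 10.0


# ---------------------------------------------------------------------------
# Geometric primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    semiaxes: tuple[float, float, float]

    def bounds(self):
        return (
            tuple(c - s for c, s in zip(self.center, self.semiaxes)),
            tuple(c + s for c, s in zip(self.center, self.semiaxes)),
        )

    def contains(self, x, y, z):
        cx, cy, cz = self.center
        ax, ay, az = self.semiaxes
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float

    def bounds(self):
        r = self.radius
        return (
            tuple(c - r for c in self.center),
            tuple(c + r for c in self.center),
        )

    def contains(self, x, y, z):
        cx, cy, cz = self.center
        return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= self.radius**2


@dataclass(frozen=True)
class ZCylinder:
    """Axis-aligned cylinder along z between z_lo and z_hi (mm)."""

    center_xy: tuple[float, float]
    radius: float
    z_lo: float
    z_hi: float

    def bounds(self):
        cx, cy = self.center_xy
        r = self.radius
        return ((cx - r, cy - r, self.z_lo), (cx + r, cy + r, self.z_hi))

    def contains(self, x, y, z):
        cx, cy = self.center_xy
        return ((x - cx) ** 2 + (y - cy) ** 2 <= self.radius**2) & (z >= self.z_lo) & (z <= self.z_hi)


Primitive = Ellipsoid | Sphere | ZCylinder


# ---------------------------------------------------------------------------
# Phantom specification
# ---------------------------------------------------------------------------

def default_geometry() -> GridGeometry:
    """Default cohort grid: 96 x 96 x 64 voxels at 4 mm isotropic."""
    return GridGeometry(shape=(96, 96, 64), spacing=(4.0, 4.0, 4.0))


def coarse_geometry() -> GridGeometry:
    """Coarse grid covering the same physical extent, for large replicate
    ensembles: 64 x 64 x 44 voxels at 6 mm isotropic."""
    return GridGeometry(shape=(64, 64, 44), spacing=(6.0, 6.0, 6.0))


@dataclass(frozen=True)
class PhantomSpec:
    """Complete geometric description of one synthetic patient.

    ``side`` is +1 or -1 and lateralises the tumour and its ipsilateral
    organs along x; y runs anterior (low) to posterior (high); z runs
    inferior to superior. All coordinates in mm.
    """

    geometry: GridGeometry
    body: Ellipsoid
    gtv: Ellipsoid
    side: int
    organs: dict[str, Primitive]
    boost_fraction: float = 0.35  # posterior cap of the CTV, as a fraction of the GTV y-semiaxis
    seed: int = 0

    @classmethod
    def build(
        cls,
        geometry: GridGeometry | None = None,
        side: int = 1,
        size_scale: float = 1.0,
        center_shift: tuple[float, float, float] = (0.0, 0.0, 0.0),
        seed: int = 0,
    ) -> "PhantomSpec":
        """Construct the canonical abdominal phantom on ``geometry``.

        ``size_scale`` scales the tumour's semi-axes; ``center_shift``
        displaces the tumour center — both are the per-patient jitter
        hooks used by :func:`generate_cohort`.
        """
        geometry = geometry or default_geometry()
        if side not in (-1, 1):
            raise ValueError("side must be +1 or -1")
        axes = geometry.coordinate_axes()
        c = tuple(0.5 * (ax[0] + ax[-1]) for ax in axes)
        cx, cy, cz = c
        s = float(side)
        jx, jy, jz = center_shift
        gtv = Ellipsoid(
            center=(cx + 52 * s + jx, cy + 14 + jy, cz + jz),
            semiaxes=(44 * size_scale, 38 * size_scale, 50 * size_scale),
        )
        organs: dict[str, Primitive] = {
            "stomach": Ellipsoid((cx - 45, cy - 35, cz + 48), (34, 28, 32)),
            "duodenum": ZCylinder((cx + 10, cy - 10), 13, cz - 35, cz + 35),
            "bowel": Ellipsoid((cx - 20 * s, cy - 48, cz + 4), (82, 46, 72)),
            "liver": Ellipsoid((cx + 62, cy - 20, cz + 55), (52, 42, 40)),
            "kidney_ipsi": Sphere((cx + 96 * s, cy + 52, cz - 6), 25),
            "kidney_contra": Sphere((cx - 96 * s, cy + 52, cz - 6), 25),
            "femoral_head_ipsi": Sphere((cx + 68 * s, cy + 12, cz - 96), 21),
            "femoral_head_contra": Sphere((cx - 68 * s, cy + 12, cz - 96), 21),
            "spinal_canal": ZCylinder((cx, cy + 52), 8, axes[2][0], axes[2][-1]),
            "bone_spine": ZCylinder((cx, cy + 52), 21, axes[2][0], axes[2][-1]),
        }
        return cls(
            geometry=geometry,
            body=Ellipsoid((cx, cy, cz), (165.0, 108.0, 122.0)),
            gtv=gtv,
            side=side,
            organs=organs,
            seed=seed,
        )

    def validate(self) -> None:
        """Reject primitives that extend beyond the grid's physical extent."""
        axes = self.geometry.coordinate_axes()
        half = self.geometry.spacing
        lo = tuple(axes[i][0] - half[i] / 2 for i in range(3))
        hi = tuple(axes[i][-1] + half[i] / 2 for i in range(3))
        for name, prim in {"body": self.body, "gtv": self.gtv, **self.organs}.items():
            pmin, pmax = prim.bounds()
            for i in range(3):
                if pmin[i] < lo[i] - 1e-9 or pmax[i] > hi[i] + 1e-9:
                    raise ValueError(
                        f"primitive {name!r} extends beyond the grid along axis {i}: "
                        f"[{pmin[i]:.1f}, {pmax[i]:.1f}] mm vs grid [{lo[i]:.1f}, {hi[i]:.1f}] mm"
                    )


@dataclass(frozen=True)
class Phantom:
    """A generated patient: structure set plus the spec that produced it."""

    spec: PhantomSpec
    structures: StructureSet


# ---------------------------------------------------------------------------
# Phantom rasterisation
# ---------------------------------------------------------------------------

def _rasterise(prim: Primitive, geometry: GridGeometry, name: str) -> StructureMask:
    ax, ay, az = geometry.coordinate_axes()
    x = ax[:, None, None]
    y = ay[None, :, None]
    z = az[None, None, :]
    return StructureMask(name, prim.contains(x, y, z), geometry)


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Build the full structure set for one synthetic patient.

    Derivation rules: CTV = (GTV + 15 mm) within the body; PTV =
    (CTV + 5 mm) cropped 3 mm from the skin; the boost CTV is the
    posterior cap of the CTV behind the tumour midline; bone is the
    vertebral column truncated 10 mm cranio-caudal of the CTV; skin is
    the outermost shell of the body; body_minus_ctv is the integral-dose
    volume. OAR masks are clipped to the body and exclude gross tumour.
    """
    spec.validate()
    g = spec.geometry
    body = _rasterise(spec.body, g, "body")
    gtv = _rasterise(spec.gtv, g, "gtv")
    if not (gtv.occupancy & ~body.occupancy).sum() == 0:
        raise ValueError("GTV must lie entirely inside the body")

    ctv = intersect_mask(expand_mask(gtv, CTV_MARGIN_MM), body, name="ctv")
    ptv = crop_from_surface(expand_mask(ctv, PTV_MARGIN_MM), body, SKIN_CROP_MM, name="ptv")

    # posterior boost cap: CTV behind a coronal plane through the tumour
    ay = g.coordinate_axes()[1]
    y_cut = spec.gtv.center[1] + spec.boost_fraction * spec.gtv.semiaxes[1]
    posterior = ay[None, :, None] >= y_cut
    ctv_boost = StructureMask("ctv_boost", ctv.occupancy & np.broadcast_to(posterior, ctv.occupancy.shape), g)
    if ctv_boost.voxel_count == 0:
        raise ValueError("boost sub-volume is empty; tumour jitter moved the cap outside the CTV")
    ptv_boost = crop_from_surface(
        expand_mask(ctv_boost, PTV_MARGIN_MM), body, SKIN_CROP_MM, name="ptv_boost"
    )

    structures = StructureSet(g)
    for m in (body, gtv, ctv, ctv_boost, ptv, ptv_boost):
        structures.add(m)

    # skin: outermost shell of the body (3 mm or one voxel, whichever thicker)
    shell = max(SKIN_CROP_MM, max(g.spacing))
    dist_in = exterior_distance(body)
    structures.add(StructureMask("skin", body.occupancy & (dist_in <= shell), g))

    # OARs: clipped to body, gross tumour carved out
    oars: dict[str, StructureMask] = {}
    for name, prim in spec.organs.items():
        raw = _rasterise(prim, g, name)
        oars[name] = subtract_mask(intersect_mask(raw, body), gtv, name=name)

    canal = oars.pop("spinal_canal")
    spine = oars.pop("bone_spine")
    bone_annulus = subtract_mask(spine, canal, name="bone")
    # truncate bone to 10 mm cranio-caudal of the CTV
    az = g.coordinate_axes()[2]
    z_idx = np.where(ctv.occupancy.any(axis=(0, 1)))[0]
    z_lo, z_hi = az[z_idx[0]] - BONE_CRANIOCAUDAL_MM, az[z_idx[-1]] + BONE_CRANIOCAUDAL_MM
    zband = (az[None, None, :] >= z_lo) & (az[None, None, :] <= z_hi)
    bone = StructureMask(
        "bone", bone_annulus.occupancy & np.broadcast_to(zband, bone_annulus.occupancy.shape), g
    )
    structures.add(canal)
    structures.add(bone)

    # bowel excludes the other abdominal organs it would otherwise overlap
    for other in ("stomach", "duodenum", "liver", "kidney_ipsi", "kidney_contra"):
        oars["bowel"] = subtract_mask(oars["bowel"], oars[other], name="bowel")
    oars["bowel"] = subtract_mask(oars["bowel"], bone, name="bowel")
    for m in oars.values():
        structures.add(m)

    structures.add(
        union_mask(oars["kidney_ipsi"], oars["kidney_contra"], name="kidneys_bilateral")
    )
    structures.add(subtract_mask(body, ctv, name="body_minus_ctv"))
    return Phantom(spec=spec, structures=structures)


# ---------------------------------------------------------------------------
# Beam parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeamParams:
    """Phenomenological beam-model parameters for one modality.

    ``angles_deg`` are directions of travel in the axial (x, y) plane;
    for protons they are chosen on the tumour side (lateral and
    posterior obliques) so no beam traverses the contralateral body or
    enters anteriorly through bowel.
    """

    modality: str
    n_beams: int
    angles_deg: tuple[float, ...] | None = None
    attenuation_per_mm: float = 0.0045  # photon: ~6 MV linear attenuation in water
    entrance_plateau: float = 0.32  # proton: entrance dose relative to target dose
    distal_falloff_mm: float = 4.0  # proton: Gaussian distal falloff length
    proximal_ramp_mm: float = 12.0  # proton: plateau-to-target ramp length
    aperture_margin_mm: float = 6.0
    penumbra_sigma_mm: float = 7.0
    target_smoothing_mm: float = 6.0
    #: crude stand-in for inverse-optimised OAR sparing: fraction of the
    #: unmodulated beam bath that survives optimisation
    bath_scale: float = 1.0
    noise_amplitude: float = 0.015
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_beams < 1:
            raise ValueError("n_beams must be >= 1")
        if self.modality not in ("photon_like", "proton_like"):
            raise ValueError(f"unknown modality {self.modality!r}")

    @classmethod
    def photon_default(cls, seed: int = 0) -> "BeamParams":
        """Sixteen equispaced coplanar beams: an arc-therapy stand-in."""
        return cls(
            modality="photon_like",
            n_beams=16,
            angles_deg=tuple(np.arange(16) * 22.5),
            target_smoothing_mm=6.0,
            penumbra_sigma_mm=7.0,
            bath_scale=0.35,
            noise_amplitude=0.015,
            seed=seed,
        )

    @classmethod
    def proton_default(cls, side: int, seed: int = 0) -> "BeamParams":
        """Four beams entering from the tumour side: one lateral and three
        posterior-ipsilateral obliques. Directions of travel point
        medially/anteriorly so the distal falloff lands past the target,
        which leaves the contralateral body — and the spinal column, which
        sits distal or lateral to every beam — essentially unirradiated."""
        s = float(side)
        dirs = [(-s, 0.0), (-s, -0.45), (-s, -0.9), (-0.8 * s, -1.0)]
        angles = tuple(math.degrees(math.atan2(dy, dx)) for dx, dy in dirs)
        return cls(
            modality="proton_like",
            n_beams=4,
            angles_deg=angles,
            target_smoothing_mm=4.0,
            penumbra_sigma_mm=5.0,
            bath_scale=0.7,
            noise_amplitude=0.008,
            seed=seed,
        )


# ---------------------------------------------------------------------------
# Dose simulation
# ---------------------------------------------------------------------------

def _entry_depth(px, py, pz, ux, uy, body: Ellipsoid):
    """Radiological depth (mm) of points inside an ellipsoidal body for a
    coplanar beam travelling along (ux, uy, 0): distance from the beam's
    entry point on the body surface to the point."""
    cx, cy, cz = body.center
    ax, ay, az = body.semiaxes
    qx, qy, qz = (px - cx) / ax, (py - cy) / ay, (pz - cz) / az
    vx, vy = ux / ax, uy / ay
    a = vx * vx + vy * vy
    b = -2.0 * (qx * vx + qy * vy)
    c = qx * qx + qy * qy + qz * qz - 1.0
    disc = np.maximum(b * b - 4.0 * a * c, 0.0)
    return (-b + np.sqrt(disc)) / (2.0 * a)


def _target_field(mask: StructureMask, sigma_mm: float, sat_percentile: float) -> np.ndarray:
    """Smoothed, saturated indicator of a target: ~1 throughout the
    target, rolling off over a penumbra outside it."""
    g = mask.geometry
    one_voxel = min(g.spacing)
    grown = expand_mask(mask, one_voxel * 1.01)
    sigmas = [sigma_mm / sp for sp in g.spacing]
    f = ndimage.gaussian_filter(grown.occupancy.astype(np.float32), sigma=sigmas)
    ref = np.percentile(f[mask.occupancy], sat_percentile)
    return np.clip(f / max(ref, 1e-6), 0.0, 1.0)


def _simulate(
    phantom: Phantom,
    params: BeamParams,
    prescriptions: tuple[float, float],
) -> DoseGrid:
    rx_ctv, rx_boost = prescriptions
    g = phantom.spec.geometry
    st = phantom.structures
    proton = params.modality == "proton_like"

    target = st["ctv"] if proton else st["ptv"]
    boost_target = st["ctv_boost"] if proton else st["ptv_boost"]

    # --- conformal target component ---------------------------------------
    f = _target_field(target, params.target_smoothing_mm, 1.0)
    fb = _target_field(boost_target, params.target_smoothing_mm, 4.0)

    # --- beam bath component ----------------------------------------------
    body_occ = st["body"].occupancy
    axes = g.coordinate_axes()
    ii, jj, kk = np.nonzero(body_occ)
    px = axes[0][ii].astype(np.float32)
    py = axes[1][jj].astype(np.float32)
    pz = axes[2][kk].astype(np.float32)

    t_ii, t_jj, t_kk = np.nonzero(target.occupancy)
    tx = axes[0][t_ii]
    ty = axes[1][t_jj]
    tz = axes[2][t_kk]
    c = np.array([tx.mean(), ty.mean(), tz.mean()])
    rz = np.abs(tz - c[2]).max()

    angles = params.angles_deg
    if angles is None:
        angles = tuple(np.arange(params.n_beams) * 360.0 / params.n_beams)

    bath_flat = np.zeros(px.size, dtype=np.float32)
    per_beam = rx_ctv / params.n_beams
    for ang in angles:
        ux, uy = math.cos(math.radians(ang)), math.sin(math.radians(ang))
        # lateral aperture: target extent perpendicular to the beam + margin
        r1 = np.abs(-(tx - c[0]) * uy + (ty - c[1]) * ux).max() + params.aperture_margin_mm
        r2 = rz + params.aperture_margin_mm
        s1 = -(px - c[0]) * uy + (py - c[1]) * ux
        s2 = pz - c[2]
        rho = np.sqrt((s1 / r1) ** 2 + (s2 / r2) ** 2)
        d_out = np.maximum(rho - 1.0, 0.0) * min(r1, r2)
        w = np.exp(-(d_out**2) / (2.0 * params.penumbra_sigma_mm**2))

        if proton:
            s_par = (px - c[0]) * ux + (py - c[1]) * uy
            t_par = (tx - c[0]) * ux + (ty - c[1]) * uy
            a_lo, a_hi = float(t_par.min()), float(t_par.max())
            profile = np.ones_like(s_par)
            ramp_start = a_lo - params.proximal_ramp_mm
            prox = s_par < a_lo
            frac = np.clip((s_par - ramp_start) / params.proximal_ramp_mm, 0.0, 1.0)
            profile = np.where(
                prox, params.entrance_plateau + (1.0 - params.entrance_plateau) * frac, profile
            )
            distal = s_par > a_hi
            profile = np.where(
                distal, np.exp(-(((s_par - a_hi) / params.distal_falloff_mm) ** 2)), profile
            )
            bath_flat += (per_beam * profile * w).astype(np.float32)
        else:
            depth = _entry_depth(px, py, pz, ux, uy, phantom.spec.body)
            depth_c = float(_entry_depth(c[0], c[1], c[2], ux, uy, phantom.spec.body))
            bath_flat += (
                per_beam * np.exp(-params.attenuation_per_mm * (depth - depth_c)) * w
            ).astype(np.float32)

    bath = np.zeros(g.shape, dtype=np.float32)
    bath[ii, jj, kk] = bath_flat * params.bath_scale

    # --- compose, add texture noise, scale to coverage ---------------------
    dose = rx_ctv * f + (rx_boost - rx_ctv) * fb + bath * (1.0 - f)
    dose *= body_occ

    rng = np.random.default_rng(params.seed)
    noise = ndimage.gaussian_filter(rng.standard_normal(g.shape).astype(np.float32), sigma=1.5)
    noise /= max(noise.std(), 1e-9)
    dose *= 1.0 + params.noise_amplitude * noise

    ctv_mask = st["ctv"].occupancy
    boost_mask = st["ctv_boost"].occupancy
    q_ctv = float(np.percentile(dose[ctv_mask], 1.0))
    q_boost = float(np.percentile(dose[boost_mask], 4.0))
    k = max(rx_ctv * 1.002 / q_ctv, rx_boost * 1.002 / q_boost, 1.0)
    if k > 1.5:
        raise RuntimeError(
            f"cannot reach target coverage by scaling (factor {k:.2f} needed; "
            f"CTV 1st-percentile dose {q_ctv:.2f} GyE, boost 4th-percentile {q_boost:.2f} GyE)"
        )
    dose = dose.astype(np.float64) * k
    # hot-spot suppression at the global point-dose ceiling
    np.clip(dose, 0.0, MAX_POINT_PCT / 100.0 * rx_boost, out=dose)
    return DoseGrid(values=dose, geometry=g)


def simulate_photon_dose(
    phantom: Phantom,
    params: BeamParams | None = None,
    prescriptions: tuple[float, float] = (PRESCRIPTION_CTV_GYE, PRESCRIPTION_BOOST_GYE),
) -> DoseGrid:
    """Photon-like plan: many-beam superposition with entrance and exit
    dose along every beam path (the low-dose bath), scaled so the CTV is
    covered at the prescription and the boost at its boost dose."""
    params = params or BeamParams.photon_default()
    if params.modality != "photon_like":
        raise ValueError("params.modality must be 'photon_like'")
    return _simulate(phantom, params, prescriptions)


def simulate_proton_dose(
    phantom: Phantom,
    params: BeamParams | None = None,
    prescriptions: tuple[float, float] = (PRESCRIPTION_CTV_GYE, PRESCRIPTION_BOOST_GYE),
    lq: LQParameters = LQParameters(),
) -> DoseGrid:
    """Proton-like plan: few-beam superposition with a reduced entrance
    plateau and near-zero dose distal to the target, with the same
    coverage contract as the photon plan. The profile is built in
    physical dose and reported RBE-weighted (GyE)."""
    params = params or BeamParams.proton_default(side=phantom.spec.side)
    if params.modality != "proton_like":
        raise ValueError("params.modality must be 'proton_like'")
    phys_rx = tuple(p / lq.rbe for p in prescriptions)
    physical = _simulate(phantom, params, phys_rx)
    return DoseGrid(values=rbe_weight(physical.values, lq), geometry=physical.geometry)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientPlans:
    """One synthetic patient with both modality plans.

    ``phantom`` is None for cohorts re-read from disk, where only the
    rasterised structures survive."""

    patient_id: str
    phantom: Phantom | None
    photon: Plan
    proton: Plan

    @property
    def structures(self) -> StructureSet:
        return self.photon.structures


def generate_cohort(
    n_patients: int = 10,
    master_seed: int = 0,
    geometry: GridGeometry | None = None,
) -> list[PatientPlans]:
    """Generate a paired cohort: one phantom and both modality plans per
    patient, with per-patient tumour size/position/side jitter drawn
    deterministically from ``master_seed + patient_index``."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    geometry = geometry or default_geometry()
    cohort: list[PatientPlans] = []
    for i in range(n_patients):
        seed = master_seed + i
        rng = np.random.default_rng(seed)
        side = int(rng.choice([-1, 1]))
        scale = float(rng.uniform(0.85, 1.15))
        shift = (
            float(rng.uniform(-8, 8)),
            float(rng.uniform(-8, 8)),
            float(rng.uniform(-12, 12)),
        )
        spec = PhantomSpec.build(
            geometry=geometry, side=side, size_scale=scale, center_shift=shift, seed=seed
        )
        phantom = generate_phantom(spec)
        photon_seed = int(rng.integers(2**31))
        proton_seed = int(rng.integers(2**31))
        pid = f"P{i + 1:02d}"
        photon = Plan(
            patient_id=pid,
            modality="photon_like",
            dose=simulate_photon_dose(phantom, BeamParams.photon_default(seed=photon_seed)),
            structures=phantom.structures,
        )
        proton = Plan(
            patient_id=pid,
            modality="proton_like",
            dose=simulate_proton_dose(
                phantom, BeamParams.proton_default(side=side, seed=proton_seed)
            ),
            structures=phantom.structures,
        )
        cohort.append(PatientPlans(pid, phantom, photon, proton))
    return cohort


# ---------------------------------------------------------------------------
# Cohort persistence (NIfTI volumes + YAML manifest)
# ---------------------------------------------------------------------------

def write_cohort(cohort: Sequence[PatientPlans], out_dir) -> "str":
    """Write a cohort as a directory tree of NIfTI volumes plus a YAML
    manifest binding patient ids, modality labels and files. Returns the
    manifest path."""
    import yaml
    from pathlib import Path

    from .volumes import write_dose_nifti, write_mask_nifti

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients = []
    for p in cohort:
        pdir = out / p.patient_id
        (pdir / "structures").mkdir(parents=True, exist_ok=True)
        entry = {"id": p.patient_id, "doses": {}, "structures": {}}
        for label, plan in (("photon_like", p.photon), ("proton_like", p.proton)):
            rel = f"{p.patient_id}/dose_{label}.nii.gz"
            write_dose_nifti(plan.dose, out / rel)
            entry["doses"][label] = rel
        for name in p.structures.names():
            rel = f"{p.patient_id}/structures/{name}.nii.gz"
            write_mask_nifti(p.structures[name], out / rel)
            entry["structures"][name] = rel
        if p.phantom is not None:
            entry["side"] = p.phantom.spec.side
            entry["seed"] = p.phantom.spec.seed
        patients.append(entry)
    g = cohort[0].photon.dose.geometry
    manifest = {
        "n_patients": len(cohort),
        "geometry": {
            "shape": list(g.shape),
            "spacing_mm": list(g.spacing),
            "origin_mm": list(g.origin),
        },
        "patients": patients,
    }
    mpath = out / "manifest.yaml"
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return str(mpath)


def read_cohort(manifest_path) -> list[PatientPlans]:
    """Re-read a cohort written by :func:`write_cohort`."""
    import yaml
    from pathlib import Path

    from .volumes import read_dose_nifti, read_mask_nifti

    mpath = Path(manifest_path)
    root = mpath.parent
    doc = yaml.safe_load(mpath.read_text())
    cohort: list[PatientPlans] = []
    for entry in doc["patients"]:
        pid = entry["id"]
        doses = {
            label: read_dose_nifti(root / rel) for label, rel in entry["doses"].items()
        }
        geometry = next(iter(doses.values())).geometry
        structures = StructureSet(geometry)
        for name, rel in entry["structures"].items():
            structures.add(read_mask_nifti(root / rel, name))
        cohort.append(
            PatientPlans(
                patient_id=pid,
                phantom=None,
                photon=Plan(pid, "photon_like", doses["photon_like"], structures),
                proton=Plan(pid, "proton_like", doses["proton_like"], structures),
            )
        )
    return cohort
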