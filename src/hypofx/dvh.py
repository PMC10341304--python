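"""Cumulative DVH construction and dosimetric endpoint extraction.

Endpoints are always computed from the raw voxel doses inside a mask,
never from the binned cumulative curve — the curve (default bin width
0.05 GyE) exists for export and plotting only, so binning error never
enters a reported metric.

Conventions:

* V_at_dose counts voxels with dose **>= threshold** (closed DVH
  convention), reported in cc or in % of the structure volume.
* D_at_volume_percent(p) is the largest dose d such that at least p% of
  the structure receives >= d: the ceil(p*N/100)-th hottest voxel, which
  breaks ties toward the higher dose.
* Maximum dose is the single hottest voxel (no small-volume point-dose
  smoothing); mean dose is the plain voxel average.
* Integral dose assumes unit density (water, 1.0 g/cc) by default:
  energy (J) = mean dose (J/kg) x mass (kg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .volumes import DoseGrid, StructureMask, StructureSet

__all__ = [
    "DVHCurve",
    "MetricSpec",
    "MetricResult",
    "Plan",
    "compute_dvh",
    "v_at_dose",
    "d_at_volume_percent",
    "max_dose",
    "mean_dose",
    "integral_dose",
    "extract_catalogue",
    "default_endpoint_catalogue",
    "catalogue_to_dataframe",
    "dvh_to_dataframe",
]

DEFAULT_BIN_WIDTH_GYE = 0.05
WATER_DENSITY_G_PER_CC = 1.0


@dataclass(frozen=True)
class Plan:
    """A patient's treatment plan: dose grid plus structure set."""

    patient_id: str
    modality: str
    dose: DoseGrid
    structures: StructureSet

    def __post_init__(self) -> None:
        if self.dose.geometry != self.structures.geometry:
            raise ValueError("dose grid and structure set geometries differ")


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative DVH: volume receiving >= each dose edge."""

    structure: str
    dose_edges: np.ndarray
    cum_volume_cc: np.ndarray
    cum_volume_pct: np.ndarray


@dataclass(frozen=True)
class MetricSpec:
    """One endpoint definition: what to extract and in which units.

    ``kind`` is one of V_at_dose, D_at_volume_percent, max, mean,
    integral; ``threshold`` is a dose (GyE) for V_at_dose or a volume
    percentage for D_at_volume_percent, and absent otherwise.
    """

    kind: str
    threshold: float | None = None
    output_units: str = "GyE"

    _KINDS = ("V_at_dose", "D_at_volume_percent", "max", "mean", "integral")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown metric kind {self.kind!r}")
        if self.kind in ("V_at_dose", "D_at_volume_percent") and self.threshold is None:
            raise ValueError(f"{self.kind} requires a threshold")
        if self.kind in ("max", "mean", "integral") and self.threshold is not None:
            raise ValueError(f"{self.kind} takes no threshold")
        if self.kind == "V_at_dose" and self.output_units not in ("cc", "%"):
            raise ValueError("V_at_dose reports cc or %")

    @property
    def label(self) -> str:
        """Human-readable endpoint label in the comparison-table style."""
        if self.kind == "V_at_dose":
            thr = f"{self.threshold:g}"
            return f"V{thr} GyE ({self.output_units})"
        if self.kind == "D_at_volume_percent":
            return f"D{self.threshold:g}% (GyE)"
        if self.kind == "max":
            return "Max Dose (GyE)"
        if self.kind == "mean":
            return "Mean Dose (GyE)"
        return "Integral Dose (J)"


@dataclass(frozen=True)
class MetricResult:
    """One extracted endpoint value for one structure of one plan."""

    patient_id: str
    modality: str
    structure: str
    spec: MetricSpec
    value: float
    units: str

    @property
    def endpoint_id(self) -> str:
        return f"{self.structure}|{self.spec.label}"


# ---------------------------------------------------------------------------
# Core extraction
# ---------------------------------------------------------------------------

def _masked_doses(grid: DoseGrid, m: StructureMask) -> np.ndarray:
    if grid.geometry != m.geometry:
        raise ValueError(f"mask {m.name!r} is not congruent with the dose grid")
    doses = grid.values[m.occupancy]
    if doses.size == 0:
        raise ValueError(f"structure {m.name!r} is empty; DVH metrics are undefined")
    return doses


def compute_dvh(
    grid: DoseGrid, m: StructureMask, bin_width: float = DEFAULT_BIN_WIDTH_GYE
) -> DVHCurve:
    """Exact cumulative DVH of ``m`` sampled at multiples of ``bin_width``."""
    if not bin_width > 0:
        raise ValueError("bin_width must be > 0")
    doses = np.sort(_masked_doses(grid, m))
    n = doses.size
    top = float(doses[-1])
    n_edges = int(math.floor(top / bin_width)) + 2
    edges = np.arange(n_edges) * bin_width
    # voxels with dose >= edge (closed convention)
    counts = n - np.searchsorted(doses, edges, side="left")
    vox_cc = m.geometry.voxel_volume_cc
    return DVHCurve(
        structure=m.name,
        dose_edges=edges,
        cum_volume_cc=counts * vox_cc,
        cum_volume_pct=counts * (100.0 / n),
    )


def v_at_dose(grid: DoseGrid, m: StructureMask, threshold: float, mode: str = "cc") -> float:
    """Volume of ``m`` receiving >= ``threshold`` GyE, in cc or %."""
    doses = _masked_doses(grid, m)
    count = int(np.count_nonzero(doses >= threshold))
    if mode == "cc":
        return count * m.geometry.voxel_volume_cc
    if mode == "%":
        return 100.0 * count / doses.size
    raise ValueError(f"mode must be 'cc' or '%', got {mode!r}")


def d_at_volume_percent(grid: DoseGrid, m: StructureMask, p: float) -> float:
    """Largest dose received by at least ``p`` % of the structure volume."""
    if not 0 < p <= 100:
        raise ValueError(f"p must be in (0, 100], got {p}")
    doses = np.sort(_masked_doses(grid, m))[::-1]  # hottest first
    k = math.ceil(p * doses.size / 100.0)
    return float(doses[k - 1])


def max_dose(grid: DoseGrid, m: StructureMask) -> float:
    """Dose of the single hottest voxel in the mask."""
    return float(_masked_doses(grid, m).max())


def mean_dose(grid: DoseGrid, m: StructureMask) -> float:
    """Arithmetic mean voxel dose over the mask."""
    return float(_masked_doses(grid, m).mean())


def integral_dose(
    grid: DoseGrid, m: StructureMask, density_g_per_cc: float = WATER_DENSITY_G_PER_CC
) -> float:
    """Energy deposited in the masked volume, in joules.

    Each voxel contributes dose (Gy = J/kg) x voxel volume (cc) x density
    (g/cc) x 1e-3 kg/g; equivalently mean dose times structure mass.
    """
    if not density_g_per_cc > 0:
        raise ValueError("density must be > 0")
    doses = _masked_doses(grid, m)
    mass_kg_per_voxel = m.geometry.voxel_volume_cc * density_g_per_cc * 1e-3
    return float(doses.sum() * mass_kg_per_voxel)


# ---------------------------------------------------------------------------
# Endpoint catalogue
# ---------------------------------------------------------------------------

def _vcc(thr: float) -> MetricSpec:
    return MetricSpec("V_at_dose", thr, "cc")


def _vpct(thr: float) -> MetricSpec:
    return MetricSpec("V_at_dose", thr, "%")


_D50 = MetricSpec("D_at_volume_percent", 50.0, "GyE")
_MAX = MetricSpec("max", None, "GyE")
_MEAN = MetricSpec("mean", None, "GyE")
_INTEGRAL = MetricSpec("integral", None, "J")


def default_endpoint_catalogue() -> dict[str, tuple[MetricSpec, ...]]:
    """The default per-structure endpoint catalogue for a paired photon
    vs. proton comparison: target coverage, OAR V_d / D50% / max / mean
    endpoints, and whole-body (minus CTV) integral dose."""
    gi_specs = (_vcc(5), _vcc(10), _vcc(15), _vcc(20), _vcc(25), _D50, _MAX, _MEAN)
    kidney_specs = (_vpct(10), _vpct(12), _D50, _MEAN)
    fem_specs = (_vpct(23.2), _vcc(30), _MAX, _MEAN)
    return {
        "gtv": (_vpct(25),),
        "ctv": (_vpct(25),),
        "ctv_boost": (_vpct(30),),
        "ptv": (_vpct(25),),
        "ptv_boost": (_vpct(30),),
        "stomach": gi_specs,
        "duodenum": gi_specs,
        "bowel": gi_specs,
        "liver": (_vcc(5), _vcc(10), _vcc(15), _vcc(20), _vcc(25), _D50, _MEAN),
        "kidney_ipsi": kidney_specs,
        "kidney_contra": kidney_specs,
        "kidneys_bilateral": kidney_specs,
        "femoral_head_ipsi": fem_specs,
        "femoral_head_contra": fem_specs,
        "bone": (_vcc(5), _vcc(10), _vcc(15), _vcc(20), _vcc(25), _MEAN),
        "spinal_canal": (_MAX,),
        "skin": (_vpct(12),),
        "body": (_MAX,),
        "body_minus_ctv": (_INTEGRAL,),
    }


def _evaluate_spec(grid: DoseGrid, m: StructureMask, spec: MetricSpec) -> float:
    if spec.kind == "V_at_dose":
        return v_at_dose(grid, m, spec.threshold, spec.output_units)
    if spec.kind == "D_at_volume_percent":
        return d_at_volume_percent(grid, m, spec.threshold)
    if spec.kind == "max":
        return max_dose(grid, m)
    if spec.kind == "mean":
        return mean_dose(grid, m)
    return integral_dose(grid, m)


def extract_catalogue(
    plan: Plan,
    catalogue: Mapping[str, Sequence[MetricSpec]] | None = None,
) -> list[MetricResult]:
    """Evaluate every configured endpoint of every structure of a plan.

    Structures absent from the plan's structure set are skipped silently
    only if the catalogue is the default one; an explicitly supplied
    catalogue must match the structure set exactly.
    """
    explicit = catalogue is not None
    cat = catalogue if explicit else default_endpoint_catalogue()
    results: list[MetricResult] = []
    for structure, specs in cat.items():
        mask = plan.structures.get(structure)
        if mask is None:
            if explicit:
                raise KeyError(f"catalogue references missing structure {structure!r}")
            continue
        for spec in specs:
            value = _evaluate_spec(plan.dose, mask, spec)
            results.append(
                MetricResult(
                    patient_id=plan.patient_id,
                    modality=plan.modality,
                    structure=structure,
                    spec=spec,
                    value=value,
                    units=spec.output_units,
                )
            )
    return results


def catalogue_to_dataframe(results: Iterable[MetricResult]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": r.patient_id,
            "modality": r.modality,
            "structure": r.structure,
            "endpoint": r.spec.label,
            "value": r.value,
            "units": r.units,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def dvh_to_dataframe(curve: DVHCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "structure": curve.structure,
            "dose_gye": curve.dose_edges,
            "volume_cc": curve.cum_volume_cc,
            "volume_pct": curve.cum_volume_pct,
        }
    )
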