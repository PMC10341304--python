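"""Linear-quadratic (LQ) radiobiology arithmetic.

Biologically effective dose (BED), iso-effective total dose across
fractionation schedules, constant-RBE weighting of proton physical dose,
and batch conversion of normal-tissue constraint tables between schedules.

The LQ model used throughout is the plain fractionated form with no
repair/repopulation time factors:

    BED(D; n, alpha/beta) = D * (1 + (D / n) / (alpha/beta))

where ``D`` is the total dose delivered in ``n`` equal fractions. Two
schedules are iso-effective when their BEDs agree; solving the quadratic

    D^2 / (n_target * alpha/beta) + D - BED_ref = 0

for the positive root gives the iso-effective total dose in the target
schedule in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "FractionationScheme",
    "LQParameters",
    "DoseConstraint",
    "ConstraintTable",
    "bed",
    "isoeffective_total_dose",
    "convert_constraint",
    "convert_table",
    "rbe_weight",
    "load_constraint_table",
    "save_constraint_table",
]

#: Metric kinds a DoseConstraint may carry. ``spare_volume`` encodes
#: liver-style sparing rules ("spare at least <limit> cc below
#: <threshold_dose>"); the others are conventional DVH constraint kinds.
METRIC_KINDS = ("V_at_dose", "D_at_volume_percent", "max_dose", "mean_dose", "spare_volume")

#: Kinds whose ``limit_value`` is itself a dose in Gy and therefore moves
#: under a fractionation conversion.
_DOSE_LIMIT_KINDS = ("max_dose", "mean_dose")

#: Kinds carrying a ``threshold_dose`` in Gy.
_THRESHOLDED_KINDS = ("V_at_dose", "spare_volume")


@dataclass(frozen=True)
class FractionationScheme:
    """A delivery schedule: the number of equal fractions.

    Total dose is supplied per call; dose per fraction is ``total / n``.
    """

    n_fractions: int

    def __post_init__(self) -> None:
        if int(self.n_fractions) != self.n_fractions or self.n_fractions < 1:
            raise ValueError(f"n_fractions must be a positive integer, got {self.n_fractions!r}")


@dataclass(frozen=True)
class LQParameters:
    """LQ tissue parameters: alpha/beta ratio (Gy) and a constant RBE."""

    alpha_beta: float = 3.0
    rbe: float = 1.1

    def __post_init__(self) -> None:
        if not self.alpha_beta > 0:
            raise ValueError(f"alpha_beta must be > 0, got {self.alpha_beta!r}")
        if not self.rbe > 0:
            raise ValueError(f"rbe must be > 0, got {self.rbe!r}")


@dataclass(frozen=True)
class DoseConstraint:
    """One machine-readable normal-tissue constraint.

    ``threshold_dose`` (Gy) is present iff the metric kind needs one
    (V_at_dose, spare_volume); ``limit_value`` is interpreted in
    ``limit_units`` (%, cc, or Gy). ``comparator`` is "<" or "<=" for
    upper limits and ">=" for spare_volume.
    """

    structure: str
    metric_kind: str
    limit_value: float
    limit_units: str
    comparator: str = "<"
    threshold_dose: float | None = None
    label: str | None = None
    #: optional applicability condition, e.g. the kidney rules that differ
    #: between "both_remain" and "one_resected" patients
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.metric_kind not in METRIC_KINDS:
            raise ValueError(f"unknown metric_kind {self.metric_kind!r}; expected one of {METRIC_KINDS}")
        needs_threshold = self.metric_kind in _THRESHOLDED_KINDS
        if needs_threshold and self.threshold_dose is None:
            raise ValueError(f"{self.metric_kind} constraint on {self.structure!r} requires threshold_dose")
        if not needs_threshold and self.threshold_dose is not None:
            raise ValueError(f"{self.metric_kind} constraint on {self.structure!r} must not set threshold_dose")
        if self.limit_value < 0:
            raise ValueError("limit_value must be >= 0")
        if self.limit_units not in ("%", "cc", "Gy"):
            raise ValueError(f"limit_units must be %%, cc or Gy, got {self.limit_units!r}")
        if self.comparator not in ("<", "<=", ">="):
            raise ValueError(f"unsupported comparator {self.comparator!r}")


@dataclass(frozen=True)
class ConstraintTable:
    """An ordered collection of constraints plus the schedule they assume."""

    constraints: tuple[DoseConstraint, ...]
    n_fractions: int | None = None
    name: str | None = None

    def __iter__(self):
        return iter(self.constraints)

    def __len__(self) -> int:
        return len(self.constraints)


# ---------------------------------------------------------------------------
# Core LQ arithmetic
# ---------------------------------------------------------------------------

def bed(total_dose: float, scheme: FractionationScheme, lq: LQParameters) -> float:
    """Biologically effective dose of ``total_dose`` Gy in ``scheme``.

    BED = D * (1 + (D/n) / (alpha/beta)). Zero maps to zero and the
    function is strictly increasing in D.
    """
    if total_dose < 0:
        raise ValueError(f"total_dose must be >= 0, got {total_dose}")
    d_per_fx = total_dose / scheme.n_fractions
    return total_dose * (1.0 + d_per_fx / lq.alpha_beta)


def isoeffective_total_dose(
    ref_dose: float,
    ref_scheme: FractionationScheme,
    target_scheme: FractionationScheme,
    lq: LQParameters,
) -> float:
    """Total dose in ``target_scheme`` iso-effective with ``ref_dose`` in ``ref_scheme``.

    Solves D^2/(n*ab) + D - BED = 0 for the unique non-negative root in
    closed form. Returns ``ref_dose`` exactly when the schemes match.
    """
    if ref_dose < 0:
        raise ValueError(f"ref_dose must be >= 0, got {ref_dose}")
    if target_scheme.n_fractions == ref_scheme.n_fractions:
        return float(ref_dose)
    b = bed(ref_dose, ref_scheme, lq)
    k = target_scheme.n_fractions * lq.alpha_beta
    # positive root of D^2/k + D - b = 0
    return 0.5 * k * (math.sqrt(1.0 + 4.0 * b / k) - 1.0)


def rbe_weight(physical_dose, lq: LQParameters):
    """RBE-weighted dose in GyE: physical dose times a constant RBE factor.

    Accepts scalars or arrays; negative doses are rejected.
    """
    import numpy as np

    if np.any(np.asarray(physical_dose) < 0):
        raise ValueError("physical_dose must be >= 0")
    return physical_dose * lq.rbe


def _round_to_increment(value: float, increment: float) -> float:
    if increment <= 0:
        return value
    # round half away from zero, to the printed-table convention
    return round(math.floor(value / increment + 0.5) * increment, 10)


def convert_constraint(
    c: DoseConstraint,
    ref_scheme: FractionationScheme,
    target_scheme: FractionationScheme,
    lq: LQParameters,
    rounding_increment: float = 0.05,
) -> DoseConstraint:
    """Re-express a constraint under a different fractionation schedule.

    Dose quantities (the V_at_dose / spare_volume threshold, or the limit
    itself for max/mean constraints in Gy) are replaced by their
    iso-effective value in the target schedule, rounded to the nearest
    ``rounding_increment``; %/cc limit values are untouched.
    """
    if c.metric_kind in _THRESHOLDED_KINDS:
        new_thr = isoeffective_total_dose(c.threshold_dose, ref_scheme, target_scheme, lq)
        return replace(c, threshold_dose=_round_to_increment(new_thr, rounding_increment))
    if c.metric_kind in _DOSE_LIMIT_KINDS:
        if c.limit_units != "Gy":
            raise ValueError(f"{c.metric_kind} constraint on {c.structure!r} must carry a Gy limit to convert")
        new_lim = isoeffective_total_dose(c.limit_value, ref_scheme, target_scheme, lq)
        return replace(c, limit_value=_round_to_increment(new_lim, rounding_increment))
    raise ValueError(f"cannot convert constraint of kind {c.metric_kind!r}")


def convert_table(
    table: ConstraintTable,
    ref_scheme: FractionationScheme,
    target_scheme: FractionationScheme,
    lq: LQParameters,
    rounding_increment: float = 0.05,
) -> ConstraintTable:
    """Convert every constraint in a table; see :func:`convert_constraint`."""
    converted = tuple(
        convert_constraint(c, ref_scheme, target_scheme, lq, rounding_increment) for c in table
    )
    return ConstraintTable(
        constraints=converted,
        n_fractions=target_scheme.n_fractions,
        name=table.name,
    )


# ---------------------------------------------------------------------------
# Constraint table (de)serialization
# ---------------------------------------------------------------------------

def _constraint_to_dict(c: DoseConstraint) -> dict:
    d = {
        "structure": c.structure,
        "metric": c.metric_kind,
        "limit": c.limit_value,
        "units": c.limit_units,
        "comparator": c.comparator,
    }
    if c.threshold_dose is not None:
        d["threshold_dose_gy"] = c.threshold_dose
    if c.label is not None:
        d["label"] = c.label
    if c.condition is not None:
        d["condition"] = c.condition
    return d


def _constraint_from_dict(d: dict) -> DoseConstraint:
    return DoseConstraint(
        structure=d["structure"],
        metric_kind=d["metric"],
        limit_value=float(d["limit"]),
        limit_units=str(d["units"]),
        comparator=d.get("comparator", "<"),
        threshold_dose=(float(d["threshold_dose_gy"]) if "threshold_dose_gy" in d else None),
        label=d.get("label"),
        condition=d.get("condition"),
    )


def save_constraint_table(table: ConstraintTable, path: str | Path) -> None:
    doc = {
        "name": table.name,
        "n_fractions": table.n_fractions,
        "constraints": [_constraint_to_dict(c) for c in table],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_constraint_table(source: str | Path | dict) -> ConstraintTable:
    """Load a constraint table from a YAML file path or a parsed mapping."""
    doc = source if isinstance(source, dict) else yaml.safe_load(Path(source).read_text())
    if not isinstance(doc, dict) or "constraints" not in doc:
        raise ValueError("malformed constraint table: expected a mapping with a 'constraints' list")
    constraints = tuple(_constraint_from_dict(d) for d in doc["constraints"])
    nfx = doc.get("n_fractions")
    return ConstraintTable(
        constraints=constraints,
        n_fractions=(int(nfx) if nfx is not None else None),
        name=doc.get("name"),
    )
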