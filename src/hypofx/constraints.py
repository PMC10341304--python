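"""Evaluation of plans against coverage goals and OAR constraint tables.

Every constraint in a table yields exactly one finding — nothing is
silently dropped. Comparators are honoured exactly at the boundary: an
observed value equal to a "<" limit fails, equal to a "<=" limit passes.
Margins are signed in the constraint's native units so that negative
always means violation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .dvh import MetricResult, MetricSpec, Plan, extract_catalogue, max_dose
from .radiobiology import ConstraintTable, DoseConstraint
from .volumes import mask_volume

__all__ = [
    "CoverageGoal",
    "CoverageFinding",
    "ConstraintFinding",
    "load_coverage_goals",
    "evaluate_coverage",
    "evaluate_constraints",
    "evaluate_plan_constraints",
    "specs_from_constraints",
    "findings_summary",
]


@dataclass(frozen=True)
class CoverageGoal:
    """Target coverage requirement: % of volume at 100% of the dose."""

    target: str
    prescription_gye: float
    goal_pct: float
    hard_pct: float
    max_point_pct: float = 108.0

    def __post_init__(self) -> None:
        if not (self.hard_pct <= self.goal_pct <= 100.0):
            raise ValueError(
                f"expected hard <= goal <= 100, got hard={self.hard_pct}, goal={self.goal_pct}"
            )


@dataclass(frozen=True)
class CoverageFinding:
    """One coverage check: observed V(prescription) against goal and hard limits."""

    target: str
    quantity: str
    observed: float
    goal: float
    hard: float
    goal_met: bool
    passed: bool
    margin: float
    units: str


@dataclass(frozen=True)
class ConstraintFinding:
    """One OAR constraint check with its signed margin.

    ``status`` is "evaluated", "not_evaluable" (endpoint missing from the
    catalogue) or "not_applicable" (condition switch excludes it);
    ``passed`` is None unless evaluated.
    """

    constraint: DoseConstraint
    observed: float | None
    limit: float
    passed: bool | None
    margin: float | None
    status: str


# ---------------------------------------------------------------------------
# Coverage (target goals)
# ---------------------------------------------------------------------------

def load_coverage_goals(path: str | Path | None = None) -> list[CoverageGoal]:
    """Load coverage goals from YAML; defaults to the packaged goal table."""
    if path is None:
        text = resources.files("hypofx.data").joinpath("coverage_goals.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    return [
        CoverageGoal(
            target=g["target"],
            prescription_gye=float(g["prescription_gye"]),
            goal_pct=float(g["goal_pct"]),
            hard_pct=float(g["hard_pct"]),
            max_point_pct=float(g.get("max_point_pct", 108.0)),
        )
        for g in doc["goals"]
    ]


def evaluate_coverage(plan: Plan, goals: Sequence[CoverageGoal]) -> list[CoverageFinding]:
    """Check every target's V(prescription) in % against its goal and hard
    constraint, plus the global maximum point dose against the point-dose
    ceiling (a percentage of the highest prescription among the goals).
    """
    from .dvh import v_at_dose

    findings: list[CoverageFinding] = []
    for goal in goals:
        mask = plan.structures.get(goal.target)
        if mask is None:
            raise KeyError(f"plan {plan.patient_id!r} is missing target structure {goal.target!r}")
        observed = v_at_dose(plan.dose, mask, goal.prescription_gye, "%")
        findings.append(
            CoverageFinding(
                target=goal.target,
                quantity=f"V{goal.prescription_gye:g} GyE (%)",
                observed=observed,
                goal=goal.goal_pct,
                hard=goal.hard_pct,
                goal_met=observed >= goal.goal_pct,
                passed=observed >= goal.hard_pct,
                margin=observed - goal.hard_pct,
                units="%",
            )
        )
    if goals:
        # global hot-spot ceiling, referred to the highest prescription
        ref = max(goals, key=lambda g: g.prescription_gye)
        ceiling = ref.max_point_pct / 100.0 * ref.prescription_gye
        body = plan.structures.get("body")
        observed_max = (
            max_dose(plan.dose, body) if body is not None else float(plan.dose.values.max())
        )
        findings.append(
            CoverageFinding(
                target="body",
                quantity="Max Point Dose (GyE)",
                observed=observed_max,
                goal=ceiling,
                hard=ceiling,
                goal_met=observed_max <= ceiling,
                passed=observed_max <= ceiling,
                margin=ceiling - observed_max,
                units="GyE",
            )
        )
    return findings


# ---------------------------------------------------------------------------
# OAR constraints
# ---------------------------------------------------------------------------

def _spec_for_constraint(c: DoseConstraint) -> MetricSpec:
    if c.metric_kind in ("V_at_dose", "spare_volume"):
        units = "cc" if (c.limit_units == "cc" or c.metric_kind == "spare_volume") else "%"
        return MetricSpec("V_at_dose", c.threshold_dose, units)
    if c.metric_kind == "max_dose":
        return MetricSpec("max", None, "GyE")
    if c.metric_kind == "mean_dose":
        return MetricSpec("mean", None, "GyE")
    raise ValueError(f"no metric spec for constraint kind {c.metric_kind!r}")


def specs_from_constraints(table: ConstraintTable) -> dict[str, tuple[MetricSpec, ...]]:
    """Per-structure metric specs a catalogue must contain to evaluate
    ``table`` (spare_volume rules need the V(threshold) volume in cc)."""
    out: dict[str, list[MetricSpec]] = {}
    for c in table:
        spec = _spec_for_constraint(c)
        out.setdefault(c.structure, [])
        if spec not in out[c.structure]:
            out[c.structure].append(spec)
    return {k: tuple(v) for k, v in out.items()}


def _satisfied(observed: float, limit: float, comparator: str) -> bool:
    if comparator == "<":
        return observed < limit
    if comparator == "<=":
        return observed <= limit
    if comparator == ">=":
        return observed >= limit
    raise ValueError(f"unsupported comparator {comparator!r}")


def evaluate_constraints(
    catalogue: Iterable[MetricResult],
    table: ConstraintTable,
    structure_volumes_cc: Mapping[str, float] | None = None,
    kidney_condition: str = "both_remain",
) -> list[ConstraintFinding]:
    """Evaluate a metric catalogue against an OAR constraint table.

    Returns exactly one finding per constraint. Constraints whose
    ``condition`` does not match ``kidney_condition`` are reported as
    not_applicable; constraints whose endpoint (or, for sparing rules,
    whose structure volume) is absent are reported as not_evaluable.
    """
    index: dict[tuple[str, str, float | None, str], float] = {}
    for r in catalogue:
        key = (r.structure, r.spec.kind, r.spec.threshold, r.spec.output_units)
        index[key] = r.value

    findings: list[ConstraintFinding] = []
    for c in table:
        if c.condition is not None and c.condition != kidney_condition:
            findings.append(ConstraintFinding(c, None, c.limit_value, None, None, "not_applicable"))
            continue
        spec = _spec_for_constraint(c)
        key = (c.structure, spec.kind, spec.threshold, spec.output_units)
        if key not in index:
            findings.append(ConstraintFinding(c, None, c.limit_value, None, None, "not_evaluable"))
            continue
        value = index[key]
        if c.metric_kind == "spare_volume":
            # observed = volume receiving < threshold = total - V(threshold)
            total = (structure_volumes_cc or {}).get(c.structure)
            if total is None:
                findings.append(
                    ConstraintFinding(c, None, c.limit_value, None, None, "not_evaluable")
                )
                continue
            observed = total - value
            passed = _satisfied(observed, c.limit_value, c.comparator)
            margin = observed - c.limit_value
        else:
            observed = value
            passed = _satisfied(observed, c.limit_value, c.comparator)
            margin = c.limit_value - observed
        findings.append(ConstraintFinding(c, observed, c.limit_value, passed, margin, "evaluated"))
    return findings


def evaluate_plan_constraints(
    plan: Plan,
    table: ConstraintTable,
    kidney_condition: str = "both_remain",
) -> list[ConstraintFinding]:
    """Convenience wrapper: extract exactly the endpoints ``table`` needs
    from ``plan`` and evaluate them."""
    specs = specs_from_constraints(table)
    present = {s: sp for s, sp in specs.items() if s in plan.structures}
    catalogue = extract_catalogue(plan, present) if present else []
    volumes = {name: mask_volume(plan.structures[name]) for name in present}
    return evaluate_constraints(catalogue, table, volumes, kidney_condition)


def findings_summary(findings: Sequence[ConstraintFinding], modality: str | None = None) -> str:
    """Human-readable summary: which constraints were exceeded."""
    prefix = f"{modality}: " if modality else ""
    failed = [f for f in findings if f.status == "evaluated" and f.passed is False]
    skipped = [f for f in findings if f.status != "evaluated"]
    lines = []
    if failed:
        labels = ", ".join(
            f"{f.constraint.structure} {f.constraint.label or _spec_for_constraint(f.constraint).label}"
            f" (observed {f.observed:.2f} vs {f.constraint.comparator} {f.limit:g} {f.constraint.limit_units})"
            for f in failed
        )
        lines.append(f"{prefix}exceeded constraints for {labels}")
    else:
        lines.append(f"{prefix}met all evaluated OAR constraints")
    if skipped:
        lines.append(
            f"{prefix}{len(skipped)} constraint(s) not evaluated "
            f"({', '.join(sorted({f.status for f in skipped}))})"
        )
    return "\n".join(lines)
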