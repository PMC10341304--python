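"""Paired cohort statistics: per-endpoint t-tests and the comparison table.

Each dosimetric endpoint is compared between two modalities across a
cohort of patients with Student t-tests — paired and two-sided by
default, since both plans exist for every patient; unpaired (pooled
variance) and one-sided modes are available behind flags. Endpoints that
are constant and identical in both arms (e.g. 100% target coverage
everywhere) carry no information for a t-test and are reported with
p = "N/A" instead of a number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dvh import MetricResult

__all__ = [
    "CohortComparison",
    "t_test",
    "summarize_endpoint",
    "relative_reduction",
    "build_report",
    "report_to_dataframe",
    "format_p",
]

ALPHA = 0.050


@dataclass(frozen=True)
class CohortComparison:
    """Summary of one endpoint across the paired cohort."""

    endpoint_id: str
    structure: str
    endpoint: str
    units: str
    values_a: tuple[float, ...]
    values_b: tuple[float, ...]
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float | None
    p_value: float | None
    significant: bool

    @property
    def p_display(self) -> str:
        return format_p(self.p_value)


def format_p(p: float | None) -> str:
    """Three-decimal p-value string; values below 0.0005 render "0.000",
    and a missing (degenerate) p renders "N/A"."""
    if p is None:
        return "N/A"
    return f"{p:.3f}"


def t_test(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool = True,
    two_sided: bool = True,
) -> tuple[float, float]:
    """Classical Student t-test between two samples.

    Paired mode tests the per-patient differences; unpaired mode uses the
    pooled-variance (equal variance) statistic. Degenerate zero-variance
    cases follow fixed conventions: identical paired samples give
    (0.0, 1.0); a constant nonzero paired difference gives (+/-inf, 0.0).
    One-sided mode halves the two-sided p when the effect is in the a > b
    direction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired and a.size != b.size:
        raise ValueError(f"paired samples must align: {a.size} vs {b.size}")
    if min(a.size, b.size) < 2:
        raise ValueError("need at least two observations per arm")

    if paired:
        diff = a - b
        if np.all(diff == diff[0]):
            if diff[0] == 0:
                return 0.0, 1.0
            t = math.copysign(math.inf, diff[0])
            return t, 0.0
        t, p = stats.ttest_rel(a, b)
    else:
        if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
            if a.mean() == b.mean():
                return 0.0, 1.0
            return math.copysign(math.inf, a.mean() - b.mean()), 0.0
        t, p = stats.ttest_ind(a, b, equal_var=True)
    t, p = float(t), float(p)
    if not two_sided:
        p = p / 2.0 if t > 0 else 1.0 - p / 2.0
    return t, p


def relative_reduction(mean_a: float, mean_b: float) -> float:
    """Relative reduction of arm B versus arm A, in percent:
    100 * (mean_a - mean_b) / mean_a. Requires mean_a > 0."""
    if not mean_a > 0:
        raise ValueError(f"mean_a must be > 0, got {mean_a}")
    return 100.0 * (mean_a - mean_b) / mean_a


def summarize_endpoint(
    endpoint_id: str,
    values_a: Sequence[float],
    values_b: Sequence[float],
    structure: str = "",
    endpoint: str = "",
    units: str = "",
    paired: bool = True,
    two_sided: bool = True,
    alpha: float = ALPHA,
) -> CohortComparison:
    """Means, sample SDs (n-1 denominator) and the t-test for one endpoint.

    When both arms are constant and equal the p-value is reported as
    missing ("N/A") rather than 1.0, mirroring degenerate coverage rows.
    """
    va = np.asarray(values_a, dtype=float)
    vb = np.asarray(values_b, dtype=float)
    if paired and va.size != vb.size:
        raise ValueError("paired cohorts must have one value per patient in each arm")
    if min(va.size, vb.size) < 2:
        raise ValueError("cohort comparison needs at least two patients")

    degenerate = (
        np.all(va == va[0]) and np.all(vb == vb[0]) and va[0] == vb[0]
    )
    if degenerate:
        t_stat, p = None, None
    else:
        t_stat, p = t_test(va, vb, paired=paired, two_sided=two_sided)
    return CohortComparison(
        endpoint_id=endpoint_id,
        structure=structure,
        endpoint=endpoint,
        units=units,
        values_a=tuple(va),
        values_b=tuple(vb),
        mean_a=float(va.mean()),
        sd_a=float(va.std(ddof=1)),
        mean_b=float(vb.mean()),
        sd_b=float(vb.std(ddof=1)),
        t_statistic=t_stat,
        p_value=p,
        significant=(p is not None and p < alpha),
    )


# ---------------------------------------------------------------------------
# Table-style comparison report
# ---------------------------------------------------------------------------

def _pivot(catalogues: Iterable[MetricResult]) -> dict[str, dict[str, MetricResult]]:
    """endpoint_id -> patient_id -> result, preserving endpoint order."""
    out: dict[str, dict[str, MetricResult]] = {}
    for r in catalogues:
        out.setdefault(r.endpoint_id, {})[r.patient_id] = r
    return out


def build_report(
    catalogue_a: Iterable[MetricResult],
    catalogue_b: Iterable[MetricResult],
    paired: bool = True,
    two_sided: bool = True,
    alpha: float = ALPHA,
) -> list[CohortComparison]:
    """Compare two modalities' metric catalogues endpoint by endpoint.

    Rows follow the endpoint order of catalogue A (the configured
    catalogue order); patients are aligned by patient id, and every
    endpoint must be present for every patient in both arms.
    """
    by_ep_a = _pivot(catalogue_a)
    by_ep_b = _pivot(catalogue_b)
    report: list[CohortComparison] = []
    for endpoint_id, per_patient_a in by_ep_a.items():
        if endpoint_id not in by_ep_b:
            raise KeyError(f"endpoint {endpoint_id!r} missing from the second modality")
        per_patient_b = by_ep_b[endpoint_id]
        patients = sorted(per_patient_a)
        if sorted(per_patient_b) != patients:
            raise ValueError(f"patient sets differ for endpoint {endpoint_id!r}")
        sample = per_patient_a[patients[0]]
        report.append(
            summarize_endpoint(
                endpoint_id,
                [per_patient_a[p].value for p in patients],
                [per_patient_b[p].value for p in patients],
                structure=sample.structure,
                endpoint=sample.spec.label,
                units=sample.units,
                paired=paired,
                two_sided=two_sided,
                alpha=alpha,
            )
        )
    return report


def report_to_dataframe(
    report: Sequence[CohortComparison],
    label_a: str = "photon",
    label_b: str = "proton",
) -> pd.DataFrame:
    """Comparison report as a DataFrame in the Mean / St-Dev / p-Value
    column layout, with a significance mark and the relative reduction of
    arm B vs arm A where the arm-A mean is positive."""
    rows = []
    for c in report:
        rel = (
            relative_reduction(c.mean_a, c.mean_b) if c.mean_a > 0 else float("nan")
        )
        rows.append(
            {
                "structure": c.structure,
                "endpoint": c.endpoint,
                f"{label_a}_mean": c.mean_a,
                f"{label_a}_sd": c.sd_a,
                f"{label_b}_mean": c.mean_b,
                f"{label_b}_sd": c.sd_b,
                "t": c.t_statistic,
                "p_value": c.p_display + (" *" if c.significant else ""),
                "relative_reduction_pct": rel,
            }
        )
    return pd.DataFrame(rows)
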