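"""Delivery-QA statistics and metric-vs-QA correlation.

The delivery-QA side of the analysis consumes, per plan, a gamma-analysis
pass percentage (2 %/2 mm local, 20 % threshold) and a median dose
difference (MDD): the median of ``(Meas - Calc) / Meas`` over measurement
points above half the maximum dose, in percent.  Each zone's average GPF
is regressed against the QA quantities by ordinary least squares, and a
t-test on the slope (n - 2 degrees of freedom) decides whether the metric
predicts the QA outcome.  Raw p-values are reported without
multiple-testing correction across the zone x metric grid.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .zones import ZONE_NAMES

__all__ = [
    "DQARecord",
    "RegressionResult",
    "median_dose_difference",
    "sphere_equivalent_diameter",
    "fit_slope_with_t_test",
    "correlate_cohort",
    "read_dqa_csv",
    "write_dqa_csv",
]


@dataclass
class DQARecord:
    """Per-plan delivery-QA result."""

    plan_id: str
    gamma_pass: float  # percent, 2%/2mm local with 20% threshold
    mdd: float  # percent
    target_volume: float | None = None  # cm^3

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma_pass <= 100.0:
            raise ValueError(f"gamma_pass must be in [0, 100], got {self.gamma_pass}")


@dataclass
class RegressionResult:
    """OLS fit of a QA quantity on a single metric."""

    slope: float
    intercept: float
    slope_se: float
    t_value: float
    p_value: float
    r_squared: float
    n: int


def median_dose_difference(
    meas: np.ndarray,
    calc: np.ndarray,
    threshold_fraction: float = 0.5,
    threshold_on: str = "meas",
) -> float:
    """Median of ``(Meas - Calc) / Meas`` in percent over high-dose points.

    Points with measured dose below ``threshold_fraction`` of the maximum
    are excluded.  ``threshold_on`` chooses whether the maximum (and the
    mask) is taken from the measured or calculated distribution; the
    measured one is the default.
    """
    meas = np.asarray(meas, dtype=float)
    calc = np.asarray(calc, dtype=float)
    if meas.shape != calc.shape:
        raise ValueError("meas and calc must have the same shape")
    ref = {"meas": meas, "calc": calc}[threshold_on]
    if ref.size == 0 or ref.max() <= 0:
        raise ValueError("reference dose array empty or nonpositive")
    mask = ref >= threshold_fraction * ref.max()
    if not np.any(mask):
        raise ValueError("no points above the dose threshold")
    return float(np.median((meas[mask] - calc[mask]) / meas[mask]) * 100.0)


def sphere_equivalent_diameter(volume: float, decimals: int = 1) -> float:
    """Diameter (cm) of the sphere with the given volume (cm^3).

    ``d = (6 V / pi)**(1/3)``, rounded to 0.1 cm for reporting.
    """
    if volume <= 0:
        raise ValueError(f"volume must be > 0, got {volume}")
    return round(float((6.0 * volume / np.pi) ** (1.0 / 3.0)), decimals)


def fit_slope_with_t_test(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Simple OLS of y on x with the slope's two-sided t-test.

    Residual-variance-based standard error, Student t with n - 2 degrees
    of freedom, ``r_squared = 1 - SSres / SStot`` (0 for constant y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: x is constant")
    if np.ptp(y) == 0:
        # OLS is exact: zero slope, zero residuals; define R^2 = 0
        return RegressionResult(0.0, float(y[0]), 0.0, 0.0, 1.0, 0.0, n)
    res = stats.linregress(x, y)
    t = res.slope / res.stderr if res.stderr > 0 else np.inf * np.sign(res.slope)
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        t_value=float(t),
        p_value=float(p),
        r_squared=float(res.rvalue**2),
        n=n,
    )


def read_dqa_csv(path: str | Path) -> list[DQARecord]:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        records.append(
            DQARecord(
                plan_id=str(row["plan_id"]),
                gamma_pass=float(row["gamma_pass"]),
                mdd=float(row["mdd"]),
                target_volume=float(row["target_volume"])
                if "target_volume" in df.columns and pd.notna(row.get("target_volume"))
                else None,
            )
        )
    return records


def write_dqa_csv(records: Iterable[DQARecord], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([asdict(r) for r in records]).to_csv(path, index=False)
    return path


def correlate_cohort(
    plan_table: pd.DataFrame,
    dqa: Sequence[DQARecord] | pd.DataFrame,
) -> pd.DataFrame:
    """Regress QA results on every zone's average GPF across a cohort.

    ``plan_table`` has one row per plan with a ``plan_id`` column, the
    seven raw zone columns (``open`` .. ``neglected``) and optionally
    their normalized counterparts (``open_norm`` ..).  ``dqa`` provides
    gamma pass % and MDD per plan.  Plans present on only one side are
    excluded with a warning.

    Returns a long table with one :class:`RegressionResult` row per
    (zone, raw/normalized, gamma_pass/mdd) combination.
    """
    if isinstance(dqa, pd.DataFrame):
        dqa_df = dqa.copy()
    else:
        dqa_df = pd.DataFrame([asdict(r) for r in dqa])
    dqa_df["plan_id"] = dqa_df["plan_id"].astype(str)
    plan_table = plan_table.copy()
    plan_table["plan_id"] = plan_table["plan_id"].astype(str)

    unmatched = set(plan_table["plan_id"]).symmetric_difference(dqa_df["plan_id"])
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} unmatched plan id(s) excluded: {sorted(unmatched)}",
            stacklevel=2,
        )
    merged = plan_table.merge(dqa_df, on="plan_id", how="inner")
    if len(merged) < 3:
        raise ValueError(f"cohort too small after join: n={len(merged)} < 3")

    rows = []
    for zone in ZONE_NAMES:
        for suffix, normalized in (("", False), ("_norm", True)):
            col = zone + suffix
            if col not in merged.columns:
                continue
            for target in ("gamma_pass", "mdd"):
                try:
                    res = fit_slope_with_t_test(
                        merged[col].to_numpy(), merged[target].to_numpy()
                    )
                except ValueError as exc:
                    warnings.warn(f"{col} vs {target}: {exc}", stacklevel=2)
                    continue
                rows.append(
                    {
                        "zone": zone,
                        "normalized": normalized,
                        "qa_metric": target,
                        **asdict(res),
                    }
                )
    return pd.DataFrame(rows)
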