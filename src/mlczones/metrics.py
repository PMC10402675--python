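"""Grid point fractions (GPFs) and their MU-weighted averages.

For control point i with zone fractions ``f_i`` (a 7-vector summing to 1)
and MU weight ``m_i``, the plan- or beam-level average per zone is

    AverageGPF      = sum_i f_i * m_i / sum_i m_i

and, normalizing each control point by its open-zone fraction ``o_i``,

    NormAverageGPF  = sum_i (f_i / o_i) * m_i / sum_i m_i.

The normalized form distinguishes plans whose jaw settings (and hence
raw zone fractions) are similar but whose open-field areas differ.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .params import BeamModelParameters
from .plan_io import Plan, control_point_mu
from .zones import N_ZONES, ZONE_NAMES, ZoneGrid, ZoneLabel, classify_control_point

__all__ = [
    "GPFVector",
    "AverageGPF",
    "gpf_from_grid",
    "weighted_average_gpf",
    "normalized_weighted_average_gpf",
    "plan_metrics",
    "plan_gpf_table",
]


@dataclass
class GPFVector:
    """Zone fractions of one control point plus its MU weight."""

    f: np.ndarray  # (7,) fractions ordered by ZoneLabel
    m: float
    cp_index: int = 0
    beam_id: str = ""

    @property
    def o(self) -> float:
        """Open-zone fraction ``o_i``."""
        return float(self.f[ZoneLabel.OPEN])


@dataclass
class AverageGPF:
    """Aggregate record: per-zone weighted and normalized averages."""

    scope: str  # 'beam' or 'plan'
    beam_id: str | None
    weighted: np.ndarray  # (7,)
    normalized: np.ndarray | None  # (7,) or None if a closed CP was skipped


def gpf_from_grid(grid: ZoneGrid, m: float, cp_index: int = 0, beam_id: str = "") -> GPFVector:
    """Zone fractions of a classified grid: counts over total points."""
    counts = grid.zone_counts()
    total = counts.sum()
    if total == 0:
        raise ValueError("empty grid")
    return GPFVector(f=counts / total, m=float(m), cp_index=cp_index, beam_id=beam_id)


def _weights_fractions(vectors: Sequence[GPFVector]) -> tuple[np.ndarray, np.ndarray]:
    if not vectors:
        raise ValueError("no GPF vectors")
    f = np.stack([v.f for v in vectors])
    m = np.array([v.m for v in vectors], dtype=float)
    return f, m


def weighted_average_gpf(vectors: Sequence[GPFVector]) -> np.ndarray:
    """MU-weighted per-zone average over a scope (7-vector)."""
    f, m = _weights_fractions(vectors)
    total = m.sum()
    if total <= 0:
        raise ValueError("zero meterset scope")
    return (f * m[:, None]).sum(axis=0) / total


def normalized_weighted_average_gpf(
    vectors: Sequence[GPFVector], skip_closed: bool = False
) -> np.ndarray:
    """MU-weighted average of the open-normalized fractions ``f_i / o_i``.

    A control point with zero open fraction but nonzero MU is an error by
    default; with ``skip_closed`` it is excluded with a warning instead.
    """
    f, m = _weights_fractions(vectors)
    o = f[:, ZoneLabel.OPEN]
    bad = (o == 0) & (m > 0)
    if np.any(bad):
        if not skip_closed:
            raise ValueError(
                f"closed aperture with nonzero MU at control point(s) "
                f"{[vectors[i].cp_index for i in np.flatnonzero(bad)]}"
            )
        import warnings

        warnings.warn(
            f"{int(bad.sum())} closed control point(s) with nonzero MU "
            "excluded from normalized average",
            stacklevel=2,
        )
        keep = ~bad
        f, m, o = f[keep], m[keep], o[keep]
    active = m > 0
    total = m.sum()
    if total <= 0:
        raise ValueError("zero meterset scope")
    ratio = np.zeros_like(f)
    ratio[active] = f[active] / o[active, None]
    return (ratio * m[:, None]).sum(axis=0) / total


def plan_metrics(
    plan: Plan,
    params: BeamModelParameters,
    spacing: float = 0.01,
    mu_convention: str = "forward",
    skip_closed: bool = False,
) -> pd.DataFrame:
    """Classify every control point and tabulate GPFs at all levels.

    Returns a tidy table with one row per control point (``level ==
    'control_point'``) plus two aggregate rows (``kind`` 'weighted' and
    'normalized') per beam and per plan.  Columns hold the plan id, beam
    id, control-point index, MU weight ``m``, the seven zone fractions
    and the open fraction ``o``.  Zero-MU control points (e.g. the
    terminal one under the forward-difference convention) are classified
    and reported but contribute nothing to the averages.

    Repeated aperture shapes (identical leaves + jaws) are classified
    once and cached.
    """
    plan.validate()
    cache: dict[bytes, np.ndarray] = {}
    rows: list[dict] = []
    all_vectors: list[GPFVector] = []
    beam_aggregates: list[AverageGPF] = []

    for beam in plan.beams:
        m = control_point_mu(beam, convention=mu_convention)
        vectors: list[GPFVector] = []
        for cp, mi in zip(beam.control_points, m):
            key = (
                cp.bank_a.tobytes()
                + cp.bank_b.tobytes()
                + np.array(
                    [cp.jaw_x_low, cp.jaw_x_high, cp.jaw_y_low, cp.jaw_y_high]
                ).tobytes()
            )
            f = cache.get(key)
            if f is None:
                grid = classify_control_point(cp, plan.geometry, params, spacing)
                f = gpf_from_grid(grid, 0.0).f
                cache[key] = f
            vectors.append(
                GPFVector(f=f, m=float(mi), cp_index=cp.index, beam_id=beam.name)
            )
        all_vectors.extend(vectors)
        w = weighted_average_gpf(vectors)
        try:
            nrm = normalized_weighted_average_gpf(vectors, skip_closed=skip_closed)
        except ValueError:
            if not skip_closed:
                raise
            nrm = None
        beam_aggregates.append(
            AverageGPF(scope="beam", beam_id=beam.name, weighted=w, normalized=nrm)
        )
        for v in vectors:
            rows.append(_row(plan.plan_id, v.beam_id, v.cp_index, "control_point", "raw", v.m, v.f))

    for agg in beam_aggregates:
        rows.append(_row(plan.plan_id, agg.beam_id, None, "beam", "weighted", None, agg.weighted))
        if agg.normalized is not None:
            rows.append(_row(plan.plan_id, agg.beam_id, None, "beam", "normalized", None, agg.normalized))

    # plan level pools all control points directly
    plan_w = weighted_average_gpf(all_vectors)
    rows.append(_row(plan.plan_id, None, None, "plan", "weighted", None, plan_w))
    try:
        plan_n = normalized_weighted_average_gpf(all_vectors, skip_closed=skip_closed)
        rows.append(_row(plan.plan_id, None, None, "plan", "normalized", None, plan_n))
    except ValueError:
        if not skip_closed:
            raise

    return pd.DataFrame(rows)


def plan_gpf_table(tables: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Collapse per-plan metric tables into one cohort-wide plan table.

    Takes the tidy outputs of :func:`plan_metrics` (one per plan) and
    returns one row per plan with the seven weighted zone columns and,
    where available, the normalized ones suffixed ``_norm`` — the input
    format of :func:`mlczones.qa.correlate_cohort`.
    """
    rows = []
    for df in tables:
        plan_rows = df[df["level"] == "plan"]
        if plan_rows.empty:
            raise ValueError("metrics table has no plan-level rows")
        plan_id = plan_rows["plan_id"].iloc[0]
        out: dict = {"plan_id": plan_id}
        for _, r in plan_rows.iterrows():
            suffix = "" if r["kind"] == "weighted" else "_norm"
            for name in ZONE_NAMES:
                out[name + suffix] = r[name]
        rows.append(out)
    return pd.DataFrame(rows)


def _row(plan_id, beam_id, cp_index, level, kind, m, f) -> dict:
    d = {
        "plan_id": plan_id,
        "beam_id": beam_id,
        "cp_index": cp_index,
        "level": level,
        "kind": kind,
        "m": m,
    }
    for z, name in enumerate(ZONE_NAMES):
        d[name] = float(f[z])
    d["o"] = float(f[ZoneLabel.OPEN])
    return d
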