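"""Synthetic plans, simulated DQA cohorts and the analytic GPF oracle.

Three generators emulate the study's inputs:

- :func:`make_validation_plan` rebuilds the hand-checkable validation
  suite: a 30 x 30 cm^2 jaw field with all leaves closed at the field
  center except one 0.5 cm leaf retracted by 0.5 cm (a 0.5 x 0.5 cm^2
  aperture), plus centered MLC-defined squares from 1 x 1 to
  28 x 28 cm^2 (the 10 x 10 case retracts the 20 innermost pairs).
- :func:`make_random_vmat_plan` produces reproducible VMAT-like plans
  with smoothly random-walking leaves for cohort-scale exercises.
- :func:`simulate_dqa_cohort` draws per-plan QA results with a known
  linear GPF -> MDD relationship plus Gaussian noise, and gamma pass
  percentages deliberately uncorrelated with the metrics.

:func:`analytic_gpf_oracle` is the independent reference for the grid
classifier: it derives each zone's exact x-interval per leaf row and
tongue-and-groove strip by interval arithmetic and counts the cell
centers falling inside, never scanning a 2D grid.  Because it counts the
same cell centers the classifier samples, agreement is limited only by
floating point.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .params import BeamModelParameters, MLCGeometry
from .plan_io import Beam, ControlPoint, Plan
from .qa import DQARecord
from .zones import N_ZONES, ZONE_NAMES, ZoneLabel, calibration_shift

__all__ = [
    "ApertureSpec",
    "SimulatedCohortSpec",
    "make_validation_plan",
    "analytic_gpf_oracle",
    "analytic_area_fractions",
    "make_random_vmat_plan",
    "simulate_dqa_cohort",
]


@dataclass
class ApertureSpec:
    """A static, axis-aligned aperture: jaws plus per-pair tip positions."""

    jaw_x_low: float
    jaw_x_high: float
    jaw_y_low: float
    jaw_y_high: float
    bank_a: np.ndarray
    bank_b: np.ndarray
    description: str = ""
    geometry: MLCGeometry = field(default_factory=MLCGeometry.millennium120)

    @classmethod
    def from_control_point(
        cls, cp: ControlPoint, geometry: MLCGeometry, description: str = ""
    ) -> "ApertureSpec":
        return cls(
            jaw_x_low=cp.jaw_x_low,
            jaw_x_high=cp.jaw_x_high,
            jaw_y_low=cp.jaw_y_low,
            jaw_y_high=cp.jaw_y_high,
            bank_a=np.asarray(cp.bank_a, dtype=float),
            bank_b=np.asarray(cp.bank_b, dtype=float),
            description=description,
            geometry=geometry,
        )

    def to_control_point(self, index: int = 0, cumulative_weight: float = 0.0) -> ControlPoint:
        cp = ControlPoint(
            index=index,
            bank_a=self.bank_a.copy(),
            bank_b=self.bank_b.copy(),
            jaw_x_low=self.jaw_x_low,
            jaw_x_high=self.jaw_x_high,
            jaw_y_low=self.jaw_y_low,
            jaw_y_high=self.jaw_y_high,
            cumulative_weight=cumulative_weight,
        )
        cp.validate()
        return cp


@dataclass
class SimulatedCohortSpec:
    """Ground truth for a simulated DQA cohort.

    ``mdd_j = intercept + sum_z slope_by_zone[z] * GPF_j[z] + N(0, noise_sd)``
    per plan j, in percent; gamma pass percentages are drawn independently
    of the metrics.
    """

    slope_by_zone: Mapping[str, float]
    intercept: float = 0.0
    noise_sd: float = 0.5
    seed: int = 0
    n_plans: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_plans is not None and self.n_plans < 3:
            raise ValueError("n_plans must be >= 3")
        unknown = set(self.slope_by_zone) - set(ZONE_NAMES)
        if unknown:
            raise ValueError(f"unknown zone name(s): {sorted(unknown)}")


# ---------------------------------------------------------------------------
# Validation plan
# ---------------------------------------------------------------------------

def _static_beam(
    number: int,
    name: str,
    bank_a: np.ndarray,
    bank_b: np.ndarray,
    jaw: float = 15.0,
    meterset: float = 100.0,
) -> Beam:
    cps = [
        ControlPoint(
            index=i,
            bank_a=bank_a.copy(),
            bank_b=bank_b.copy(),
            jaw_x_low=-jaw,
            jaw_x_high=jaw,
            jaw_y_low=-jaw,
            jaw_y_high=jaw,
            cumulative_weight=float(i),
        )
        for i in (0, 1)
    ]
    return Beam(
        beam_number=number,
        name=name,
        control_points=cps,
        beam_meterset=meterset,
        final_cumulative_weight=1.0,
    )


def make_validation_plan(sizes: Sequence[int] = tuple(range(1, 29))) -> Plan:
    """The hand-checkable validation suite as a single plan.

    Beam 1: 30 x 30 cm^2 jaws, every leaf pair closed at x = 0, except the
    bank-A leaf of one innermost 0.5 cm pair retracted by 0.5 cm.
    Subsequent beams: centered MLC-defined squares with the requested side
    lengths (cm), jaws fixed at 30 x 30 cm^2.
    """
    geometry = MLCGeometry.millennium120()
    n = geometry.n_pairs
    bnd = geometry.leaf_boundaries

    a = np.zeros(n)
    b = np.zeros(n)
    retracted = int(np.searchsorted(bnd, 0.0))  # pair spanning [0.0, 0.5)
    a[retracted] = -0.5
    beams = [_static_beam(1, "closed+0.5cm-retraction", a, b)]

    for k, side in enumerate(sizes, start=2):
        half = side / 2.0
        a = np.zeros(n)
        b = np.zeros(n)
        inside = (bnd[1:] > -half) & (bnd[:-1] < half)
        a[inside] = -half
        b[inside] = half
        beams.append(_static_beam(k, f"square-{side}x{side}", a, b))

    plan = Plan(plan_id="validation", beams=beams, geometry=geometry)
    plan.validate()
    return plan


# ---------------------------------------------------------------------------
# Analytic interval-counting oracle
# ---------------------------------------------------------------------------

_ORACLE_OPEN = 0
_ORACLE_CAL = 1
_ORACLE_TIP = 2
_ORACLE_BODY = 3


def _base_zone_at(x: float, a: float, b: float, ac: float, bc: float, w: float) -> int:
    """Zone of a single-row point, evaluated only at interval midpoints."""
    if ac < x < bc:
        return _ORACLE_OPEN if a < x < b else _ORACLE_CAL
    if (ac - w <= x <= ac) or (bc <= x <= bc + w):
        return _ORACLE_TIP
    return _ORACLE_BODY


def _strip_zone(z_own: int, z_other: int) -> int:
    own_open = z_own in (_ORACLE_OPEN, _ORACLE_CAL)
    other_open = z_other in (_ORACLE_OPEN, _ORACLE_CAL)
    if own_open and other_open:
        return z_own  # OPEN or CALIBRATION of the own row
    if not own_open and not other_open:
        return int(ZoneLabel.PAIRED)
    covered = z_other if own_open else z_own
    return int(ZoneLabel.NEGLECTED) if covered == _ORACLE_TIP else int(ZoneLabel.EXPOSED)


def _row_edges(spec: ApertureSpec, params: BeamModelParameters, j: int) -> tuple:
    a = float(spec.bank_a[j])
    b = float(spec.bank_b[j])
    ac = a - float(calibration_shift(a, params))
    bc = b + float(calibration_shift(b, params))
    return a, b, ac, bc


def _breakpoints(
    rows: Iterable[tuple], params: BeamModelParameters, xlo: float, xhi: float
) -> list[float]:
    w = params.tip_width
    pts = {xlo, xhi}
    for a, b, ac, bc in rows:
        for p in (a, b, ac, bc, ac - w, bc + w):
            if xlo < p < xhi:
                pts.add(p)
    return sorted(pts)


def _count_between(centers: np.ndarray, lo: float, hi: float) -> int:
    """Cell centers in [lo, hi); no center may coincide with an endpoint."""
    return int(np.searchsorted(centers, hi) - np.searchsorted(centers, lo))


def _x_measures(
    spec: ApertureSpec,
    params: BeamModelParameters,
    rows: list[tuple],
    combine: bool,
    x_centers: np.ndarray | None,
) -> np.ndarray:
    """Per-zone measure along x for one row (or strip of two rows).

    Counts cell centers when ``x_centers`` is given, else sums interval
    lengths (the area-based variant).
    """
    w = params.tip_width
    out = np.zeros(N_ZONES)
    pts = _breakpoints(rows, params, spec.jaw_x_low, spec.jaw_x_high)
    for lo, hi in zip(pts[:-1], pts[1:]):
        mid = 0.5 * (lo + hi)
        z = _base_zone_at(mid, *rows[0], w)
        if combine:
            z = _strip_zone(z, _base_zone_at(mid, *rows[1], w))
        measure = (
            _count_between(x_centers, lo, hi) if x_centers is not None else hi - lo
        )
        out[z] += measure
    return out


def _gpf_bands(
    spec: ApertureSpec,
    params: BeamModelParameters,
    spacing: float | None,
) -> np.ndarray:
    """Shared engine: per-zone measure (center counts or areas)."""
    bnd = spec.geometry.leaf_boundaries
    tg = params.tg_width
    n_pairs = spec.geometry.n_pairs
    ylo, yhi = spec.jaw_y_low, spec.jaw_y_high
    xlo, xhi = spec.jaw_x_low, spec.jaw_x_high
    if ylo < bnd[0] or yhi > bnd[-1]:
        raise ValueError("jaw y-range extends beyond the MLC leaf boundaries")
    if tg > 0 and 2 * tg > spec.geometry.widths.min():
        raise ValueError("tongue-and-groove strips wider than a leaf row")

    if spacing is not None:
        n_x = int(round((xhi - xlo) / spacing))
        n_y = int(round((yhi - ylo) / spacing))
        if n_x <= 0 or n_y <= 0:
            raise ValueError("jaw rectangle of zero area")
        x_centers = xlo + (np.arange(n_x) + 0.5) * spacing
        y_centers = ylo + (np.arange(n_y) + 0.5) * spacing

        def y_measure(lo: float, hi: float, lo_closed: bool, hi_closed: bool) -> float:
            i0 = np.searchsorted(y_centers, lo, side="left" if lo_closed else "right")
            i1 = np.searchsorted(y_centers, hi, side="right" if hi_closed else "left")
            return float(max(0, i1 - i0))

    else:
        x_centers = None

        def y_measure(lo: float, hi: float, lo_closed: bool, hi_closed: bool) -> float:
            return max(0.0, min(hi, yhi) - max(lo, ylo))

    edges = [_row_edges(spec, params, j) for j in range(n_pairs)]
    counts = np.zeros(N_ZONES)
    for j in range(n_pairs):
        b0, b1 = bnd[j], bnd[j + 1]
        if b1 <= ylo or b0 >= yhi:
            continue
        lo_strip = tg if (tg > 0 and j > 0) else 0.0
        hi_strip = tg if (tg > 0 and j < n_pairs - 1) else 0.0
        # Core of the row. The strip conditions are strict (|y - b| < tg),
        # so both trimmed edges belong to the core; with no upper strip the
        # top edge is open because rows are half-open [b0, b1).
        h = y_measure(
            b0 + lo_strip, b1 - hi_strip, lo_closed=True, hi_closed=hi_strip > 0
        )
        if h:
            counts += h * _x_measures(spec, params, [edges[j]], False, x_centers)
        if lo_strip:  # [b0, b0 + tg): own row j, neighbor j - 1
            h = y_measure(b0, b0 + tg, lo_closed=True, hi_closed=False)
            if h:
                counts += h * _x_measures(
                    spec, params, [edges[j], edges[j - 1]], True, x_centers
                )
        if hi_strip:  # (b1 - tg, b1): own row j, neighbor j + 1
            h = y_measure(b1 - tg, b1, lo_closed=False, hi_closed=False)
            if h:
                counts += h * _x_measures(
                    spec, params, [edges[j], edges[j + 1]], True, x_centers
                )
    return counts


def analytic_gpf_oracle(
    spec: ApertureSpec,
    params: BeamModelParameters,
    spacing: float = 0.01,
) -> np.ndarray:
    """Independent per-zone grid point fractions for a static aperture.

    Counts cell centers inside each zone's exact x/y intervals per leaf
    row and tongue-and-groove strip, so agreement with the grid
    classifier is limited only by floating point.  Returns the 7-vector
    of fractions ordered by :class:`~mlczones.zones.ZoneLabel`.
    """
    counts = _gpf_bands(spec, params, spacing)
    total = counts.sum()
    if total == 0:
        raise ValueError("jaw rectangle of zero area")
    return counts / total


def analytic_area_fractions(
    spec: ApertureSpec, params: BeamModelParameters
) -> np.ndarray:
    """Exact area fractions per zone (for grid-convergence studies)."""
    areas = _gpf_bands(spec, params, None)
    return areas / areas.sum()


# ---------------------------------------------------------------------------
# Random VMAT-like plans
# ---------------------------------------------------------------------------

def make_random_vmat_plan(
    seed: int,
    n_beams: int = 2,
    n_cp: int = 30,
    plan_id: str | None = None,
) -> Plan:
    """Reproducible VMAT-like plan with smoothly varying random apertures.

    Jaws are a random rectangle (rounded to 0.1 cm); leaf tips start as a
    rounded random aperture and random-walk between control points
    (rounded to 0.01 cm, order-preserving, closed pairs allowed);
    cumulative meterset weights increase strictly.  Identical seeds give
    identical plans.
    """
    if n_beams < 1 or n_cp < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    geometry = MLCGeometry.millennium120()
    n = geometry.n_pairs
    centers = 0.5 * (geometry.leaf_boundaries[:-1] + geometry.leaf_boundaries[1:])

    beams = []
    for bnum in range(1, n_beams + 1):
        jx = np.round(rng.uniform(3.0, 10.0, size=2), 1)
        jy = np.round(rng.uniform(3.0, 10.0, size=2), 1)
        # initial aperture: elliptical-ish opening over the in-jaw rows
        gap = np.where(
            np.abs(centers) < jy[1],
            rng.uniform(0.5, 4.0) * np.sqrt(np.clip(1 - (centers / (jy[1] + 1.0)) ** 2, 0, 1)),
            0.0,
        )
        mid = rng.uniform(-2.0, 2.0, size=n)
        a = mid - gap / 2.0
        b = mid + gap / 2.0

        cps = []
        weights = np.concatenate([[0.0], np.cumsum(rng.uniform(0.5, 1.5, n_cp - 1))])
        if n_cp > 1:
            weights /= weights[-1]
        for i in range(n_cp):
            aa = np.round(np.clip(a, -14.5, 14.5), 2)
            bb = np.round(np.clip(b, -14.5, 14.5), 2)
            bb = np.maximum(aa, bb)
            cps.append(
                ControlPoint(
                    index=i,
                    bank_a=aa,
                    bank_b=bb,
                    jaw_x_low=float(-jx[0]),
                    jaw_x_high=float(jx[1]),
                    jaw_y_low=float(-jy[0]),
                    jaw_y_high=float(jy[1]),
                    cumulative_weight=float(weights[i]),
                )
            )
            a = a + rng.normal(0.0, 0.3, size=n)
            b = b + rng.normal(0.0, 0.3, size=n)
            a, b = np.minimum(a, b), np.maximum(a, b)
        beams.append(
            Beam(
                beam_number=bnum,
                name=f"arc{bnum}",
                control_points=cps,
                beam_meterset=float(np.round(rng.uniform(150.0, 400.0), 1)),
                final_cumulative_weight=1.0,
            )
        )
    plan = Plan(
        plan_id=plan_id or f"vmat-seed{seed}", beams=beams, geometry=geometry
    )
    plan.validate()
    return plan


# ---------------------------------------------------------------------------
# Simulated DQA cohorts
# ---------------------------------------------------------------------------

def simulate_dqa_cohort(
    plan_table: pd.DataFrame, spec: SimulatedCohortSpec
) -> list[DQARecord]:
    """Draw per-plan QA results with a known GPF -> MDD relationship.

    ``plan_table`` holds one row per plan with a ``plan_id`` column and
    the seven raw zone columns.  MDD follows the spec's linear model plus
    Gaussian noise; gamma pass % is drawn from a normal distribution
    truncated to [0, 100], independent of the metrics (mirroring the
    null finding for gamma).
    """
    n = len(plan_table)
    if spec.n_plans is not None and spec.n_plans != n:
        raise ValueError(f"spec.n_plans={spec.n_plans} but table has {n} plans")
    if n < 3:
        raise ValueError("cohort needs >= 3 plans")
    rng = np.random.default_rng(spec.seed)
    mdd = np.full(n, spec.intercept, dtype=float)
    for zone, slope in spec.slope_by_zone.items():
        mdd += slope * plan_table[zone].to_numpy(dtype=float)
    if spec.noise_sd > 0:
        mdd += rng.normal(0.0, spec.noise_sd, size=n)
    gamma = np.clip(rng.normal(96.0, 3.0, size=n), 0.0, 100.0)
    return [
        DQARecord(
            plan_id=str(pid), gamma_pass=float(g), mdd=float(d), target_volume=None
        )
        for pid, g, d in zip(plan_table["plan_id"], gamma, mdd)
    ]
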