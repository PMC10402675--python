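"""Seven-zone transmission classification of MLC control points.

Every sample point of the jaw-bounded isocenter-plane grid is assigned
exactly one of seven zones of the RayStation-style MLC model:

========== ============ =======================================================
zone       transmission criterion
========== ============ =======================================================
OPEN        1           inside the aperture before and after leaf calibration
CALIBRATION 1           inside the aperture only after the calibration shift
TIP         sqrt(T)     within ``tip_width`` of a calibrated leaf end, inside
                        the leaf
BODY        T           under the leaf, beyond the tip zone
PAIRED      T           tongue-and-groove strip, both adjacent rows covered
EXPOSED     sqrt(T)     strip, one row open and the other row body
NEGLECTED   1           strip, one row open and the other row tip
========== ============ =======================================================

Sampling is at cell centers ``x_k = jaw_low + (k + 1/2) * spacing`` so no
sample falls on the jaw edge; open-aperture intervals are open and tip
intervals closed, which makes every boundary tie deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .params import BeamModelParameters, MLCGeometry
from .plan_io import ControlPoint

__all__ = [
    "ZoneLabel",
    "CoverageState",
    "ZoneGrid",
    "calibration_shift",
    "coverage_state",
    "classify_control_point",
    "zone_transmission_map",
    "ZONE_NAMES",
]


class ZoneLabel(IntEnum):
    OPEN = 0
    CALIBRATION = 1
    TIP = 2
    BODY = 3
    PAIRED = 4
    EXPOSED = 5
    NEGLECTED = 6


ZONE_NAMES = tuple(z.name.lower() for z in ZoneLabel)

N_ZONES = len(ZoneLabel)


class CoverageState(IntEnum):
    """Per-(x, leaf-row) state before tongue-and-groove sub-zoning."""

    OPEN_NOW = 0
    OPEN_ONLY_AFTER_CAL = 1
    TIP = 2
    BODY = 3


def calibration_shift(
    tip_position: float | np.ndarray, params: BeamModelParameters
) -> float | np.ndarray:
    """Leaf-position calibration shift (cm) for a tip at ``tip_position``.

    ``shift = offset + gain * p + curvature * p**2``; a positive shift
    retracts the leaf, enlarging the aperture.
    """
    p = tip_position
    return params.offset + params.gain * p + params.curvature * p * p


def _row_states(
    bank_a: np.ndarray,
    bank_b: np.ndarray,
    x: np.ndarray,
    params: BeamModelParameters,
) -> np.ndarray:
    """Coverage state for every (leaf pair, x sample): (n_pairs, n_x) int8."""
    a = bank_a[:, None]
    b = bank_b[:, None]
    ac = a - calibration_shift(a, params)  # calibrated bank-A tip
    bc = b + calibration_shift(b, params)
    w = params.tip_width
    open_cal = (x > ac) & (x < bc)
    open_now = open_cal & (x > a) & (x < b)
    tip = ((x >= ac - w) & (x <= ac)) | ((x >= bc) & (x <= bc + w))
    states = np.full((bank_a.size, x.size), CoverageState.BODY, dtype=np.int8)
    states[tip] = CoverageState.TIP
    states[open_cal] = CoverageState.OPEN_ONLY_AFTER_CAL
    states[open_now] = CoverageState.OPEN_NOW
    return states


def coverage_state(
    x: float,
    pair_index: int,
    cp: ControlPoint,
    params: BeamModelParameters,
) -> CoverageState:
    """Coverage state of leaf pair ``pair_index`` at position ``x``."""
    if not 0 <= pair_index < cp.bank_a.size:
        raise IndexError(f"pair_index {pair_index} out of range")
    s = _row_states(
        cp.bank_a[pair_index : pair_index + 1],
        cp.bank_b[pair_index : pair_index + 1],
        np.array([float(x)]),
        params,
    )
    return CoverageState(int(s[0, 0]))


@dataclass
class ZoneGrid:
    """Zone labels sampled over the jaw rectangle of one control point."""

    labels: np.ndarray  # (n_y, n_x) int8 of ZoneLabel values
    x_origin: float
    y_origin: float
    spacing: float

    @property
    def n_x(self) -> int:
        return self.labels.shape[1]

    @property
    def n_y(self) -> int:
        return self.labels.shape[0]

    @property
    def x_centers(self) -> np.ndarray:
        return self.x_origin + (np.arange(self.n_x) + 0.5) * self.spacing

    @property
    def y_centers(self) -> np.ndarray:
        return self.y_origin + (np.arange(self.n_y) + 0.5) * self.spacing

    def zone_counts(self) -> np.ndarray:
        """Grid-point counts per zone, ordered by :class:`ZoneLabel`."""
        return np.bincount(self.labels.ravel(), minlength=N_ZONES)


def _axis_size(low: float, high: float, spacing: float, name: str) -> int:
    n = int(round((high - low) / spacing))
    if n <= 0:
        raise ValueError(f"jaw rectangle has zero {name}-extent")
    return n


# strip outcome when exactly one of the two rows is open-type: indexed by
# the covered row's state (TIP -> NEGLECTED, BODY -> EXPOSED)
_COVERED_TO_STRIP = {
    int(CoverageState.TIP): int(ZoneLabel.NEGLECTED),
    int(CoverageState.BODY): int(ZoneLabel.EXPOSED),
}


def _combine_strip(own: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Tongue-and-groove strip labels from the two adjacent rows' states.

    Both rows open-type -> the own row's open label (OPEN or CALIBRATION);
    both covered -> PAIRED; one open + other BODY -> EXPOSED; one open +
    other TIP -> NEGLECTED.
    """
    own_open = own <= CoverageState.OPEN_ONLY_AFTER_CAL
    other_open = other <= CoverageState.OPEN_ONLY_AFTER_CAL
    covered = np.where(own_open, other, own)  # the covered row's state
    out = np.where(
        own_open & other_open,
        own,  # OPEN_NOW -> OPEN, OPEN_ONLY_AFTER_CAL -> CALIBRATION
        np.where(
            ~own_open & ~other_open,
            int(ZoneLabel.PAIRED),
            np.where(
                covered == CoverageState.TIP,
                int(ZoneLabel.NEGLECTED),
                int(ZoneLabel.EXPOSED),
            ),
        ),
    )
    return out.astype(np.int8)


def classify_control_point(
    cp: ControlPoint,
    geometry: MLCGeometry,
    params: BeamModelParameters,
    spacing: float = 0.01,
) -> ZoneGrid:
    """Classify every grid sample of a control point into the seven zones.

    The grid spans the jaw rectangle with cell-center sampling at
    ``spacing`` cm (default 0.01 cm).  Preliminary tongue-and-groove
    strips of half-width ``tg_width`` straddle every interior leaf
    boundary; strip points are labelled from the coverage states of both
    adjacent leaf rows, all other points from their own row's state.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    cp.validate()
    n_x = _axis_size(cp.jaw_x_low, cp.jaw_x_high, spacing, "x")
    n_y = _axis_size(cp.jaw_y_low, cp.jaw_y_high, spacing, "y")
    x = cp.jaw_x_low + (np.arange(n_x) + 0.5) * spacing
    y = cp.jaw_y_low + (np.arange(n_y) + 0.5) * spacing

    bnd = geometry.leaf_boundaries
    if y[0] < bnd[0] or y[-1] >= bnd[-1]:
        raise ValueError("jaw y-range extends beyond the MLC leaf boundaries")

    states = _row_states(cp.bank_a, cp.bank_b, x, params)

    # own leaf row of each y sample (rows are half-open [b_j, b_{j+1}))
    row = np.searchsorted(bnd, y, side="right") - 1

    labels = states[row].copy()  # CoverageState values coincide with the
    # first four ZoneLabel values for non-strip points

    tg = params.tg_width
    if tg > 0:
        d_lo = y - bnd[row]  # distance to the row's lower boundary
        d_hi = bnd[row + 1] - y
        in_lower = (d_lo < tg) & (row > 0)  # strip of the boundary below
        in_upper = (d_hi < tg) & (row < geometry.n_pairs - 1)
        strip = in_lower | in_upper
        if np.any(strip):
            other = np.where(in_lower, row - 1, row + 1)
            labels[strip] = _combine_strip(states[row[strip]], states[other[strip]])

    return ZoneGrid(
        labels=labels,
        x_origin=cp.jaw_x_low,
        y_origin=cp.jaw_y_low,
        spacing=spacing,
    )


def zone_transmission_map(
    grid: ZoneGrid, params: BeamModelParameters
) -> np.ndarray:
    """Pointwise transmission fractions for a classified grid.

    OPEN, CALIBRATION and NEGLECTED transmit 1; TIP and EXPOSED
    ``sqrt(T)``; BODY and PAIRED ``T``.
    """
    t = params.transmission
    rt = float(np.sqrt(t))
    lut = np.array([1.0, 1.0, rt, t, t, rt, 1.0])
    return lut[grid.labels]
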