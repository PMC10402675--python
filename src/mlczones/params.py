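"""Beam-model parameters and multileaf-collimator geometry.

The transmission model treated here is the RayStation-style zero-height MLC
plane: every control point is reduced to a 2D map in the isocenter plane
(100 cm from the source) whose extent is bounded by the jaws.  Six scalar
parameters describe the model: the three coefficients of the leaf-position
calibration polynomial, the rounded-tip zone width, the leaf-body
transmission ``T`` and the tongue-and-groove strip width.
"""
from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Mapping

import numpy as np

__all__ = ["BeamModelParameters", "MLCGeometry", "DEFAULT_PARAMETERS"]


@dataclass(frozen=True)
class BeamModelParameters:
    """Parameters of a TPS MLC transmission-model instance.

    Parameters
    ----------
    offset, gain, curvature
        Coefficients of the leaf-position calibration polynomial
        ``shift(p) = offset + gain * p + curvature * p**2`` with the tip
        position ``p`` in cm (units cm, dimensionless, cm^-1).  A positive
        shift retracts the leaf, i.e. enlarges the effective aperture.
    tip_width
        Extent of the rounded leaf-tip zone along the leaf-travel axis, cm.
    transmission
        Leaf-body transmission fraction ``T`` (a fraction, not percent).
        Tip-type zones transmit ``sqrt(T)``.
    tg_width
        Tongue-and-groove width parameter, cm.  The preliminary strip
        centred on each interior leaf boundary is twice this wide.

    Defaults are a clinically optimised flattened 6 MV TrueBeam /
    Millennium 120 model: offset 0.026 cm, gain 0, curvature 0 cm^-1,
    tip width 0.36 cm, transmission 1.5 %, tongue-and-groove width 0.04 cm.
    """

    offset: float = 0.026
    gain: float = 0.0
    curvature: float = 0.0
    tip_width: float = 0.36
    transmission: float = 0.015
    tg_width: float = 0.04

    def __post_init__(self) -> None:
        if not (0.0 < self.transmission < 1.0):
            raise ValueError(
                f"transmission must lie in (0, 1), got {self.transmission}"
            )
        if self.tip_width <= 0.0:
            raise ValueError(f"tip_width must be > 0, got {self.tip_width}")
        if self.tg_width < 0.0:
            raise ValueError(f"tg_width must be >= 0, got {self.tg_width}")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "BeamModelParameters":
        """Build from a dict, ignoring unknown keys (e.g. a JSON config)."""
        known = {f.name for f in fields(cls)}
        return cls(**{k: float(v) for k, v in mapping.items() if k in known})

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: The default clinical beam-model instance.
DEFAULT_PARAMETERS = BeamModelParameters()


@dataclass(frozen=True, eq=False)
class MLCGeometry:
    """Leaf-pair layout perpendicular to leaf travel.

    ``leaf_boundaries`` holds the ``n_pairs + 1`` ordered edge positions of
    the leaf rows (cm at the isocenter plane, y axis).  Leaves travel along
    x; bank A occupies ``x <= tip`` and bank B ``x >= tip``.
    """

    leaf_boundaries: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.leaf_boundaries, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("leaf_boundaries must be a 1D array of >= 2 edges")
        if not np.all(np.diff(b) > 0):
            raise ValueError("leaf_boundaries must be strictly increasing")
        object.__setattr__(self, "leaf_boundaries", b)

    @property
    def n_pairs(self) -> int:
        return self.leaf_boundaries.size - 1

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.leaf_boundaries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MLCGeometry):
            return NotImplemented
        return (
            self.leaf_boundaries.shape == other.leaf_boundaries.shape
            and bool(np.allclose(self.leaf_boundaries, other.leaf_boundaries))
        )

    def __hash__(self) -> int:  # frozen dataclass with eq=False needs none, keep usable
        return hash(self.leaf_boundaries.tobytes())

    @classmethod
    def millennium120(cls) -> "MLCGeometry":
        """Standard 120-leaf Millennium MLC: 60 pairs spanning -20..+20 cm.

        10 outer 1.0 cm pairs, 40 central 0.5 cm pairs, 10 outer 1.0 cm
        pairs.
        """
        edges = np.concatenate(
            [
                np.arange(-20.0, -10.0, 1.0),
                np.arange(-10.0, 10.0, 0.5),
                np.arange(10.0, 20.0 + 0.5, 1.0),
            ]
        )
        return cls(edges)
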