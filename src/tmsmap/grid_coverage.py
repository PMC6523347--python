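"""Coverage of gridless representations by candidate square grids.

A square grid centered at the hotspot is guaranteed (under any rotation)
to cover the disk inscribed in it, so the covered fraction of a point-cloud
representation is estimated conservatively as the fraction of its
suprathreshold points within half the grid side of the hotspot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .map_model import PointMap

__all__ = [
    "DEFAULT_GRID_SIDES_MM",
    "CoverageCurve",
    "coverage_fraction",
    "coverage_curve",
    "mean_coverage",
]

#: Candidate grid side lengths (mm) evaluated by default.
DEFAULT_GRID_SIDES_MM = (38.0, 46.0, 53.0, 61.0, 69.0)


@dataclass
class CoverageCurve:
    """Fraction of maps with at least X percent of their points covered."""

    grid_side_mm: float
    x_percent: np.ndarray
    fraction_of_maps: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "grid_side_mm": self.grid_side_mm,
                "x_percent": self.x_percent,
                "fraction_of_maps": self.fraction_of_maps,
            }
        )


def coverage_fraction(
    point_map: PointMap, grid_side_mm: float, threshold_uV: float = 50.0
) -> float:
    """Fraction of suprathreshold points within grid_side/2 of the hotspot."""
    supra = ~point_map.censored & (point_map.amplitude_uV >= threshold_uV)
    if not supra.any():
        raise ValueError("point map has no suprathreshold points")
    hotspot = point_map.hotspot_index()
    dx = point_map.x_mm[supra] - point_map.x_mm[hotspot]
    dy = point_map.y_mm[supra] - point_map.y_mm[hotspot]
    within = np.hypot(dx, dy) <= grid_side_mm / 2.0
    return float(within.mean())


def coverage_curve(
    point_maps: Sequence[PointMap],
    grid_side_mm: float,
    x_grid_percent: Sequence[float] | None = None,
    threshold_uV: float = 50.0,
) -> CoverageCurve:
    """For each X, the fraction of maps covered to at least X percent."""
    if len(point_maps) == 0:
        raise ValueError("need at least one point map")
    if x_grid_percent is None:
        x_grid_percent = np.arange(0.0, 101.0)
    x = np.asarray(x_grid_percent, dtype=float)
    fractions = np.array(
        [coverage_fraction(pm, grid_side_mm, threshold_uV) for pm in point_maps]
    )
    curve = np.array([(fractions >= xi / 100.0).mean() for xi in x])
    return CoverageCurve(grid_side_mm=grid_side_mm, x_percent=x, fraction_of_maps=curve)


def mean_coverage(
    point_maps: Sequence[PointMap],
    grid_sides_mm: Sequence[float] = DEFAULT_GRID_SIDES_MM,
    threshold_uV: float = 50.0,
) -> pd.DataFrame:
    """Mean covered fraction per grid size, with the implied coverage bias.

    The bias column is ``-(1 - mean coverage)`` expressed in percent: the
    systematic underestimation of the representation extent caused by
    incomplete coverage.
    """
    rows = []
    for side in grid_sides_mm:
        fractions = [coverage_fraction(pm, side, threshold_uV) for pm in point_maps]
        mean_frac = float(np.mean(fractions))
        rows.append(
            {
                "grid_side_mm": side,
                "mean_coverage": mean_frac,
                "mean_bias_percent": -(1.0 - mean_frac) * 100.0,
                "n_maps": len(fractions),
            }
        )
    return pd.DataFrame.from_records(rows)
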