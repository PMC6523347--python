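"""The eight muscle-representation parameters of a grid map.

Three thresholded areas, two weighted areas, and three centers of gravity
(COGs).  Areas are in mm² (mm²·µV for the amplitude-weighted area); COGs
are 2D points in mm.  All parameters are functions of per-cell summary
statistics (mean, max, suprathreshold fraction), so they are invariant to
the order of samples within a cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .map_model import MapValidationError, TMSMap, cell_summaries

__all__ = [
    "ParameterSpec",
    "ParameterValue",
    "UndefinedParameterError",
    "AREA_VARIANTS",
    "WEIGHTED_AREA_VARIANTS",
    "COG_WEIGHTINGS",
    "default_parameter_specs",
    "representation_area",
    "weighted_area",
    "center_of_gravity",
    "compute_parameter",
]

AREA_VARIANTS = ("mean_above", "any_supra", "majority_supra")
WEIGHTED_AREA_VARIANTS = ("amplitude", "probability")
COG_WEIGHTINGS = ("mean_amplitude", "max_amplitude", "probability")

_VALID_VARIANTS = {
    "area": AREA_VARIANTS,
    "weighted_area": WEIGHTED_AREA_VARIANTS,
    "cog": COG_WEIGHTINGS,
}


class UndefinedParameterError(ValueError):
    """A parameter is undefined on the given map (e.g. all-censored COG)."""


@dataclass(frozen=True)
class ParameterSpec:
    """Which representation parameter to compute and at which threshold."""

    family: str
    variant: str
    threshold_uV: float = 50.0

    def __post_init__(self) -> None:
        if self.family not in _VALID_VARIANTS:
            raise ValueError(f"unknown parameter family {self.family!r}")
        if self.variant not in _VALID_VARIANTS[self.family]:
            raise ValueError(
                f"unknown variant {self.variant!r} for family {self.family!r}"
            )
        if not self.threshold_uV > 0:
            raise ValueError("threshold_uV must be positive")

    @property
    def name(self) -> str:
        return f"{self.family}_{self.variant}"

    @property
    def is_cog(self) -> bool:
        return self.family == "cog"

    @property
    def units(self) -> str:
        if self.family == "cog":
            return "mm"
        if self.family == "weighted_area" and self.variant == "amplitude":
            return "mm2.uV"
        return "mm2"


@dataclass(frozen=True)
class ParameterValue:
    """A computed parameter: scalar for areas, 2D point (mm) for COGs."""

    value: Union[float, np.ndarray]
    spec: ParameterSpec


def default_parameter_specs(threshold_uV: float = 50.0) -> list[ParameterSpec]:
    """The canonical list of all eight parameters."""
    specs = []
    for family, variants in _VALID_VARIANTS.items():
        for variant in variants:
            specs.append(ParameterSpec(family, variant, threshold_uV))
    return specs


# ---------------------------------------------------------------------------
# Vectorised kernels on per-cell statistic arrays.  Shapes: (..., n_cells);
# the leading axes index bootstrap replicates.  These are shared between the
# direct map-level API below and the bootstrap engine.
# ---------------------------------------------------------------------------

def area_from_stats(
    variant: str,
    mean_uV: np.ndarray,
    max_uV: np.ndarray,
    n_supra: np.ndarray,
    n: np.ndarray,
    cell_area: float,
    threshold: float,
) -> np.ndarray:
    if variant == "mean_above":
        qualifies = mean_uV >= threshold
    elif variant == "any_supra":
        qualifies = n_supra >= 1
    elif variant == "majority_supra":
        qualifies = n_supra > n / 2.0
    else:
        raise ValueError(f"unknown area variant {variant!r}")
    return cell_area * qualifies.sum(axis=-1)


def weighted_area_from_stats(
    variant: str,
    mean_uV: np.ndarray,
    p_supra: np.ndarray,
    cell_area: float,
) -> np.ndarray:
    if variant == "amplitude":
        return cell_area * mean_uV.sum(axis=-1)
    if variant == "probability":
        return cell_area * p_supra.sum(axis=-1)
    raise ValueError(f"unknown weighted-area variant {variant!r}")


def cog_from_stats(
    weighting: str,
    mean_uV: np.ndarray,
    max_uV: np.ndarray,
    p_supra: np.ndarray,
    centers: np.ndarray,
) -> np.ndarray:
    """Weighted centroid of the cell centers; NaN where total weight is 0.

    ``centers`` has shape (n_cells, 2); the result has shape (..., 2).
    """
    if weighting == "mean_amplitude":
        weights = mean_uV
    elif weighting == "max_amplitude":
        weights = max_uV
    elif weighting == "probability":
        weights = p_supra
    else:
        raise ValueError(f"unknown COG weighting {weighting!r}")
    totals = weights.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cog = (weights @ centers) / totals[..., None]
    return np.where(totals[..., None] > 0, cog, np.nan)


def _map_stats(tms_map: TMSMap, threshold: float):
    summary = cell_summaries(tms_map, threshold)
    return (
        summary["mean_uV"].to_numpy(),
        summary["max_uV"].to_numpy(),
        summary["n_supra"].to_numpy(),
        summary["n"].to_numpy(),
        summary["p_supra"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# Map-level API
# ---------------------------------------------------------------------------

def representation_area(
    tms_map: TMSMap, variant: str, threshold: float = 50.0
) -> ParameterValue:
    """Thresholded representation area (mm²) = cell area x qualifying cells.

    Variants: ``mean_above`` (cell mean >= threshold), ``any_supra`` (at
    least one suprathreshold response), ``majority_supra`` (strictly more
    than half of the cell's responses suprathreshold).
    """
    spec = ParameterSpec("area", variant, threshold)
    mean_uV, max_uV, n_supra, n, _ = _map_stats(tms_map, threshold)
    value = area_from_stats(
        variant, mean_uV, max_uV, n_supra, n, tms_map.grid.cell_area_mm2, threshold
    )
    return ParameterValue(float(value), spec)


def weighted_area(
    tms_map: TMSMap, variant: str, threshold: float = 50.0
) -> ParameterValue:
    """Sum over all cells of cell area times the cell weight.

    ``amplitude``: weight = mean amplitude (µV), yielding mm²·µV (also
    known as map volume).  ``probability``: weight = suprathreshold
    fraction, yielding mm².
    """
    spec = ParameterSpec("weighted_area", variant, threshold)
    mean_uV, _, _, _, p_supra = _map_stats(tms_map, threshold)
    value = weighted_area_from_stats(variant, mean_uV, p_supra, tms_map.grid.cell_area_mm2)
    return ParameterValue(float(value), spec)


def center_of_gravity(
    tms_map: TMSMap, weighting: str, threshold: float = 50.0
) -> ParameterValue:
    """Weighted centroid (mm) of cell centers.

    Weights per cell are the mean amplitude, the max amplitude, or the
    suprathreshold probability.  Undefined (raises) when all weights are 0.
    """
    spec = ParameterSpec("cog", weighting, threshold)
    mean_uV, max_uV, _, _, p_supra = _map_stats(tms_map, threshold)
    centers = tms_map.grid.cell_centers()
    value = cog_from_stats(weighting, mean_uV, max_uV, p_supra, centers)
    if np.any(np.isnan(value)):
        raise UndefinedParameterError(
            f"COG ({weighting}) undefined: all cell weights are zero"
        )
    return ParameterValue(np.asarray(value, dtype=float), spec)


def compute_parameter(tms_map: TMSMap, spec: ParameterSpec) -> ParameterValue:
    """Dispatch a :class:`ParameterSpec` to the matching computation."""
    if spec.family == "area":
        return representation_area(tms_map, spec.variant, spec.threshold_uV)
    if spec.family == "weighted_area":
        return weighted_area(tms_map, spec.variant, spec.threshold_uV)
    return center_of_gravity(tms_map, spec.variant, spec.threshold_uV)
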