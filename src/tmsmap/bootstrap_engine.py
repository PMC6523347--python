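"""Bootstrap simulation of mapping with k stimuli per cell.

Resampling each cell's amplitudes with replacement simulates the map that
would have been obtained with a different number of stimuli per cell
(including more than were actually delivered).  The resulting replicate
parameter distributions yield the normalized bias, the within-session
coefficient of variation, the between-session variability index, and the
COG positional error — all as functions of k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .map_model import MEPSample, SessionSet, TMSMap
from .map_parameters import (
    ParameterSpec,
    UndefinedParameterError,
    area_from_stats,
    cog_from_stats,
    compute_parameter,
    weighted_area_from_stats,
)

__all__ = [
    "BootstrapSample",
    "AccuracyProfile",
    "resample_map",
    "bootstrap_distribution",
    "normalized_bias",
    "coefficient_of_variation",
    "variability_index",
    "between_session_variability",
    "cog_error",
    "accuracy_profile",
]

logger = logging.getLogger(__name__)


@dataclass
class BootstrapSample:
    """B replicate parameter values at k stimuli per cell.

    ``values`` has shape (B,) for scalar parameters and (B, 2) for COGs;
    COG replicates with zero total weight are NaN and counted in
    ``n_undefined``.
    """

    values: np.ndarray
    k: int
    B: int
    spec: ParameterSpec
    source: tuple[str, str] = ("", "")
    n_undefined: int = 0

    def defined_values(self) -> np.ndarray:
        if self.spec.is_cog:
            return self.values[~np.isnan(self.values).any(axis=-1)]
        return self.values[~np.isnan(self.values)]


def resample_map(tms_map: TMSMap, k: int, rng: np.random.Generator) -> TMSMap:
    """Draw k samples per cell, i.i.d. uniformly with replacement.

    The source map is left unchanged; k may exceed the observed per-cell
    sample count.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    tms_map.require_complete()
    cells: dict[tuple[int, int], list[MEPSample]] = {}
    for key in tms_map.grid.cell_keys():
        samples = tms_map.cells[key]
        idx = rng.integers(0, len(samples), size=k)
        cells[key] = [samples[i] for i in idx]
    return TMSMap(
        grid=tms_map.grid,
        cells=cells,
        subject_id=tms_map.subject_id,
        session_id=tms_map.session_id,
        intensity_meta=tms_map.intensity_meta,
    )


def _resampled_cell_stats(
    tms_map: TMSMap, k: int, B: int, rng: np.random.Generator, threshold: float
):
    """Per-replicate cell statistics for B bootstrap maps at k stimuli/cell.

    Returns arrays of shape (B, n_cells): mean, max, n_supra, p_supra.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if B < 1:
        raise ValueError("B must be >= 1")
    tms_map.require_complete()
    stacked = tms_map.stacked_amplitudes()
    if stacked is not None:
        n_cells, n = stacked.shape
        idx = rng.integers(0, n, size=(B, n_cells, k))
        draws = np.take_along_axis(stacked[None, :, :], idx, axis=2)
    else:
        # ragged per-cell counts: draw cell by cell
        arrays = tms_map.amplitude_arrays()
        n_cells = len(arrays)
        draws = np.empty((B, n_cells, k))
        for j, amps in enumerate(arrays):
            idx = rng.integers(0, len(amps), size=(B, k))
            draws[:, j, :] = amps[idx]
    mean_uV = draws.mean(axis=2)
    max_uV = draws.max(axis=2)
    n_supra = (draws >= threshold).sum(axis=2)
    return mean_uV, max_uV, n_supra, n_supra / k


def _values_from_stats(
    spec: ParameterSpec,
    mean_uV: np.ndarray,
    max_uV: np.ndarray,
    n_supra: np.ndarray,
    p_supra: np.ndarray,
    k: int,
    tms_map: TMSMap,
) -> np.ndarray:
    cell_area = tms_map.grid.cell_area_mm2
    if spec.family == "area":
        n = np.full_like(n_supra, k)
        return area_from_stats(
            spec.variant, mean_uV, max_uV, n_supra, n, cell_area, spec.threshold_uV
        )
    if spec.family == "weighted_area":
        return weighted_area_from_stats(spec.variant, mean_uV, p_supra, cell_area)
    return cog_from_stats(
        spec.variant, mean_uV, max_uV, p_supra, tms_map.grid.cell_centers()
    )


def bootstrap_distribution(
    tms_map: TMSMap,
    spec: ParameterSpec,
    k: int,
    B: int,
    rng: np.random.Generator,
) -> BootstrapSample:
    """Parameter values of B bootstrap maps resampled at k stimuli per cell."""
    stats = _resampled_cell_stats(tms_map, k, B, rng, spec.threshold_uV)
    values = _values_from_stats(spec, *stats[:3], stats[3], k, tms_map)
    if spec.is_cog:
        n_undefined = int(np.isnan(values).any(axis=-1).sum())
    else:
        n_undefined = int(np.isnan(values).sum())
    if n_undefined:
        logger.info(
            "bootstrap_distribution: %d of %d replicates undefined for %s",
            n_undefined, B, spec.name,
        )
    return BootstrapSample(
        values=values,
        k=k,
        B=B,
        spec=spec,
        source=(tms_map.subject_id, tms_map.session_id),
        n_undefined=n_undefined,
    )


def normalized_bias(boot_sample: BootstrapSample, p0: float) -> float:
    """Relative bias (mean of replicates minus the observed value) / observed."""
    if p0 == 0:
        raise UndefinedParameterError("normalized bias undefined for P0 = 0")
    return float((np.mean(boot_sample.defined_values()) - p0) / p0)


def coefficient_of_variation(boot_sample: BootstrapSample) -> float:
    """Sample standard deviation over mean of the replicate values."""
    values = boot_sample.defined_values()
    mean = float(np.mean(values))
    if mean == 0:
        raise UndefinedParameterError("CV undefined: replicate mean is 0")
    ddof = 1 if len(values) > 1 else 0
    return float(np.std(values, ddof=ddof) / mean)


def variability_index(values: Sequence[float]) -> float:
    """(max - min) / (max + min) of a set of parameter values; 0 if all zero."""
    arr = np.asarray(values, dtype=float)
    hi, lo = float(arr.max()), float(arr.min())
    if hi + lo == 0:
        return 0.0
    return (hi - lo) / (hi + lo)


def between_session_variability(
    maps_3: Sequence[TMSMap],
    spec: ParameterSpec,
    k: int,
    B: int,
    rng: np.random.Generator,
) -> float:
    """Mean variability index over B bootstrap triples (one map per session).

    Triples whose parameter values are all zero contribute 0 (no observable
    change); their count is logged.
    """
    if len(maps_3) != 3:
        raise ValueError("between_session_variability requires exactly 3 maps")
    if spec.is_cog:
        raise ValueError("variability index is defined for scalar parameters only")
    per_session = []
    for tms_map in maps_3:
        stats = _resampled_cell_stats(tms_map, k, B, rng, spec.threshold_uV)
        per_session.append(_values_from_stats(spec, *stats[:3], stats[3], k, tms_map))
    values = np.vstack(per_session)  # (3, B)
    hi = values.max(axis=0)
    lo = values.min(axis=0)
    total = hi + lo
    degenerate = total == 0
    if degenerate.any():
        logger.info(
            "between_session_variability: %d of %d degenerate triples", int(degenerate.sum()), B
        )
    v = np.where(degenerate, 0.0, (hi - lo) / np.where(degenerate, 1.0, total))
    return float(np.mean(v))


def cog_error(
    tms_map: TMSMap,
    weighting: str,
    k: int,
    B: int,
    rng: np.random.Generator,
    threshold: float = 50.0,
) -> float:
    """Mean Euclidean distance (mm) between the map's COG and bootstrap COGs.

    Replicates with undefined COG are skipped (count logged); errors if the
    source map's COG is itself undefined.
    """
    spec = ParameterSpec("cog", weighting, threshold)
    reference = compute_parameter(tms_map, spec).value
    boot = bootstrap_distribution(tms_map, spec, k, B, rng)
    cogs = boot.defined_values()
    if len(cogs) == 0:
        raise UndefinedParameterError("all bootstrap COGs undefined")
    distances = np.linalg.norm(cogs - reference[None, :], axis=1)
    return float(np.mean(distances))


@dataclass
class AccuracyProfile:
    """Per-map accuracy measures and their medians across maps.

    ``per_map`` has one row per (subject, session, parameter, k) with bias,
    cv and cog_error_mm; ``per_subject_v`` one row per (subject, parameter,
    k) with the between-session variability index; ``medians`` aggregates
    both across maps/subjects.
    """

    per_map: pd.DataFrame
    per_subject_v: pd.DataFrame
    medians: pd.DataFrame
    B: int = 0
    n_excluded: int = 0


def _spawn_rng(seed_seq: np.random.SeedSequence, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed_seq.entropy, spawn_key=tuple(key))
    )


def accuracy_profile(
    session_set: SessionSet,
    specs: Sequence[ParameterSpec],
    k_range: Sequence[int],
    B: int,
    rng: np.random.Generator | int,
) -> AccuracyProfile:
    """Bias, CV, V and COG error for every map, spec and k, plus medians.

    Maps whose observed parameter is zero are excluded from bias/CV medians
    (the normalized bias is undefined there); exclusions are counted.  The
    variability index V is computed per subject from the subjects having
    exactly three sessions.  One independent RNG stream is derived per
    (map, spec, k) so results do not depend on iteration order.
    """
    if len(session_set) == 0:
        raise ValueError("empty session set")
    if isinstance(rng, (int, np.integer)):
        seed_seq = np.random.SeedSequence(int(rng))
    else:
        seed_seq = np.random.SeedSequence(rng.integers(0, 2**63 - 1))
    keys = sorted(session_set.keys())
    records = []
    n_excluded = 0
    for i_map, key in enumerate(keys):
        tms_map = session_set[key]
        for i_spec, spec in enumerate(specs):
            if spec.is_cog:
                try:
                    compute_parameter(tms_map, spec)
                except UndefinedParameterError:
                    n_excluded += 1
                    continue
                for k in k_range:
                    stream = _spawn_rng(seed_seq, i_map, i_spec, k)
                    err = cog_error(
                        tms_map, spec.variant, k, B, stream, spec.threshold_uV
                    )
                    records.append(
                        {
                            "subject": key[0],
                            "session": key[1],
                            "parameter": spec.name,
                            "k": k,
                            "bias": np.nan,
                            "cv": np.nan,
                            "cog_error_mm": err,
                        }
                    )
                continue
            p0 = float(compute_parameter(tms_map, spec).value)
            if p0 == 0:
                n_excluded += 1
                logger.info(
                    "accuracy_profile: excluding %s for map %s (P0 = 0)", spec.name, key
                )
                continue
            for k in k_range:
                stream = _spawn_rng(seed_seq, i_map, i_spec, k)
                boot = bootstrap_distribution(tms_map, spec, k, B, stream)
                records.append(
                    {
                        "subject": key[0],
                        "session": key[1],
                        "parameter": spec.name,
                        "k": k,
                        "bias": normalized_bias(boot, p0),
                        "cv": coefficient_of_variation(boot),
                        "cog_error_mm": np.nan,
                    }
                )
    per_map = pd.DataFrame.from_records(
        records,
        columns=["subject", "session", "parameter", "k", "bias", "cv", "cog_error_mm"],
    )

    v_records = []
    for i_subject, subject in enumerate(sorted(session_set.subjects())):
        maps = session_set.maps_for_subject(subject)
        if len(maps) != 3:
            continue
        for i_spec, spec in enumerate(specs):
            if spec.is_cog:
                continue
            for k in k_range:
                stream = _spawn_rng(seed_seq, 10_000 + i_subject, i_spec, k)
                v = between_session_variability(maps, spec, k, B, stream)
                v_records.append(
                    {"subject": subject, "parameter": spec.name, "k": k, "v": v}
                )
    per_subject_v = pd.DataFrame.from_records(
        v_records, columns=["subject", "parameter", "k", "v"]
    )

    def _median(series: pd.Series) -> float:
        values = series.dropna()
        return float(values.median()) if len(values) else np.nan

    med_rows = []
    if not per_map.empty:
        grouped = per_map.groupby(["parameter", "k"], sort=True)
        for (parameter, k), group in grouped:
            med_rows.append(
                {
                    "parameter": parameter,
                    "k": k,
                    "bias": _median(group["bias"]),
                    "cv": _median(group["cv"]),
                    "cog_error_mm": _median(group["cog_error_mm"]),
                    "v": np.nan,
                    "n_maps": len(group),
                }
            )
    if not per_subject_v.empty:
        for (parameter, k), group in per_subject_v.groupby(["parameter", "k"], sort=True):
            med_rows.append(
                {
                    "parameter": parameter,
                    "k": k,
                    "bias": np.nan,
                    "cv": np.nan,
                    "cog_error_mm": np.nan,
                    "v": group["v"].median(),
                    "n_maps": len(group),
                }
            )
    medians = pd.DataFrame.from_records(
        med_rows, columns=["parameter", "k", "bias", "cv", "cog_error_mm", "v", "n_maps"]
    )
    return AccuracyProfile(
        per_map=per_map,
        per_subject_v=per_subject_v,
        medians=medians,
        B=B,
        n_excluded=n_excluded,
    )
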