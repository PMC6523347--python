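"""Data model, validation and tabular I/O for grid-based motor maps.

A :class:`TMSMap` holds, for every cell of a rectangular stimulation grid,
an ordered list of MEP amplitude samples.  Responses below the detection
threshold are left-censored: their true amplitude is unknown and is stored
as 0 by convention.  Gridless mapping sessions are represented as
:class:`PointMap` point clouds.  Multi-session collections are grouped in a
:class:`SessionSet` keyed by ``(subject_id, session_id)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GridSpec",
    "MEPSample",
    "TMSMap",
    "PointMap",
    "SessionSet",
    "AnalysisConfig",
    "MapFormatError",
    "MapValidationError",
    "cell_summaries",
    "read_map_table",
    "write_map_table",
    "read_point_table",
    "write_point_table",
]

#: Columns of the grid-map table format.
MAP_COLUMNS = (
    "subject",
    "session",
    "row",
    "col",
    "x_mm",
    "y_mm",
    "stim_index",
    "amplitude_uV",
    "censored",
)

#: Columns of the point-cloud table format.
POINT_COLUMNS = ("subject", "muscle", "x_mm", "y_mm", "amplitude_uV", "censored")


class MapFormatError(ValueError):
    """A table does not conform to the expected file format."""


class MapValidationError(ValueError):
    """Table content violates a data-model invariant."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a rectangular stimulation grid.

    Cell indices are 0-based ``(row, col)``; x increases with ``col`` and y
    with ``row``.  ``origin_xy_mm`` is the center of cell (0, 0).
    ``peeling_depth_mm`` is informational metadata only.
    """

    n_rows: int = 7
    n_cols: int = 7
    cell_side_mm: float = 7.63
    origin_xy_mm: tuple[float, float] = (0.0, 0.0)
    peeling_depth_mm: float | None = None

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.cell_side_mm > 0:
            raise ValueError("cell_side_mm must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_mm2(self) -> float:
        return self.cell_side_mm**2

    @property
    def side_lengths_mm(self) -> tuple[float, float]:
        """Total (width, height) of the grid in mm."""
        return (self.n_cols * self.cell_side_mm, self.n_rows * self.cell_side_mm)

    def cell_keys(self) -> list[tuple[int, int]]:
        """All ``(row, col)`` indices in row-major order."""
        return [(r, c) for r in range(self.n_rows) for c in range(self.n_cols)]

    def cell_center(self, row: int, col: int) -> np.ndarray:
        """Coordinates (mm) of the center of cell ``(row, col)``."""
        x0, y0 = self.origin_xy_mm
        return np.array([x0 + col * self.cell_side_mm, y0 + row * self.cell_side_mm])

    def cell_centers(self) -> np.ndarray:
        """``(n_cells, 2)`` array of cell centers in row-major order."""
        rows, cols = np.divmod(np.arange(self.n_cells), self.n_cols)
        x0, y0 = self.origin_xy_mm
        return np.column_stack(
            [x0 + cols * self.cell_side_mm, y0 + rows * self.cell_side_mm]
        )


class MEPSample(NamedTuple):
    """One MEP amplitude observation.

    ``censored`` is true iff the response was below the detection threshold;
    the true amplitude is then unknown in ``[0, threshold)`` and
    ``amplitude_uV`` is 0 by convention.
    """

    amplitude_uV: float
    censored: bool = False


@dataclass
class TMSMap:
    """A single-session grid map: ordered per-cell MEP samples.

    ``cells`` maps ``(row, col)`` to the list of samples in stimulation
    order.  A *complete* map has at least one sample in every grid cell.
    """

    grid: GridSpec
    cells: dict[tuple[int, int], list[MEPSample]]
    subject_id: str = "s1"
    session_id: str = "d1"
    intensity_meta: str = ""

    @property
    def n_samples(self) -> int:
        return sum(len(v) for v in self.cells.values())

    def is_complete(self) -> bool:
        return all(len(self.cells.get(key, ())) >= 1 for key in self.grid.cell_keys())

    def require_complete(self) -> None:
        for key in self.grid.cell_keys():
            if len(self.cells.get(key, ())) == 0:
                raise MapValidationError(f"cell {key} has no samples")

    def cell_amplitudes(self, row: int, col: int) -> np.ndarray:
        """Amplitudes of cell ``(row, col)``, censored samples as 0."""
        return np.array(
            [0.0 if s.censored else s.amplitude_uV for s in self.cells[(row, col)]]
        )

    def amplitude_arrays(self) -> list[np.ndarray]:
        """Per-cell amplitude arrays in row-major cell order (censored -> 0)."""
        return [self.cell_amplitudes(r, c) for r, c in self.grid.cell_keys()]

    def stacked_amplitudes(self) -> np.ndarray | None:
        """``(n_cells, n)`` amplitude matrix, or None if counts are ragged."""
        arrays = self.amplitude_arrays()
        n = len(arrays[0]) if arrays else 0
        if any(len(a) != n for a in arrays):
            return None
        return np.vstack(arrays) if n else None


@dataclass
class PointMap:
    """A gridless map: stimulation points with single-stimulus outcomes."""

    x_mm: np.ndarray
    y_mm: np.ndarray
    amplitude_uV: np.ndarray
    censored: np.ndarray
    subject_id: str = "s1"
    muscle: str = "APB"

    def __post_init__(self) -> None:
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        self.amplitude_uV = np.asarray(self.amplitude_uV, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        n = len(self.x_mm)
        if not (len(self.y_mm) == len(self.amplitude_uV) == len(self.censored) == n):
            raise MapValidationError("point-map arrays must have equal length")

    def __len__(self) -> int:
        return len(self.x_mm)

    def hotspot_index(self) -> int:
        """Index of the uncensored point of maximal amplitude (ties -> lowest)."""
        amps = np.where(self.censored, -np.inf, self.amplitude_uV)
        if not np.any(np.isfinite(amps)):
            raise MapValidationError("point map has no uncensored points")
        return int(np.argmax(amps))


class SessionSet:
    """Collection of :class:`TMSMap` keyed by ``(subject_id, session_id)``.

    All maps of one subject must share a single :class:`GridSpec`.
    """

    def __init__(self, maps: Iterable[TMSMap] = ()) -> None:
        self._maps: dict[tuple[str, str], TMSMap] = {}
        for m in maps:
            self.add(m)

    def add(self, tms_map: TMSMap) -> None:
        key = (tms_map.subject_id, tms_map.session_id)
        if key in self._maps:
            raise MapValidationError(f"duplicate (subject, session) key {key}")
        for other in self.maps_for_subject(tms_map.subject_id):
            if other.grid != tms_map.grid:
                raise MapValidationError(
                    f"subject {tms_map.subject_id!r} has maps with differing grids"
                )
        self._maps[key] = tms_map

    def __len__(self) -> int:
        return len(self._maps)

    def __iter__(self) -> Iterator[TMSMap]:
        return iter(self._maps.values())

    def __getitem__(self, key: tuple[str, str]) -> TMSMap:
        return self._maps[key]

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._maps

    def keys(self) -> list[tuple[str, str]]:
        return list(self._maps)

    def subjects(self) -> list[str]:
        out: list[str] = []
        for s, _ in self._maps:
            if s not in out:
                out.append(s)
        return out

    def maps_for_subject(self, subject_id: str) -> list[TMSMap]:
        """Maps of one subject, sorted by session id."""
        return sorted(
            (m for (s, _), m in self._maps.items() if s == subject_id),
            key=lambda m: m.session_id,
        )


@dataclass
class AnalysisConfig:
    """Analysis-wide configuration knobs."""

    threshold_uV: float = 50.0
    n_boot: int = 1000
    alpha: float = 0.05
    n_bins: int = 30
    seed: int = 0
    k_range: tuple[int, ...] = tuple(range(1, 11))

    def __post_init__(self) -> None:
        if not self.threshold_uV > 0:
            raise ValueError("threshold_uV must be positive")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        self.k_range = tuple(int(k) for k in self.k_range)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def cell_summaries(tms_map: TMSMap, threshold: float = 50.0) -> pd.DataFrame:
    """Per-cell summary statistics of a complete map.

    Returns a DataFrame with one row per grid cell (row-major order) and
    columns ``row, col, n, n_supra, p_supra, mean_uV, max_uV``.  Censored
    samples contribute 0 to the mean and maximum; a response counts as
    suprathreshold when it is uncensored and its amplitude is >= threshold.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    records = []
    for row, col in tms_map.grid.cell_keys():
        samples = tms_map.cells.get((row, col), [])
        n = len(samples)
        if n == 0:
            raise MapValidationError(f"cell ({row}, {col}) has no samples")
        amps = tms_map.cell_amplitudes(row, col)
        n_supra = int(np.sum(amps >= threshold))
        records.append(
            {
                "row": row,
                "col": col,
                "n": n,
                "n_supra": n_supra,
                "p_supra": n_supra / n,
                "mean_uV": float(np.mean(amps)),
                "max_uV": float(np.max(amps)),
            }
        )
    return pd.DataFrame.from_records(records)


def _normalise_censored(values: pd.Series) -> pd.Series:
    return values.astype(float).astype(int).astype(bool)


def infer_grid_spec(path: str | Path, default_cell_side_mm: float = 7.63) -> GridSpec:
    """Infer a GridSpec from a map table: extent from row/col indices,
    cell side and origin from the x/y coordinate columns when present."""
    df = pd.read_csv(path, float_precision="round_trip")
    for column in ("row", "col"):
        if column not in df.columns:
            raise MapFormatError(f"missing required column {column!r}")
    if df.empty:
        return GridSpec(cell_side_mm=default_cell_side_mm)
    n_rows = int(df["row"].max()) + 1
    n_cols = int(df["col"].max()) + 1
    cell_side = default_cell_side_mm
    origin = (0.0, 0.0)
    if "x_mm" in df.columns and "y_mm" in df.columns:
        sides = []
        if df["col"].nunique() > 1:
            sides.append(
                (df["x_mm"].max() - df["x_mm"].min()) / (df["col"].max() - df["col"].min())
            )
        if df["row"].nunique() > 1:
            sides.append(
                (df["y_mm"].max() - df["y_mm"].min()) / (df["row"].max() - df["row"].min())
            )
        if sides:
            cell_side = float(np.mean(sides))
        x0 = float(df["x_mm"].min() - df["col"].min() * cell_side)
        y0 = float(df["y_mm"].min() - df["row"].min() * cell_side)
        origin = (x0, y0)
    return GridSpec(
        n_rows=n_rows, n_cols=n_cols, cell_side_mm=cell_side, origin_xy_mm=origin
    )


def read_map_table(
    path: str | Path, grid_spec: GridSpec, threshold_uV: float = 50.0
) -> SessionSet:
    """Read a grid-map CSV table into a :class:`SessionSet`.

    Required columns: ``subject, session, row, col, stim_index,
    amplitude_uV, censored`` (``x_mm``/``y_mm`` are accepted and ignored on
    read; geometry comes from ``grid_spec``).  Samples are ordered by
    ``stim_index`` within each cell.  Uncensored amplitudes below the
    threshold are rejected.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = ("subject", "session", "row", "col", "stim_index", "amplitude_uV", "censored")
    for column in required:
        if column not in df.columns:
            raise MapFormatError(f"missing required column {column!r}")
    session_set = SessionSet()
    if df.empty:
        return session_set
    df = df.copy()
    df["censored"] = _normalise_censored(df["censored"])
    df["amplitude_uV"] = df["amplitude_uV"].fillna(0.0).astype(float)
    bad = ~df["censored"] & (df["amplitude_uV"] < threshold_uV)
    if bad.any():
        rows = df.index[bad].tolist()
        raise MapValidationError(
            f"uncensored amplitudes below threshold {threshold_uV} µV at table rows {rows}"
        )
    oob = (
        (df["row"] < 0)
        | (df["row"] >= grid_spec.n_rows)
        | (df["col"] < 0)
        | (df["col"] >= grid_spec.n_cols)
    )
    if oob.any():
        raise MapValidationError(
            f"cell indices outside the {grid_spec.n_rows}x{grid_spec.n_cols} grid "
            f"at table rows {df.index[oob].tolist()}"
        )
    df = df.sort_values("stim_index", kind="stable")
    for (subject, session), group in df.groupby(["subject", "session"], sort=True):
        cells: dict[tuple[int, int], list[MEPSample]] = {}
        for rec in group.itertuples():
            sample = MEPSample(
                amplitude_uV=0.0 if rec.censored else float(rec.amplitude_uV),
                censored=bool(rec.censored),
            )
            cells.setdefault((int(rec.row), int(rec.col)), []).append(sample)
        session_set.add(
            TMSMap(grid=grid_spec, cells=cells, subject_id=str(subject), session_id=str(session))
        )
    return session_set


def write_map_table(session_set: SessionSet, path: str | Path) -> None:
    """Write a :class:`SessionSet` as a CSV map table (round-trip safe)."""
    records = []
    for tms_map in session_set:
        for (row, col) in sorted(tms_map.cells):
            center = tms_map.grid.cell_center(row, col)
            for stim_index, sample in enumerate(tms_map.cells[(row, col)]):
                records.append(
                    {
                        "subject": tms_map.subject_id,
                        "session": tms_map.session_id,
                        "row": row,
                        "col": col,
                        "x_mm": center[0],
                        "y_mm": center[1],
                        "stim_index": stim_index,
                        "amplitude_uV": sample.amplitude_uV,
                        "censored": int(sample.censored),
                    }
                )
    pd.DataFrame.from_records(records, columns=list(MAP_COLUMNS)).to_csv(path, index=False)


def read_point_table(path: str | Path, threshold_uV: float = 50.0) -> list[PointMap]:
    """Read gridless point-cloud maps; one PointMap per (subject, muscle)."""
    df = pd.read_csv(path, float_precision="round_trip")
    for column in POINT_COLUMNS:
        if column not in df.columns:
            raise MapFormatError(f"missing required column {column!r}")
    if df.empty:
        return []
    df = df.copy()
    df["censored"] = _normalise_censored(df["censored"])
    df["amplitude_uV"] = df["amplitude_uV"].fillna(0.0).astype(float)
    bad = ~df["censored"] & (df["amplitude_uV"] < threshold_uV)
    if bad.any():
        raise MapValidationError(
            f"uncensored amplitudes below threshold at table rows {df.index[bad].tolist()}"
        )
    out = []
    for (subject, muscle), group in df.groupby(["subject", "muscle"], sort=True):
        out.append(
            PointMap(
                x_mm=group["x_mm"].to_numpy(),
                y_mm=group["y_mm"].to_numpy(),
                amplitude_uV=np.where(group["censored"], 0.0, group["amplitude_uV"]),
                censored=group["censored"].to_numpy(),
                subject_id=str(subject),
                muscle=str(muscle),
            )
        )
    return out


def write_point_table(point_maps: Sequence[PointMap], path: str | Path) -> None:
    frames = []
    for pm in point_maps:
        frames.append(
            pd.DataFrame(
                {
                    "subject": pm.subject_id,
                    "muscle": pm.muscle,
                    "x_mm": pm.x_mm,
                    "y_mm": pm.y_mm,
                    "amplitude_uV": pm.amplitude_uV,
                    "censored": pm.censored.astype(int),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=list(POINT_COLUMNS))
    df.to_csv(path, index=False)
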