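import numpy as np
import pytest

from tmsmap.map_model import GridSpec, MEPSample, TMSMap

THRESHOLD = 50.0


def make_map(
    cell_amplitudes: dict[tuple[int, int], list[float]],
    grid: GridSpec | None = None,
    subject_id: str = "s1",
    session_id: str = "d1",
) -> TMSMap:
    """Build a TMSMap from per-cell amplitude lists; 0 means censored.

    If no grid is given, the smallest grid containing all cells is used.
    """
    if grid is None:
        n_rows = max(r for r, _ in cell_amplitudes) + 1
        n_cols = max(c for _, c in cell_amplitudes) + 1
        grid = GridSpec(n_rows=n_rows, n_cols=n_cols, cell_side_mm=1.0)
    cells = {
        key: [
            MEPSample(0.0, True) if a == 0 else MEPSample(float(a), False)
            for a in amps
        ]
        for key, amps in cell_amplitudes.items()
    }
    return TMSMap(grid=grid, cells=cells, subject_id=subject_id, session_id=session_id)


@pytest.fixture
def grid7() -> GridSpec:
    return GridSpec()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def half_supra_cell_map() -> TMSMap:
    """Single-cell map with 5 of 10 suprathreshold samples (cell area 1)."""
    return make_map({(0, 0): [100, 120, 140, 160, 180, 0, 0, 0, 0, 0]})
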