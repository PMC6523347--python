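"""Censored-data session comparisons and discrimination statistics.

Per-cell amplitude samples are left-censored at the detection threshold, so
two-sample comparisons use Gehan's generalization of the Mann-Whitney test:
a censored value is definitely smaller than any observed value, two
censored values are incomparable.  Cell-wise tests between sessions (or
between the two halves of one session) are summarized as signed
significance diagrams.  Session discrimination is quantified by histogram
overlaps of bootstrap parameter distributions and a one-way random-effects
intraclass correlation on those distributions.  Page's trend test serves
the ordered-alternative claims (accuracy improving with stimulus count).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .bootstrap_engine import bootstrap_distribution
from .map_model import MEPSample, TMSMap
from .map_parameters import ParameterSpec

__all__ = [
    "CensoredSample",
    "SignificanceDiagram",
    "SessionDiscrimination",
    "gehan_test",
    "change_diagram",
    "within_session_diagram",
    "histogram_overlap",
    "bicc",
    "page_trend_test",
    "discriminate_sessions",
]

_EXACT_LIMIT = 50_000  # max number of group assignments enumerated exactly


@dataclass
class CensoredSample:
    """Amplitudes observed at/above the threshold plus a count of censored ones."""

    observed: np.ndarray
    n_censored: int
    threshold_uV: float = 50.0

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        if self.n_censored < 0:
            raise ValueError("n_censored must be >= 0")
        if self.n() < 1:
            raise ValueError("sample must contain at least one value")
        if np.any(self.observed < self.threshold_uV):
            raise ValueError("observed values must be >= the censoring threshold")

    @classmethod
    def from_samples(
        cls, samples: Sequence[MEPSample], threshold_uV: float = 50.0
    ) -> "CensoredSample":
        observed = [s.amplitude_uV for s in samples if not s.censored]
        n_censored = sum(1 for s in samples if s.censored)
        return cls(np.asarray(observed, dtype=float), n_censored, threshold_uV)

    def n(self) -> int:
        return len(self.observed) + self.n_censored

    def encoded(self) -> np.ndarray:
        """Values encoded for Gehan scoring: censored -> common value below θ.

        With a shared censoring threshold the Gehan pair score reduces to
        sign comparison of these encoded values (censored values are all
        tied with each other and below every observed value).
        """
        return np.concatenate(
            [self.observed, np.full(self.n_censored, -1.0)]
        )


@dataclass(frozen=True)
class GehanResult:
    statistic: float
    p_value: float
    method: str
    n_permutations: int

    def __iter__(self):
        return iter((self.statistic, self.p_value))


@lru_cache(maxsize=64)
def _assignment_masks(n: int, n_a: int) -> np.ndarray:
    """Boolean (C(n, n_a), n) matrix of all group-A index assignments."""
    combos = list(itertools.combinations(range(n), n_a))
    masks = np.zeros((len(combos), n), dtype=bool)
    for i, combo in enumerate(combos):
        masks[i, list(combo)] = True
    return masks


def _pair_scores(pooled: np.ndarray) -> np.ndarray:
    """S[i, j] = +1/0/-1 Gehan score of pooled[i] vs pooled[j]."""
    return np.sign(pooled[:, None] - pooled[None, :])


def _perm_statistics(scores: np.ndarray, masks: np.ndarray) -> np.ndarray:
    # W for each assignment: sum of S[i, j] over i in A, j in B
    group_b = ~masks
    return np.einsum("pi,ij,pj->p", masks, scores, group_b)


def gehan_test(
    sample_a: CensoredSample,
    sample_b: CensoredSample,
    method: str = "auto",
    n_permutations: int = 9999,
    rng: np.random.Generator | None = None,
) -> GehanResult:
    """Two-sample rank test for left-censored data (permutation p-value).

    The statistic is ``W = sum over pairs U(a, b)`` with ``U = +1`` when the
    value from ``sample_a`` is definitely greater, ``-1`` when definitely
    smaller and 0 when indeterminate (two censored values, or tied observed
    values).  The two-sided p-value comes from the exact permutation
    distribution of W when the number of group assignments is enumerable
    (always for total n <= 12), otherwise from ``n_permutations``
    Monte-Carlo permutations with add-one correction.
    """
    if sample_a.n() < 1 or sample_b.n() < 1:
        raise ValueError("both samples must be nonempty")
    n_a, n_b = sample_a.n(), sample_b.n()
    n = n_a + n_b
    pooled = np.concatenate([sample_a.encoded(), sample_b.encoded()])
    scores = _pair_scores(pooled)
    in_a = np.zeros(n, dtype=bool)
    in_a[:n_a] = True
    w_obs = float(np.einsum("i,ij,j->", in_a, scores, ~in_a))

    n_assignments = math.comb(n, n_a)
    if method == "auto":
        method = "exact" if n_assignments <= _EXACT_LIMIT else "montecarlo"
    if method == "exact":
        masks = _assignment_masks(n, n_a)
        w_perm = _perm_statistics(scores, masks)
        p = float(np.mean(np.abs(w_perm) >= abs(w_obs) - 1e-9))
        return GehanResult(w_obs, p, "exact", n_assignments)
    if method == "montecarlo":
        if rng is None:
            rng = np.random.default_rng(0)
        order = np.argsort(rng.random((n_permutations, n)), axis=1)
        masks = order < n_a
        w_perm = _perm_statistics(scores, masks)
        exceed = int(np.sum(np.abs(w_perm) >= abs(w_obs) - 1e-9))
        p = (1 + exceed) / (n_permutations + 1)
        return GehanResult(w_obs, p, "montecarlo", n_permutations)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class SignificanceDiagram:
    """Per-cell signed test outcomes: +1 greater later, -1 smaller, 0 n.s."""

    matrix: np.ndarray
    alpha: float
    comparison: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        if not np.isin(self.matrix, (-1, 0, 1)).all():
            raise ValueError("diagram entries must be -1, 0 or +1")

    def n_significant(self) -> int:
        return int(np.count_nonzero(self.matrix))


def _cell_test_sign(
    samples_a: Sequence[MEPSample],
    samples_b: Sequence[MEPSample],
    alpha: float,
    threshold_uV: float,
) -> int:
    a = CensoredSample.from_samples(samples_a, threshold_uV)
    b = CensoredSample.from_samples(samples_b, threshold_uV)
    result = gehan_test(a, b)
    if result.p_value >= alpha:
        return 0
    # statistic > 0 means the first sample tends to be greater; the diagram
    # convention is +1 when the *second* (later) epoch is greater
    return -int(np.sign(result.statistic))


def change_diagram(
    map_a: TMSMap,
    map_b: TMSMap,
    n_per_cell: int = 5,
    alpha: float = 0.05,
    threshold_uV: float = 50.0,
) -> SignificanceDiagram:
    """Cell-wise comparison of two sessions on the first n samples per cell.

    Entry +1 when the second map's amplitudes are significantly greater at
    the (uncorrected) level alpha, -1 when smaller, 0 otherwise.
    """
    if map_a.grid != map_b.grid:
        raise ValueError("maps must share one grid")
    grid = map_a.grid
    matrix = np.zeros((grid.n_rows, grid.n_cols), dtype=int)
    for row, col in grid.cell_keys():
        sa = map_a.cells.get((row, col), [])
        sb = map_b.cells.get((row, col), [])
        if len(sa) < n_per_cell or len(sb) < n_per_cell:
            raise ValueError(f"cell ({row}, {col}) has fewer than {n_per_cell} samples")
        matrix[row, col] = _cell_test_sign(
            sa[:n_per_cell], sb[:n_per_cell], alpha, threshold_uV
        )
    return SignificanceDiagram(matrix, alpha, "between-sessions")


def within_session_diagram(
    tms_map: TMSMap, alpha: float = 0.05, threshold_uV: float = 50.0
) -> SignificanceDiagram:
    """Compare samples 1-5 vs 6-10 of every cell within one session."""
    grid = tms_map.grid
    matrix = np.zeros((grid.n_rows, grid.n_cols), dtype=int)
    for row, col in grid.cell_keys():
        samples = tms_map.cells.get((row, col), [])
        if len(samples) < 10:
            raise ValueError(f"cell ({row}, {col}) has fewer than 10 samples")
        matrix[row, col] = _cell_test_sign(
            samples[:5], samples[5:10], alpha, threshold_uV
        )
    return SignificanceDiagram(matrix, alpha, "within-session")


def histogram_overlap(
    values_a: Sequence[float], values_b: Sequence[float], n_bins: int = 30
) -> float:
    """Overlap of two normalized histograms on shared equal-width bins.

    1 for identical distributions, 0 for disjoint supports; histograms are
    normalized to unit mass before taking the bin-wise minimum.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both value lists must be nonempty")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:  # all values identical across both samples
        return 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    ha, _ = np.histogram(a, bins=edges)
    hb, _ = np.histogram(b, bins=edges)
    return float(np.minimum(ha / len(a), hb / len(b)).sum())


def bicc(values_by_session: Sequence[Sequence[float]]) -> float:
    """One-way random-effects intraclass correlation on equal-size groups.

    ``(MSB - MSW) / (MSB + (n - 1) MSW)`` with n values per group; small
    negative results are reported as computed (no clamping).
    """
    groups = [np.asarray(g, dtype=float) for g in values_by_session]
    if len(groups) < 2:
        raise ValueError("need at least 2 sessions")
    n = len(groups[0])
    if n < 2 or any(len(g) != n for g in groups):
        raise ValueError("groups must have equal size >= 2")
    data = np.vstack(groups)
    k = data.shape[0]
    group_means = data.mean(axis=1)
    grand = data.mean()
    msb = n * np.sum((group_means - grand) ** 2) / (k - 1)
    msw = np.sum((data - group_means[:, None]) ** 2) / (k * (n - 1))
    denominator = msb + (n - 1) * msw
    if denominator == 0:
        raise ValueError("ICC undefined: all values identical")
    return float((msb - msw) / denominator)


# ---------------------------------------------------------------------------
# Page's trend test
# ---------------------------------------------------------------------------

def _block_contribution_pmf(ranks2: tuple[int, ...]) -> tuple[np.ndarray, int]:
    """Exact pmf of sum_j j * r_perm(j) over all permutations of one block.

    ``ranks2`` are mid-ranks on a doubled integer scale so contributions
    are integers.  Returns (pmf, offset) with pmf[i] = P(contribution =
    offset + i).
    """
    m = len(ranks2)
    weights = np.arange(1, m + 1)
    values = np.fromiter(
        (int(np.dot(weights, perm)) for perm in itertools.permutations(ranks2)),
        dtype=int,
    )
    lo, hi = values.min(), values.max()
    pmf = np.bincount(values - lo, minlength=hi - lo + 1).astype(float)
    return pmf / pmf.sum(), int(lo)


def page_trend_test(
    blocks_by_condition: np.ndarray,
    direction: str = "increasing",
    method: str = "auto",
) -> tuple[float, float]:
    """Page's L test for a monotone ordering of conditions across blocks.

    ``blocks_by_condition`` is a (b, m) matrix of one value per block and
    ordered condition; ties get mid-ranks.  ``direction`` states the
    alternative: values increasing or decreasing with condition index.
    Returns ``(L, one-sided p)``.  For few conditions (m <= 5, or
    ``method='exact'`` with m <= 7) the permutation null of L is built
    exactly by convolving per-block contribution distributions; otherwise a
    normal approximation with E[L] = b m(m+1)²/4 and
    Var[L] = b m²(m+1)²(m-1)/144 is used.
    """
    data = np.asarray(blocks_by_condition, dtype=float)
    if data.ndim != 2:
        raise ValueError("expected a 2D (blocks x conditions) matrix")
    b, m = data.shape
    if m < 3:
        raise ValueError("need at least 3 ordered conditions")
    if b < 1:
        raise ValueError("need at least 1 block")
    if direction == "decreasing":
        data = data[:, ::-1]
    elif direction != "increasing":
        raise ValueError(f"unknown direction {direction!r}")

    ranks = np.apply_along_axis(sps.rankdata, 1, data)
    weights = np.arange(1, m + 1)
    L = float(np.sum(weights * ranks.sum(axis=0)))

    if method == "auto":
        method = "exact" if m <= 5 else "asymptotic"
    if method == "exact":
        if m > 7:
            raise ValueError("exact method limited to <= 7 conditions")
        # doubled scale keeps mid-ranks integral
        total_pmf = np.array([1.0])
        total_offset = 0
        for block_ranks in ranks:
            ranks2 = tuple(int(round(2 * r)) for r in block_ranks)
            pmf, offset = _block_contribution_pmf(ranks2)
            total_pmf = np.convolve(total_pmf, pmf)
            total_offset += offset
        L2 = int(round(2 * L))
        support = total_offset + np.arange(len(total_pmf))
        p = float(total_pmf[support >= L2].sum())
        return L, min(p, 1.0)
    if method == "asymptotic":
        mean_L = b * m * (m + 1) ** 2 / 4.0
        var_L = b * m**2 * (m + 1) ** 2 * (m - 1) / 144.0
        z = (L - mean_L) / math.sqrt(var_L)
        return L, float(sps.norm.sf(z))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class SessionDiscrimination:
    """BICC plus pairwise histogram overlaps of bootstrap distributions."""

    bicc: float
    pairwise_overlaps: dict[tuple[str, str], float]
    spec: ParameterSpec
    k: int
    B: int


def discriminate_sessions(
    session_triple: Sequence[TMSMap],
    spec: ParameterSpec,
    k: int,
    B: int,
    rng: np.random.Generator,
    n_bins: int = 30,
) -> SessionDiscrimination:
    """Bootstrap B parameter values per session, then BICC and overlaps."""
    if len(session_triple) != 3:
        raise ValueError("discriminate_sessions requires exactly 3 maps")
    if spec.is_cog:
        raise ValueError("session discrimination is defined for scalar parameters")
    values = []
    labels = []
    for tms_map in session_triple:
        boot = bootstrap_distribution(tms_map, spec, k, B, rng)
        values.append(boot.values)
        labels.append(tms_map.session_id)
    overlaps = {}
    for i, j in itertools.combinations(range(3), 2):
        overlaps[(labels[i], labels[j])] = histogram_overlap(
            values[i], values[j], n_bins
        )
    return SessionDiscrimination(
        bicc=bicc(values), pairwise_overlaps=overlaps, spec=spec, k=k, B=B
    )
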