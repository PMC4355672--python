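"""Permutation null distributions, SAM-style FDR at top-n cuts, noise filtering.

Group labels are shuffled within each (time point, sampling time) stratum so
the time-course design (per-stratum sample counts) is preserved; scores are
recomputed for each of B shuffles. The FDR at a top-n cut is the expected
number of null scores exceeding the n-th largest observed score, divided by
n and clipped to [0, 1] — the SAM-flavored estimator without a pi0
correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .data_model import TimeCourseDataset
from .scoring import (
    DEFAULT_EPSILON,
    ScoreTable,
    _accumulate,
    _summarize_arrays,
)
from .weights import WeightScheme

__all__ = [
    "PermutationNull",
    "FdrCurve",
    "permute_scores",
    "exhaustive_null",
    "fdr_at_n",
    "fdr_curve",
    "lowest_fdr",
    "noise_filter",
]

DEFAULT_N_GRID = (50, 45, 40, 35, 30)


@dataclass
class PermutationNull:
    """B x F matrix of scores under within-stratum label permutation."""

    B: int
    null_scores: np.ndarray
    seed: int | None
    epsilon: float
    omega_label: str
    k_label: str | None = None
    diagnostics: list[str] = field(default_factory=list)


@dataclass
class FdrCurve:
    n: np.ndarray
    threshold: np.ndarray  # n-th largest observed score
    expected_exceedances: np.ndarray
    fdr: np.ndarray


def _score_for_codes(
    dataset: TimeCourseDataset,
    codes: np.ndarray,
    omega_values: np.ndarray,
    k_values_per_tp: list[np.ndarray],
    epsilon: float,
    n_tp: int,
    p: np.ndarray,
) -> np.ndarray:
    mean, sd, _ = _summarize_arrays(
        dataset.values, codes, dataset.time_point, dataset.sampling_time, n_tp, p
    )
    D, S = _accumulate(mean, sd, omega_values, k_values_per_tp)
    return D / (S + epsilon)


def _k_values(
    dataset: TimeCourseDataset, k_schemes: list[WeightScheme] | None
) -> list[np.ndarray]:
    p = dataset.sampling_times_per_point
    if k_schemes is None:
        return [np.ones(int(pi)) for pi in p]
    if len(k_schemes) != len(p):
        raise ValueError("need one k scheme per time point")
    for i, (s, pi) in enumerate(zip(k_schemes, p)):
        if s.length != pi:
            raise ValueError(f"k scheme at time point {i} has length {s.length}, expected {pi}")
    return [s.values for s in k_schemes]


def _strata(dataset: TimeCourseDataset) -> list[np.ndarray]:
    p = dataset.sampling_times_per_point
    out = []
    for i in range(dataset.n_time_points):
        for j in range(int(p[i])):
            idx = np.flatnonzero((dataset.time_point == i) & (dataset.sampling_time == j))
            if idx.size:
                out.append(idx)
    return out


def permute_scores(
    dataset: TimeCourseDataset,
    omega: WeightScheme,
    k_schemes: list[WeightScheme] | None = None,
    epsilon: float = DEFAULT_EPSILON,
    B: int = 200,
    seed: int = 0,
) -> PermutationNull:
    """Sample B within-stratum label permutations and rescore each.

    Omitting *k_schemes* uses unit sampling-time weights, i.e. the plain
    wRDA null when every time point has a single sampling time.
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    n_tp = dataset.n_time_points
    p = dataset.sampling_times_per_point
    k_vals = _k_values(dataset, k_schemes)
    codes = dataset.group_codes()
    strata = _strata(dataset)
    diags = [
        f"stratum with samples {idx.tolist()} has a single label or <2 samples; "
        "permutation is a no-op there"
        for idx in strata
        if idx.size < 2 or len(np.unique(codes[idx])) < 2
    ]
    rng = np.random.default_rng(seed)
    null = np.empty((B, dataset.n_features))
    for b in range(B):
        perm = codes.copy()
        for idx in strata:
            perm[idx] = rng.permutation(codes[idx])
        null[b] = _score_for_codes(dataset, perm, omega.values, k_vals, epsilon, n_tp, p)
    return PermutationNull(
        B=B,
        null_scores=null,
        seed=seed,
        epsilon=epsilon,
        omega_label=omega.label,
        k_label=None if k_schemes is None else "per-time-point",
        diagnostics=diags,
    )


def exhaustive_null(
    dataset: TimeCourseDataset,
    omega: WeightScheme,
    k_schemes: list[WeightScheme] | None = None,
    epsilon: float = DEFAULT_EPSILON,
    max_permutations: int = 100_000,
) -> PermutationNull:
    """Enumerate every distinct within-stratum label assignment (tiny data only).

    Within each stratum, a label assignment is a choice of which samples
    carry the C labels; the full null is the Cartesian product over strata.
    """
    n_tp = dataset.n_time_points
    p = dataset.sampling_times_per_point
    k_vals = _k_values(dataset, k_schemes)
    codes = dataset.group_codes()
    strata = _strata(dataset)
    per_stratum: list[list[np.ndarray]] = []
    for idx in strata:
        n_c = int((codes[idx] == 0).sum())
        assignments = []
        for c_pos in itertools.combinations(range(idx.size), n_c):
            local = np.ones(idx.size, dtype=np.int8)
            local[list(c_pos)] = 0
            assignments.append(local)
        per_stratum.append(assignments)
    total = int(np.prod([len(a) for a in per_stratum]))
    if total > max_permutations:
        raise ValueError(f"{total} distinct permutations exceed max_permutations")
    null = np.empty((total, dataset.n_features))
    for b, combo in enumerate(itertools.product(*per_stratum)):
        perm = codes.copy()
        for idx, local in zip(strata, combo):
            perm[idx] = local
        null[b] = _score_for_codes(dataset, perm, omega.values, k_vals, epsilon, n_tp, p)
    return PermutationNull(
        B=total,
        null_scores=null,
        seed=None,
        epsilon=epsilon,
        omega_label=omega.label,
        k_label=None if k_schemes is None else "per-time-point",
    )


def fdr_at_n(observed: ScoreTable, null: PermutationNull, n: int) -> float:
    """FDR estimate at the top-n cut: min(1, E[null exceedances of s_(n)] / n)."""
    if not 1 <= n <= observed.n_features:
        raise ValueError(f"n must be in 1..{observed.n_features}, got {n}")
    s_n = np.sort(observed.score)[::-1][n - 1]
    expected = (null.null_scores >= s_n).sum(axis=1).mean()
    return float(min(1.0, expected / n))


def fdr_curve(observed: ScoreTable, null: PermutationNull, n_grid=DEFAULT_N_GRID) -> FdrCurve:
    n_arr = np.asarray(list(n_grid), dtype=int)
    if n_arr.size == 0:
        raise ValueError("n_grid must be nonempty")
    sorted_desc = np.sort(observed.score)[::-1]
    thr = sorted_desc[n_arr - 1]
    expected = np.array(
        [(null.null_scores >= t).sum(axis=1).mean() for t in thr]
    )
    fdr = np.minimum(1.0, expected / n_arr)
    return FdrCurve(n=n_arr, threshold=thr, expected_exceedances=expected, fdr=fdr)


def lowest_fdr(
    observed: ScoreTable, null: PermutationNull, n_grid=DEFAULT_N_GRID
) -> tuple[float, int]:
    """Minimum FDR over the top-n grid; ties resolved toward the largest n."""
    curve = fdr_curve(observed, null, n_grid)
    best = curve.fdr.min()
    tied_n = curve.n[curve.fdr == best]
    return float(best), int(tied_n.max())


def noise_filter(
    observed: ScoreTable, null: PermutationNull, quantile: float = 0.95
) -> list[str]:
    """Retain features scoring above the pooled-null quantile, in rank order."""
    if not 0.0 < quantile < 1.0:
        raise ValueError(f"quantile must lie in (0, 1), got {quantile}")
    threshold = np.quantile(null.null_scores.ravel(), quantile)
    keep = observed.score > threshold
    order = np.argsort(observed.rank, kind="stable")
    return [observed.feature_ids[k] for k in order if keep[k]]
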