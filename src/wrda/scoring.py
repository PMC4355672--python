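"""Group summaries and the wRDA / w2RDA discriminability scores.

For a feature f measured in control (C) and model (M) groups at time points
i = 0..N-1 (optionally with sampling times j = 0..p_i-1 within each point):

    D(f) = sum_i omega_i * |mu_C,f(i) - mu_M,f(i)|            (wRDA)
    S(f) = sum_i omega_i * (sigma_C,f(i) + sigma_M,f(i))
    score(f) = D(f) / (S(f) + epsilon)

w2RDA inserts a second weight layer k_j over sampling times:

    D(f) = sum_i omega_i * sum_j k_j * |mu_C,f(i,j) - mu_M,f(i,j)|
    S(f) = sum_i omega_i * sum_j k_j * (sigma_C,f(i,j) + sigma_M,f(i,j))

With p_i = 1 and k = (1) everywhere, w2RDA reduces to wRDA exactly.
epsilon (default 0.005) regularizes the denominator against tiny
accumulated scatter. Higher scores mean stronger, more consistent
between-group divergence along the weighted time course.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import TimeCourseDataset
from .weights import WeightScheme

__all__ = ["GroupSummary", "ScoreTable", "summarize", "wrda", "w2rda", "top_n"]

DEFAULT_EPSILON = 0.005


@dataclass
class GroupSummary:
    """Per (group, time point, sampling time, feature) mean/SD/count arrays.

    ``mean`` and ``sd`` have shape ``(2, N, p_max, F)`` (axis 0: C then M);
    ``count`` has shape ``(2, N, p_max)``. Cells with no samples hold NaN
    means and zero counts. SD uses denominator n-1 and is set to 0 for
    singleton cells (recorded in ``diagnostics``).
    """

    mean: np.ndarray
    sd: np.ndarray
    count: np.ndarray
    feature_ids: list[str]
    p_per_time_point: np.ndarray
    diagnostics: list[str] = field(default_factory=list)

    @property
    def n_time_points(self) -> int:
        return self.mean.shape[1]

    @property
    def n_features(self) -> int:
        return self.mean.shape[3]


def _summarize_arrays(
    values: np.ndarray,
    group_codes: np.ndarray,
    time_point: np.ndarray,
    sampling_time: np.ndarray,
    n_tp: int,
    p: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized core shared with the permutation engine."""
    n_feat = values.shape[1]
    p_max = int(p.max())
    mean = np.full((2, n_tp, p_max, n_feat), np.nan)
    sd = np.zeros((2, n_tp, p_max, n_feat))
    count = np.zeros((2, n_tp, p_max), dtype=int)
    for i in range(n_tp):
        for j in range(int(p[i])):
            cell = (time_point == i) & (sampling_time == j)
            for g in (0, 1):
                idx = np.flatnonzero(cell & (group_codes == g))
                count[g, i, j] = idx.size
                if idx.size == 0:
                    continue
                sub = values[idx]
                mean[g, i, j] = sub.mean(axis=0)
                if idx.size > 1:
                    sd[g, i, j] = sub.std(axis=0, ddof=1)
    return mean, sd, count


def summarize(dataset: TimeCourseDataset) -> GroupSummary:
    """Compute per-stratum means and sample SDs for both groups."""
    n_tp = dataset.n_time_points
    p = dataset.sampling_times_per_point
    mean, sd, count = _summarize_arrays(
        dataset.values,
        dataset.group_codes(),
        dataset.time_point,
        dataset.sampling_time,
        n_tp,
        p,
    )
    diags = []
    for g, gname in ((0, "C"), (1, "M")):
        for i in range(n_tp):
            for j in range(int(p[i])):
                if count[g, i, j] == 1:
                    diags.append(
                        f"singleton stratum (group {gname}, time point {i}, "
                        f"sampling time {j}): SD set to 0"
                    )
    return GroupSummary(
        mean=mean,
        sd=sd,
        count=count,
        feature_ids=list(dataset.feature_ids),
        p_per_time_point=p,
        diagnostics=diags,
    )


@dataclass
class ScoreTable:
    """Per-feature D, S, score and 1-based rank (1 = highest score)."""

    feature_ids: list[str]
    D: np.ndarray
    S: np.ndarray
    score: np.ndarray
    rank: np.ndarray
    epsilon: float
    omega_label: str
    k_label: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "D": self.D,
                "S": self.S,
                "score": self.score,
                "rank": self.rank,
            }
        )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)


def _ranks_descending(score: np.ndarray) -> np.ndarray:
    # stable sort: ties keep input feature order
    order = np.argsort(-score, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, score.size + 1)
    return rank


def _accumulate(
    mean: np.ndarray,
    sd: np.ndarray,
    omega_values: np.ndarray,
    k_values_per_tp: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Shared D/S accumulation over (time point, sampling time) cells."""
    n_feat = mean.shape[3]
    D = np.zeros(n_feat)
    S = np.zeros(n_feat)
    for i, w in enumerate(omega_values):
        if w == 0.0:
            continue  # zero-weight points are fully inert
        k = k_values_per_tp[i]
        for j, kj in enumerate(k):
            if kj == 0.0:
                continue
            mu_c, mu_m = mean[0, i, j], mean[1, i, j]
            if np.isnan(mu_c).any() or np.isnan(mu_m).any():
                raise ValueError(
                    f"stratum (time point {i}, sampling time {j}) carries nonzero "
                    "weight but lacks samples in one group"
                )
            D += w * kj * np.abs(mu_c - mu_m)
            S += w * kj * (sd[0, i, j] + sd[1, i, j])
    return D, S


def wrda(
    summary: GroupSummary,
    omega: WeightScheme,
    epsilon: float = DEFAULT_EPSILON,
) -> ScoreTable:
    """Score features by weighted relative-difference accumulation.

    Requires a single sampling time per time point (p_i = 1 for all i).
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    if omega.length != summary.n_time_points:
        raise ValueError(
            f"omega has length {omega.length}, dataset has {summary.n_time_points} time points"
        )
    if (summary.p_per_time_point != 1).any():
        raise ValueError("wrda requires p_i = 1 at every time point; use w2rda")
    ones = [np.ones(1)] * summary.n_time_points
    D, S = _accumulate(summary.mean, summary.sd, omega.values, ones)
    score = D / (S + epsilon)
    return ScoreTable(
        feature_ids=list(summary.feature_ids),
        D=D,
        S=S,
        score=score,
        rank=_ranks_descending(score),
        epsilon=epsilon,
        omega_label=omega.label,
    )


def w2rda(
    summary: GroupSummary,
    omega: WeightScheme,
    k_schemes: list[WeightScheme],
    epsilon: float = DEFAULT_EPSILON,
) -> ScoreTable:
    """Sampling-time-weighted extension; one k scheme per time point."""
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    n_tp = summary.n_time_points
    if omega.length != n_tp:
        raise ValueError(
            f"omega has length {omega.length}, dataset has {n_tp} time points"
        )
    if len(k_schemes) != n_tp:
        raise ValueError(f"need one k scheme per time point ({n_tp}), got {len(k_schemes)}")
    for i, (scheme, p_i) in enumerate(zip(k_schemes, summary.p_per_time_point)):
        if scheme.length != p_i:
            raise ValueError(
                f"k scheme at time point {i} has length {scheme.length}, expected p_i={p_i}"
            )
    D, S = _accumulate(summary.mean, summary.sd, omega.values, [s.values for s in k_schemes])
    score = D / (S + epsilon)
    k_labels = {s.label for s in k_schemes}
    return ScoreTable(
        feature_ids=list(summary.feature_ids),
        D=D,
        S=S,
        score=score,
        rank=_ranks_descending(score),
        epsilon=epsilon,
        omega_label=omega.label,
        k_label=k_labels.pop() if len(k_labels) == 1 else "mixed",
    )


def top_n(table: ScoreTable, n: int) -> list[str]:
    """The n highest-scoring feature ids, in rank order (stable ties)."""
    if not 1 <= n <= table.n_features:
        raise ValueError(f"n must be in 1..{table.n_features}, got {n}")
    order = np.argsort(table.rank, kind="stable")
    return [table.feature_ids[k] for k in order[:n]]
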