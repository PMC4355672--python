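"""Grid search over (k-family, q_k) x (omega-family, q_omega) weight settings.

Each grid cell scores the dataset with its weight pair, builds a permutation
null from a cell-specific stream derived from the master seed, and records
the lowest FDR across the top-n grid. Selection takes the cell attaining the
global minimum; when several cells tie, the modal family pair among the tied
cells wins, then the smallest changing factor of k, then the smallest
changing factor of omega.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import TimeCourseDataset
from .permutation import DEFAULT_N_GRID, lowest_fdr, permute_scores
from .scoring import DEFAULT_EPSILON, summarize, w2rda
from .weights import FAMILIES, WeightScheme, make_k_schemes, make_weights

__all__ = ["GridCell", "GridResult", "grid_search", "select_weights", "family_preference"]

DEFAULT_Q_GRID = tuple(round(0.1 * m, 1) for m in range(1, 11))


@dataclass(frozen=True)
class GridCell:
    k_family: str
    q_k: float | None
    omega_family: str
    q_omega: float | None
    lowest_fdr: float
    argmin_n: int


@dataclass
class GridResult:
    cells: list[GridCell]
    selected: GridCell
    n_grid: tuple[int, ...]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.__dict__ for c in self.cells])


def _axis(families, q_grid) -> list[tuple[str, float | None]]:
    axis: list[tuple[str, float | None]] = []
    for fam in families:
        if fam == "equal":
            axis.append(("equal", None))  # single q-less cell
        else:
            axis.extend((fam, q) for q in q_grid)
    return axis


def grid_search(
    dataset: TimeCourseDataset,
    families=FAMILIES,
    q_grid=DEFAULT_Q_GRID,
    n_grid=DEFAULT_N_GRID,
    epsilon: float = DEFAULT_EPSILON,
    B: int = 200,
    seed: int = 0,
    normalize: bool = True,
) -> GridResult:
    """Evaluate every weight-pair cell and select per the tie-break rules."""
    if not families or not len(q_grid) or not len(n_grid):
        raise ValueError("families, q_grid and n_grid must be nonempty")
    unknown = set(families) - set(FAMILIES)
    if unknown:
        raise ValueError(f"unknown families: {sorted(unknown)}")
    n_tp = dataset.n_time_points
    p = dataset.sampling_times_per_point
    summary = summarize(dataset)
    n_grid = tuple(int(n) for n in n_grid)
    if max(n_grid) > dataset.n_features:
        raise ValueError("n_grid exceeds the number of features")
    cells: list[GridCell] = []
    cell_index = 0
    for k_family, q_k in _axis(families, q_grid):
        k_schemes = make_k_schemes(k_family, q_k, p, normalize)
        for omega_family, q_omega in _axis(families, q_grid):
            omega = make_weights(omega_family, q_omega, n_tp, normalize)
            observed = w2rda(summary, omega, k_schemes, epsilon)
            # cell-specific stream: independent of other cells, reproducible
            null = permute_scores(
                dataset,
                omega,
                k_schemes,
                epsilon=epsilon,
                B=B,
                seed=np.random.SeedSequence([seed, cell_index]).generate_state(1)[0] >> 1,
            )
            fdr, argmin_n = lowest_fdr(observed, null, n_grid)
            cells.append(GridCell(k_family, q_k, omega_family, q_omega, fdr, argmin_n))
            cell_index += 1
    result = GridResult(cells=cells, selected=cells[0], n_grid=n_grid, seed=seed)
    result.selected = _select_cell(cells)
    return result


def _q_or_zero(q: float | None) -> float:
    # the equal family behaves as the q=0 limit of every parametric family
    return 0.0 if q is None else q


def _select_cell(cells: list[GridCell]) -> GridCell:
    if not cells:
        raise ValueError("empty grid result")
    best = min(c.lowest_fdr for c in cells)
    tied = [c for c in cells if c.lowest_fdr == best]
    if len(tied) > 1:
        counts: dict[tuple[str, str], int] = {}
        for c in tied:
            counts[(c.k_family, c.omega_family)] = counts.get((c.k_family, c.omega_family), 0) + 1
        top = max(counts.values())
        modal = {pair for pair, n in counts.items() if n == top}
        if len(modal) == 1:
            pair = modal.pop()
            tied = [c for c in tied if (c.k_family, c.omega_family) == pair]
    return min(tied, key=lambda c: (_q_or_zero(c.q_k), _q_or_zero(c.q_omega)))


def select_weights(
    result: GridResult, length_omega: int | None = None, p_per_time_point=None
) -> tuple[GridCell, WeightScheme | None, list[WeightScheme] | None]:
    """Resolve the winning cell; optionally materialize its weight schemes.

    Returns the selected cell plus, when the target lengths are supplied,
    the omega scheme and the per-time-point k schemes it describes.
    """
    cell = _select_cell(result.cells)
    omega = make_weights(cell.omega_family, cell.q_omega, length_omega) if length_omega else None
    k = (
        make_k_schemes(cell.k_family, cell.q_k, p_per_time_point)
        if p_per_time_point is not None
        else None
    )
    return cell, omega, k


def family_preference(result: GridResult, fdr_ceiling: float = 0.05) -> pd.DataFrame:
    """Fractions of qualifying cells (lowest FDR below the ceiling) per
    (k family, omega family) pair; empty when nothing qualifies."""
    qualifying = [c for c in result.cells if c.lowest_fdr < fdr_ceiling]
    if not qualifying:
        return pd.DataFrame(columns=["k_family", "omega_family", "count", "fraction"])
    df = (
        pd.DataFrame({"k_family": [c.k_family for c in qualifying],
                      "omega_family": [c.omega_family for c in qualifying]})
        .value_counts()
        .rename("count")
        .reset_index()
    )
    df["fraction"] = df["count"] / df["count"].sum()
    return df.sort_values("count", ascending=False, ignore_index=True)
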