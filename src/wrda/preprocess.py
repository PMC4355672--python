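"""Feature-table preprocessing: zero-fraction filtering and outlier correction.

Two rules, applied per (group, time point) stratum:

* a feature is dropped when zeros make up strictly more than ``max_zero_frac``
  of the values in any stratum (an unreliably detected ion cannot be scored);
* a value lying outside mu +/- k_sigma * sigma of its stratum is treated as an
  instrument artifact and replaced by a draw from a normal distribution
  fitted to the stratum's in-range values, redrawn until inside the range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import TimeCourseDataset

__all__ = ["PreprocessReport", "zero_filter", "outlier_correct"]


@dataclass
class PreprocessReport:
    removed_feature_ids: list[str] = field(default_factory=list)
    corrected_cells: list[tuple[str, str, float, float]] = field(default_factory=list)
    seed: int | None = None
    diagnostics: list[str] = field(default_factory=list)


def _stratum_masks(dataset: TimeCourseDataset):
    for g in ("C", "M"):
        for i in range(dataset.n_time_points):
            mask = (dataset.group == g) & (dataset.time_point == i)
            if mask.any():
                yield g, i, np.flatnonzero(mask)


def zero_filter(
    dataset: TimeCourseDataset, max_zero_frac: float = 0.2
) -> tuple[TimeCourseDataset, PreprocessReport]:
    """Drop features whose zero fraction strictly exceeds the threshold in
    any (group, time point) stratum; retained features keep their order."""
    if not 0.0 <= max_zero_frac <= 1.0:
        raise ValueError(f"max_zero_frac must lie in [0, 1], got {max_zero_frac}")
    drop = np.zeros(dataset.n_features, dtype=bool)
    for _, _, idx in _stratum_masks(dataset):
        frac = (dataset.values[idx] == 0.0).mean(axis=0)
        drop |= frac > max_zero_frac
    kept = [f for f, d in zip(dataset.feature_ids, drop) if not d]
    removed = [f for f, d in zip(dataset.feature_ids, drop) if d]
    out = replace(
        dataset,
        values=dataset.values[:, ~drop].copy(),
        feature_ids=kept,
    )
    return out, PreprocessReport(removed_feature_ids=removed)


def outlier_correct(
    dataset: TimeCourseDataset,
    k_sigma: float = 2.0,
    seed: int = 0,
    max_redraws: int = 1000,
) -> tuple[TimeCourseDataset, PreprocessReport]:
    """Replace per-stratum outliers beyond mu +/- k_sigma*sigma.

    mu and sigma are computed from the full stratum (outliers included), so
    the flagging range matches the acceptance range. Replacements are drawn
    from a normal fitted to the non-outlier values and rejected until they
    land inside the range; deterministic given *seed*. Strata with fewer
    than 2 samples are skipped with a diagnostic.
    """
    if k_sigma <= 0:
        raise ValueError(f"k_sigma must be positive, got {k_sigma}")
    rng = np.random.default_rng(seed)
    values = dataset.values.copy()
    report = PreprocessReport(seed=seed)
    clipped = np.clip  # replacement stays non-negative like every intensity
    for g, i, idx in _stratum_masks(dataset):
        if idx.size < 2:
            report.diagnostics.append(
                f"stratum (group {g}, time point {i}) has {idx.size} sample(s); "
                "outlier correction skipped"
            )
            continue
        sub = dataset.values[idx]  # flagging uses pre-correction statistics
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        lo, hi = mu - k_sigma * sd, mu + k_sigma * sd
        out_mask = (sub < lo) | (sub > hi)
        for f in np.flatnonzero(out_mask.any(axis=0)):
            flagged = out_mask[:, f]
            inliers = sub[~flagged, f]
            fit_mu = inliers.mean()
            fit_sd = inliers.std(ddof=1) if inliers.size > 1 else 0.0
            for local in np.flatnonzero(flagged):
                s = idx[local]
                old = dataset.values[s, f]
                new = fit_mu
                if fit_sd > 0:
                    for _ in range(max_redraws):
                        draw = rng.normal(fit_mu, fit_sd)
                        if lo[f] <= draw <= hi[f]:
                            new = draw
                            break
                new = float(clipped(new, 0.0, None))
                values[s, f] = new
                report.corrected_cells.append(
                    (dataset.sample_ids[s], dataset.feature_ids[f], float(old), new)
                )
    return replace(dataset, values=values), report
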