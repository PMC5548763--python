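"""Cross-condition correlation profiles over time.

For each feature class, features with extreme intensities (top/bottom
percentile at any timepoint) are removed, then features whose
treatment-baseline intensity difference never exceeds one SD of the
per-timepoint difference distribution are removed, and the Pearson
correlation between the two conditions' intensity vectors across the
surviving features is computed at every timepoint.  The timepoint with the
lowest correlation marks the transition stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (CONDITIONS, ExpressionDataset, pearson_strict)
from .errors import DegenerateInputError


@dataclass
class PccSeries:
    """Per-class Pearson correlation series over timepoints.

    ``series`` maps class → list of (timepoint, PCC); ``n_features`` maps
    class → number of features surviving the filters; ``argmin`` maps class
    → the timepoint with the lowest PCC.
    """

    series: dict[str, list[tuple[str, float]]]
    n_features: dict[str, int]
    argmin: dict[str, str]


def filter_for_pcc(dataset: ExpressionDataset, clazz: str,
                   percentile: float = 0.01,
                   sd_multiplier: float = 1.0) -> pd.Index:
    """Two-stage feature filter applied before the correlation profile.

    Stage 1 removes features whose intensity lies at or beyond the top or
    bottom ``percentile`` of all same-class intensities (both conditions
    pooled) at any timepoint.  Stage 2, computed over stage-1 survivors,
    removes features whose |treatment − baseline| difference is within
    ``sd_multiplier`` SDs of the per-timepoint difference distribution at
    every timepoint.
    """
    features = dataset.features_of_class(clazz)
    if len(features) == 0:
        raise DegenerateInputError(f"no features of class {clazz!r}")
    base = dataset.condition(CONDITIONS[0], features)
    treat = dataset.condition(CONDITIONS[1], features)

    keep = np.ones(len(features), dtype=bool)
    for t in dataset.timepoints:
        pooled = np.concatenate([base[t].to_numpy(), treat[t].to_numpy()])
        lo = np.quantile(pooled, percentile)
        hi = np.quantile(pooled, 1.0 - percentile)
        extreme = ((base[t].to_numpy() >= hi) | (base[t].to_numpy() <= lo) |
                   (treat[t].to_numpy() >= hi) | (treat[t].to_numpy() <= lo))
        keep &= ~extreme
    stage1 = features[keep]
    if len(stage1) == 0:
        return stage1

    diff = (dataset.condition(CONDITIONS[1], stage1).to_numpy()
            - dataset.condition(CONDITIONS[0], stage1).to_numpy())
    sd = diff.std(axis=0, ddof=1) if diff.shape[0] > 1 else np.zeros(diff.shape[1])
    responsive = (np.abs(diff) > sd_multiplier * sd).any(axis=1)
    return stage1[responsive]


def condition_pcc(dataset: ExpressionDataset, subset, timepoint: str) -> float:
    """PCC between baseline and treatment intensity vectors at a timepoint."""
    subset = list(subset)
    if len(subset) < 3:
        raise DegenerateInputError(
            f"need >= 3 features for a correlation, got {len(subset)}")
    base = dataset.condition(CONDITIONS[0], subset)[timepoint].to_numpy()
    treat = dataset.condition(CONDITIONS[1], subset)[timepoint].to_numpy()
    return pearson_strict(base, treat,
                          what=f"intensities at {timepoint}")


def transition_profile(dataset: ExpressionDataset,
                       classes: tuple[str, ...] | None = None,
                       percentile: float = 0.01,
                       sd_multiplier: float = 1.0) -> PccSeries:
    """Filtered per-class, per-timepoint cross-condition PCC series."""
    if classes is None:
        classes = tuple(sorted(dataset.classes.unique()))
    series: dict[str, list[tuple[str, float]]] = {}
    n_features: dict[str, int] = {}
    argmin: dict[str, str] = {}
    for clazz in classes:
        subset = filter_for_pcc(dataset, clazz, percentile, sd_multiplier)
        n_features[clazz] = len(subset)
        values = [(t, condition_pcc(dataset, subset, t))
                  for t in dataset.timepoints]
        series[clazz] = values
        argmin[clazz] = min(values, key=lambda tv: tv[1])[0]
    return PccSeries(series, n_features, argmin)
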