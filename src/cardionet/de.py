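"""Differential-expression calling by a per-timepoint mean ± 2·SD envelope.

At each timepoint the mean and standard deviation of all features' log2 fold
changes are computed; a feature is labelled +1 (up) if its fold change
exceeds mean + k·SD, -1 (down) if below mean - k·SD, else 0.  A feature is
"DE" if any timepoint label is nonzero.  Genes and miRNAs are called
separately so each class sets its own envelope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import DECallTable, EmergenceTable
from .errors import DegenerateInputError


def call_de(fold_changes: pd.DataFrame, sd_multiplier: float = 2.0,
            center: str = "mean", ddof: int = 1) -> DECallTable:
    """Label each feature at each timepoint against the mean ± k·SD envelope.

    Parameters
    ----------
    fold_changes
        Feature × timepoint log2 ratio matrix; must be finite.
    sd_multiplier
        k in the mean ± k·SD rule.
    center
        ``"mean"`` (default) centres the envelope at the per-timepoint mean;
        ``"zero"`` centres it at 0.
    ddof
        Delta degrees of freedom for the SD (1 = sample SD, 0 = population).
    """
    if fold_changes.shape[0] < 2:
        raise DegenerateInputError(
            "need at least 2 features to estimate a standard deviation")
    arr = fold_changes.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("fold changes must be finite")
    if center == "mean":
        mu = arr.mean(axis=0)
    elif center == "zero":
        mu = np.zeros(arr.shape[1])
    else:
        raise ValueError(f"unknown center {center!r}")
    sd = arr.std(axis=0, ddof=ddof)
    upper = mu + sd_multiplier * sd
    lower = mu - sd_multiplier * sd
    labels = (arr > upper).astype(np.int8) - (arr < lower).astype(np.int8)
    labels = pd.DataFrame(labels, index=fold_changes.index,
                          columns=fold_changes.columns)
    thresholds = pd.DataFrame(
        {"mean": arr.mean(axis=0), "sd": sd, "lower": lower, "upper": upper},
        index=fold_changes.columns)
    return DECallTable(labels, thresholds)


def classify_emergence(calls: DECallTable) -> EmergenceTable:
    """First-emergence classification of DE calls.

    For each timepoint t, the New+ set holds features up-regulated at t for
    the first time; the Old+ set holds features up-regulated at t that were
    already up at an earlier timepoint.  ``first_emergence`` maps each DE
    feature to its earliest timepoint with any nonzero label.
    """
    labels = calls.labels
    tps = list(labels.columns)
    first: dict[str, str] = {}
    new_plus: dict[str, set[str]] = {t: set() for t in tps}
    old_plus: dict[str, set[str]] = {t: set() for t in tps}
    arr = labels.to_numpy()
    for i, feature in enumerate(labels.index):
        seen_up = False
        for j, t in enumerate(tps):
            lab = arr[i, j]
            if lab != 0 and feature not in first:
                first[feature] = t
            if lab == 1:
                (old_plus if seen_up else new_plus)[t].add(feature)
                seen_up = True
    series = pd.Series(first, dtype=object)
    series.index.name = "feature"
    return EmergenceTable(series, new_plus, old_plus, tuple(tps))


def de_summary(calls: DECallTable, emergence: EmergenceTable | None = None,
               classes: pd.Series | None = None) -> dict:
    """Per-timepoint DE counts, per-class counts, and first-time proportions."""
    if emergence is None:
        emergence = classify_emergence(calls)
    labels = calls.labels
    tps = list(labels.columns)
    out: dict = {"timepoints": tps, "n_features": int(labels.shape[0])}
    de_any = labels.ne(0)
    out["n_de_total"] = int(de_any.any(axis=1).sum())
    out["n_de_per_timepoint"] = {t: int(de_any[t].sum()) for t in tps}
    out["n_up_per_timepoint"] = {t: int((labels[t] == 1).sum()) for t in tps}
    out["n_down_per_timepoint"] = {t: int((labels[t] == -1).sum()) for t in tps}
    out["new_plus"] = {t: len(emergence.new_plus[t]) for t in tps}
    out["old_plus"] = {t: len(emergence.old_plus[t]) for t in tps}
    first_counts = {t: 0 for t in tps}
    for t in emergence.first_emergence:
        first_counts[t] += 1
    out["first_emergence_counts"] = first_counts
    out["first_time_proportion"] = {
        t: (first_counts[t] / out["n_de_per_timepoint"][t]
            if out["n_de_per_timepoint"][t] else 0.0)
        for t in tps}
    if classes is not None:
        classes = classes.reindex(labels.index)
        by_class = {}
        for clazz, group in labels.groupby(classes):
            de = group.ne(0)
            by_class[str(clazz)] = {
                "n_de_total": int(de.any(axis=1).sum()),
                "n_de_per_timepoint": {t: int(de[t].sum()) for t in tps},
            }
        out["by_class"] = by_class
    return out
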