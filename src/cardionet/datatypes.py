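"""Shared data containers for the time-course expression pipeline.

Expression matrices are pandas DataFrames whose columns are sample labels of
the form ``<condition>_<timepoint>`` (e.g. ``TAB_d5``) and whose index holds
feature identifiers.  Two conditions are modelled: a baseline (``sham``) and
a treatment (``TAB``), each measured at the same ordered list of timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError

#: The two experimental conditions, in (baseline, treatment) order.
CONDITIONS = ("sham", "TAB")
SHAM, TAB = CONDITIONS

#: Default ordered timepoint labels (days after surgery).
DEFAULT_TIMEPOINTS = ("d3", "d5", "d7", "d14", "d28")

#: Feature class labels.
CLASS_GENE = "gene"
CLASS_TF = "tf"
CLASS_MIRNA = "mirna"
FEATURE_CLASSES = (CLASS_GENE, CLASS_TF, CLASS_MIRNA)


def sample_column(condition: str, timepoint: str) -> str:
    """Column name for one (condition, timepoint) sample."""
    return f"{condition}_{timepoint}"


def sample_columns(timepoints: Sequence[str],
                   conditions: Sequence[str] = CONDITIONS) -> list[str]:
    """All sample columns, condition-major (sham_d3.. then TAB_d3..)."""
    return [sample_column(c, t) for c in conditions for t in timepoints]


@dataclass
class ExpressionDataset:
    """Normalized feature-by-sample intensity matrix with feature classes.

    Parameters
    ----------
    values
        Strictly positive intensities; index = feature ids, columns =
        ``<condition>_<timepoint>`` for every condition/timepoint pair.
    classes
        Series mapping each feature id to one of :data:`FEATURE_CLASSES`.
    timepoints
        Ordered timepoint labels shared by both conditions.
    """

    values: pd.DataFrame
    classes: pd.Series
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS

    def __post_init__(self) -> None:
        self.timepoints = tuple(self.timepoints)
        expected = sample_columns(self.timepoints)
        missing = [c for c in expected if c not in self.values.columns]
        if missing:
            raise ValueError(f"expression matrix missing sample columns: {missing}")
        self.values = self.values.loc[:, expected]
        self.classes = self.classes.reindex(self.values.index)
        if self.classes.isna().any():
            bad = self.classes.index[self.classes.isna()].tolist()[:5]
            raise ValueError(f"features without a class label: {bad}")
        unknown = set(self.classes.unique()) - set(FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("expression intensities must be strictly positive")

    # -- accessors ---------------------------------------------------------

    def condition(self, condition: str,
                  features: Iterable[str] | None = None) -> pd.DataFrame:
        """Intensity sub-matrix for one condition, columns renamed to timepoints."""
        cols = [sample_column(condition, t) for t in self.timepoints]
        frame = self.values.loc[:, cols] if features is None \
            else self.values.loc[list(features), cols]
        frame = frame.copy()
        frame.columns = list(self.timepoints)
        return frame

    def features_of_class(self, clazz: str) -> pd.Index:
        if clazz not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {clazz!r}")
        return self.classes.index[self.classes == clazz]

    def subset(self, features: Iterable[str]) -> "ExpressionDataset":
        features = list(features)
        return ExpressionDataset(self.values.loc[features].copy(),
                                 self.classes.loc[features].copy(),
                                 self.timepoints)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]


@dataclass
class ProbeMatrix:
    """Probe-level linear-scale intensities before the probe→gene collapse.

    ``replicate_groups`` maps an output sample label to the list of raw
    column names it averages over; ``None`` means singleton groups.
    """

    intensities: pd.DataFrame
    probe_to_gene: pd.Series | None = None
    replicate_groups: Mapping[str, Sequence[str]] | None = None

    def copy_with(self, intensities: pd.DataFrame) -> "ProbeMatrix":
        p2g = None
        if self.probe_to_gene is not None:
            p2g = self.probe_to_gene.reindex(intensities.index)
        return ProbeMatrix(intensities, p2g, self.replicate_groups)


@dataclass
class DECallTable:
    """Per-feature, per-timepoint differential-expression labels.

    ``labels`` holds values in {+1, 0, -1}; ``thresholds`` is a timepoint ×
    [mean, sd, lower, upper] frame recording the envelope used for calling.
    """

    labels: pd.DataFrame
    thresholds: pd.DataFrame

    @property
    def timepoints(self) -> tuple[str, ...]:
        return tuple(self.labels.columns)

    def de_features(self) -> pd.Index:
        """Features with a nonzero label at any timepoint."""
        return self.labels.index[(self.labels != 0).any(axis=1)]

    def concat(self, other: "DECallTable") -> "DECallTable":
        if tuple(other.labels.columns) != self.timepoints:
            raise ValueError("timepoint axes differ")
        labels = pd.concat([self.labels, other.labels])
        if labels.index.duplicated().any():
            raise ValueError("overlapping feature ids")
        thresholds = pd.concat(
            [self.thresholds, other.thresholds],
            keys=["a", "b"])  # kept only for provenance; rarely inspected
        return DECallTable(labels, thresholds)


@dataclass
class EmergenceTable:
    """First-emergence bookkeeping derived from a :class:`DECallTable`.

    ``first_emergence`` maps each DE feature to the earliest timepoint with a
    nonzero label.  ``new_plus``/``old_plus`` partition the up-regulated
    features at each timepoint into first-time versus previously up-regulated.
    """

    first_emergence: pd.Series
    new_plus: dict[str, set[str]]
    old_plus: dict[str, set[str]]
    timepoints: tuple[str, ...]


#: Module id of the residual module (isolated nodes / tiny components).
RESIDUAL_MODULE = 0


@dataclass
class ModulePartition:
    """Result of the iterated bridge-bisection partitioner.

    Modules are numbered 1..k by decreasing size; nodes in components no
    larger than ``min_size`` (including isolated nodes) receive
    :data:`RESIDUAL_MODULE`.  ``cuts`` records, in order, each bridge removed
    and its balancing value (size of the larger side).
    """

    module_of: dict[str, int]
    cuts: list[tuple[tuple[str, str], int]] = field(default_factory=list)

    @property
    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, mid in self.module_of.items():
            out.setdefault(mid, []).append(node)
        return {mid: sorted(nodes) for mid, nodes in sorted(out.items())}

    def members(self, module_id: int) -> list[str]:
        return self.modules.get(module_id, [])


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two equal-length vectors; NaN if degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd * xd).sum() * (yd * yd).sum())
    if denom == 0.0:
        return float("nan")
    return float(np.clip((xd * yd).sum() / denom, -1.0, 1.0))


def pearson_strict(x: np.ndarray, y: np.ndarray, what: str = "vector") -> float:
    """Pearson correlation that raises on zero variance instead of NaN."""
    r = pearson(x, y)
    if np.isnan(r):
        raise DegenerateInputError(f"zero variance in {what}; PCC undefined")
    return r
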