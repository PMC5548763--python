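"""Probe-level preprocessing: scaling, filtering, normalization, collapse.

The processing order mirrors a single-channel microarray workflow: per-sample
median scaling, replicate averaging, a positivity filter (every retained
intensity >= 1 in every sample), between-sample quantile normalization, and a
probe→gene collapse that keeps, per gene, the probe with the largest summed
absolute log2 fold change across timepoints.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (CLASS_GENE, CLASS_MIRNA, CLASS_TF, CONDITIONS,
                        ExpressionDataset, ProbeMatrix, sample_column)
from .errors import DegenerateInputError


def median_scale(probes: ProbeMatrix,
                 reference: float | None = None) -> ProbeMatrix:
    """Rescale each sample so its median matches a common reference.

    The reference defaults to the median of the per-sample medians.  Scaling
    multiplies every value in a sample by one scalar, so within-sample rank
    order is preserved.

    Raises
    ------
    DegenerateInputError
        If any sample median is <= 0 (no positive scale factor exists).
    """
    df = probes.intensities
    medians = df.median(axis=0)
    if (medians <= 0).any():
        bad = medians.index[medians <= 0].tolist()
        raise DegenerateInputError(
            f"cannot median-scale samples with nonpositive median: {bad}")
    ref = float(np.median(medians.to_numpy())) if reference is None else float(reference)
    scaled = df * (ref / medians)
    return probes.copy_with(scaled)


def average_replicates(probes: ProbeMatrix) -> ProbeMatrix:
    """Collapse replicate sample columns by their arithmetic mean.

    ``probes.replicate_groups`` maps output sample label → raw column names.
    ``None`` is treated as singleton groups (identity).
    """
    groups = probes.replicate_groups
    if groups is None:
        return probes
    out = {}
    for label, members in groups.items():
        members = list(members)
        if not members:
            raise ValueError(f"replicate group {label!r} has zero members")
        out[label] = probes.intensities.loc[:, members].mean(axis=1)
    averaged = pd.DataFrame(out, index=probes.intensities.index)
    return ProbeMatrix(averaged, probes.probe_to_gene, None)


def combine_replicates_median(probes: ProbeMatrix) -> ProbeMatrix:
    """Collapse replicate sample columns by their median (miRNA convention)."""
    groups = probes.replicate_groups
    if groups is None:
        return probes
    out = {}
    for label, members in groups.items():
        members = list(members)
        if not members:
            raise ValueError(f"replicate group {label!r} has zero members")
        out[label] = probes.intensities.loc[:, members].median(axis=1)
    combined = pd.DataFrame(out, index=probes.intensities.index)
    return ProbeMatrix(combined, probes.probe_to_gene, None)


def filter_probes(probes: ProbeMatrix, min_intensity: float = 1.0) -> ProbeMatrix:
    """Drop probes whose intensity falls below ``min_intensity`` anywhere.

    A probe is retained only if its value is >= ``min_intensity`` in every
    sample of both conditions; negative and sub-unit intensities are thereby
    removed in one pass.  May return an empty matrix.
    """
    keep = (probes.intensities >= min_intensity).all(axis=1)
    return probes.copy_with(probes.intensities.loc[keep].copy())


def quantile_normalize(probes: ProbeMatrix) -> ProbeMatrix:
    """Between-sample quantile normalization.

    Each sample is sorted from highest to lowest; for every rank position the
    reference value is the median across samples of the values at that rank;
    each sample's value at a rank is then replaced by the reference.  All
    samples end up with the identical multiset of values, and the operation
    is idempotent.  Ties are broken by stable (original-row-order) sort.
    """
    df = probes.intensities
    arr = df.to_numpy(dtype=float)
    if arr.size == 0:
        return probes.copy_with(df.copy())
    # descending stable order per sample
    order = np.argsort(-arr, axis=0, kind="stable")
    sorted_desc = np.take_along_axis(arr, order, axis=0)
    reference = np.median(sorted_desc, axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        out[order[:, j], j] = reference
    return probes.copy_with(pd.DataFrame(out, index=df.index, columns=df.columns))


def probe_fold_changes(probes: ProbeMatrix, timepoints: Sequence[str],
                       treatment: str = CONDITIONS[1],
                       baseline: str = CONDITIONS[0]) -> pd.DataFrame:
    """Per-probe log2(treatment/baseline) ratios at each timepoint."""
    df = probes.intensities
    cols_t = [sample_column(treatment, t) for t in timepoints]
    cols_b = [sample_column(baseline, t) for t in timepoints]
    t = df.loc[:, cols_t].to_numpy(dtype=float)
    b = df.loc[:, cols_b].to_numpy(dtype=float)
    if (t <= 0).any() or (b <= 0).any():
        raise ValueError("nonpositive intensities; run filter_probes first")
    fc = np.log2(t) - np.log2(b)
    return pd.DataFrame(fc, index=df.index, columns=list(timepoints))


def collapse_probes(probes: ProbeMatrix, fold_changes: pd.DataFrame,
                    tf_genes: set[str] | frozenset[str] = frozenset(),
                    timepoints: Sequence[str] | None = None,
                    clazz: str | None = None) -> ExpressionDataset:
    """Collapse multi-probe genes to the probe with the largest DE signal.

    For each gene with several surviving probes, the probe maximizing the sum
    over timepoints of |log2 fold change| is kept; ties go to the
    lexicographically smallest probe id.  Genes with no surviving probe are
    absent from the output.
    """
    if probes.probe_to_gene is None:
        raise ValueError("probe→gene mapping required for collapse")
    df = probes.intensities
    mapping = probes.probe_to_gene.reindex(df.index)
    if mapping.isna().any():
        bad = mapping.index[mapping.isna()].tolist()[:5]
        raise ValueError(f"probes without a gene symbol: {bad}")
    score = fold_changes.reindex(df.index).abs().sum(axis=1)

    chosen: dict[str, str] = {}
    for probe in sorted(df.index):
        gene = mapping.loc[probe]
        if gene not in chosen or score.loc[probe] > score.loc[chosen[gene]]:
            chosen[gene] = probe
    genes = sorted(chosen)
    values = df.loc[[chosen[g] for g in genes]].copy()
    values.index = pd.Index(genes, name="feature")

    if timepoints is None:
        # infer ordered timepoints from the baseline-condition columns
        prefix = CONDITIONS[0] + "_"
        timepoints = [c[len(prefix):] for c in df.columns if c.startswith(prefix)]
    if clazz is not None:
        classes = pd.Series(clazz, index=values.index)
    else:
        classes = pd.Series(
            [CLASS_TF if g in tf_genes else CLASS_GENE for g in genes],
            index=values.index)
    return ExpressionDataset(values, classes, tuple(timepoints))


def mirna_preprocess(probes: ProbeMatrix, flags: pd.DataFrame,
                     timepoints: Sequence[str] | None = None) -> ExpressionDataset:
    """miRNA-specific preprocessing.

    Removes miRNA probes flagged < 0 in *every* replicate probe and chip,
    combines replicate probes of one miRNA by median, then applies
    between-sample quantile normalization.

    ``flags`` must be aligned to ``probes.intensities`` (same index/columns).
    """
    if flags is None:
        raise ValueError("flag table required for miRNA preprocessing")
    df = probes.intensities
    flags = flags.reindex(index=df.index, columns=df.columns)
    if flags.isna().any().any():
        raise ValueError("flag table does not cover every probe/sample")
    if probes.probe_to_gene is None:
        raise ValueError("probe→miRNA mapping required")
    mapping = probes.probe_to_gene.reindex(df.index)

    # a miRNA survives if any of its probes has a nonnegative flag anywhere
    ok_probe = (flags >= 0).any(axis=1)
    ok_mirna = ok_probe.groupby(mapping).any()
    keep = mapping.map(ok_mirna)
    df = df.loc[keep[keep].index]
    mapping = mapping.loc[df.index]

    combined = df.groupby(mapping).median()
    combined.index.name = "feature"
    combined = combined.sort_index()
    normalized = quantile_normalize(ProbeMatrix(combined)).intensities

    if timepoints is None:
        prefix = CONDITIONS[0] + "_"
        timepoints = [c[len(prefix):] for c in normalized.columns
                      if c.startswith(prefix)]
    classes = pd.Series(CLASS_MIRNA, index=normalized.index)
    return ExpressionDataset(normalized, classes, tuple(timepoints))


def compute_fold_changes(dataset: ExpressionDataset,
                         treatment: str = CONDITIONS[1],
                         baseline: str = CONDITIONS[0]) -> pd.DataFrame:
    """Feature × timepoint log2(treatment/baseline) matrix."""
    t = dataset.condition(treatment).to_numpy(dtype=float)
    b = dataset.condition(baseline).to_numpy(dtype=float)
    if (t <= 0).any() or (b <= 0).any():
        raise ValueError("nonpositive intensity; must be filtered upstream")
    fc = np.log2(t) - np.log2(b)
    return pd.DataFrame(fc, index=dataset.values.index,
                        columns=list(dataset.timepoints))
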