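"""Synthetic two-condition time-course expression data with ground truth.

The generator plants, on top of a log-normal intensity background shared by
both conditions, (a) differential-expression effects on a configurable
fraction of genes and miRNAs, (b) TF co-expression modules with distinct
temporal activation patterns, and (c) regulatory and suppression
relationships consistent with the planted expression, recorded in a
:class:`GroundTruth` object for recovery testing.  Effects are added in
log2 space to the treatment condition only, so log2(treatment/baseline)
fold changes recover them directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (CLASS_GENE, CLASS_MIRNA, CLASS_TF, CONDITIONS,
                        DEFAULT_TIMEPOINTS, ExpressionDataset, sample_column)
from .errors import ConfigurationError
from . import io as cio


@dataclass
class ModuleSpec:
    """One planted TF module: member count and per-timepoint log2 effect."""

    size: int
    temporal_pattern: tuple[float, ...]


@dataclass
class SimulationConfig:
    n_genes: int = 400
    n_tfs: int = 60
    n_mirnas: int = 40
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    baseline_log_mean: float = 8.0
    baseline_log_sd: float = 1.5
    noise_sd: float = 0.2
    module_specs: list[ModuleSpec] = field(default_factory=list)
    frac_de_genes: float = 0.1
    de_effect: float = 2.0
    #: optional per-timepoint multiplier shaping every planted DE effect;
    #: None means a random contiguous activation window per feature
    divergence_pattern: tuple[float, ...] | None = None
    n_tf_target_pairs: int = 100
    n_mirna_target_pairs: int = 80
    frac_cv_genes: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_tfs", "n_mirnas",
                     "n_tf_target_pairs", "n_mirna_target_pairs"):
            if getattr(self, name) < 0:
                raise ConfigurationError(name, "must be >= 0")
        for name in ("frac_de_genes", "frac_cv_genes"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(name, "must be in [0, 1]")
        for name in ("baseline_log_sd", "noise_sd", "de_effect"):
            if getattr(self, name) < 0:
                raise ConfigurationError(name, "must be >= 0")
        if len(self.timepoints) < 2:
            raise ConfigurationError("timepoints", "need at least 2 timepoints")
        if len(set(self.timepoints)) != len(self.timepoints):
            raise ConfigurationError("timepoints", "labels must be unique")
        total = sum(m.size for m in self.module_specs)
        if total > self.n_tfs:
            raise ConfigurationError(
                "module_specs",
                f"module sizes sum to {total} > n_tfs={self.n_tfs}")
        for i, m in enumerate(self.module_specs):
            if len(m.temporal_pattern) != len(self.timepoints):
                raise ConfigurationError(
                    "module_specs",
                    f"module {i} pattern length {len(m.temporal_pattern)} != "
                    f"{len(self.timepoints)} timepoints")
        if self.divergence_pattern is not None and \
                len(self.divergence_pattern) != len(self.timepoints):
            raise ConfigurationError(
                "divergence_pattern", "length must match timepoints")


@dataclass
class GroundTruth:
    """Everything the simulator planted, for downstream recovery tests."""

    de_labels: pd.DataFrame
    module_of: dict[str, int]
    tf_target_pairs: list[tuple[str, str]]
    mirna_target_pairs: list[tuple[str, str]]
    suppression_events: list[tuple[str, str, str]]
    cv_genes: list[str]

    def to_json_dict(self) -> dict:
        return {
            "de_labels": {f: [int(v) for v in row]
                          for f, row in self.de_labels.iterrows()},
            "timepoints": list(self.de_labels.columns),
            "module_of": self.module_of,
            "tf_target_pairs": [list(p) for p in self.tf_target_pairs],
            "mirna_target_pairs": [list(p) for p in self.mirna_target_pairs],
            "suppression_events": [list(e) for e in self.suppression_events],
            "cv_genes": self.cv_genes,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "GroundTruth":
        labels = pd.DataFrame.from_dict(d["de_labels"], orient="index",
                                        columns=d["timepoints"], dtype=np.int8)
        labels.index.name = "feature"
        return cls(labels, {k: int(v) for k, v in d["module_of"].items()},
                   [tuple(p) for p in d["tf_target_pairs"]],
                   [tuple(p) for p in d["mirna_target_pairs"]],
                   [tuple(e) for e in d["suppression_events"]],
                   list(d["cv_genes"]))


def _feature_ids(config: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    genes = [f"g{i:05d}" for i in range(1, config.n_genes + 1)]
    tfs = [f"TF{i:04d}" for i in range(1, config.n_tfs + 1)]
    mirnas = [f"mir{i:04d}" for i in range(1, config.n_mirnas + 1)]
    return genes, tfs, mirnas


def simulate_dataset(config: SimulationConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Generate a (dataset, ground truth) pair from a validated config.

    Identical configs (including ``seed``) produce bit-identical output; the
    generator draws from one seeded stream in a fixed order.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, tfs, mirnas = _feature_ids(config)
    features = genes + tfs + mirnas
    tps = list(config.timepoints)
    n_tp = len(tps)
    n_feat = len(features)
    idx_of = {f: i for i, f in enumerate(features)}

    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd,
                          size=n_feat)
    effects = np.zeros((n_feat, n_tp))
    labels = np.zeros((n_feat, n_tp), dtype=np.int8)

    # --- TF modules -------------------------------------------------------
    module_of: dict[str, int] = {}
    cursor = 0
    for mid, spec in enumerate(config.module_specs, start=1):
        members = tfs[cursor:cursor + spec.size]
        cursor += spec.size
        pattern = np.asarray(spec.temporal_pattern, dtype=float)
        for tf in members:
            module_of[tf] = mid
            effects[idx_of[tf]] = pattern
            labels[idx_of[tf]] = np.sign(pattern).astype(np.int8)
    module_tfs = [tf for tf in tfs if tf in module_of]

    def _plant(feature: str) -> None:
        """Plant one DE effect: random sign, windowed or shaped magnitude."""
        i = idx_of[feature]
        sign = 1 if rng.random() < 0.5 else -1
        if config.divergence_pattern is not None:
            shape = np.asarray(config.divergence_pattern, dtype=float)
            effects[i] = sign * config.de_effect * shape
        else:
            # effects persist for at least two consecutive timepoints
            min_len = min(2, n_tp)
            onset = int(rng.integers(0, n_tp - min_len + 1))
            length = int(rng.integers(min_len, n_tp - onset + 1))
            shape = np.zeros(n_tp)
            shape[onset:onset + length] = 1.0
            effects[i] = sign * config.de_effect * shape
        labels[i] = np.sign(effects[i]).astype(np.int8)

    # --- DE genes and miRNAs ---------------------------------------------
    n_de_genes = int(round(config.frac_de_genes * config.n_genes))
    de_genes = sorted(rng.choice(genes, size=n_de_genes, replace=False)) \
        if n_de_genes else []
    for g in de_genes:
        _plant(g)
    n_de_mirnas = int(round(config.frac_de_genes * config.n_mirnas))
    de_mirnas = sorted(rng.choice(mirnas, size=n_de_mirnas, replace=False)) \
        if n_de_mirnas else []
    for m in de_mirnas:
        _plant(m)

    # --- TF → target table; targets inherit their regulator's pattern -----
    tf_target_pairs: list[tuple[str, str]] = []
    regulator_pool = module_tfs if module_tfs else tfs
    claimed_genes: set[str] = set()
    if regulator_pool and de_genes and config.n_tf_target_pairs:
        max_pairs = len(regulator_pool) * len(de_genes)
        attempts = 0
        pair_set: set[tuple[str, str]] = set()
        while (len(pair_set) < min(config.n_tf_target_pairs, max_pairs)
               and attempts < 50 * config.n_tf_target_pairs):
            attempts += 1
            tf = regulator_pool[int(rng.integers(0, len(regulator_pool)))]
            g = de_genes[int(rng.integers(0, len(de_genes)))]
            if (tf, g) in pair_set:
                continue
            pair_set.add((tf, g))
            tf_pattern = effects[idx_of[tf]]
            if g not in claimed_genes and np.any(tf_pattern != 0):
                claimed_genes.add(g)
                sign = 1 if rng.random() < 0.75 else -1  # mostly positive regulation
                effects[idx_of[g]] = sign * tf_pattern
                labels[idx_of[g]] = np.sign(effects[idx_of[g]]).astype(np.int8)
        tf_target_pairs = sorted(pair_set)

    # --- miRNA → target table with suppression plants ---------------------
    mirna_target_pairs: list[tuple[str, str]] = []
    suppression_events: list[tuple[str, str, str]] = []
    suppressor_pool = de_mirnas
    tf_pool = module_tfs if module_tfs else []
    if suppressor_pool and config.n_mirna_target_pairs:
        pair_set = set()
        n_tf_side = config.n_mirna_target_pairs // 2 if tf_pool else 0
        attempts = 0
        while len(pair_set) < n_tf_side and attempts < 50 * max(n_tf_side, 1):
            attempts += 1
            m = suppressor_pool[int(rng.integers(0, len(suppressor_pool)))]
            tf = tf_pool[int(rng.integers(0, len(tf_pool)))]
            if (m, tf) in pair_set:
                continue
            pair_set.add((m, tf))
            # re-plant the miRNA as up-regulated exactly where the TF is not
            # up, so the suppression rule's ground truth is well defined
            tf_up = labels[idx_of[tf]] == 1
            if not tf_up.all():
                shape = (~tf_up).astype(float)
                effects[idx_of[m]] = config.de_effect * shape
                labels[idx_of[m]] = shape.astype(np.int8)
        gene_pool = de_genes if de_genes else genes
        attempts = 0
        while (len(pair_set) < config.n_mirna_target_pairs
               and attempts < 50 * config.n_mirna_target_pairs):
            attempts += 1
            m = suppressor_pool[int(rng.integers(0, len(suppressor_pool)))]
            g = gene_pool[int(rng.integers(0, len(gene_pool)))]
            if (m, g) in pair_set:
                continue
            pair_set.add((m, g))
        mirna_target_pairs = sorted(pair_set)
        tf_set = set(tfs)
        for m, target in mirna_target_pairs:
            if target in tf_set:
                for j, t in enumerate(tps):
                    if labels[idx_of[m], j] == 1 and labels[idx_of[target], j] != 1:
                        suppression_events.append((m, target, t))

    # --- CV genes ---------------------------------------------------------
    n_cv = int(round(config.frac_cv_genes * config.n_genes))
    cv_genes = sorted(rng.choice(genes, size=n_cv, replace=False)) if n_cv else []

    # --- intensities ------------------------------------------------------
    noise_base = rng.normal(0.0, config.noise_sd, size=(n_feat, n_tp)) \
        if config.noise_sd > 0 else np.zeros((n_feat, n_tp))
    noise_treat = rng.normal(0.0, config.noise_sd, size=(n_feat, n_tp)) \
        if config.noise_sd > 0 else np.zeros((n_feat, n_tp))
    log_base = baseline[:, None] + noise_base
    log_treat = baseline[:, None] + effects + noise_treat
    cols = {}
    for j, t in enumerate(tps):
        cols[sample_column(CONDITIONS[0], t)] = np.exp2(log_base[:, j])
    for j, t in enumerate(tps):
        cols[sample_column(CONDITIONS[1], t)] = np.exp2(log_treat[:, j])
    values = pd.DataFrame(cols, index=pd.Index(features, name="feature"))

    classes = pd.Series(
        [CLASS_GENE] * len(genes) + [CLASS_TF] * len(tfs)
        + [CLASS_MIRNA] * len(mirnas),
        index=values.index)
    dataset = ExpressionDataset(values, classes, tuple(tps))

    de_labels = pd.DataFrame(labels, index=values.index, columns=tps)
    truth = GroundTruth(de_labels, module_of, tf_target_pairs,
                        mirna_target_pairs, sorted(set(suppression_events)),
                        cv_genes)
    return dataset, truth


def make_annotation_sets(truth: GroundTruth, dataset: ExpressionDataset,
                         n_random_terms: int = 10, term_size: int = 25,
                         seed: int = 0) -> dict[str, set[str]]:
    """Annotation sets for the enrichment stage: random terms plus one term
    concentrated on the planted DE genes."""
    rng = np.random.default_rng(seed)
    genes = sorted(dataset.features_of_class(CLASS_GENE))
    sets: dict[str, set[str]] = {}
    for i in range(1, n_random_terms + 1):
        size = min(term_size, len(genes))
        sets[f"T{i:03d}"] = set(rng.choice(genes, size=size, replace=False))
    de = [g for g in genes
          if g in truth.de_labels.index
          and (truth.de_labels.loc[g] != 0).any()]
    if de:
        sets["T_planted_de"] = set(de)
    return sets


def write_dataset(dataset: ExpressionDataset, truth: GroundTruth,
                  directory) -> dict[str, Path]:
    """Serialize a simulated dataset to the pipeline's input formats.

    Emits gene and miRNA expression TSVs, TF and CV gene lists, the two
    interaction tables, annotation sets in GMT format, and the ground truth
    as JSON.  Returns a name → path mapping.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    gene_feats = sorted(dataset.features_of_class(CLASS_GENE)) \
        + sorted(dataset.features_of_class(CLASS_TF))
    mirna_feats = sorted(dataset.features_of_class(CLASS_MIRNA))
    paths["genes"] = cio.write_expression_tsv(
        dataset.values.loc[gene_feats], directory / "genes.tsv")
    paths["mirnas"] = cio.write_expression_tsv(
        dataset.values.loc[mirna_feats], directory / "mirnas.tsv")
    paths["tf_genes"] = cio.write_feature_list(
        sorted(dataset.features_of_class(CLASS_TF)), directory / "tf_genes.txt")
    paths["cv_genes"] = cio.write_feature_list(
        truth.cv_genes, directory / "cv_genes.txt")
    paths["tf_targets"] = cio.write_interaction_table(
        truth.tf_target_pairs, directory / "tf_targets.tsv")
    paths["mirna_targets"] = cio.write_interaction_table(
        truth.mirna_target_pairs, directory / "mirna_targets.tsv")
    sets = make_annotation_sets(truth, dataset)
    paths["annotations"] = cio.write_gmt(sets, directory / "annotations.gmt")
    paths["ground_truth"] = directory / "ground_truth.json"
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        return GroundTruth.from_json_dict(json.load(fh))
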