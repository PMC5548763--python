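"""End-to-end pipeline: fold changes → DE → transition → modules →
suppression → regulatory network → hubs → enrichment, with a run manifest.

Every stage writes its outputs as TSV/JSON under the run directory; the
manifest records the configuration echo, library versions, and a SHA-256
hash of every tracked output so a rerun can be compared byte-for-byte.
"""

from __future__ import annotations

import hashlib
import logging
import sys
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as cio
from .config import PipelineConfig
from .datatypes import (CLASS_GENE, CLASS_MIRNA, CLASS_TF, CONDITIONS,
                        DECallTable, ExpressionDataset)
from .de import call_de, classify_emergence, de_summary
from .enrich import AnnotationSets, enrich
from .errors import PipelineError
from .modules import (bisect_network, build_tf_network,
                      module_regulation_summary)
from .preprocess import compute_fold_changes
from .regnet import (build_network, network_targets, cv_enrichment,
                     mirna_target_edges, rank_hubs, suppression_edges,
                     tf_mirna_edges, tf_target_edges, validate_network)
from .simulate import GroundTruth, read_ground_truth
from .suppression import infer_suppression, suppression_counts
from .transition import transition_profile

log = logging.getLogger("cardionet.pipeline")


@dataclass
class PipelineResult:
    out_dir: Path
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def adjusted_rand_index(labels_a: list, labels_b: list) -> float:
    """Adjusted Rand index between two labelings of the same items."""
    if len(labels_a) != len(labels_b):
        raise ValueError("labelings must cover the same items")
    n = len(labels_a)
    if n == 0:
        return 1.0
    from collections import Counter
    pairs = Counter(zip(labels_a, labels_b))
    a_counts = Counter(labels_a)
    b_counts = Counter(labels_b)
    comb2 = lambda x: x * (x - 1) // 2
    sum_ij = sum(comb2(c) for c in pairs.values())
    sum_a = sum(comb2(c) for c in a_counts.values())
    sum_b = sum(comb2(c) for c in b_counts.values())
    total = comb2(n)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def load_inputs(config: PipelineConfig):
    """Read the expression matrices, class lists, and tables from config paths."""
    genes = cio.read_expression_tsv(config.genes_path)
    mirnas = cio.read_expression_tsv(config.mirnas_path)
    tf_list = set(cio.read_feature_list(config.tf_list_path))
    values = pd.concat([genes, mirnas])
    classes = pd.Series(
        [CLASS_MIRNA if f in mirnas.index
         else (CLASS_TF if f in tf_list else CLASS_GENE)
         for f in values.index],
        index=values.index)
    prefix = CONDITIONS[0] + "_"
    timepoints = tuple(c[len(prefix):] for c in genes.columns
                       if c.startswith(prefix))
    dataset = ExpressionDataset(values, classes, timepoints)
    cv = set(cio.read_feature_list(config.cv_list_path)) \
        if config.cv_list_path else set()
    tf_table = cio.read_interaction_table(config.tf_targets_path) \
        if config.tf_targets_path else pd.DataFrame(columns=["regulator", "target"])
    mirna_table = cio.read_interaction_table(config.mirna_targets_path) \
        if config.mirna_targets_path else pd.DataFrame(columns=["regulator", "target"])
    sets = None
    if config.annotations_path:
        raw, desc = cio.read_gmt(config.annotations_path)
        sets = AnnotationSets.from_dict(raw, desc)
    truth = read_ground_truth(config.ground_truth_path) \
        if config.ground_truth_path else None
    return dataset, cv, tf_table, mirna_table, sets, truth


def run_pipeline(config: PipelineConfig, out_dir,
                 dataset: ExpressionDataset | None = None,
                 cv_genes: set | None = None,
                 tf_table: pd.DataFrame | None = None,
                 mirna_table: pd.DataFrame | None = None,
                 annotation_sets: AnnotationSets | None = None,
                 truth: GroundTruth | None = None) -> PipelineResult:
    """Execute every stage and write TSV/JSON outputs plus a manifest.

    Inputs may be passed directly (as from the simulator) or loaded from the
    paths in ``config``.  Any stage error aborts with the stage name; files
    already written are retained.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tracked: dict[str, Path] = {}
    manifest: dict = {"config": config.to_dict(), "seed": config.seed,
                      "versions": {"cardionet": __version__,
                                   "python": sys.version.split()[0],
                                   "numpy": np.__version__,
                                   "pandas": pd.__version__}}

    def stage(name):
        log.info("stage %s", name)
        return _StageTimer(name)

    if dataset is None:
        with _StageTimer("load"):
            try:
                dataset, cv_genes, tf_table, mirna_table, annotation_sets, \
                    truth = load_inputs(config)
            except Exception as exc:
                raise PipelineError("load", exc)
    cv_genes = cv_genes or set()
    if tf_table is None:
        tf_table = pd.DataFrame(columns=["regulator", "target"])
    if mirna_table is None:
        mirna_table = pd.DataFrame(columns=["regulator", "target"])

    tps = list(dataset.timepoints)
    gene_feats = list(dataset.features_of_class(CLASS_GENE)) \
        + list(dataset.features_of_class(CLASS_TF))
    mirna_feats = list(dataset.features_of_class(CLASS_MIRNA))

    # --- fold changes and DE calls ---------------------------------------
    try:
        with stage("fold_changes"):
            fc = compute_fold_changes(dataset)
            tracked["fold_changes"] = cio.write_expression_tsv(
                fc, out_dir / "fold_changes.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("fold_changes", exc)

    try:
        with stage("de"):
            calls_gene = call_de(fc.loc[gene_feats], config.de_sd_multiplier,
                                 config.de_center, config.sd_ddof)
            calls_mirna = call_de(fc.loc[mirna_feats], config.de_sd_multiplier,
                                  config.de_center, config.sd_ddof) \
                if len(mirna_feats) >= 2 else None
            labels = calls_gene.labels if calls_mirna is None \
                else pd.concat([calls_gene.labels, calls_mirna.labels])
            thresholds = calls_gene.thresholds if calls_mirna is None \
                else pd.concat([calls_gene.thresholds, calls_mirna.thresholds],
                               keys=["genes", "mirnas"])
            calls_all = DECallTable(labels, thresholds)
            emergence = classify_emergence(calls_all)
            summary = de_summary(calls_all, emergence, dataset.classes)
            tracked["de_calls"] = cio.write_labels_tsv(labels,
                                                       out_dir / "de_calls.tsv")
            tracked["de_summary"] = cio.write_json(summary,
                                                   out_dir / "de_summary.json")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("de", exc)

    # --- transition profile ----------------------------------------------
    try:
        with stage("transition"):
            profile = transition_profile(dataset,
                                         percentile=config.percentile_cut,
                                         sd_multiplier=config.pcc_filter_sd)
            with open(out_dir / "transition.tsv", "w", newline="") as fh:
                fh.write("class\ttimepoint\tpcc\tn_features\n")
                for clazz in sorted(profile.series):
                    for t, r in profile.series[clazz]:
                        fh.write(f"{clazz}\t{t}\t{r!r}\t"
                                 f"{profile.n_features[clazz]}\n")
            tracked["transition"] = out_dir / "transition.tsv"
            tracked["transition_summary"] = cio.write_json(
                {"argmin": profile.argmin,
                 "n_features": profile.n_features},
                out_dir / "transition_summary.json")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("transition", exc)

    # --- TF co-expression modules ----------------------------------------
    try:
        with stage("modules"):
            de_tfs = [f for f in calls_gene.de_features()
                      if dataset.classes.loc[f] == CLASS_TF]
            tf_profiles = dataset.condition(CONDITIONS[1], de_tfs)
            network = build_tf_network(tf_profiles, config.pcc_threshold)
            partition = bisect_network(network, config.min_module_size)
            reg_summary = module_regulation_summary(partition, calls_gene)
            from .regnet import Edge
            coexp_edges = [Edge(u, v, "coexpression", 1, d["pcc"])
                           for u, v, d in network.edges(data=True)]
            tracked["tf_network"] = cio.write_edge_list(
                coexp_edges, out_dir / "tf_network.tsv")
            tracked["modules"] = cio.write_partition_tsv(
                partition.module_of, out_dir / "modules.tsv")
            with open(out_dir / "module_summary.tsv", "w", newline="") as fh:
                fh.write("module\ttimepoint\tup\tdown\n")
                for (mid, t), row in reg_summary.iterrows():
                    fh.write(f"{mid}\t{t}\t{row['up']}\t{row['down']}\n")
            tracked["module_summary"] = out_dir / "module_summary.tsv"
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("modules", exc)

    # --- miRNA suppression -----------------------------------------------
    try:
        with stage("suppression"):
            tf_feats = list(dataset.features_of_class(CLASS_TF))
            calls_tf = DECallTable(calls_gene.labels.loc[
                [f for f in tf_feats if f in calls_gene.labels.index]],
                calls_gene.thresholds)
            tf_set = set(tf_feats)
            mirna_tf_table = mirna_table[
                mirna_table["target"].astype(str).isin(tf_set)]
            if calls_mirna is not None:
                events = infer_suppression(calls_mirna, calls_tf, mirna_tf_table)
            else:
                events = []
            counts = suppression_counts(events, tuple(tps))
            with open(out_dir / "suppression_events.tsv", "w", newline="") as fh:
                fh.write("mirna\ttf\ttimepoint\n")
                for ev in events:
                    fh.write(f"{ev.mirna}\t{ev.tf}\t{ev.timepoint}\n")
            tracked["suppression_events"] = out_dir / "suppression_events.tsv"
            tracked["suppression_counts"] = cio.write_json(
                counts, out_dir / "suppression_counts.json")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("suppression", exc)

    # --- regulatory network and hubs -------------------------------------
    try:
        with stage("network"):
            de_features = set(calls_all.de_features())
            profiles_tab = dataset.condition(CONDITIONS[1])
            profiles_sham = dataset.condition(CONDITIONS[0])
            de_tf_set = {f for f in de_features
                         if dataset.classes.loc[f] == CLASS_TF}
            de_mirna_set = {f for f in de_features
                            if dataset.classes.loc[f] == CLASS_MIRNA}
            edges = []
            edges += tf_target_edges(profiles_tab, de_features, tf_table,
                                     config.pcc_threshold)
            edges += mirna_target_edges(profiles_tab, de_features, mirna_table,
                                        config.pcc_threshold)
            edges += tf_mirna_edges(profiles_tab, profiles_sham, de_tf_set,
                                    de_mirna_set, config.pcc_threshold,
                                    config.tab_specific_tf_mirna_edges)
            edges += suppression_edges(events)
            net = build_network(edges, dataset.classes, cv_genes, emergence)
            hubs = rank_hubs(net, emergence, calls_all,
                             config.hub_k_tf, config.hub_k_mirna)
            tracked["network_edges"] = cio.write_edge_list(
                sorted(( __edge_from_net(net, u, v) for u, v in net.edges()),
                       key=lambda e: (e.source, e.target)),
                out_dir / "network_edges.tsv")
            with open(out_dir / "network_nodes.tsv", "w", newline="") as fh:
                fh.write("node\tclass\tcv\tfirst_emergence\n")
                for node in sorted(net.nodes):
                    d = net.nodes[node]
                    fh.write(f"{node}\t{d['clazz']}\t{int(d['cv'])}\t"
                             f"{d['first_emergence'] or ''}\n")
            tracked["network_nodes"] = out_dir / "network_nodes.tsv"
            tracked["hubs"] = _write_hub_tsv(hubs, tps, out_dir / "hubs.tsv")

            targets = network_targets(net)
            bg = {f for f in de_features
                  if dataset.classes.loc[f] in (CLASS_GENE, CLASS_TF)}
            cv_report: dict = {"n_targets": len(targets)}
            if targets & bg and bg:
                prop, p = cv_enrichment(targets & bg, cv_genes, bg)
                cv_report.update({"cv_proportion": prop, "p_value": p,
                                  "background": "de_genes",
                                  "n_background": len(bg)})
            tracked["cv_enrichment"] = cio.write_json(
                cv_report, out_dir / "cv_enrichment.json")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("network", exc)

    # --- annotation-set enrichment ---------------------------------------
    try:
        with stage("enrichment"):
            rows = []
            if annotation_sets is not None:
                background = set(dataset.features_of_class(CLASS_GENE))
                query = {f for f in calls_all.de_features()
                         if dataset.classes.loc[f] == CLASS_GENE}
                if query:
                    for r in enrich(query, annotation_sets, background,
                                    config.fdr):
                        rows.append(r)
            with open(out_dir / "enrichment.tsv", "w", newline="") as fh:
                fh.write("term\tdescription\toverlap\tquery_size\tterm_size\t"
                         "background_size\tp_value\tq_value\tenriched\n")
                for r in rows:
                    fh.write(f"{r.term}\t{r.description}\t{r.overlap}\t"
                             f"{r.query_size}\t{r.term_size}\t"
                             f"{r.background_size}\t{r.p_value!r}\t"
                             f"{r.q_value!r}\t{int(r.enriched)}\n")
            tracked["enrichment"] = out_dir / "enrichment.tsv"
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("enrichment", exc)

    # --- ground-truth recovery metrics -----------------------------------
    if truth is not None:
        with stage("recovery"):
            manifest["recovery"] = _recovery_metrics(
                truth, calls_all, partition, events)

    manifest["outputs"] = {name: {"path": str(p.relative_to(out_dir)),
                                  "sha256": _sha256(p)}
                           for name, p in sorted(tracked.items())}
    cio.write_json(manifest, out_dir / "manifest.json")
    return PipelineResult(out_dir, manifest)


def __edge_from_net(net, u, v):
    from .regnet import Edge
    d = net.edges[u, v]
    return Edge(u, v, d["etype"], d["sign"], d["pcc"])


def _write_hub_tsv(hubs, timepoints, path) -> Path:
    with open(path, "w", newline="") as fh:
        header = ["timepoint", "class", "rank", "regulator", "total",
                  "outward", "outward_pos", "outward_neg",
                  "inward", "inward_pos", "inward_neg", "cv"]
        header += [f"label_{t}" for t in timepoints]
        fh.write("\t".join(header) + "\n")
        for t in timepoints:
            for clazz in ("tf", "mirna"):
                for rank, h in enumerate(hubs.get(t, {}).get(clazz, []),
                                         start=1):
                    row = [t, clazz, str(rank), h.regulator, str(h.total),
                           str(h.outward), str(h.outward_pos),
                           str(h.outward_neg), str(h.inward),
                           str(h.inward_pos), str(h.inward_neg),
                           str(int(h.cv))]
                    row += [str(h.labels.get(tp, 0)) for tp in timepoints]
                    fh.write("\t".join(row) + "\n")
    return Path(path)


def _recovery_metrics(truth: GroundTruth, calls: DECallTable,
                      partition, events) -> dict:
    out: dict = {}
    planted = truth.de_labels
    common = planted.index.intersection(calls.labels.index)
    planted_de = set(common[(planted.loc[common] != 0).any(axis=1)])
    called_de = set(calls.de_features()) & set(common)
    if planted_de:
        out["de_sensitivity"] = len(planted_de & called_de) / len(planted_de)
    non_de = set(common) - planted_de
    if non_de:
        out["de_false_positive_rate"] = len(non_de & called_de) / len(non_de)
    if truth.module_of:
        members = sorted(truth.module_of)
        truth_labels = [truth.module_of[m] for m in members]
        found_labels = [partition.module_of.get(m, -1) for m in members]
        out["module_ari"] = adjusted_rand_index(truth_labels, found_labels)
    if truth.suppression_events:
        planted_ev = {tuple(e) for e in truth.suppression_events}
        found_ev = {(e.mirna, e.tf, e.timepoint) for e in events}
        out["suppression_recall"] = \
            len(planted_ev & found_ev) / len(planted_ev)
    return out


class _StageTimer:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.monotonic()
        return self

    def __exit__(self, *exc):
        log.info("stage %s finished in %.2fs", self.name,
                 time.monotonic() - self.t0)
        return False
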