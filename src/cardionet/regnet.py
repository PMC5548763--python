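"""Signed TF–miRNA–gene regulatory network construction and hub ranking.

Three edge types are assembled from DE features' treatment-condition
profiles plus interaction tables:

* ``tf_target``   — TF → gene, sign = sign of the profile PCC, requires a
  supporting TF-target table row and |PCC| >= threshold;
* ``mirna_target`` — miRNA → target (negative), requires a table row and
  PCC <= -threshold;
* ``tf_mirna``    — TF → miRNA positive co-expression specific to the
  treatment condition (PCC_treatment >= threshold, PCC_baseline below it);
* ``suppression`` — miRNA → TF events from the suppression rule, merged as
  negative edges; a pair already present as ``mirna_target`` is not
  duplicated.

Hubs are regulators ranked, within the set first emerging as DE at a given
timepoint, by total (inward + outward) degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy.stats import hypergeom

from .datatypes import (CLASS_MIRNA, CLASS_TF, DECallTable, EmergenceTable,
                        pearson)
from .suppression import SuppressionEvent

EDGE_TF_TARGET = "tf_target"
EDGE_MIRNA_TARGET = "mirna_target"
EDGE_TF_MIRNA = "tf_mirna"
EDGE_SUPPRESSION = "suppression"


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    etype: str
    sign: int
    pcc: float


def _profile_pcc(profiles: pd.DataFrame, a: str, b: str) -> float:
    return pearson(profiles.loc[a].to_numpy(dtype=float),
                   profiles.loc[b].to_numpy(dtype=float))


def tf_target_edges(profiles: pd.DataFrame, de_features,
                    tf_table: pd.DataFrame,
                    threshold: float = 0.9) -> list[Edge]:
    """TF → target edges: table-supported pairs co-expressed either way.

    ``tf_table`` columns: ``regulator`` (TF), ``target`` (gene).  Both
    endpoints must be DE and have profiles; the edge sign is the sign of
    the treatment-profile PCC, kept when |PCC| >= threshold.
    """
    de = set(de_features)
    edges = []
    seen = set()
    for row in tf_table.itertuples(index=False):
        tf, target = str(row.regulator), str(row.target)
        if (tf, target) in seen or tf == target:
            continue
        seen.add((tf, target))
        if tf not in de or target not in de:
            continue
        if tf not in profiles.index or target not in profiles.index:
            continue
        r = _profile_pcc(profiles, tf, target)
        if not np.isnan(r) and abs(r) >= threshold:
            edges.append(Edge(tf, target, EDGE_TF_TARGET,
                              1 if r > 0 else -1, float(r)))
    return edges


def mirna_target_edges(profiles: pd.DataFrame, de_features,
                       mirna_table: pd.DataFrame,
                       threshold: float = 0.9) -> list[Edge]:
    """miRNA → target negative edges: table-supported, PCC <= -threshold."""
    de = set(de_features)
    edges = []
    seen = set()
    for row in mirna_table.itertuples(index=False):
        mirna, target = str(row.regulator), str(row.target)
        if (mirna, target) in seen:
            continue
        seen.add((mirna, target))
        if mirna not in de or target not in de:
            continue
        if mirna not in profiles.index or target not in profiles.index:
            continue
        r = _profile_pcc(profiles, mirna, target)
        if not np.isnan(r) and r <= -threshold:
            edges.append(Edge(mirna, target, EDGE_MIRNA_TARGET, -1, float(r)))
    return edges


def tf_mirna_edges(profiles_treatment: pd.DataFrame,
                   profiles_baseline: pd.DataFrame,
                   de_tfs, de_mirnas,
                   threshold: float = 0.9,
                   treatment_specific: bool = True) -> list[Edge]:
    """TF → miRNA positive co-expression edges specific to the treatment.

    An edge requires PCC >= threshold in the treatment condition and, when
    ``treatment_specific`` (default), PCC < threshold in the baseline.
    """
    edges = []
    for tf in sorted(map(str, de_tfs)):
        if tf not in profiles_treatment.index:
            continue
        for mirna in sorted(map(str, de_mirnas)):
            if mirna not in profiles_treatment.index:
                continue
            r_t = _profile_pcc(profiles_treatment, tf, mirna)
            if np.isnan(r_t) or r_t < threshold:
                continue
            if treatment_specific:
                if (tf in profiles_baseline.index
                        and mirna in profiles_baseline.index):
                    r_b = _profile_pcc(profiles_baseline, tf, mirna)
                    if not np.isnan(r_b) and r_b >= threshold:
                        continue
            edges.append(Edge(tf, mirna, EDGE_TF_MIRNA, 1, float(r_t)))
    return edges


def suppression_edges(events: list[SuppressionEvent]) -> list[Edge]:
    """Collapse suppression events to one negative miRNA → TF edge per pair."""
    pairs = sorted({(ev.mirna, ev.tf) for ev in events})
    return [Edge(m, t, EDGE_SUPPRESSION, -1, float("nan")) for m, t in pairs]


def build_network(edges: list[Edge], node_classes: pd.Series,
                  cv_genes: set | frozenset = frozenset(),
                  emergence: EmergenceTable | None = None) -> nx.DiGraph:
    """Merge typed edge lists into one directed network with node metadata.

    Duplicate (source, target) pairs collapse; the first edge in the input
    order wins (callers pass table-backed edges before derived suppression
    edges so the better-attributed edge is kept).  Dangling endpoints raise.
    """
    net = nx.DiGraph()
    first = None if emergence is None else emergence.first_emergence
    for edge in edges:
        for node in (edge.source, edge.target):
            if node not in node_classes.index:
                raise ValueError(f"edge endpoint {node!r} has no class annotation")
            if node not in net:
                net.add_node(
                    node,
                    clazz=node_classes.loc[node],
                    cv=bool(node in cv_genes),
                    first_emergence=(None if first is None
                                     else first.get(node)))
        if net.has_edge(edge.source, edge.target):
            continue
        net.add_edge(edge.source, edge.target, etype=edge.etype,
                     sign=edge.sign, pcc=edge.pcc)
    return net


def validate_network(net: nx.DiGraph, profiles_treatment: pd.DataFrame,
                     tf_table: pd.DataFrame | None = None,
                     mirna_table: pd.DataFrame | None = None,
                     threshold: float = 0.9) -> None:
    """Check every edge against its type's invariant; raise on violation."""
    tf_pairs = (set(map(tuple, tf_table[["regulator", "target"]].astype(str)
                        .itertuples(index=False)))
                if tf_table is not None else None)
    mir_pairs = (set(map(tuple, mirna_table[["regulator", "target"]].astype(str)
                         .itertuples(index=False)))
                 if mirna_table is not None else None)
    for u, v, data in net.edges(data=True):
        etype = data["etype"]
        if etype == EDGE_TF_TARGET:
            if tf_pairs is not None and (u, v) not in tf_pairs:
                raise ValueError(f"tf_target edge {u}->{v} lacks table support")
            r = _profile_pcc(profiles_treatment, u, v)
            if abs(r) < threshold:
                raise ValueError(f"tf_target edge {u}->{v} |PCC|={r:.3f}")
        elif etype == EDGE_MIRNA_TARGET:
            if mir_pairs is not None and (u, v) not in mir_pairs:
                raise ValueError(f"mirna_target edge {u}->{v} lacks table support")
            r = _profile_pcc(profiles_treatment, u, v)
            if r > -threshold:
                raise ValueError(f"mirna_target edge {u}->{v} PCC={r:.3f}")
        elif etype == EDGE_TF_MIRNA:
            r = _profile_pcc(profiles_treatment, u, v)
            if r < threshold:
                raise ValueError(f"tf_mirna edge {u}->{v} PCC={r:.3f}")
        elif etype != EDGE_SUPPRESSION:
            raise ValueError(f"unknown edge type {etype!r}")
        if data["sign"] not in (-1, 1):
            raise ValueError(f"edge {u}->{v} has invalid sign {data['sign']!r}")


@dataclass
class HubRecord:
    """Degree bookkeeping for one regulator, split by direction and sign."""

    regulator: str
    clazz: str
    outward_pos: int
    outward_neg: int
    inward_pos: int
    inward_neg: int
    first_emergence: str | None
    cv: bool
    labels: dict[str, int] = field(default_factory=dict)

    @property
    def outward(self) -> int:
        return self.outward_pos + self.outward_neg

    @property
    def inward(self) -> int:
        return self.inward_pos + self.inward_neg

    @property
    def total(self) -> int:
        return self.outward + self.inward


def hub_record(net: nx.DiGraph, node: str,
               calls: DECallTable | None = None) -> HubRecord:
    data = net.nodes[node]
    opos = sum(1 for _, _, d in net.out_edges(node, data=True) if d["sign"] > 0)
    oneg = net.out_degree(node) - opos
    ipos = sum(1 for _, _, d in net.in_edges(node, data=True) if d["sign"] > 0)
    ineg = net.in_degree(node) - ipos
    labels = {}
    if calls is not None and node in calls.labels.index:
        labels = {t: int(calls.labels.at[node, t]) for t in calls.timepoints}
    return HubRecord(node, data.get("clazz", ""), opos, oneg, ipos, ineg,
                     data.get("first_emergence"), bool(data.get("cv", False)),
                     labels)


def rank_hubs(net: nx.DiGraph, emergence: EmergenceTable,
              calls: DECallTable | None = None,
              k_tf: int = 5, k_mirna: int = 3) -> dict[str, dict[str, list[HubRecord]]]:
    """Top regulators per first-emergence timepoint, by total degree.

    Returns ``{timepoint: {"tf": [...], "mirna": [...]}}``; within a
    timepoint, regulators of each class are sorted by total degree
    descending, ties broken by id, and truncated to the class's k.
    """
    first = emergence.first_emergence
    out: dict[str, dict[str, list[HubRecord]]] = {
        t: {"tf": [], "mirna": []} for t in emergence.timepoints}
    for node in net.nodes:
        clazz = net.nodes[node].get("clazz")
        if clazz not in (CLASS_TF, CLASS_MIRNA):
            continue
        t = first.get(node)
        if t is None or t not in out:
            continue
        out[t][clazz].append(hub_record(net, node, calls))
    for t in out:
        for clazz, k in ((CLASS_TF, k_tf), (CLASS_MIRNA, k_mirna)):
            ranked = sorted(out[t][clazz],
                            key=lambda h: (-h.total, h.regulator))
            out[t][clazz] = ranked[:k]
    return out


def network_targets(net: nx.DiGraph) -> set:
    """Nodes with at least one inward regulatory edge."""
    return {v for _, v in net.edges}


def cv_enrichment(target_set, cv_list, background) -> tuple[float, float]:
    """Proportion of CV-flagged targets and a one-sided hypergeometric p.

    Tests over-representation of ``cv_list`` members in ``target_set``
    relative to ``background`` (which must contain the targets).
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    targets = set(target_set) & background
    if not targets:
        raise ValueError("empty target set")
    cv = set(cv_list) & background
    k = len(targets & cv)
    proportion = k / len(targets)
    p = float(hypergeom.sf(k - 1, len(background), len(cv), len(targets)))
    return proportion, p
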