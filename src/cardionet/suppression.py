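"""Per-timepoint miRNA → TF suppression inference.

A DE miRNA putatively suppresses a DE TF gene at a timepoint when (1) the
miRNA targets the TF according to the interaction table, (2) the miRNA is
up-regulated at that timepoint, and (3) the TF is *not* up-regulated there
(label 0 or -1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .datatypes import DECallTable

log = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class SuppressionEvent:
    mirna: str
    tf: str
    timepoint: str


def infer_suppression(calls_mirna: DECallTable, calls_tf: DECallTable,
                      target_table: pd.DataFrame) -> list[SuppressionEvent]:
    """Emit every (miRNA, TF, timepoint) triple satisfying the three-part rule.

    ``target_table`` must have columns ``regulator`` (miRNA) and ``target``
    (TF gene).  Rows referencing identifiers absent from the call tables are
    skipped with a warning.  Only DE features can participate.
    """
    if calls_mirna.timepoints != calls_tf.timepoints:
        raise ValueError("call tables have different timepoint axes")
    tps = calls_mirna.timepoints
    mirna_labels = calls_mirna.labels
    tf_labels = calls_tf.labels
    de_mirnas = set(calls_mirna.de_features())
    de_tfs = set(calls_tf.de_features())

    events: list[SuppressionEvent] = []
    seen_pairs = set()
    for row in target_table.itertuples(index=False):
        mirna, tf = str(row.regulator), str(row.target)
        if (mirna, tf) in seen_pairs:
            continue
        seen_pairs.add((mirna, tf))
        if mirna not in mirna_labels.index or tf not in tf_labels.index:
            log.warning("skipping unknown pair in target table: %s -> %s",
                        mirna, tf)
            continue
        if mirna not in de_mirnas or tf not in de_tfs:
            continue
        for t in tps:
            if mirna_labels.at[mirna, t] == 1 and tf_labels.at[tf, t] != 1:
                events.append(SuppressionEvent(mirna, tf, t))
    return sorted(events)


def suppression_counts(events: list[SuppressionEvent],
                       timepoints: tuple[str, ...]) -> dict:
    """Distinct suppressing-miRNA and suppressed-TF counts, per tp and overall."""
    per_tp = {t: {"mirnas": set(), "tfs": set()} for t in timepoints}
    all_mirnas: set[str] = set()
    all_tfs: set[str] = set()
    for ev in events:
        per_tp[ev.timepoint]["mirnas"].add(ev.mirna)
        per_tp[ev.timepoint]["tfs"].add(ev.tf)
        all_mirnas.add(ev.mirna)
        all_tfs.add(ev.tf)
    return {
        "per_timepoint": {
            t: {"n_suppressing_mirnas": len(d["mirnas"]),
                "n_suppressed_tfs": len(d["tfs"])}
            for t, d in per_tp.items()},
        "overall": {"n_suppressing_mirnas": len(all_mirnas),
                    "n_suppressed_tfs": len(all_tfs),
                    "n_events": len(events)},
    }
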