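"""Hypergeometric over-representation analysis with Benjamini–Hochberg FDR.

A query gene set is tested against each annotation set (GMT-style term →
members) over a declared background of all expressed genes.  Terms with no
overlap are reported with p = 1 so the number of tests is stable.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class AnnotationSets:
    """Term id → (description, member gene set)."""

    descriptions: dict[str, str]
    members: dict[str, frozenset]

    @classmethod
    def from_dict(cls, sets: dict[str, set], descriptions: dict[str, str] | None = None):
        desc = descriptions or {t: "" for t in sets}
        return cls({t: desc.get(t, "") for t in sets},
                   {t: frozenset(m) for t, m in sets.items()})

    def terms(self) -> list[str]:
        return sorted(self.members)


@dataclass
class EnrichmentResult:
    term: str
    description: str
    overlap: int
    query_size: int
    term_size: int
    background_size: int
    p_value: float
    q_value: float
    enriched: bool


def enrich(query, sets: AnnotationSets, background,
           fdr: float = 0.05) -> list[EnrichmentResult]:
    """One-sided hypergeometric upper-tail test per term, BH-adjusted.

    ``query`` must be a subset of ``background``; set members outside the
    background are ignored.  Results are sorted by (q, p, term id) and
    flagged enriched when q < ``fdr``.
    """
    background = frozenset(background)
    query = frozenset(query)
    if not background:
        raise ValueError("empty background")
    if not query:
        raise ValueError("empty query")
    if not query <= background:
        extra = sorted(query - background)[:5]
        raise ValueError(f"query genes outside background: {extra}")

    terms = sets.terms()
    if not terms:
        return []
    rows = []
    for term in terms:
        members = sets.members[term] & background
        k = len(members & query)
        # P(overlap >= k) drawing |query| from background with |members| marked
        p = float(hypergeom.sf(k - 1, len(background), len(members), len(query)))
        rows.append((term, k, len(members), min(p, 1.0)))

    pvals = [r[3] for r in rows]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(term, sets.descriptions.get(term, ""), k, len(query),
                         size, len(background), p, float(q), bool(q < fdr))
        for (term, k, size, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.q_value, r.p_value, r.term))
    return results


def background_excluding_transcription_terms(background, exclusion) -> frozenset:
    """Background minus an exclusion gene set; error if nothing remains."""
    remaining = frozenset(background) - frozenset(exclusion)
    if not remaining:
        raise ValueError("exclusion removes the entire background")
    return remaining
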