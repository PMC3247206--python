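"""Completeness, redundancy and annotation procedures over hit tables.

All operations consume the 12-column outfmt-6 dialect (see
:mod:`coraltrx.io`).  Completeness is judged against a reference
transcript set (fraction of reference sequences hit, and the modal
query/subject length ratio); redundancy against a panel of conserved
single-copy orthologs, whose mean number of distinct assembled matches
estimates residual fragmentation and deflates the contig count into a
gene-count estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_AVOID_KEYWORDS = ("uncharacterized protein", "predicted protein")


@dataclass
class AnnotationRecord:
    query_id: str
    chosen_subject: str
    description: str
    rank_used: int  # 1 = best hit
    informative: bool


@dataclass
class CompletenessSummary:
    pct_reference_hit: float
    length_ratios: list[float] = field(default_factory=list, repr=False)
    modal_ratio: float | None = None
    redundancy: float | None = None
    gene_count_estimate: int | None = None


def dedup_reference(
    lengths: dict[str, int], self_hits: pd.DataFrame | None, similarity_threshold: float = 90.0
) -> list[str]:
    """Greedy longest-first removal of near-duplicate reference sequences.

    A sequence is dropped when it has a hit with percent identity above
    ``similarity_threshold`` to an already-kept (longer or tie-earlier)
    sequence.  Requires an all-vs-all self-hit table; self-hits of a
    sequence to itself are ignored.
    """
    if not 0 < similarity_threshold <= 100:
        raise ValueError("similarity_threshold must be in (0, 100]")
    if self_hits is None:
        raise ValueError(
            "dedup_reference needs an all-vs-all self-hit table; run the "
            "reference against itself and supply the outfmt-6 result"
        )
    sim: dict[str, dict[str, float]] = {}
    for row in self_hits.itertuples(index=False):
        q, s = row.query_id, row.subject_id
        if q == s:
            continue
        ident = float(row.pct_identity)
        sim.setdefault(q, {})
        sim[q][s] = max(sim[q].get(s, 0.0), ident)
        sim.setdefault(s, {})
        sim[s][q] = max(sim[s].get(q, 0.0), ident)
    order = sorted(lengths, key=lambda sid: (-lengths[sid], sid))
    kept: list[str] = []
    kept_set: set[str] = set()
    for sid in order:
        neighbours = sim.get(sid, {})
        if any(
            other in kept_set and ident > similarity_threshold
            for other, ident in neighbours.items()
        ):
            continue
        kept.append(sid)
        kept_set.add(sid)
    return kept


def best_unique_hits(
    hits: pd.DataFrame, min_bitscore: float = 45.0
) -> dict[str, str]:
    """One-to-one query-to-subject map by greedy descending bitscore.

    Hits below ``min_bitscore`` are discarded; remaining hits are taken
    best-first (ties by ascending e-value, then subject id, then query
    id), each query and each subject used at most once.
    """
    ok = hits[hits["bitscore"] >= min_bitscore]
    ok = ok.sort_values(
        ["bitscore", "evalue", "subject_id", "query_id"],
        ascending=[False, True, True, True],
        kind="mergesort",
    )
    mapping: dict[str, str] = {}
    used_subjects: set[str] = set()
    for row in ok.itertuples(index=False):
        if row.query_id in mapping or row.subject_id in used_subjects:
            continue
        mapping[row.query_id] = row.subject_id
        used_subjects.add(row.subject_id)
    return mapping


def length_ratio_summary(
    mapping: dict[str, str],
    query_lens: dict[str, int],
    subject_lens: dict[str, int],
    n_reference: int | None = None,
    bin_width: float = 2.0,
) -> CompletenessSummary:
    """Percent length-ratio distribution of mapped pairs.

    Ratio = 100 * query length / subject length per mapped pair; the
    modal ratio is the centre of the fullest ``bin_width``-percent
    histogram bin.  ``pct_reference_hit`` is the percentage of the
    reference (subject) set with a mapped partner.
    """
    ratios = [
        100.0 * query_lens[q] / subject_lens[s] for q, s in mapping.items()
    ]
    total_ref = n_reference if n_reference is not None else len(subject_lens)
    pct_hit = 100.0 * len(set(mapping.values())) / total_ref if total_ref else 0.0
    modal = None
    if ratios:
        top = max(ratios)
        edges = np.arange(0.0, top + 2 * bin_width, bin_width)
        counts, edges = np.histogram(ratios, bins=edges)
        k = int(np.argmax(counts))
        modal = float((edges[k] + edges[k + 1]) / 2.0)
    return CompletenessSummary(
        pct_reference_hit=pct_hit, length_ratios=ratios, modal_ratio=modal
    )


def redundancy_factor(
    hits: pd.DataFrame,
    ortholog_ids: list[str],
    min_bitscore: float = 130.0,
    max_evalue: float = 2e-38,
) -> dict:
    """Mean number of distinct assembled sequences per single-copy ortholog.

    Counts distinct query sequences hitting each ortholog (subject)
    above both cutoffs.  Orthologs with zero hits are excluded from the
    mean and reported separately.  Returns a dict with ``mean``, ``sd``,
    ``min``/``max``, ``frac_multiple``, ``n_hit`` and ``n_unhit``.
    """
    if not ortholog_ids:
        raise ValueError("ortholog list must be non-empty")
    ok = hits[
        (hits["bitscore"] >= min_bitscore)
        & (hits["evalue"] <= max_evalue)
        & hits["subject_id"].isin(set(ortholog_ids))
    ]
    per_ortholog = ok.groupby("subject_id")["query_id"].nunique()
    counts = np.array(
        [per_ortholog.get(o, 0) for o in ortholog_ids], dtype=int
    )
    hit_counts = counts[counts > 0]
    if hit_counts.size == 0:
        return {
            "mean": math.nan, "sd": math.nan, "min": 0, "max": 0,
            "frac_multiple": 0.0, "n_hit": 0, "n_unhit": len(ortholog_ids),
        }
    return {
        "mean": float(hit_counts.mean()),
        "sd": float(hit_counts.std(ddof=1)) if hit_counts.size > 1 else 0.0,
        "min": int(hit_counts.min()),
        "max": int(hit_counts.max()),
        "frac_multiple": float((hit_counts > 1).mean()),
        "n_hit": int(hit_counts.size),
        "n_unhit": int((counts == 0).sum()),
    }


def gene_count_estimate(n_contigs: int, redundancy: float) -> int:
    """Deflate the contig count by the redundancy factor (floored)."""
    if redundancy <= 0:
        raise ValueError("redundancy must be positive")
    if n_contigs < 0:
        raise ValueError("n_contigs must be non-negative")
    return int(n_contigs // redundancy)


def select_informative_annotation(
    ranked_hits: list[tuple[str, str, float, float]],
    avoid_keywords: tuple[str, ...] = DEFAULT_AVOID_KEYWORDS,
    min_bitscore: float = 45.0,
    max_evalue: float = 1e-5,
    query_id: str = "",
) -> AnnotationRecord | None:
    """Pick the best informative annotation from rank-ordered hits.

    ``ranked_hits`` rows are ``(subject_id, description, bitscore,
    evalue)`` in rank order (best first).  Hits must clear bitscore
    > ``min_bitscore`` and e-value < ``max_evalue``; the first passing
    hit whose description contains no avoid keyword (case-insensitive
    substring) wins.  When every passing hit is uninformative the best
    passing one is returned with ``informative=False``; with no passing
    hits the query stays unannotated (None).
    """
    avoid = tuple(k.lower() for k in avoid_keywords)
    fallback: AnnotationRecord | None = None
    for rank, (subject, desc, bitscore, evalue) in enumerate(ranked_hits, start=1):
        if bitscore <= min_bitscore or evalue >= max_evalue:
            continue
        informative = not any(k in desc.lower() for k in avoid)
        rec = AnnotationRecord(
            query_id=query_id,
            chosen_subject=subject,
            description=desc,
            rank_used=rank,
            informative=informative,
        )
        if informative:
            return rec
        if fallback is None:
            fallback = rec
    return fallback


def annotation_efficiency(matched: int, total: int) -> int:
    """Percentage of reference genes recovered in the annotation, rounded."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * matched / total)
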