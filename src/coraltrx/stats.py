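"""Exact-test enrichment and likelihood-ratio-test utilities.

GO-term enrichment of a subset against its background uses Fisher's
exact test per term with Benjamini-Hochberg false-discovery-rate
adjustment.  The likelihood-ratio test compares nested models via
2*(lnL_alt - lnL_null) against a chi-squared upper tail — the statistic
used, e.g., for branch-site tests of positive selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class ContingencyTable2x2:
    """Counts for one term: a = term in subset, b = term in background
    outside the subset, c = subset without the term, d = neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def has_zero_margin(self) -> bool:
        return (
            self.a + self.b == 0 or self.c + self.d == 0
            or self.a + self.c == 0 or self.b + self.d == 0
        )


@dataclass
class EnrichmentResult:
    go_id: str
    n_subset: int  # term count in subset
    n_background: int  # term count in the whole background
    pct_subset: float
    pct_background: float
    p_raw: float
    p_adjusted: float
    go_term: str = ""


@dataclass
class LrtResult:
    lnL_null: float
    lnL_alt: float
    df: int
    two_delta: float
    p: float

    @property
    def p_display(self) -> float:
        """p rounded to two decimals, the precision papers print."""
        return round(self.p, 2)


def fisher_exact_2x2(t: ContingencyTable2x2, side: str = "two-sided") -> float:
    """Exact hypergeometric p for a 2x2 table.

    ``side`` is ``"two-sided"`` (sum of tables with point probability
    at most the observed one) or ``"greater"`` (enrichment of cell a).
    A zero margin makes the test undefined; p = 1 with a warning.
    """
    if side not in ("two-sided", "greater"):
        raise ValueError(f"unknown side: {side!r}")
    if t.has_zero_margin:
        warnings.warn("zero margin: Fisher's exact test is undefined, p = 1")
        return 1.0
    _, p = sps.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative=side)
    return float(min(p, 1.0))


def adjust_pvalues(ps, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1.

    Output order matches input order; the adjusted values are invariant
    to permuting the input.
    """
    if method.lower() not in ("bh", "fdr_bh"):
        raise ValueError(f"unsupported method: {method!r}")
    ps = np.asarray(ps, dtype=float)
    if ps.size == 0:
        return ps
    return sps.false_discovery_control(ps, method="bh")


def enrich_terms(
    subset: set[str],
    background: set[str],
    go_map: dict[str, set[str]],
    alpha: float | None = 0.05,
    side: str = "greater",
) -> list[EnrichmentResult]:
    """Per-term Fisher enrichment of ``subset`` against ``background``.

    One test per GO term annotated to any background member; counts and
    percentages are reported for both sets.  Results are BH-adjusted,
    filtered at adjusted p <= ``alpha`` (pass ``alpha=None`` to keep
    all), and sorted by raw p (ties by term id).
    """
    if not subset <= background:
        raise ValueError("subset must be contained in background")
    term_members: dict[str, set[str]] = {}
    for sid in background:
        for term in go_map.get(sid, ()):
            term_members.setdefault(term, set()).add(sid)
    n_sub, n_bg = len(subset), len(background)
    if not term_members or n_sub == 0:
        return []
    terms = sorted(term_members)
    p_raw = []
    for term in terms:
        members = term_members[term]
        a = len(members & subset)
        b = len(members) - a
        c = n_sub - a
        d = (n_bg - n_sub) - b
        p_raw.append(fisher_exact_2x2(ContingencyTable2x2(a, b, c, d), side=side))
    p_adj = adjust_pvalues(p_raw)
    results = []
    for term, pr, pa in zip(terms, p_raw, p_adj):
        members = term_members[term]
        a = len(members & subset)
        results.append(
            EnrichmentResult(
                go_id=term,
                n_subset=a,
                n_background=len(members),
                pct_subset=round(100.0 * a / n_sub, 1),
                pct_background=round(100.0 * len(members) / n_bg, 1),
                p_raw=float(pr),
                p_adjusted=float(pa),
            )
        )
    if alpha is not None:
        results = [r for r in results if r.p_adjusted <= alpha]
    results.sort(key=lambda r: (r.p_raw, r.go_id))
    return results


def likelihood_ratio_test(lnL_null: float, lnL_alt: float, df: int) -> LrtResult:
    """LRT of nested models: 2*(lnL_alt - lnL_null) vs chi-squared(df).

    A negative statistic (alternative fitting worse than the null,
    impossible for properly nested optimized fits) yields p = 1 with a
    warning.
    """
    if df <= 0:
        raise ValueError("df must be a positive integer")
    two_delta = 2.0 * (lnL_alt - lnL_null)
    if two_delta < 0:
        warnings.warn(
            "negative 2*deltaLnL: alternative fits worse than null; p = 1"
        )
        p = 1.0
    else:
        p = float(sps.chi2.sf(two_delta, df))
    return LrtResult(lnL_null=lnL_null, lnL_alt=lnL_alt, df=df,
                     two_delta=two_delta, p=p)
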