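"""SNP discovery from padded contig alignments and Ts/Tv screens.

A contig alignment is a padded stack of reads over a consensus; a
column is called as a SNP when enough reads carry a second allele.
Transition/transversion (Ts/Tv) ratios are computed per contig and
transcriptome-wide; contigs in the tails of the Ts/Tv distribution are
flagged as candidates for selection (a low ratio is a rough signal of
positive selection, a high one of purifying selection, because
transversions are more likely to change the encoded amino acid).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections import Counter

import numpy as np
from scipy import stats as sps

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

#: The 6 unordered substitution types (2 transitions + 4 transversions).
SNP_TYPES = ("A/G", "C/T", "A/C", "A/T", "C/G", "G/T")
TRANSITION_TYPES = ("A/G", "C/T")


def classify_substitution(a: str, b: str) -> str:
    """Classify a base pair as ``"transition"`` or ``"transversion"``.

    Transitions stay within the purines {A, G} or within the
    pyrimidines {C, T}; everything else crosses the ring classes and is
    a transversion.
    """
    a, b = a.upper(), b.upper()
    if a not in "ACGT" or b not in "ACGT":
        raise ValueError(f"bases must be in ACGT, got {a!r}/{b!r}")
    if a == b:
        raise ValueError(f"not a substitution: {a}/{b}")
    if {a, b} <= PURINES or {a, b} <= PYRIMIDINES:
        return "transition"
    return "transversion"


def snp_type(a: str, b: str) -> str:
    """Unordered substitution type label, e.g. ``("G", "A") -> "A/G"``."""
    x, y = sorted((a.upper(), b.upper()))
    return f"{x}/{y}"


@dataclass
class SnpCall:
    contig_id: str
    column: int  # 0-based
    major_base: str
    minor_base: str
    major_count: int
    minor_count: int
    depth: int
    klass: str  # "transition" | "transversion"
    multiallelic: bool = False


@dataclass
class ContigTsTv:
    contig_id: str
    n_ts: int
    n_tv: int
    assayed_bp: int

    @property
    def ratio(self) -> float | None:
        """Ts/Tv quotient; undefined (None) when no transversions."""
        if self.n_tv == 0:
            return None
        return self.n_ts / self.n_tv


@dataclass
class SnpSummary:
    n_snps: int
    n_contigs_with_snps: int
    total_assayed_bp: int
    density_bp_per_snp: int | None  # floor(bp / n_snps); None if no SNPs
    pct_ts: int
    pct_tv: int
    global_tstv: float | None  # round1(n_ts/n_tv); None if no Tv
    per_type_per_kb: dict[str, float]
    type_counts: dict[str, int]


def call_snps(
    consensus: str,
    reads: list[str],
    contig_id: str = "contig",
    min_depth: int = 4,
    min_minor: int = 2,
    min_minor_frac: float = 0.2,
) -> list[SnpCall]:
    """Call SNP columns from a padded read stack.

    A column is a candidate SNP iff its non-gap, non-N depth is at
    least ``min_depth`` and the second-most-common base has count
    >= ``min_minor`` and frequency >= ``min_minor_frac``.  Columns where
    three or more alleles pass the minor thresholds are emitted as the
    top-2 pair with ``multiallelic=True``.
    """
    width = len(consensus)
    if any(len(r) != width for r in reads):
        raise ValueError("ragged alignment rows")
    calls: list[SnpCall] = []
    for col in range(width):
        counts = Counter()
        for r in reads:
            base = r[col]
            if base in "ACGT":
                counts[base] += 1
        depth = sum(counts.values())
        if depth < min_depth or len(counts) < 2:
            continue
        # deterministic tie-break: count desc, then base alphabetical
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        (major, major_n), (minor, minor_n) = ranked[0], ranked[1]
        if minor_n < min_minor or minor_n / depth < min_minor_frac:
            continue
        n_passing = sum(
            1 for _, n in ranked if n >= min_minor and n / depth >= min_minor_frac
        )
        calls.append(
            SnpCall(
                contig_id=contig_id,
                column=col,
                major_base=major,
                minor_base=minor,
                major_count=major_n,
                minor_count=minor_n,
                depth=depth,
                klass=classify_substitution(major, minor),
                multiallelic=n_passing > 2,
            )
        )
    return calls


def assayed_columns(consensus: str, reads: list[str], min_depth: int = 4) -> int:
    """Number of columns with non-gap, non-N depth >= min_depth."""
    n = 0
    for col in range(len(consensus)):
        depth = sum(1 for r in reads if r[col] in "ACGT")
        if depth >= min_depth:
            n += 1
    return n


def contig_tstv(calls: list[SnpCall], contig_id: str, assayed_bp: int) -> ContigTsTv:
    n_ts = sum(1 for c in calls if c.klass == "transition")
    n_tv = len(calls) - n_ts
    return ContigTsTv(contig_id=contig_id, n_ts=n_ts, n_tv=n_tv, assayed_bp=assayed_bp)


def snp_summary(calls: list[SnpCall], total_assayed_bp: int) -> SnpSummary:
    """Transcriptome-wide SNP summary.

    Density is reported the way resource papers print it, "1 SNP per
    N bp" with N = floor(assayed bp / n SNPs); the global Ts/Tv
    quotient is rounded to one decimal.
    """
    n = len(calls)
    type_counts = {t: 0 for t in SNP_TYPES}
    for c in calls:
        type_counts[snp_type(c.major_base, c.minor_base)] += 1
    n_ts = sum(type_counts[t] for t in TRANSITION_TYPES)
    n_tv = n - n_ts
    kb = total_assayed_bp / 1000.0
    per_type_per_kb = {
        t: (cnt / kb if kb > 0 else 0.0) for t, cnt in type_counts.items()
    }
    return SnpSummary(
        n_snps=n,
        n_contigs_with_snps=len({c.contig_id for c in calls}),
        total_assayed_bp=total_assayed_bp,
        density_bp_per_snp=(total_assayed_bp // n) if n else None,
        pct_ts=round(100.0 * n_ts / n) if n else 0,
        pct_tv=round(100.0 * n_tv / n) if n else 0,
        global_tstv=round(n_ts / n_tv, 1) if n_tv else None,
        per_type_per_kb=per_type_per_kb,
        type_counts=type_counts,
    )


def validation_rate(n_confirmed: int, n_tested: int) -> int:
    """Percentage of assayed candidate SNPs confirmed by resequencing."""
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    if not 0 <= n_confirmed <= n_tested:
        raise ValueError("n_confirmed must be in [0, n_tested]")
    return round(100.0 * n_confirmed / n_tested)


def tstv_screen(
    ratios: dict[str, float | None], low: float = 1.0, high: float = 5.0
) -> tuple[set[str], set[str], dict[str, float]]:
    """Flag contigs in the tails of the Ts/Tv distribution.

    Returns ``(low_set, high_set, percentiles)``: contigs with a
    defined ratio strictly below ``low`` resp. strictly above ``high``,
    plus the empirical percentile of each threshold among defined
    ratios.  Undefined ratios (no transversions) are excluded.
    """
    defined = {cid: r for cid, r in ratios.items() if r is not None}
    low_set = {cid for cid, r in defined.items() if r < low}
    high_set = {cid for cid, r in defined.items() if r > high}
    values = np.fromiter(defined.values(), dtype=float)
    if values.size:
        percentiles = {
            "low": float(sps.percentileofscore(values, low, kind="strict")),
            "high": float(sps.percentileofscore(values, high, kind="weak")),
        }
    else:
        percentiles = {"low": math.nan, "high": math.nan}
    return low_set, high_set, percentiles
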