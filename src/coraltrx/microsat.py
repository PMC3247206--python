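"""Microsatellite (SSR) detection for 2-6 bp motifs.

Motifs are pooled into canonical classes under rotation and reverse
complement (GTT -> AAC), the convention used when comparing repeat
spectra across species.  The scanner reports maximal, mostly-pure
tandem tracts; interruptions longer than one motif length split a
tract.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: default minimum copy number per motif length
DEFAULT_MIN_COPIES = {2: 6, 3: 5, 4: 4, 5: 4, 6: 4}
DEFAULT_MIN_PURITY = 90.0


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _is_reducible(motif: str) -> bool:
    """True when the motif is a whole-number power of a shorter motif."""
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif == motif[:d] * (m // d):
            return True
    return False


def canonicalize(motif: str) -> str:
    """Canonical class of a motif: the lexicographic minimum over all
    rotations of the motif and of its reverse complement.

    Raises ``ValueError`` for non-ACGT characters, lengths outside
    [2, 6], or period-reducible motifs (``"ATAT"`` is an AT dimer, not
    a tetramer).
    """
    motif = motif.upper()
    if not 2 <= len(motif) <= 6:
        raise ValueError(f"motif length must be in [2, 6]: {motif!r}")
    if any(b not in "ACGT" for b in motif):
        raise ValueError(f"motif must be ACGT only: {motif!r}")
    if _is_reducible(motif):
        raise ValueError(f"motif is a power of a shorter motif: {motif!r}")
    rc = reverse_complement(motif)
    candidates = [motif[i:] + motif[:i] for i in range(len(motif))]
    candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(candidates)


def canonical_classes(length: int) -> set[str]:
    """All canonical classes for a given motif length, by enumeration."""
    from itertools import product

    classes = set()
    for tup in product("ACGT", repeat=length):
        motif = "".join(tup)
        if not _is_reducible(motif):
            classes.add(canonicalize(motif))
    return classes


@dataclass
class RepeatLocus:
    seq_id: str
    start: int  # 0-based
    end: int  # exclusive
    motif: str  # as found in the sequence
    canonical_class: str
    copies: float
    purity: float  # % of positions matching the perfect repeat

    @property
    def length(self) -> int:
        return self.end - self.start


def _perfect_runs(seq: str, m: int) -> list[tuple[int, int]]:
    """Maximal runs with perfect period m, as (start, end) pairs.

    A position extends a period-m run when seq[j] == seq[j-m] and both
    are unambiguous bases; Ns therefore break repeats.
    """
    n = len(seq)
    runs: list[tuple[int, int]] = []
    j = m
    run_start = 0
    while j < n:
        if seq[j] == seq[j - m] and seq[j] in "ACGT":
            j += 1
            continue
        if j - run_start >= 2 * m:
            runs.append((run_start, j))
        run_start = j - m + 1
        j += 1
    if j - run_start >= 2 * m:
        runs.append((run_start, j))
    return runs


def find_repeats(
    seq: str,
    seq_id: str = "seq",
    min_copies: dict[int, int] | None = None,
    min_purity: float = DEFAULT_MIN_PURITY,
) -> list[RepeatLocus]:
    """Find maximal non-overlapping tandem repeats with 2-6 bp motifs.

    Perfect period-m runs are found for every motif length, runs of the
    same motif separated by an interruption of at most one motif length
    are merged when the merged tract stays above ``min_purity``, and
    overlapping candidates are resolved longest-first (then purer, then
    leftmost).  Mononucleotide runs are out of scope, as are motifs
    reducible to a shorter period.
    """
    min_copies = dict(DEFAULT_MIN_COPIES if min_copies is None else min_copies)
    seq = seq.upper()
    candidates: list[RepeatLocus] = []
    for m in range(2, 7):
        need = min_copies.get(m, DEFAULT_MIN_COPIES[m])
        raw = []
        for start, end in _perfect_runs(seq, m):
            motif = seq[start:start + m]
            if _is_reducible(motif):
                continue
            raw.append((start, end, motif))
        # merge same-class runs across interruptions of <= one motif
        # length; only substantial components merge, so a planted tract
        # is not dragged onto an accidental 2-copy neighbour, and an N
        # in the interruption always splits
        min_component = need // 2 + 1
        merged: list[tuple[int, int, str, int]] = []  # start, end, motif, mismatches
        for start, end, motif in raw:
            if merged:
                ps, pe, pm, pmm = merged[-1]
                gap = start - pe
                if (
                    0 < gap <= m
                    and canonicalize(motif) == canonicalize(pm)
                    and (end - start) / m >= min_component
                    and (pe - ps) / m >= min_component
                    and "N" not in seq[pe:start]
                ):
                    mm = pmm + gap
                    purity = 100.0 * (1 - mm / (end - ps))
                    if purity >= min_purity:
                        merged[-1] = (ps, end, pm, mm)
                        continue
            merged.append((start, end, motif, 0))
        for start, end, motif, mm in merged:
            length = end - start
            copies = length / m
            if copies < need:
                continue
            purity = 100.0 * (1 - mm / length)
            candidates.append(
                RepeatLocus(
                    seq_id=seq_id,
                    start=start,
                    end=end,
                    motif=motif,
                    canonical_class=canonicalize(motif),
                    copies=round(copies, 2),
                    purity=round(purity, 1),
                )
            )
    # longest, then purest, then leftmost wins among overlaps
    candidates.sort(key=lambda r: (-(r.length), -r.purity, r.start))
    chosen: list[RepeatLocus] = []
    for cand in candidates:
        if all(cand.end <= c.start or cand.start >= c.end for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda r: r.start)
    return chosen


@dataclass
class RepeatSpectrum:
    by_length: dict[int, int]
    by_class: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.by_length.values())

    def superclass_count(self, pattern: str = "AAN") -> int:
        """Count of trinucleotide classes matching a pattern like AAN
        (N = any base)."""
        n = 0
        for klass, cnt in self.by_class.items():
            if len(klass) != len(pattern):
                continue
            if all(p == "N" or p == b for p, b in zip(pattern, klass)):
                n += cnt
        return n


def spectrum(loci: list[RepeatLocus]) -> RepeatSpectrum:
    """Tally loci by motif length and by canonical class."""
    by_length = Counter({m: 0 for m in range(2, 7)})
    by_class: Counter[str] = Counter()
    for loc in loci:
        by_length[len(loc.motif)] += 1
        by_class[loc.canonical_class] += 1
    return RepeatSpectrum(by_length=dict(by_length), by_class=dict(by_class))
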