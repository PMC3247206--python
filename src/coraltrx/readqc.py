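"""Read trimming and filtering for single-end (454-style) libraries.

Reads are first screened for residual SMART cDNA-synthesis primer at
either end (the primer and anything outboard of it is clipped, with
qualities kept in lockstep), then whole-read filtered on N count,
average phred quality and a length window.  Boundary semantics follow
the strict inequalities: a read of exactly the minimum length or
exactly the minimum average quality is kept.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

from Bio import SeqIO

SMART_PRIMER = "AAGCAGTGGTATCAACGCAGAGT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class QualRead:
    id: str
    bases: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"{self.id}: {len(self.bases)} bases but {len(self.quals)} quals"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def mean_quality(self) -> float:
        return sum(self.quals) / len(self.quals) if self.quals else 0.0

    @property
    def n_count(self) -> int:
        return self.bases.upper().count("N")


@dataclass
class QcConfig:
    max_n: int = 1
    min_avg_qual: float = 20.0
    min_len: int = 280
    max_len: int = 530
    primer: str = SMART_PRIMER
    max_primer_mismatches: int = 2

    def __post_init__(self) -> None:
        if self.min_len >= self.max_len:
            raise ValueError("min_len must be below max_len")
        if not self.primer:
            raise ValueError("primer must be non-empty")


@dataclass
class QcReport:
    n_in: int = 0
    n_out: int = 0
    total_bp_in: int = 0
    total_bp_out: int = 0
    rejections: dict[str, int] = field(
        default_factory=lambda: {"n_count": 0, "quality": 0, "length": 0}
    )

    @property
    def mean_len_in(self) -> float | None:
        return self.total_bp_in / self.n_in if self.n_in else None

    @property
    def mean_len_out(self) -> float | None:
        return self.total_bp_out / self.n_out if self.n_out else None

    def to_json(self, path: str | os.PathLike) -> None:
        payload = asdict(self)
        payload["mean_len_in"] = self.mean_len_in
        payload["mean_len_out"] = self.mean_len_out
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _hamming_within(a: str, b: str, limit: int) -> bool:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return False
    return True


def screen_primer(read: QualRead, cfg: QcConfig) -> QualRead:
    """Clip primer occurrences (forward or reverse complement) off the ends.

    Any occurrence of the primer within ``max_primer_mismatches``
    (substitutions only) whose match lies in the outer half of the read
    is removed together with everything outboard of it.  Both ends are
    screened repeatedly until clean; reads without a primer pass
    through unchanged.
    """
    probes = (cfg.primer.upper(), _revcomp(cfg.primer.upper()))
    bases, quals = read.bases.upper(), list(read.quals)
    k = len(cfg.primer)
    changed = True
    while changed and len(bases) >= k:
        changed = False
        for probe in probes:
            # prefix-side occurrence: match starting in the first half
            limit = min(len(bases) - k, max(0, len(bases) // 2 - k)) + 1
            for i in range(limit):
                if _hamming_within(bases[i:i + k], probe, cfg.max_primer_mismatches):
                    bases, quals = bases[i + k:], quals[i + k:]
                    changed = True
                    break
            if changed or len(bases) < k:
                break
            # suffix-side occurrence: match ending in the last half
            for j in range(len(bases), max(k - 1, len(bases) // 2), -1):
                if _hamming_within(bases[j - k:j], probe, cfg.max_primer_mismatches):
                    bases, quals = bases[:j - k], quals[:j - k]
                    changed = True
                    break
            if changed:
                break
    return QualRead(id=read.id, bases=bases, quals=quals)


def filter_read(read: QualRead, cfg: QcConfig) -> tuple[bool, str | None]:
    """Keep/reject a (primer-screened) read; reject reasons in rule order.

    Reject iff N count > ``max_n``, or mean quality < ``min_avg_qual``,
    or length outside [``min_len``, ``max_len``].  The first failing
    rule is reported.  An empty read is a length rejection.
    """
    if len(read) == 0:
        return False, "length"
    if read.n_count > cfg.max_n:
        return False, "n_count"
    if read.mean_quality < cfg.min_avg_qual:
        return False, "quality"
    if len(read) < cfg.min_len or len(read) > cfg.max_len:
        return False, "length"
    return True, None


def process_read(read: QualRead, cfg: QcConfig) -> tuple[QualRead, bool, str | None]:
    screened = screen_primer(read, cfg)
    keep, reason = filter_read(screened, cfg)
    return screened, keep, reason


def run_qc(
    fastq_in: str | os.PathLike,
    fastq_out: str | os.PathLike,
    cfg: QcConfig | None = None,
) -> QcReport:
    """Screen and filter a FASTQ file; write survivors and tally a report.

    Conservation holds by construction: every input read is either
    written out or counted under exactly one rejection reason.
    """
    cfg = cfg or QcConfig()
    report = QcReport()
    with open(fastq_out, "w") as out:
        for rec in SeqIO.parse(str(fastq_in), "fastq"):
            read = QualRead(
                id=rec.id,
                bases=str(rec.seq).upper(),
                quals=list(rec.letter_annotations["phred_quality"]),
            )
            report.n_in += 1
            report.total_bp_in += len(read)
            screened, keep, reason = process_read(read, cfg)
            if keep:
                report.n_out += 1
                report.total_bp_out += len(screened)
                qstr = "".join(chr(q + 33) for q in screened.quals)
                out.write(f"@{screened.id}\n{screened.bases}\n+\n{qstr}\n")
            else:
                report.rejections[reason] += 1
    return report
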