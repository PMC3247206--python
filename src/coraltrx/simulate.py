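"""Ground-truthed synthetic transcriptome generator.

Every downstream stage of the pipeline (read QC, completeness,
SNP calling, microsatellite scanning, paralog clustering) is testable
against data produced here, with a manifest recording exactly what was
planted where.  The generator emulates the shape of a 454-era de novo
transcriptome project:

* transcripts with lognormal lengths (mean 1030 bp, sd 623 bp by
  default, the scale typical of assembled cnidarian contigs),
* single-end reads of ~398 +/- 118 bp with per-base phred qualities,
  occasional Ns and residual SMART cDNA-synthesis primer at the ends,
* redundant fragmented contigs (a shifted-Poisson number of fragments
  per transcript, so the mean fragments/transcript equals the requested
  redundancy factor),
* SNPs planted into padded read stacks with a configurable
  transition:transversion odds,
* 2-6 bp tandem repeats planted at recorded coordinates,
* two-species gene families with an internally consistent bitscore
  table (within-family scores exceed between-family scores by
  construction) standing in for an external homology search.

All coordinates in ground-truth records are 0-based, half-open;
hit-table coordinates are 1-based inclusive (the outfmt-6 convention).
All operations are deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import OUTFMT6_COLUMNS
from .microsat import canonicalize
from .variants import classify_substitution

SMART_PRIMER = "AAGCAGTGGTATCAACGCAGAGT"

_BASES = "ACGT"
_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSION_PARTNERS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


@dataclass
class SimConfig:
    """Parameters of the synthetic transcriptome.

    Length distributions are lognormal with the requested mean and sd
    (always positive, mean unbiased).  Probabilities are per read
    (``primer_rate``) or per base (``n_rate``).
    """

    n_transcripts: int = 200
    transcript_len_mean: float = 1030.0
    transcript_len_sd: float = 623.0
    read_len_mean: float = 398.0
    read_len_sd: float = 118.0
    primer_rate: float = 0.15
    n_rate: float = 0.002
    quality_mean: float = 30.0
    quality_sd: float = 5.0
    n_reads: int | None = None  # default: 20 per transcript
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts <= 0:
            raise ValueError("n_transcripts must be positive")
        for name in ("transcript_len_mean", "transcript_len_sd", "read_len_mean",
                     "read_len_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("primer_rate", "n_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")


@dataclass
class GroundTruth:
    """Manifest of everything the generator planted."""

    transcripts: list[tuple[str, str]] = field(default_factory=list)
    #: family-id -> {"A": [ids...], "B": [ids...]}; member 0 of each
    #: species is the ortholog seed.
    gene_families: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    #: (contig-id, column, ref-base, alt-base, class)
    planted_snps: list[tuple[str, int, str, str, str]] = field(default_factory=list)
    #: (seq-id, start, motif, copies); 0-based start
    planted_repeats: list[tuple[str, int, str, int]] = field(default_factory=list)
    redundancy_factor: float = 1.0
    tstv_odds: float = 2.0

    def validate(self) -> None:
        for _, _, ref, alt, klass in self.planted_snps:
            if classify_substitution(ref, alt) != klass:
                raise ValueError(f"inconsistent SNP class for pair {ref}/{alt}")
        for _, _, motif, _ in self.planted_repeats:
            if not 2 <= len(motif) <= 6:
                raise ValueError(f"motif length outside [2, 6]: {motif!r}")
        if self.redundancy_factor < 1:
            raise ValueError("redundancy_factor must be >= 1")

    def to_json(self, path: str | os.PathLike) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["transcripts"] = [tuple(t) for t in payload["transcripts"]]
        payload["planted_snps"] = [tuple(t) for t in payload["planted_snps"]]
        payload["planted_repeats"] = [tuple(t) for t in payload["planted_repeats"]]
        return cls(**payload)


def _lognormal_lengths(rng, n: int, mean: float, sd: float, floor: int = 50):
    """Integer lengths from a lognormal with the given mean and sd."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    lens = rng.lognormal(mu, math.sqrt(sigma2), size=n)
    return np.maximum(np.rint(lens).astype(int), floor)


def _random_seq(rng, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def generate_transcriptome(config: SimConfig) -> GroundTruth:
    """Generate transcripts and a two-species gene-family structure.

    Species A holds the generated transcripts, partitioned into
    families; species B gets id-only counterparts (its sequences are
    never needed, only the bitscore table from :func:`emit_hit_table`).
    Family sizes are geometric so single-member families dominate, as
    in real ortholog-group size distributions.
    """
    rng = np.random.default_rng(config.seed)
    lengths = _lognormal_lengths(
        rng, config.n_transcripts, config.transcript_len_mean,
        config.transcript_len_sd,
    )
    transcripts = [
        (f"tx{i:05d}", _random_seq(rng, int(L))) for i, L in enumerate(lengths)
    ]

    gene_families: dict[str, dict[str, list[str]]] = {}
    i = 0
    fam = 0
    while i < config.n_transcripts:
        size_a = min(int(rng.geometric(0.7)), 4, config.n_transcripts - i)
        size_b = min(int(rng.geometric(0.7)), 4)
        fam_id = f"fam{fam:04d}"
        members_a = [transcripts[i + j][0] for j in range(size_a)]
        members_b = [f"nv{fam:04d}_{j}" for j in range(size_b)]
        gene_families[fam_id] = {"A": members_a, "B": members_b}
        i += size_a
        fam += 1

    truth = GroundTruth(transcripts=transcripts, gene_families=gene_families)
    truth.validate()
    return truth


def simulate_reads(
    truth: GroundTruth, config: SimConfig
) -> list[tuple[str, str, list[int]]]:
    """Sample single-end reads as ``(id, bases, quals)`` triples.

    Reads are substrings of transcripts with lognormal lengths,
    Gaussian per-read quality means with per-base jitter, Ns sprinkled
    at ``n_rate``, and (with probability ``primer_rate``) the SMART
    primer prepended, as happens when cDNA-synthesis oligos survive
    into the library.
    """
    rng = np.random.default_rng(config.seed + 1)
    n_reads = config.n_reads if config.n_reads is not None else 20 * len(
        truth.transcripts
    )
    reads = []
    tx_idx = rng.integers(0, len(truth.transcripts), size=n_reads)
    lens = _lognormal_lengths(rng, n_reads, config.read_len_mean, config.read_len_sd)
    for r in range(n_reads):
        _, tx_seq = truth.transcripts[tx_idx[r]]
        L = min(int(lens[r]), len(tx_seq))
        start = int(rng.integers(0, len(tx_seq) - L + 1))
        bases = list(tx_seq[start:start + L])
        n_mask = rng.random(L) < config.n_rate
        for j in np.flatnonzero(n_mask):
            bases[j] = "N"
        if rng.random() < config.primer_rate:
            bases = list(SMART_PRIMER) + bases
        q_mean = float(rng.normal(config.quality_mean, config.quality_sd))
        quals = np.clip(
            np.rint(q_mean + rng.normal(0.0, 3.0, size=len(bases))), 0, 60
        ).astype(int)
        reads.append((f"read{r:06d}", "".join(bases), quals.tolist()))
    return reads


def write_fastq(reads, path: str | os.PathLike) -> None:
    """Write ``(id, bases, quals)`` triples as Sanger phred+33 FASTQ."""
    with open(path, "w") as fh:
        for name, bases, quals in reads:
            qstr = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{name}\n{bases}\n+\n{qstr}\n")


def fragment_contigs(
    truth: GroundTruth, redundancy: float, seed: int
) -> tuple[list[tuple[str, str]], dict[str, tuple[str, int, int]]]:
    """Fragment transcripts into redundant contigs.

    The number of fragments per transcript is 1 + Poisson(redundancy-1),
    so the mean converges to ``redundancy``.  Every contig is a
    substring of exactly one transcript; the provenance map records
    ``contig_id -> (transcript_id, start, end)`` (0-based, half-open).
    """
    if redundancy < 1:
        raise ValueError("redundancy must be >= 1")
    rng = np.random.default_rng(seed)
    contigs: list[tuple[str, str]] = []
    provenance: dict[str, tuple[str, int, int]] = {}
    for tx_id, tx_seq in truth.transcripts:
        k = 1 + int(rng.poisson(redundancy - 1.0))
        L = len(tx_seq)
        for j in range(k):
            cid = f"{tx_id}.c{j}"
            if k == 1:
                start, end = 0, L
            else:
                min_len = min(100, L)
                frag_len = int(rng.integers(min_len, L + 1))
                start = int(rng.integers(0, L - frag_len + 1))
                end = start + frag_len
            contigs.append((cid, tx_seq[start:end]))
            provenance[cid] = (tx_id, start, end)
    return contigs, provenance


def plant_snps(
    contigs: list[tuple[str, str]],
    density: float,
    tstv_odds: float,
    depth_range: tuple[int, int] = (6, 12),
    seed: int = 0,
    min_minor: int = 2,
    min_minor_frac: float = 0.2,
) -> tuple[dict[str, tuple[str, list[str]]], list[tuple[str, int, str, str, str]]]:
    """Plant SNPs into padded read stacks over each contig.

    Each contig gets a stack of full-length error-free reads (uniform
    depth in ``depth_range``); at each planted column a minor allele is
    written into enough reads to clear the caller's default thresholds.
    A planted site is a transition with probability
    ``tstv_odds / (1 + tstv_odds)`` (odds 0 gives pure transversions).

    Returns ``(alignments, planted)`` where ``alignments`` maps
    contig-id to ``(consensus, reads)`` and ``planted`` lists
    ``(contig_id, column, ref, alt, class)``.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    if tstv_odds < 0:
        raise ValueError("tstv_odds must be non-negative")
    lo, hi = depth_range
    if lo < 2 * min_minor:
        raise ValueError("depth_range too shallow to carry both alleles")
    rng = np.random.default_rng(seed)
    p_ts = tstv_odds / (1.0 + tstv_odds) if tstv_odds > 0 else 0.0

    alignments: dict[str, tuple[str, list[str]]] = {}
    planted: list[tuple[str, int, str, str, str]] = []
    for cid, seq in contigs:
        L = len(seq)
        depth = int(rng.integers(lo, hi + 1))
        rows = [list(seq) for _ in range(depth)]
        n_sites = int(rng.binomial(L, density))
        cols = rng.choice(L, size=min(n_sites, L), replace=False)
        for col in sorted(int(c) for c in cols):
            ref = seq[col]
            if ref not in _BASES:
                continue
            if rng.random() < p_ts:
                alt = _TRANSITION_PARTNER[ref]
            else:
                alt = _TRANSVERSION_PARTNERS[ref][int(rng.integers(0, 2))]
            klass = classify_substitution(ref, alt)
            floor_minor = max(min_minor, math.ceil(min_minor_frac * depth))
            top = max(floor_minor, depth // 2)
            minor = int(rng.integers(floor_minor, top + 1))
            carriers = rng.choice(depth, size=minor, replace=False)
            for r in carriers:
                rows[int(r)][col] = alt
            planted.append((cid, col, ref, alt, klass))
        alignments[cid] = (seq, ["".join(r) for r in rows])
    return alignments, planted


def plant_repeat(
    seq: str, pos: int, motif: str, copies: int
) -> str:
    """Overwrite ``seq[pos:pos + len(motif)*copies]`` with a perfect repeat.

    The flanking bases are adjusted if they would extend the repeat's
    period, so the planted locus is maximal at exactly the recorded
    coordinates.
    """
    canonicalize(motif)  # validates length 2-6, ACGT, irreducibility
    m = len(motif)
    tract = motif * copies
    end = pos + len(tract)
    if pos < 0 or end > len(seq):
        raise ValueError("repeat tract does not fit in sequence")
    out = list(seq)
    out[pos:end] = tract
    if pos > 0 and out[pos - 1] == motif[-1]:
        out[pos - 1] = "C" if motif[-1] != "C" else "G"
    if end < len(out) and out[end] == motif[0]:
        out[end] = "C" if motif[0] != "C" else "G"
    return "".join(out)


def plant_repeats(
    seqs: list[tuple[str, str]],
    motif_classes: list[str],
    copies: int | list[int] = 8,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[tuple[str, int, str, int]]]:
    """Plant one tandem repeat per sequence, cycling over motif classes.

    Returns the modified sequences plus planted-locus records
    ``(seq_id, start, motif, copies)`` with 0-based starts.  Sequences
    too short to host their assigned tract are passed through
    unchanged.
    """
    for motif in motif_classes:
        canonicalize(motif)  # reject non-ACGT / reducible / out-of-range motifs
    rng = np.random.default_rng(seed)
    copies_list = (
        list(copies) if isinstance(copies, (list, tuple))
        else [copies] * len(motif_classes)
    )
    out_seqs: list[tuple[str, str]] = []
    planted: list[tuple[str, int, str, int]] = []
    for i, (sid, seq) in enumerate(seqs):
        motif = motif_classes[i % len(motif_classes)]
        n_cop = int(copies_list[i % len(motif_classes)])
        tract_len = len(motif) * n_cop
        if len(seq) < tract_len + 2:
            out_seqs.append((sid, seq))
            continue
        pos = int(rng.integers(1, len(seq) - tract_len))
        out_seqs.append((sid, plant_repeat(seq, pos, motif, n_cop)))
        planted.append((sid, pos, motif, n_cop))
    return out_seqs, planted


def emit_ortholog_hits(
    truth: GroundTruth,
    provenance: dict[str, tuple[str, int, int]],
    seed: int = 0,
) -> pd.DataFrame:
    """Emit contig-vs-ortholog hits consistent with the provenance map.

    Every transcript is treated as a known single-copy ortholog
    (subject id ``ortho:<tx_id>``); each contig hits the ortholog of
    its source transcript, and nothing else, with a high-quality score.
    Feeding the result to the redundancy estimator therefore recovers
    the fragmentation level used by :func:`fragment_contigs`.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cid, (tx_id, start, end) in provenance.items():
        aln = end - start
        score = round(float(rng.uniform(150.0, 400.0)), 1)
        rows.append(
            (cid, f"ortho:{tx_id}", 99.0, aln, 0, 0, 1, aln, start + 1, end,
             1e-60, score)
        )
    return pd.DataFrame(rows, columns=OUTFMT6_COLUMNS)


def emit_hit_table(
    truth: GroundTruth, noise: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Emit an outfmt-6 bitscore table consistent with the gene families.

    Score design (before noise): self-hits 400 bits; within-species
    member-to-seed 300; the cross-species seed pair 200; all other
    within-family cross pairs 150.  Between-family pairs get no rows.
    Thus at noise 0 the mutual best hit of every ortholog seed is its
    true partner, and every non-seed member scores closer to its seed
    than the seed pair scores to each other (the in-paralog condition).
    """
    if noise < 0:
        raise ValueError("noise must be non-negative")
    rng = np.random.default_rng(seed)
    tx_len = {tid: len(s) for tid, s in truth.transcripts}
    rows: list[tuple] = []

    def add(q: str, s: str, score: float) -> None:
        score = max(41.0, score + (rng.normal(0.0, noise) if noise > 0 else 0.0))
        aln = min(tx_len.get(q, 500), tx_len.get(s, 500))
        ident = min(100.0, 40.0 + score / 8.0)
        # short scientific form, as search tools print it (and so the
        # table round-trips through TSV bit-exactly)
        evalue = float(f"{max(1e-180, aln * 2.0 ** (-score)):.2e}")
        rows.append((q, s, round(ident, 2), aln, 0, 0, 1, aln, 1, aln,
                     evalue, round(score, 1)))

    for members in truth.gene_families.values():
        mem_a, mem_b = members["A"], members["B"]
        for x in mem_a + mem_b:
            add(x, x, 400.0)
        for x in mem_a[1:]:
            add(x, mem_a[0], 300.0)
            add(mem_a[0], x, 300.0)
        for y in mem_b[1:]:
            add(y, mem_b[0], 300.0)
            add(mem_b[0], y, 300.0)
        for i, x in enumerate(mem_a):
            for j, y in enumerate(mem_b):
                score = 200.0 if i == j == 0 else 150.0
                add(x, y, score)
                add(y, x, score)

    return pd.DataFrame(rows, columns=OUTFMT6_COLUMNS)
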