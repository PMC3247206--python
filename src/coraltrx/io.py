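"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA/FASTQ go through Biopython; tabular homology hits are the
12-column BLAST ``outfmt 6`` dialect held in a pandas DataFrame; padded
contig alignments are multi-FASTA files whose first record is the
consensus; SNP calls are written as a minimal VCF and as TSV; repeat
loci as BED + TSV.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Column names of the 12-column BLAST tabular (outfmt 6) dialect.
OUTFMT6_COLUMNS = [
    "query_id",
    "subject_id",
    "pct_identity",
    "aln_len",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bitscore",
]

_OUTFMT6_DTYPES = {
    "query_id": str,
    "subject_id": str,
    "pct_identity": float,
    "aln_len": int,
    "mismatches": int,
    "gap_opens": int,
    "q_start": int,
    "q_end": int,
    "s_start": int,
    "s_end": int,
    "evalue": float,
    "bitscore": float,
}


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]``."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs]
    SeqIO.write(records, str(path), "fasta")


def read_outfmt6(path: str | os.PathLike) -> pd.DataFrame:
    """Read a 12-column outfmt-6 TSV into a typed DataFrame."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=OUTFMT6_COLUMNS,
        dtype=_OUTFMT6_DTYPES, float_precision="round_trip",
    )
    return df


def write_outfmt6(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=OUTFMT6_COLUMNS)


def read_alignment(path: str | os.PathLike) -> tuple[str, str, list[str]]:
    """Read a padded multi-FASTA contig alignment.

    Returns ``(contig_id, consensus, reads)``.  The first record is the
    consensus; all rows must have equal length (pad character ``-``).
    """
    records = read_fasta(path)
    if not records:
        raise ValueError(f"empty alignment file: {path}")
    contig_id, consensus = records[0]
    reads = [s for _, s in records[1:]]
    width = len(consensus)
    if any(len(r) != width for r in reads):
        raise ValueError(f"ragged alignment rows in {path}")
    return contig_id, consensus, reads


def write_alignment(
    contig_id: str, consensus: str, reads: Sequence[str], path: str | os.PathLike
) -> None:
    recs = [(contig_id, consensus)]
    recs += [(f"{contig_id}|read{i}", r) for i, r in enumerate(reads)]
    write_fasta(recs, path)


def read_go_map(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read a sequence-id → GO-term TSV (seq_id, GO:ID[, namespace])."""
    go_map: dict[str, set[str]] = {}
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    for row in df.itertuples(index=False):
        go_map.setdefault(row[0], set()).add(row[1])
    return go_map


def write_go_map(go_map: dict[str, set[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for seq_id in sorted(go_map):
            for term in sorted(go_map[seq_id]):
                fh.write(f"{seq_id}\t{term}\n")


def write_vcf(calls, path: str | os.PathLike) -> None:
    """Write SNP calls as a minimal VCF (1-based POS, REF=major, ALT=minor)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##INFO=<ID=MAC,Number=1,Type=Integer,Description="Minor allele count">\n'
        )
        fh.write(
            '##INFO=<ID=CLASS,Number=1,Type=String,'
            'Description="transition or transversion">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            info = f"DP={c.depth};MAC={c.minor_count};CLASS={c.klass}"
            fh.write(
                f"{c.contig_id}\t{c.column + 1}\t.\t{c.major_base}\t"
                f"{c.minor_base}\t.\tPASS\t{info}\n"
            )


def write_bed(loci, path: str | os.PathLike) -> None:
    """Write repeat loci as BED (0-based half-open) with the motif as name."""
    with open(path, "w") as fh:
        for loc in loci:
            fh.write(f"{loc.seq_id}\t{loc.start}\t{loc.end}\t{loc.motif}\n")
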