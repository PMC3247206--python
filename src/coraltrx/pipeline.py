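"""End-to-end orchestration: simulate -> QC -> completeness -> SNPs ->
repeats -> paralogs -> enrichment, with a run report.

A run is driven by a :class:`RunConfig` (loadable from YAML); each
stage reads/writes plain-text artifacts under the run directory and
contributes counts to the :class:`RunReport`, whose sequence-set
summaries mirror the "summary of sequencing and assembly" tables of
transcriptome resource papers (n, total Mb, mean +/- sd length).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, homology, microsat, paralogs, readqc, simulate, stats, variants
from .io import write_alignment, write_bed, write_fasta, write_outfmt6, write_vcf

log = logging.getLogger("coraltrx")

STAGES = ("simulate", "qc", "completeness", "snps", "ssrs", "paralogs", "enrich")


class StageError(RuntimeError):
    """Failure inside a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str = "run"
    stages: tuple[str, ...] = STAGES
    seed: int = 42
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    qc: readqc.QcConfig = field(default_factory=readqc.QcConfig)
    redundancy: float = 2.2
    snp_density: float = 1.0 / 272.0
    tstv_odds: float = 2.4
    min_depth: int = 4
    min_minor: int = 2
    min_minor_frac: float = 0.2
    tstv_low: float = 1.0
    tstv_high: float = 5.0
    alpha: float = 0.05
    # external inputs, used when the simulate stage is disabled
    fastq_in: str | None = None
    alignments_dir: str | None = None
    contigs_fasta: str | None = None

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        if "simulate" not in self.stages:
            if "qc" in self.stages and not self.fastq_in:
                raise StageError("qc", "missing input: fastq_in")
            if "snps" in self.stages and not self.alignments_dir:
                raise StageError("snps", "missing input: alignments_dir")
            if "ssrs" in self.stages and not self.contigs_fasta:
                raise StageError("ssrs", "missing input: contigs_fasta")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_cfg = simulate.SimConfig(**raw.pop("sim", {}))
        qc_cfg = readqc.QcConfig(**raw.pop("qc", {}))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(sim=sim_cfg, qc=qc_cfg, **raw)

    def config_hash(self) -> str:
        """Hash over the parameters that affect computation (paths excluded)."""
        payload = dataclasses.asdict(self)
        for key in ("out_dir", "fastq_in", "alignments_dir", "contigs_fasta"):
            payload.pop(key, None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def table1_summary(seq_sets: dict[str, list[int]]) -> dict:
    """Per-set n / total Mb / mean (sd) length, plus the grand total n.

    ``seq_sets`` maps a set name (e.g. "contigs", "singletons") to the
    list of its sequence lengths.  Empty sets report mean/sd as None
    (rendered as a dash).
    """
    out: dict = {"sets": {}, "total_n": 0}
    for name, lengths in seq_sets.items():
        arr = np.asarray(lengths, dtype=float)
        n = int(arr.size)
        out["sets"][name] = {
            "n": n,
            "total_mb": round(float(arr.sum()) / 1e6, 3) if n else 0.0,
            "mean_len": round(float(arr.mean()), 1) if n else None,
            "sd_len": round(float(arr.std(ddof=0)), 1) if n else None,
        }
        out["total_n"] += n
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the run report (also written to ``report.json`` and
    ``report.tsv`` in the output directory).  Any stage failure raises
    :class:`StageError` naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    truth = None
    contigs: list[tuple[str, str]] = []
    provenance: dict[str, tuple[str, int, int]] = {}
    alignments: dict[str, tuple[str, list[str]]] = {}

    if "simulate" in config.stages:
        log.info("simulate: generating synthetic transcriptome")
        try:
            cfg = dataclasses.replace(config.sim, seed=config.seed)
            truth = simulate.generate_transcriptome(cfg)
            reads = simulate.simulate_reads(truth, cfg)
            simulate.write_fastq(reads, out / "reads.fastq")
            contigs, provenance = simulate.fragment_contigs(
                truth, config.redundancy, seed=config.seed + 2
            )
            contigs, planted_reps = simulate.plant_repeats(
                contigs, ["AAC", "ATC", "AC", "AAG", "ACGACT"], copies=8,
                seed=config.seed + 3,
            )
            truth.planted_repeats = planted_reps
            alignments, planted_snps = simulate.plant_snps(
                contigs, config.snp_density, config.tstv_odds,
                seed=config.seed + 4, min_minor=config.min_minor,
                min_minor_frac=config.min_minor_frac,
            )
            truth.planted_snps = planted_snps
            truth.redundancy_factor = config.redundancy
            truth.tstv_odds = config.tstv_odds
            write_fasta(contigs, out / "contigs.fasta")
            aln_dir = out / "alignments"
            aln_dir.mkdir(exist_ok=True)
            for cid, (cons, rows) in alignments.items():
                write_alignment(cid, cons, rows, aln_dir / f"{cid}.afa")
            truth.to_json(out / "truth.json")
            hit_table = simulate.emit_hit_table(truth, seed=config.seed + 5)
            write_outfmt6(hit_table, out / "hits.tsv")
            report["stages"]["simulate"] = {
                "n_transcripts": len(truth.transcripts),
                "n_reads": len(reads),
                "n_contigs": len(contigs),
                "n_planted_snps": len(planted_snps),
                "n_planted_repeats": len(planted_reps),
            }
        except StageError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError("simulate", str(exc)) from exc
        config.fastq_in = str(out / "reads.fastq")

    if "qc" in config.stages:
        log.info("qc: trimming and filtering reads")
        try:
            qc_report = readqc.run_qc(
                config.fastq_in, out / "reads.qc.fastq", config.qc
            )
        except Exception as exc:
            raise StageError("qc", str(exc)) from exc
        report["stages"]["qc"] = {
            "n_in": qc_report.n_in,
            "n_out": qc_report.n_out,
            "total_bp_in": qc_report.total_bp_in,
            "total_bp_out": qc_report.total_bp_out,
            "rejections": qc_report.rejections,
        }
        qc_report.to_json(out / "qc_report.json")

    if "completeness" in config.stages:
        log.info("completeness: redundancy and gene-count estimate")
        if truth is None:
            raise StageError("completeness", "missing input: synthetic truth")
        try:
            ortho_hits = simulate.emit_ortholog_hits(
                truth, provenance, seed=config.seed + 7
            )
            ortho_ids = [f"ortho:{tid}" for tid, _ in truth.transcripts]
            red = homology.redundancy_factor(
                ortho_hits, ortho_ids, min_bitscore=130.0, max_evalue=2e-38
            )
            gce = homology.gene_count_estimate(len(contigs), red["mean"])
            report["stages"]["completeness"] = {
                "redundancy_mean": round(red["mean"], 3),
                "frac_multiple": round(red["frac_multiple"], 3),
                "gene_count_estimate": gce,
                "true_n_transcripts": len(truth.transcripts),
            }
        except Exception as exc:
            raise StageError("completeness", str(exc)) from exc

    if "snps" in config.stages:
        log.info("snps: calling SNPs and Ts/Tv screen")
        try:
            if not alignments and config.alignments_dir:
                from .io import read_alignment

                for path in sorted(Path(config.alignments_dir).glob("*.afa")):
                    cid, cons, rows = read_alignment(path)
                    alignments[cid] = (cons, rows)
            all_calls: list[variants.SnpCall] = []
            ratios: dict[str, float | None] = {}
            total_bp = 0
            for cid, (cons, rows) in alignments.items():
                calls = variants.call_snps(
                    cons, rows, contig_id=cid, min_depth=config.min_depth,
                    min_minor=config.min_minor,
                    min_minor_frac=config.min_minor_frac,
                )
                bp = variants.assayed_columns(cons, rows, config.min_depth)
                total_bp += bp
                if calls:
                    ratios[cid] = variants.contig_tstv(calls, cid, bp).ratio
                all_calls.extend(calls)
            summary = variants.snp_summary(all_calls, total_bp)
            low, high, pct = variants.tstv_screen(
                ratios, config.tstv_low, config.tstv_high
            )
            write_vcf(all_calls, out / "snps.vcf")
            report["stages"]["snps"] = {
                "n_snps": summary.n_snps,
                "density_bp_per_snp": summary.density_bp_per_snp,
                "pct_ts": summary.pct_ts,
                "pct_tv": summary.pct_tv,
                "global_tstv": summary.global_tstv,
                "type_counts": summary.type_counts,
                "n_low_tstv": len(low),
                "n_high_tstv": len(high),
                "threshold_percentiles": pct,
            }
        except Exception as exc:
            raise StageError("snps", str(exc)) from exc

    if "ssrs" in config.stages:
        log.info("ssrs: scanning for microsatellites")
        try:
            if not contigs and config.contigs_fasta:
                from .io import read_fasta

                contigs = read_fasta(config.contigs_fasta)
            loci = []
            for cid, seq in contigs:
                loci.extend(microsat.find_repeats(seq, seq_id=cid))
            spec_ = microsat.spectrum(loci)
            write_bed(loci, out / "ssrs.bed")
            report["stages"]["ssrs"] = {
                "n_loci": spec_.total,
                "by_length": spec_.by_length,
                "by_class": dict(sorted(spec_.by_class.items())),
                "aan_count": spec_.superclass_count("AAN"),
            }
        except Exception as exc:
            raise StageError("ssrs", str(exc)) from exc

    if "paralogs" in config.stages:
        log.info("paralogs: RBH seeds and in-paralog clustering")
        if truth is None:
            raise StageError("paralogs", "missing input: synthetic truth")
        try:
            hits = simulate.emit_hit_table(truth, seed=config.seed + 5)
            ids_a = {t for fam in truth.gene_families.values() for t in fam["A"]}
            ids_b = {t for fam in truth.gene_families.values() for t in fam["B"]}
            table = paralogs.ScoreTable.from_hits(hits, ids_a, ids_b)
            seeds = paralogs.mutual_best_hits(table)
            groups = paralogs.cluster_inparalogs(table, seeds)
            tally = paralogs.group_size_distribution(groups)
            report["stages"]["paralogs"] = {
                "n_seeds": len(seeds),
                "n_inparalogs_a": sum(g.size_a - 1 for g in groups),
                "n_inparalogs_b": sum(g.size_b - 1 for g in groups),
                "size_tally": {f"{a}x{b}": n for (a, b), n in sorted(tally.items())},
            }
        except Exception as exc:
            raise StageError("paralogs", str(exc)) from exc

    if "enrich" in config.stages:
        log.info("enrich: GO enrichment of Ts/Tv tails")
        try:
            snp_stage = report["stages"].get("snps")
            if snp_stage is None:
                raise ValueError("missing input: snps stage must run first")
            # toy GO map over contigs: deterministic assignment for the
            # smoke pipeline; real runs supply their own map
            rng = np.random.default_rng(config.seed + 6)
            terms = [f"GO:{i:07d}" for i in range(10)]
            go_map = {
                cid: {terms[int(rng.integers(0, len(terms)))]}
                for cid, _ in contigs
            }
            background = {cid for cid, _ in contigs}
            calls_by_contig = {}
            subset = set()
            if alignments:
                ratios = {}
                for cid, (cons, rows) in alignments.items():
                    calls = variants.call_snps(
                        cons, rows, contig_id=cid, min_depth=config.min_depth,
                        min_minor=config.min_minor,
                        min_minor_frac=config.min_minor_frac,
                    )
                    bp = variants.assayed_columns(cons, rows, config.min_depth)
                    if calls:
                        ratios[cid] = variants.contig_tstv(calls, cid, bp).ratio
                low, high, _ = variants.tstv_screen(
                    ratios, config.tstv_low, config.tstv_high
                )
                subset = low
            results = stats.enrich_terms(
                subset & background, background, go_map, alpha=None
            )
            report["stages"]["enrich"] = {
                "n_terms_tested": len(results),
                "n_significant": sum(
                    1 for r in results if r.p_adjusted <= config.alpha
                ),
            }
        except StageError:
            raise
        except Exception as exc:
            raise StageError("enrich", str(exc)) from exc

    if truth is not None:
        report["table1"] = table1_summary(
            {
                "transcripts": [len(s) for _, s in truth.transcripts],
                "contigs": [len(s) for _, s in contigs],
            }
        )

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    _write_report_tsv(report, out / "report.tsv")
    return report


def _flatten(prefix: str, obj, rows: list[tuple[str, str]]) -> None:
    if isinstance(obj, dict):
        for k, v in sorted(obj.items()):
            _flatten(f"{prefix}.{k}" if prefix else str(k), v, rows)
    else:
        rows.append((prefix, str(obj)))


def _write_report_tsv(report: dict, path: str | os.PathLike) -> None:
    rows: list[tuple[str, str]] = []
    _flatten("", report, rows)
    with open(path, "w") as fh:
        for key, val in rows:
            fh.write(f"{key}\t{val}\n")
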