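"""Synthetic-data generator: determinism, planted-feature bookkeeping,
and convergence of the configured rates."""

import math

import numpy as np
import pytest

from coraltrx import simulate
from coraltrx.simulate import GroundTruth, SimConfig
from coraltrx.variants import classify_substitution


class TestGenerateTranscriptome:
    def test_deterministic_under_fixed_seed(self):
        cfg = SimConfig(n_transcripts=10, seed=1)
        t1 = simulate.generate_transcriptome(cfg)
        t2 = simulate.generate_transcriptome(cfg)
        assert t1.transcripts == t2.transcripts
        assert t1.gene_families == t2.gene_families

    def test_zero_transcripts_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_transcripts=0)

    def test_sequences_are_uppercase_acgt(self, small_truth):
        for _, seq in small_truth.transcripts:
            assert set(seq) <= set("ACGT")

    def test_mean_length_within_three_sd(self):
        # sampling-distribution bound: |mean - 1030| < 3 * 623 / sqrt(n)
        cfg = SimConfig(n_transcripts=5000, transcript_len_mean=1030,
                        transcript_len_sd=623, seed=2)
        truth = simulate.generate_transcriptome(cfg)
        lens = np.array([len(s) for _, s in truth.transcripts])
        bound = 3 * 623 / math.sqrt(5000)
        assert abs(lens.mean() - 1030) < bound

    def test_every_transcript_in_exactly_one_family(self, small_truth):
        seen = [
            m for fam in small_truth.gene_families.values() for m in fam["A"]
        ]
        assert sorted(seen) == sorted(t for t, _ in small_truth.transcripts)
        assert len(seen) == len(set(seen))


class TestFragmentContigs:
    def test_redundancy_one_is_identity(self, small_truth):
        contigs, prov = simulate.fragment_contigs(small_truth, 1.0, seed=3)
        assert len(contigs) == len(small_truth.transcripts)
        tx = dict(small_truth.transcripts)
        for cid, seq in contigs:
            tid, start, end = prov[cid]
            assert (start, end) == (0, len(tx[tid]))
            assert seq == tx[tid]

    def test_mean_fragments_converges(self):
        cfg = SimConfig(n_transcripts=1000, seed=4)
        truth = simulate.generate_transcriptome(cfg)
        contigs, _ = simulate.fragment_contigs(truth, 2.2, seed=5)
        mean = len(contigs) / 1000
        assert abs(mean - 2.2) / 2.2 < 0.05

    def test_provenance_recovers_every_contig(self, small_truth, fragmented):
        contigs, prov = fragmented
        tx = dict(small_truth.transcripts)
        assert set(prov) == {cid for cid, _ in contigs}
        for cid, seq in contigs:
            tid, start, end = prov[cid]
            assert tx[tid][start:end] == seq

    def test_redundancy_below_one_rejected(self, small_truth):
        with pytest.raises(ValueError):
            simulate.fragment_contigs(small_truth, 0.9, seed=0)


class TestPlantSnps:
    def test_transition_fraction_converges(self):
        # 2.4:1 odds => Ts fraction 0.7059, binomial bound over >=1e4 sites
        cfg = SimConfig(n_transcripts=800, transcript_len_mean=1030,
                        transcript_len_sd=300, seed=6)
        truth = simulate.generate_transcriptome(cfg)
        contigs = truth.transcripts
        _, planted = simulate.plant_snps(contigs, density=0.02,
                                         tstv_odds=2.4, seed=7)
        assert len(planted) >= 10_000
        p = 2.4 / 3.4
        ts_frac = sum(1 for s in planted if s[4] == "transition") / len(planted)
        bound = 3 * math.sqrt(p * (1 - p) / len(planted))
        assert abs(ts_frac - p) < bound

    def test_planted_count_poisson_bound(self):
        # ~1 Mb at 1/272 per bp => ~3676 sites within 3 Poisson sd
        cfg = SimConfig(n_transcripts=1000, transcript_len_mean=1000,
                        transcript_len_sd=100, seed=8)
        truth = simulate.generate_transcriptome(cfg)
        total_bp = sum(len(s) for _, s in truth.transcripts)
        _, planted = simulate.plant_snps(truth.transcripts, 1 / 272,
                                         tstv_odds=2.4, seed=9)
        expected = total_bp / 272
        assert abs(len(planted) - expected) < 3 * math.sqrt(expected)

    def test_zero_odds_gives_pure_transversions(self, fragmented):
        contigs, _ = fragmented
        _, planted = simulate.plant_snps(contigs, 0.01, tstv_odds=0.0, seed=10)
        assert planted
        assert all(s[4] == "transversion" for s in planted)

    def test_classes_consistent_with_classifier(self, planted_alignments):
        _, planted = planted_alignments
        for _, _, ref, alt, klass in planted:
            assert classify_substitution(ref, alt) == klass

    def test_consensus_carries_major_allele(self, planted_alignments):
        alignments, planted = planted_alignments
        for cid, col, ref, alt, _ in planted:
            cons, rows = alignments[cid]
            assert cons[col] == ref
            counts = {b: sum(1 for r in rows if r[col] == b) for b in "ACGT"}
            assert counts[ref] >= counts[alt] >= 2

    def test_nonpositive_density_rejected(self, fragmented):
        with pytest.raises(ValueError):
            simulate.plant_snps(fragmented[0], 0.0, 2.4, seed=1)


class TestPlantRepeats:
    def test_planted_locus_recorded(self):
        seq = "ACGT" * 60
        out = simulate.plant_repeat(seq, 100, "AC", 8)
        assert out[100:116] == "AC" * 8
        assert len(out) == len(seq)

    def test_sequence_unchanged_elsewhere(self):
        seq = "TGCA" * 60
        out = simulate.plant_repeat(seq, 100, "AAG", 5)
        # flanks may be adjusted by at most one base on each side
        assert out[:99] == seq[:99]
        assert out[116:] == seq[116:]

    def test_motif_length_seven_rejected(self):
        with pytest.raises(ValueError):
            simulate.plant_repeats([("s", "ACGT" * 50)], ["ACGTACG"], 4, seed=0)

    def test_deterministic_replanting(self, fragmented):
        contigs, _ = fragmented
        out1, rec1 = simulate.plant_repeats(contigs, ["AAC", "AC"], 8, seed=21)
        out2, rec2 = simulate.plant_repeats(contigs, ["AAC", "AC"], 8, seed=21)
        assert out1 == out2 and rec1 == rec2


class TestEmitHitTable:
    def test_noise_zero_mutual_best_hits_are_family_seeds(self, small_truth):
        table = simulate.emit_hit_table(small_truth, noise=0.0, seed=1)
        # brute-force MBH over the emitted scores
        ids_a = {m for f in small_truth.gene_families.values() for m in f["A"]}
        ids_b = {m for f in small_truth.gene_families.values() for m in f["B"]}
        best = {}
        for x in ids_a | ids_b:
            other = ids_b if x in ids_a else ids_a
            rows = table[(table.query_id == x) & table.subject_id.isin(other)]
            if len(rows):
                rows = rows.sort_values(["bitscore", "subject_id"],
                                        ascending=[False, True])
                best[x] = rows.iloc[0].subject_id
        mbh = {
            (a, best[a]) for a in ids_a
            if a in best and best.get(best[a]) == a
        }
        expected = {
            (f["A"][0], f["B"][0])
            for f in small_truth.gene_families.values()
        }
        assert mbh == expected

    def test_round_trips_through_reader(self, small_truth, tmp_path):
        from coraltrx.io import read_outfmt6, write_outfmt6

        table = simulate.emit_hit_table(small_truth, seed=2)
        path = tmp_path / "hits.tsv"
        write_outfmt6(table, path)
        back = read_outfmt6(path)
        assert back.equals(table.astype(back.dtypes.to_dict()))

    def test_negative_noise_rejected(self, small_truth):
        with pytest.raises(ValueError):
            simulate.emit_hit_table(small_truth, noise=-1.0)


class TestGroundTruthManifest:
    def test_json_round_trip(self, small_truth, tmp_path):
        small_truth.planted_snps = [("c1", 5, "A", "G", "transition")]
        small_truth.planted_repeats = [("c1", 10, "AAC", 6)]
        path = tmp_path / "truth.json"
        small_truth.to_json(path)
        back = GroundTruth.from_json(path)
        assert back == small_truth
        small_truth.planted_snps = []
        small_truth.planted_repeats = []

    def test_validate_rejects_inconsistent_class(self):
        t = GroundTruth(planted_snps=[("c", 0, "A", "G", "transversion")])
        with pytest.raises(ValueError):
            t.validate()
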