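"""SNP calling, Ts/Tv classification and screens, checked against
exhaustive enumeration and the planted ground truth."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from coraltrx import variants
from coraltrx.variants import SNP_TYPES, SnpCall


class TestClassifySubstitution:
    def test_purine_pair_is_transition(self):
        assert variants.classify_substitution("A", "G") == "transition"

    def test_cross_ring_pair_is_transversion(self):
        assert variants.classify_substitution("A", "T") == "transversion"

    def test_exhaustive_four_transitions_eight_transversions(self):
        classes = Counter(
            variants.classify_substitution(a, b)
            for a, b in itertools.permutations("ACGT", 2)
        )
        assert classes == {"transition": 4, "transversion": 8}

    @pytest.mark.parametrize("pair", [("A", "A"), ("A", "N"), ("X", "G")])
    def test_invalid_pairs_rejected(self, pair):
        with pytest.raises(ValueError):
            variants.classify_substitution(*pair)

    def test_six_unordered_types_cover_all_pairs(self):
        got = {
            variants.snp_type(a, b)
            for a, b in itertools.permutations("ACGT", 2)
        }
        assert got == set(SNP_TYPES)


def _stack(columns):
    """Build (consensus, reads) from per-column base lists."""
    depth = max(len(c) for c in columns)
    cons = "".join(Counter(c).most_common(1)[0][0] for c in columns)
    reads = []
    for r in range(depth):
        reads.append("".join(c[r] if r < len(c) else "-" for c in columns))
    return cons, reads


def _oracle_calls(reads, min_depth=4, min_minor=2, min_minor_frac=0.2):
    """Brute-force column counting, written independently of the caller."""
    width = len(reads[0])
    out = []
    for col in range(width):
        counts = Counter(
            r[col] for r in reads if r[col] in "ACGT"
        )
        depth = sum(counts.values())
        if depth < min_depth or len(counts) < 2:
            continue
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        minor_n = ranked[1][1]
        if minor_n >= min_minor and minor_n / depth >= min_minor_frac:
            out.append((col, ranked[0][0], ranked[1][0]))
    return out


class TestCallSnps:
    def test_basic_transition_call(self):
        cons, reads = _stack(
            [["A"] * 5, ["A"] * 5, ["A"] * 3 + ["G"] * 2]
        )
        calls = variants.call_snps(cons, reads)
        assert len(calls) == 1
        call = calls[0]
        assert (call.column, call.major_base, call.minor_base) == (2, "A", "G")
        assert call.klass == "transition"

    def test_single_minor_read_not_called(self):
        cons, reads = _stack([["A"] * 9 + ["G"]])
        assert variants.call_snps(cons, reads) == []

    def test_minor_fraction_threshold(self):
        # 2/12 = 0.167 < 0.2 -> no call even though count passes
        cons, reads = _stack([["A"] * 10 + ["G"] * 2])
        assert variants.call_snps(cons, reads) == []

    def test_gaps_and_ns_excluded_from_depth(self):
        cons, reads = _stack([["A", "A", "G", "-", "N", "N"]])
        # non-gap non-N depth is 3 < min_depth 4
        assert variants.call_snps(cons, reads) == []

    def test_multiallelic_flagged_as_top_two(self):
        cons, reads = _stack([["A"] * 4 + ["G"] * 3 + ["T"] * 3])
        calls = variants.call_snps(cons, reads)
        assert len(calls) == 1
        assert calls[0].multiallelic
        assert (calls[0].major_base, calls[0].minor_base) == ("A", "G")

    def test_ragged_rows_rejected(self):
        with pytest.raises(ValueError):
            variants.call_snps("AAAA", ["AAAA", "AAA"])

    def test_matches_enumeration_oracle_on_random_stacks(self):
        rng = np.random.default_rng(23)
        alphabet = np.array(list("ACGT-N"))
        for trial in range(30):
            width = int(rng.integers(5, 50))
            depth = int(rng.integers(2, 20))
            reads = [
                "".join(rng.choice(alphabet, p=[0.5, 0.2, 0.1, 0.1, 0.05, 0.05],
                                   size=width))
                for _ in range(depth)
            ]
            cons = "".join(
                Counter(r[c] for r in reads).most_common(1)[0][0]
                for c in range(width)
            )
            got = [
                (c.column, c.major_base, c.minor_base)
                for c in variants.call_snps(cons, reads)
            ]
            assert got == _oracle_calls(reads)

    def test_full_recall_no_false_calls_on_planted_data(self, planted_alignments):
        alignments, planted = planted_alignments
        planted_by_contig = {}
        for cid, col, ref, alt, _ in planted:
            planted_by_contig.setdefault(cid, {})[col] = (ref, alt)
        for cid, (cons, reads) in alignments.items():
            calls = variants.call_snps(cons, reads, contig_id=cid)
            expected = planted_by_contig.get(cid, {})
            got = {c.column: (c.major_base, c.minor_base) for c in calls}
            assert set(got) == set(expected)
            for col, (ref, alt) in expected.items():
                assert set(got[col]) == {ref, alt}


class TestContigTsTv:
    def _calls(self, n_ts, n_tv):
        calls = []
        for i in range(n_ts):
            calls.append(SnpCall("c", i, "A", "G", 5, 2, 7, "transition"))
        for i in range(n_tv):
            calls.append(SnpCall("c", 100 + i, "A", "T", 5, 2, 7, "transversion"))
        return calls

    def test_ratio(self):
        assert variants.contig_tstv(self._calls(4, 2), "c", 500).ratio == 2.0

    def test_no_transversions_undefined(self):
        assert variants.contig_tstv(self._calls(3, 0), "c", 500).ratio is None

    def test_zero_transitions(self):
        assert variants.contig_tstv(self._calls(0, 3), "c", 500).ratio == 0.0


class TestSnpSummary:
    def test_resource_scale_density_floor(self):
        calls = [SnpCall("c", i, "A", "G", 5, 2, 7, "transition")
                 for i in range(72_605)]
        s = variants.snp_summary(calls, 19_800_000)
        assert s.density_bp_per_snp == 272

    def test_ts_tv_split_and_ratio_rounding(self):
        calls = [SnpCall("c", i, "A", "G", 5, 2, 7, "transition")
                 for i in range(71)]
        calls += [SnpCall("c", 100 + i, "A", "T", 5, 2, 7, "transversion")
                  for i in range(29)]
        s = variants.snp_summary(calls, 100_000)
        assert (s.pct_ts, s.pct_tv) == (71, 29)
        assert s.global_tstv == 2.4

    def test_zero_snps_valid_summary(self):
        s = variants.snp_summary([], 1000)
        assert s.n_snps == 0
        assert s.density_bp_per_snp is None
        assert s.global_tstv is None

    def test_type_counts_sum_to_n_snps(self, planted_alignments):
        alignments, _ = planted_alignments
        all_calls = []
        for cid, (cons, reads) in alignments.items():
            all_calls.extend(variants.call_snps(cons, reads, contig_id=cid))
        s = variants.snp_summary(all_calls, 10_000)
        assert sum(s.type_counts.values()) == s.n_snps == len(all_calls)

    def test_density_floor_bracket(self):
        calls = [SnpCall("c", i, "A", "G", 5, 2, 7, "transition")
                 for i in range(7)]
        s = variants.snp_summary(calls, 1000)
        d = s.density_bp_per_snp
        assert d * 7 <= 1000 < (d + 1) * 7


class TestTsTvScreen:
    def test_tail_assignment(self):
        ratios = {"a": 0.5, "b": 2.0, "c": 2.4, "d": 6.0}
        low, high, _ = variants.tstv_screen(ratios)
        assert low == {"a"} and high == {"d"}

    def test_uniform_ratios_empty_tails(self):
        low, high, _ = variants.tstv_screen({c: 2.0 for c in "abcd"})
        assert low == set() and high == set()

    def test_zero_low_threshold_empty(self):
        low, _, _ = variants.tstv_screen({"a": 0.5, "b": 9.0}, low=0.0)
        assert low == set()

    def test_undefined_ratios_excluded(self):
        low, high, _ = variants.tstv_screen({"a": None, "b": 0.5})
        assert low == {"b"} and high == set()

    def test_threshold_percentiles_reported(self):
        ratios = {f"c{i}": r for i, r in enumerate([0.5] * 5 + [2.0] * 90 + [6.0] * 5)}
        _, _, pct = variants.tstv_screen(ratios)
        assert pct["low"] == pytest.approx(5.0)
        assert pct["high"] == pytest.approx(95.0)


class TestTsFractionRecovery:
    def test_planted_odds_recovered_within_binomial_bound(self):
        from coraltrx import simulate

        cfg = simulate.SimConfig(n_transcripts=600, transcript_len_mean=1030,
                                 transcript_len_sd=300, seed=31)
        truth = simulate.generate_transcriptome(cfg)
        alignments, planted = simulate.plant_snps(
            truth.transcripts, density=0.02, tstv_odds=2.4, seed=32
        )
        n_ts = n = 0
        for cid, (cons, reads) in alignments.items():
            for call in variants.call_snps(cons, reads, contig_id=cid):
                n += 1
                n_ts += call.klass == "transition"
        assert n >= 10_000
        p = 2.4 / 3.4
        assert abs(n_ts / n - p) < 3 * math.sqrt(p * (1 - p) / n)
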