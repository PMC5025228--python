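"""Pileup construction, RDD filters, edge-bias test, signature, chi-square."""

import math

import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mitomodkit as mk
from mitomodkit.rdd_caller import PileupColumn

from oracles import chi2_oracle


def _column(ref_base="A", pos=100, **strand_counts):
    """Build a pileup column from {base+strand: count} kwargs, e.g. A_plus=10."""
    col = PileupColumn(ref_name="ref", pos=pos, ref_base=ref_base)
    for key, n in strand_counts.items():
        base, strand = key.split("_")
        col.counts[(base, {"plus": "+", "minus": "-"}[strand])] = n
    return col


def _write_sam(path, ref_name, ref_len, reads):
    """reads: list of (start0, strand, bases, quals_char)."""
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"},
         "SQ": [{"SN": ref_name, "LN": ref_len}]})
    with open(path, "w") as fh:
        fh.write(str(header))
        for i, (start, strand, bases, qchar) in enumerate(sorted(reads)):
            a = pysam.AlignedSegment(header)
            a.query_name = f"r{i}"
            a.query_sequence = bases
            a.flag = 16 if strand == "-" else 0
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = 60
            a.cigarstring = f"{len(bases)}M"
            a.query_qualities = pysam.qualitystring_to_array(qchar * len(bases))
            fh.write(a.to_string() + "\n")


class TestBuildPileup:
    def test_perfect_reads_full_coverage(self, tmp_path):
        ref = {"chrM": "ACGT" * 25}
        reads = ([(0, "+", ref["chrM"], "F")] * 10 + [(0, "-", ref["chrM"], "F")] * 10)
        sam = tmp_path / "perfect.sam"
        _write_sam(sam, "chrM", 100, reads)
        cols = mk.build_pileup(sam, ref, min_base_q=30, min_mapq=20, edge_trim=0)
        assert len(cols) == 100
        assert all(c.coverage == 20 and c.freq[c.ref_base] == 1.0 for c in cols)
        assert all(c.strand_coverage("+") == 10 for c in cols)

    def test_edge_trim_excludes_read_end_mismatch(self, tmp_path):
        ref = {"chrM": "A" * 60}
        # one + read with a mismatch 2 nt from its 3' end
        bases = "A" * 47 + "T" + "A" * 2
        sam = tmp_path / "edge.sam"
        _write_sam(sam, "chrM", 60, [(0, "+", bases, "F"), (0, "+", "A" * 50, "F")])
        trimmed = mk.build_pileup(sam, ref, min_base_q=0, min_mapq=0, edge_trim=5)
        col = next(c for c in trimmed if c.pos == 48)
        assert col.count("T") == 0  # inside the trim window
        untrimmed = mk.build_pileup(sam, ref, min_base_q=0, min_mapq=0, edge_trim=0)
        col = next(c for c in untrimmed if c.pos == 48)
        assert col.count("T") == 1

    def test_low_quality_calls_excluded(self, tmp_path):
        ref = {"chrM": "A" * 30}
        sam = tmp_path / "lowq.sam"
        _write_sam(sam, "chrM", 30, [(0, "+", "A" * 30, "#")])  # Q2
        cols = mk.build_pileup(sam, ref, min_base_q=30, min_mapq=0, edge_trim=0)
        assert cols == [] or all(c.coverage == 0 for c in cols)

    def test_unknown_reference_rejected(self, tmp_path):
        sam = tmp_path / "bad.sam"
        _write_sam(sam, "chrX", 30, [(0, "+", "A" * 30, "F")])
        with pytest.raises(ValueError, match="absent from the reference"):
            mk.build_pileup(sam, {"chrM": "A" * 30}, edge_trim=0)

    def test_simulated_fraction_recovered(self, sim_dataset):
        truth = sim_dataset["truth"]
        cols = mk.build_pileup(sim_dataset["sam_path"], sim_dataset["reference"],
                               min_base_q=0, min_mapq=0, edge_trim=0)
        col = next(c for c in cols if c.pos == sim_dataset["site"])
        # exact agreement with the truth record (round-trip invariant)
        for base in "ACGT":
            for strand in "+-":
                assert col.count(base, strand) == truth.site_counts[strand][base]
        assert col.coverage == truth.site_coverage
        # and the realized fraction sits within 3 binomial SE of the parameters
        spec = sim_dataset["spec"]
        p = spec.p_T + spec.p_G
        se = math.sqrt(p * (1 - p) / col.coverage)
        frac = (col.count("T") + col.count("G")) / col.coverage
        assert abs(frac - p) <= 3 * se


class TestCallRdd:
    @pytest.mark.parametrize("coverage,passes", [(999, False), (1000, True)])
    def test_filter_a_boundary(self, coverage, passes):
        half = coverage // 2
        col = _column(A_plus=half, A_minus=coverage - half - 40,
                      T_plus=20, T_minus=20)
        (call,) = mk.call_rdd([col])
        assert call.pass_filter_A is passes

    @pytest.mark.parametrize("n_secondary,passes", [(159, False), (160, True)])
    def test_filter_b_total_fraction_boundary(self, n_secondary, passes):
        # 10000 total reads, secondary split evenly across strands
        half = n_secondary // 2
        extra = n_secondary - half
        col = _column(A_plus=5000 - half, A_minus=5000 - extra,
                      T_plus=half, T_minus=extra)
        (call,) = mk.call_rdd([col])
        # per-strand fractions are ~1.59%/0.80%, far over the 0.8% bar;
        # only the total-fraction criterion is in play
        assert call.pass_filter_B is passes

    @pytest.mark.parametrize("minus_count,passes", [(39, False), (40, True)])
    def test_filter_b_per_strand_boundary(self, minus_count, passes):
        # 5000 reads per strand; 0.8% of a strand = 40 reads
        col = _column(A_plus=4800, A_minus=5000 - minus_count,
                      T_plus=200, T_minus=minus_count)
        (call,) = mk.call_rdd([col])
        assert call.pass_filter_B is passes

    def test_verdicts_match_truth_predicate(self):
        # generator-controlled grid around all three thresholds
        for cov in (800, 1000, 4000):
            for frac in (0.010, 0.016, 0.030):
                n_sec = round(cov * frac)
                half = n_sec // 2
                col = _column(A_plus=cov // 2 - half, A_minus=cov - cov // 2 - (n_sec - half),
                              T_plus=half, T_minus=n_sec - half)
                (call,) = mk.call_rdd([col])
                plus_cov = col.strand_coverage("+")
                minus_cov = col.strand_coverage("-")
                expect_a = cov >= 1000
                expect_b = (n_sec / cov >= 0.016
                            and half / plus_cov >= 0.008
                            and (n_sec - half) / minus_cov >= 0.008)
                assert call.pass_filter_A == expect_a
                assert call.pass_filter_B == expect_b
                assert call.is_rdd == (expect_a and expect_b)

    def test_strand_swap_leaves_verdicts_unchanged(self):
        col = _column(A_plus=2000, A_minus=1500, T_plus=60, T_minus=30, G_plus=5)
        swapped = PileupColumn(ref_name="ref", pos=100, ref_base="A",
                               counts={(b, {"+": "-", "-": "+"}[s]): n
                                       for (b, s), n in col.counts.items()})
        (c1,), (c2,) = mk.call_rdd([col]), mk.call_rdd([swapped])
        assert (c1.pass_filter_A, c1.pass_filter_B, c1.is_rdd) == \
               (c2.pass_filter_A, c2.pass_filter_B, c2.is_rdd)
        assert c1.secondary_fraction_by_strand == c2.secondary_fraction_by_strand[::-1]

    def test_waiver_admits_shallow_sample(self):
        col = _column(A_plus=300, A_minus=300, T_plus=30, T_minus=30)
        (strict,) = mk.call_rdd([col])
        (waived,) = mk.call_rdd([col], waive_coverage_filter=True)
        assert not strict.is_rdd and waived.is_rdd

    def test_rdd_level_is_nonreference_fraction(self):
        col = _column(A_plus=970, A_minus=970, T_plus=30, T_minus=30)
        (call,) = mk.call_rdd([col])
        assert call.rdd_level == pytest.approx(0.03)
        assert call.is_rdd

    def test_empty_input(self):
        assert mk.call_rdd([]) == []


class TestEdgeBias:
    def test_edge_piled_variants_flagged(self):
        flag, p = mk.edge_bias_test([1] * 50, read_length=100, window=5)
        assert flag and p < 1e-10

    def test_uniform_offsets_not_flagged(self):
        import numpy as np
        rng = np.random.default_rng(42)
        offsets = rng.integers(0, 50, size=200).tolist()
        flag, p = mk.edge_bias_test(offsets, read_length=100, window=5)
        assert not flag

    def test_no_variants(self):
        assert mk.edge_bias_test([], read_length=100, window=5) == (False, 1.0)

    def test_window_must_be_small(self):
        with pytest.raises(ValueError):
            mk.edge_bias_test([1], read_length=10, window=5)


class TestM1aSignature:
    def _columns_with_site(self, site_counts, flank_cov=1000, site=100, flank=25):
        cols = [_column(pos=site, **site_counts)]
        for p in range(site - flank, site + flank + 1):
            if p != site:
                cols.append(_column(ref_base="C", pos=p,
                                    C_plus=flank_cov // 2, C_minus=flank_cov // 2))
        return cols

    def test_component_arithmetic(self):
        # site: A 25%, T 60%, G 12%, C 3% of 800; flank median 1000
        cols = self._columns_with_site(
            dict(A_plus=100, A_minus=100, T_plus=240, T_minus=240,
                 G_plus=48, G_minus=48, C_plus=12, C_minus=12))
        sig = mk.m1a_signature(cols, 100)
        assert sig.mismatch_rate == pytest.approx(0.72)
        assert sig.coverage_drop == pytest.approx(0.2)
        assert sig.combined == pytest.approx(0.92)

    def test_unmodified_site_scores_zero(self):
        cols = self._columns_with_site(dict(A_plus=500, A_minus=500))
        sig = mk.m1a_signature(cols, 100)
        assert sig.combined == 0.0

    def test_knockdown_like_profile_scores_near_zero(self):
        # methyltransferase knockdown: reads converge to A, dip disappears
        cols = self._columns_with_site(dict(A_plus=495, A_minus=495,
                                            T_plus=5, T_minus=5))
        sig = mk.m1a_signature(cols, 100)
        assert sig.mismatch_rate < 0.02 and sig.coverage_drop == 0.0

    def test_requires_adenosine_reference(self):
        cols = self._columns_with_site(dict(A_plus=500, A_minus=500))
        cols[0].ref_base = "G"
        with pytest.raises(ValueError, match="expected A"):
            mk.m1a_signature(cols, 100)

    def test_recovers_simulated_drop(self, sim_dataset):
        cols = mk.build_pileup(sim_dataset["sam_path"], sim_dataset["reference"],
                               min_base_q=0, min_mapq=0, edge_trim=0)
        sig = mk.m1a_signature(cols, sim_dataset["site"])
        p_trunc = sim_dataset["spec"].p_trunc
        cov = sim_dataset["truth"].flank_median_coverage
        se = math.sqrt(p_trunc * (1 - p_trunc) / cov)
        assert abs(sig.coverage_drop - p_trunc) <= 3 * se


class TestCompareSamples:
    def test_total_vs_mitoribosome_proportions(self):
        chi2, p = mk.compare_samples((750, 250), (900, 100))
        assert chi2 == pytest.approx(chi2_oracle(750, 250, 900, 100), rel=1e-12)
        assert p < 1e-10

    def test_identical_tables(self):
        chi2, p = mk.compare_samples((500, 500), (500, 500))
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_minimal_table(self):
        chi2, _ = mk.compare_samples((1, 0), (0, 1))
        assert chi2 == pytest.approx(2.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            mk.compare_samples((0, 5), (0, 7))

    def test_matches_oracle_on_all_small_tables(self):
        for a in range(11):
            for b in range(11):
                for c in range(11):
                    for d in range(11):
                        if 0 in (a + b, c + d, a + c, b + d):
                            continue
                        stat, _ = mk.compare_samples((a, b), (c, d))
                        assert stat == pytest.approx(chi2_oracle(a, b, c, d),
                                                     rel=1e-12, abs=1e-12)


class TestFrequencyTable:
    def test_percentages(self):
        col = _column(A_plus=250, A_minus=250, T_plus=150, T_minus=150,
                      G_plus=75, G_minus=75, C_plus=25, C_minus=25)
        assert mk.frequency_table(col) == pytest.approx(
            {"A": 50.0, "T": 30.0, "G": 15.0, "C": 5.0})

    def test_single_base_column(self):
        col = _column(A_plus=7)
        assert mk.frequency_table(col)["A"] == 100.0

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            mk.frequency_table(_column())

    def test_simulator_truth_recovered(self, sim_dataset):
        cols = mk.build_pileup(sim_dataset["sam_path"], sim_dataset["reference"],
                               min_base_q=0, min_mapq=0, edge_trim=0)
        col = next(c for c in cols if c.pos == sim_dataset["site"])
        table = mk.frequency_table(col)
        spec = sim_dataset["spec"]
        for base, p in (("T", spec.p_T), ("G", spec.p_G)):
            se = 100 * math.sqrt(p * (1 - p) / col.coverage)
            assert abs(table[base] - 100 * p) <= 3 * se
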