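"""MUM finding (vs brute-force oracle), SMASH filters, binning, GC and CN."""

import numpy as np
import pandas as pd
import pytest

from tilescreen._suffix import ReferenceIndex
from tilescreen.genemodel import revcomp
from tilescreen.smash_cnv import (MUM, assign_counts, filter_mums, find_mums,
                                  gc_correct, make_bins, normalize_cn,
                                  profile_report, read_bedgraph,
                                  write_bedgraph)
from tilescreen.synthetic_data import gen_cnv_genome, gen_smash_reads

from conftest import count_overlapping


def brute_force_mums(read, genome):
    """Oracle: maximal substrings occurring exactly once on either strand."""
    texts = []
    for seq in genome.values():
        texts += [seq.upper(), revcomp(seq.upper())]

    def occ(sub):
        return sum(count_overlapping(t, sub) for t in texts)

    longest = {}
    for i in range(len(read)):
        l = 0
        while i + l < len(read) and occ(read[i:i + l + 1]) > 0:
            l += 1
        longest[i] = l
    mums = set()
    for i, l in longest.items():
        if l == 0 or occ(read[i:i + l]) != 1:
            continue
        if i > 0 and longest[i - 1] > l:        # contained
            continue
        mul = next(k for k in range(1, l + 1)
                   if occ(read[i:i + k]) == 1)
        mums.add((i, l, mul))
    return mums


@pytest.fixture(scope="module")
def small_ref():
    genome = gen_cnv_genome(3, {"chr1": 3000, "chr2": 2000}, [])
    return genome, ReferenceIndex(genome)


class TestFindMums:
    def test_unique_substring_single_mum(self, small_ref):
        genome, index = small_ref
        read = genome["chr1"][500:540]
        mums = find_mums(read, index)
        spanning = [m for m in mums if m.read_offset == 0]
        assert spanning and spanning[0].length == 40
        assert spanning[0].chrom == "chr1"
        assert spanning[0].genome_pos == 500
        assert spanning[0].strand == "+"

    def test_chimeric_read_split_at_junction(self, small_ref):
        genome, index = small_ref
        read = genome["chr1"][100:150] + genome["chr2"][900:950]
        mums = find_mums(read, index)
        locs = {(m.chrom, m.genome_pos) for m in mums if m.length >= 40}
        assert ("chr1", 100) in locs
        assert ("chr2", 900) in locs

    def test_reverse_strand_match(self, small_ref):
        genome, index = small_ref
        read = revcomp(genome["chr2"][300:360])
        mums = [m for m in find_mums(read, index) if m.length == 60]
        assert mums and mums[0].strand == "-"
        assert mums[0].genome_pos == 300

    def test_periodic_reference_no_unique_match(self):
        genome = {"r": "ACGTG" * 200}
        index = ReferenceIndex(genome)
        assert find_mums("ACGTG" * 4, index) == []

    def test_empty_read(self, small_ref):
        _, index = small_ref
        assert find_mums("", index) == []

    def test_equals_brute_force_oracle(self):
        genome = gen_cnv_genome(17, {"cA": 1200, "cB": 800}, [])
        index = ReferenceIndex(genome)
        rng = np.random.default_rng(18)
        for _ in range(6):
            a = int(rng.integers(0, 1100))
            b = int(rng.integers(0, 700))
            read = genome["cA"][a:a + 45] + genome["cB"][b:b + 45]
            mine = {(m.read_offset, m.length, m.min_unique_length)
                    for m in find_mums(read, index)}
            assert mine == brute_force_mums(read, genome)


class TestFilters:
    def _mum(self, length, mul=1, pos=0, mate=1):
        return MUM("r", mate, 0, "chr1", pos, length, "+", mul)

    def test_short_match_dropped(self):
        assert filter_mums([self._mum(19)], []) == []
        assert len(filter_mums([self._mum(24)], [])) == 1

    def test_excess_unique_rule(self):
        assert filter_mums([self._mum(22, mul=20)], []) == []   # excess 2
        assert len(filter_mums([self._mum(24, mul=20)], [])) == 1

    def test_mate_proximity_rule(self):
        r1 = [self._mum(30, pos=10_000)]
        near = [self._mum(30, pos=10_500, mate=2)]
        far = [self._mum(30, pos=12_000, mate=2)]
        assert len(filter_mums(r1, near)) == 1      # read-2 MUM dropped
        assert len(filter_mums(r1, far)) == 2

    def test_order_preserved(self):
        r1 = [self._mum(30, pos=100), self._mum(25, pos=5000)]
        kept = filter_mums(r1, [])
        assert [m.genome_pos for m in kept] == [100, 5000]


class TestBins:
    def test_equal_frequency_partition(self):
        genome = {"c": "ACGT" * 2500}         # 10 kb
        rng = np.random.default_rng(0)
        pos = {"c": rng.integers(0, 10_000, 5000)}
        bins = make_bins(genome, pos, target_count=250)
        counts = assign_counts(
            bins, [MUM("r", 1, 0, "c", int(p), 30, "+", 20)
                   for p in pos["c"]])
        # each bin receives close to the target number of calibration MUMs
        assert counts["raw_count"].min() > 150
        assert counts["raw_count"].max() < 350

    def test_one_bin_per_chrom_when_target_is_total(self):
        genome = {"c1": "A" * 500, "c2": "C" * 300}
        pos = {"c1": np.arange(0, 500, 5), "c2": np.arange(0, 300, 5)}
        bins = make_bins(genome, pos, target_count=100)
        assert (bins.groupby("chrom").size() == 1).all()
        assert bins[bins.chrom == "c1"].iloc[0]["end"] == 500

    def test_bins_tile_chromosomes(self):
        genome = gen_cnv_genome(5, {"chr1": 8000}, [])
        rng = np.random.default_rng(5)
        bins = make_bins(genome, {"chr1": rng.integers(0, 8000, 2000)}, 100)
        assert bins.iloc[0]["start"] == 0
        assert bins.iloc[-1]["end"] == 8000
        assert (bins["start"].values[1:] == bins["end"].values[:-1]).all()

    def test_conservation_of_assigned_mums(self):
        genome = gen_cnv_genome(6, {"chr1": 5000}, [])
        rng = np.random.default_rng(6)
        bins = make_bins(genome, {"chr1": rng.integers(0, 5000, 1000)}, 50)
        mums = [MUM("r", 1, 0, "chr1", int(p), 30, "+", 20)
                for p in rng.integers(0, 5000, 777)]
        counted = assign_counts(bins, mums)
        assert counted["raw_count"].sum() == 777


class TestGCCorrection:
    def _bins(self, gc, counts):
        return pd.DataFrame({
            "chrom": "chr1",
            "start": np.arange(len(gc)) * 100,
            "end": (np.arange(len(gc)) + 1) * 100,
            "gc": gc, "raw_count": counts})

    def test_no_bias_correction_near_identity(self):
        rng = np.random.default_rng(2)
        gc = rng.uniform(0.3, 0.7, 200)
        counts = rng.poisson(500, 200)
        out = gc_correct(self._bins(gc, counts))
        ratio = out["corrected_count"] / out["raw_count"]
        assert np.all(np.abs(ratio - 1) < 0.05)

    def test_linear_bias_removed(self):
        rng = np.random.default_rng(3)
        gc = rng.uniform(0.2, 0.8, 300)
        counts = rng.poisson(400 * (1 + 2 * gc))
        out = gc_correct(self._bins(gc, counts))
        norm = out["corrected_count"] / out["corrected_count"].mean()
        slope = np.polyfit(gc, norm, 1)[0]
        assert abs(slope) < 0.05

    def test_constant_gc_global_scaling(self):
        counts = np.array([100, 200, 300, 400] * 10)
        out = gc_correct(self._bins(np.full(40, 0.5), counts))
        ratio = out["corrected_count"] / out["raw_count"]
        assert np.allclose(ratio, ratio.iloc[0])


class TestNormalization:
    def _bins(self, cn_counts, chroms=None, width=100):
        n = len(cn_counts)
        return pd.DataFrame({
            "chrom": chroms if chroms is not None else ["chr1"] * n,
            "start": np.arange(n) * width,
            "end": (np.arange(n) + 1) * width,
            "gc": 0.5, "raw_count": cn_counts,
            "corrected_count": np.asarray(cn_counts, float)})

    def test_weighted_autosomal_mean_exactly_two(self):
        rng = np.random.default_rng(4)
        bins = normalize_cn(self._bins(rng.poisson(300, 50)))
        w = bins["end"] - bins["start"]
        assert np.average(bins["cn"], weights=w) == pytest.approx(2.0)

    def test_flat_profile_all_two(self):
        bins = normalize_cn(self._bins([400] * 30))
        assert np.allclose(bins["cn"], 2.0)

    def test_sex_chromosomes_excluded_from_baseline(self):
        bins = normalize_cn(self._bins(
            [400] * 20 + [200] * 10,
            chroms=["chr1"] * 20 + ["chrX"] * 10))
        assert np.allclose(bins[bins.chrom == "chr1"]["cn"], 2.0)
        assert np.allclose(bins[bins.chrom == "chrX"]["cn"], 1.0)

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        bins = normalize_cn(self._bins(rng.poisson(300, 40)))
        again = normalize_cn(bins.assign(corrected_count=bins["cn"]))
        assert np.allclose(again["cn"], bins["cn"])

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            normalize_cn(self._bins([0] * 10))


class TestReport:
    def test_flat_profile_no_runs(self):
        bins = pd.DataFrame({
            "chrom": "chr1", "start": np.arange(30) * 100,
            "end": (np.arange(30) + 1) * 100, "cn": 2.0})
        assert profile_report(bins)["candidate_runs"] == []

    def test_gained_run_detected(self):
        cn = np.full(40, 2.0)
        cn[10:20] = 3.1
        bins = pd.DataFrame({
            "chrom": "chr1", "start": np.arange(40) * 100,
            "end": (np.arange(40) + 1) * 100, "cn": cn})
        runs = profile_report(bins)["candidate_runs"]
        assert len(runs) == 1
        assert runs[0]["kind"] == "gain"
        assert runs[0]["start"] == 1000 and runs[0]["end"] == 2000

    def test_bedgraph_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        bins = pd.DataFrame({
            "chrom": "chr1", "start": np.arange(20) * 50,
            "end": (np.arange(20) + 1) * 50,
            "cn": np.round(rng.uniform(1, 3, 20), 4)})
        path = str(tmp_path / "cn.bedgraph")
        write_bedgraph(bins, path)
        back = read_bedgraph(path)
        assert np.allclose(back["cn"], bins["cn"])
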