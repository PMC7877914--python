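"""Quantification, normalization, LFC and the essentiality threshold rule."""

import numpy as np
import pandas as pd
import pytest

from tilescreen.screen_stats import (DEFAULT_PRIMER, ScreenTable,
                                     compare_ad_nad, compute_lfc,
                                     count_guides, essentiality_cutoff,
                                     median_normalize,
                                     replicate_correlation)


@pytest.fixture
def small_library():
    return pd.DataFrame({
        "guide_id": ["a", "b", "c", "d"],
        "gene": ["g1", "g1", "g2", "g2"],
        "category": ["tiling"] * 4,
        "sequence": ["ACGTACGTACGTACGTACGT", "TTTTAAAACCCCGGGGTTTT",
                     "GGCAGGCAGGCAGGCAGGCA", "CATGCATGCATGCATGCATG"],
    })


class TestCountGuides:
    BARCODES = {"s1": "AAAA", "s2": "CCCC"}

    def test_exact_match_counted(self, small_library):
        read = DEFAULT_PRIMER + "AAAA" + "ACGTACGTACGTACGTACGT" + "GTTTAA"
        table, stats = count_guides([read], small_library, self.BARCODES)
        assert table.raw_counts.loc["a", "s1"] == 1
        assert stats == {"total": 1, "assigned": 1, "discarded": 0}

    def test_one_substitution_discarded(self, small_library):
        guide = "ACGTACGTACGTACGTACGT"
        mutated = "T" + guide[1:]
        read = DEFAULT_PRIMER + "AAAA" + mutated
        _, stats = count_guides([read], small_library, self.BARCODES)
        assert stats["assigned"] == 0 and stats["discarded"] == 1

    def test_empty_input(self, small_library):
        table, stats = count_guides([], small_library, self.BARCODES)
        assert (table.raw_counts.values == 0).all()
        assert stats == {"total": 0, "assigned": 0, "discarded": 0}

    def test_read_conservation(self, small_library):
        reads = [DEFAULT_PRIMER + "AAAA" + "ACGTACGTACGTACGTACGT",
                 DEFAULT_PRIMER + "CCCC" + "GGCAGGCAGGCAGGCAGGCA",
                 "GARBAGE", DEFAULT_PRIMER + "GGGG" + "A" * 20]
        table, stats = count_guides(reads, small_library, self.BARCODES)
        assert stats["assigned"] + stats["discarded"] == stats["total"] == 4
        assert table.raw_counts.values.sum() == stats["assigned"]

    def test_duplicate_barcodes_rejected(self, small_library):
        with pytest.raises(ValueError):
            count_guides([], small_library, {"s1": "AAAA", "s2": "AAAA"})


class TestMedianNormalize:
    def _table(self, counts, lib=None):
        guides = list(counts.index)
        lib = lib if lib is not None else pd.DataFrame({
            "guide_id": guides, "gene": "g", "category": "tiling"})
        return ScreenTable(library=lib, raw_counts=counts)

    def test_identical_samples_factor_one(self):
        counts = pd.DataFrame({"A": [10, 20, 30], "B": [10, 20, 30]},
                              index=["a", "b", "c"])
        t = median_normalize(self._table(counts))
        assert np.allclose(t.size_factors, 1.0)
        assert np.allclose(t.norm_counts, counts)

    def test_doubled_sample_ratio_two(self):
        counts = pd.DataFrame({"A": [100, 50, 300], "B": [200, 100, 600]},
                              index=["a", "b", "c"])
        t = median_normalize(self._table(counts))
        assert t.size_factors["B"] / t.size_factors["A"] == pytest.approx(2)
        assert np.allclose(t.norm_counts["A"], t.norm_counts["B"])

    def test_single_guide_factor_is_ratio(self):
        counts = pd.DataFrame({"A": [100], "B": [400]}, index=["a"])
        t = median_normalize(self._table(counts))
        assert t.size_factors["B"] / t.size_factors["A"] == pytest.approx(4)

    def test_scale_invariance_of_ratios(self):
        # rescaling one sample's library size must not change any
        # cross-sample structure: normalized tables agree up to one
        # global scalar, so every between-sample ratio is preserved
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(10, 1000, (50, 3)),
                              index=[f"g{i}" for i in range(50)],
                              columns=["A", "B", "C"])
        t1 = median_normalize(self._table(counts))
        scaled = counts.copy()
        scaled["B"] *= 7
        t2 = median_normalize(self._table(scaled))
        ratio = (t2.norm_counts / t1.norm_counts).to_numpy()
        assert np.allclose(ratio, ratio[0, 0])
        assert np.allclose(t2.norm_counts["B"] / t2.norm_counts["A"],
                           t1.norm_counts["B"] / t1.norm_counts["A"])

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"A": [1, 2], "B": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            median_normalize(self._table(counts))


class TestLFC:
    def _normed(self, p1, p10):
        lib = pd.DataFrame({"guide_id": [f"g{i}" for i in range(len(p1))],
                            "gene": "g", "category": "tiling"})
        t = ScreenTable(library=lib, raw_counts=pd.DataFrame(
            {"P1": p1, "P10": p10}, index=lib["guide_id"]))
        t.size_factors = pd.Series({"P1": 1.0, "P10": 1.0})
        t.norm_counts = t.raw_counts / 1.0
        return t

    def test_quarter_depletion_alpha_zero(self):
        t = self._normed([1000], [250])
        assert compute_lfc(t, "P1", "P10", alpha=0)["lfc"].iloc[0] == -2

    def test_quarter_depletion_alpha_one(self):
        t = self._normed([1000], [250])
        lfc = compute_lfc(t, "P1", "P10", alpha=1)["lfc"].iloc[0]
        assert lfc == pytest.approx(np.log2(251 / 1001))

    def test_unchanged_counts_zero(self):
        t = self._normed([500, 80], [500, 80])
        assert (compute_lfc(t, "P1", "P10")["lfc"] == 0).all()

    def test_alpha_zero_with_zero_count_rejected(self):
        t = self._normed([1000], [0])
        with pytest.raises(ValueError):
            compute_lfc(t, "P1", "P10", alpha=0)


class TestEssentialityCutoff:
    def _lfcs(self, negatives, positive_gene_medians, tiling=()):
        rows = []
        for i, v in enumerate(negatives):
            rows.append(("n%d" % i, "neg", "negative_control", v))
        for g, med in enumerate(positive_gene_medians):
            # single guide per gene makes the median the value itself
            rows.append(("p%d" % g, f"pos{g}", "positive_control", med))
        for i, v in enumerate(tiling):
            rows.append(("t%d" % i, "gene", "tiling", v))
        return pd.DataFrame(rows, columns=["guide_id", "gene",
                                           "category", "lfc"])

    def test_rule_min_of_neg_and_pos_medians(self):
        call = essentiality_cutoff(
            self._lfcs([0.2, 0.0, -0.3], [-2.0, -3.5]))
        assert call.cutoff_raw == -3.5

    def test_strict_dominance_over_negatives(self):
        call = essentiality_cutoff(
            self._lfcs([-4.0, -0.1], [-3.5], tiling=[-4.0, -4.5]))
        assert call.cutoff_raw == -4.0
        # a tiling guide at exactly -4.0 ties the worst negative: not called
        assert not call.essential["t0"]
        assert call.essential["t1"]

    def test_null_tiling_none_essential(self):
        call = essentiality_cutoff(
            self._lfcs([0.0, 0.0], [-3.0], tiling=[0.0] * 5))
        assert call.essential[["t%d" % i for i in range(5)]].sum() == 0

    def test_no_negative_control_ever_essential(self):
        rng = np.random.default_rng(1)
        call = essentiality_cutoff(self._lfcs(
            rng.normal(0, 1, 200), [-5, -4], tiling=rng.normal(-2, 2, 100)))
        neg_ids = [f"n{i}" for i in range(200)]
        assert call.essential[neg_ids].sum() == 0

    def test_rounding_mode_reports_integer(self):
        call = essentiality_cutoff(
            self._lfcs([0.0], [-1.37]), round_to_int=True)
        assert call.cutoff == -1.0
        assert call.cutoff_raw == -1.37

    def test_missing_controls_rejected(self):
        with pytest.raises(ValueError):
            essentiality_cutoff(self._lfcs([], [-1.0]))


class TestADvsNAD:
    def _frame(self, ad, nad):
        return pd.DataFrame({
            "guide_id": [f"g{i}" for i in range(len(ad) + len(nad))],
            "gene": "g", "category": "tiling",
            "domain_class": ["AD"] * len(ad) + ["NAD"] * len(nad),
            "lfc": list(ad) + list(nad)})

    def test_depleted_ad_detected(self):
        res = compare_ad_nad(self._frame([-3, -2, -4], [0, -0.1, 0.2]))
        assert res["median_ad"] < res["median_nad"]
        # complete separation of 3 vs 3: the exact one-sided p is 1/20
        assert res["p_value"] == pytest.approx(0.05)

    def test_identical_distributions_p_half(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 500)
        res = compare_ad_nad(self._frame(x, x.copy()))
        assert res["p_value"] == pytest.approx(0.5, abs=0.02)

    def test_power_at_shift_two(self):
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(100):
            nad = rng.normal(0, 1, 200)
            ad = rng.normal(-2, 1, 200)
            if compare_ad_nad(self._frame(ad, nad))["p_value"] < 0.05:
                rejections += 1
        assert rejections > 99

    def test_empty_class_not_applicable(self):
        res = compare_ad_nad(self._frame([-1.0], []))
        assert res["applicable"] is False


class TestReplicateCorrelation:
    def _frames(self, x, y):
        ids = [f"g{i}" for i in range(len(x))]
        a = pd.DataFrame({"guide_id": ids, "lfc": x})
        b = pd.DataFrame({"guide_id": ids, "lfc": y})
        return a, b

    def test_identical_is_one(self):
        a, b = self._frames([1, 2, 3, 4.0], [1, 2, 3, 4.0])
        assert replicate_correlation(a, b)["pearson_r"] == pytest.approx(1)

    def test_negation_is_minus_one(self):
        a, b = self._frames([1, 2, 3.0], [-1, -2, -3.0])
        assert replicate_correlation(a, b)["pearson_r"] == pytest.approx(-1)

    def test_attenuation_yields_r_07(self):
        # y = x + N(0, sigma); r = 1/sqrt(1 + sigma^2) = 0.7 when
        # sigma^2 = 1/0.49 - 1
        rng = np.random.default_rng(12)
        sigma = np.sqrt(1 / 0.49 - 1)
        x = rng.normal(0, 1, 800)
        y = x + rng.normal(0, sigma, 800)
        r = replicate_correlation(*self._frames(x, y))["pearson_r"]
        assert r == pytest.approx(0.7, abs=0.05)

    def test_too_few_guides_rejected(self):
        a, b = self._frames([1, 2.0], [1, 2.0])
        with pytest.raises(ValueError):
            replicate_correlation(a, b)
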