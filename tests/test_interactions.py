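import numpy as np
import pandas as pd
import pytest

from enhancerlink import interactions as ix
from enhancerlink.counts import DesignSpec
from enhancerlink.differential import DifferentialResult
from enhancerlink.intervals import GenomicInterval
from enhancerlink.regulatory import RegulatoryAnnotation
from enhancerlink.synthetic import gen_annotation, gen_interactions, gen_peaks_counts


class TestWidenEnhancer:
    def test_symmetric_expansion_truncated_at_zero(self):
        got = ix.widen_enhancer(GenomicInterval("chr1", 4000, 6000), 10_000)
        assert (got.start, got.end) == (0, 10_000)

    def test_already_wide_interval_unchanged(self):
        iv = GenomicInterval("chr1", 100_000, 112_000)
        assert ix.widen_enhancer(iv, 10_000) is iv

    def test_midpoint_preserved_without_truncation(self):
        iv = GenomicInterval("chr1", 99_000, 101_000)
        got = ix.widen_enhancer(iv, 10_000)
        assert got.midpoint == iv.midpoint and got.width == 10_000


def _toy_annotation():
    promoters = {
        "gA": GenomicInterval("chr1", 7_000, 11_000),
        "gB": GenomicInterval("chr1", 97_000, 101_000),
    }
    enhancers = [
        ("e1", GenomicInterval("chr1", 48_000, 50_000)),
        ("e2", GenomicInterval("chr1", 300_000, 302_000)),
    ]
    return RegulatoryAnnotation(active_promoters=promoters, enhancers=enhancers)


def _toy_interactions():
    rows = [
        # bait gA <-> inside widened e1
        ("gA", "chr1", 8_000, 12_000, "chr1", 47_000, 48_500),
        # bait gA <-> far from any enhancer
        ("gA", "chr1", 8_000, 12_000, "chr1", 800_000, 804_000),
        # bait gB <-> just outside widened e2 ([296000,306000))
        ("gB", "chr1", 96_000, 100_000, "chr1", 306_000, 308_000),
        # unknown bait skipped
        ("gZ", "chr1", 0, 4_000, "chr1", 48_000, 50_000),
    ]
    df = pd.DataFrame(rows, columns=ix.INTERACTION_COLUMNS[:1] + ix.INTERACTION_COLUMNS[1:])
    for j in range(3):
        df[f"count_lib{j}"] = [10, 10, 10, 10]
    return df


class TestExtractPairs:
    def test_toy_map_matches_exhaustive_enumeration(self):
        pairs = ix.extract_promoter_enhancer_pairs(_toy_interactions(), _toy_annotation())
        assert len(pairs) == 1
        assert pairs.iloc[0]["bait_gene_id"] == "gA"
        assert pairs.iloc[0]["enhancer_id"] == "e1"

    def test_emitted_set_equals_bruteforce_on_random_map(self, rng):
        from enhancerlink.intervals import intervals_overlap

        ann = _toy_annotation()
        n = 60
        starts = rng.integers(0, 900_000, n)
        df = pd.DataFrame(
            {
                "bait_gene_id": rng.choice(["gA", "gB"], n),
                "chrom1": "chr1", "start1": 8_000, "end1": 12_000,
                "chrom2": "chr1", "start2": starts, "end2": starts + 2_000,
                "count_l0": 1,
            }
        )
        got = ix.extract_promoter_enhancer_pairs(df, ann)
        got_set = set(zip(got["bait_gene_id"], got["enhancer_id"], got["start2"]))
        expect = set()
        for _, row in df.iterrows():
            oe = GenomicInterval(row.chrom2, int(row.start2), int(row.end2))
            for eid, iv in ann.enhancers:
                if intervals_overlap(oe, ix.widen_enhancer(iv, 10_000)):
                    expect.add((row.bait_gene_id, eid, int(row.start2)))
        assert got_set == expect

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="lacks columns"):
            ix.extract_promoter_enhancer_pairs(pd.DataFrame({"chrom1": []}), _toy_annotation())


def _sim_pairs(seed, decay=-1.0, n_loops=40, base_mean=100.0):
    tss, sizes = gen_annotation(800, 2, 10_000_000, seed=seed)
    pk = gen_peaks_counts(tss, sizes, n_enhancers=250, seed=seed)
    inter, loops = gen_interactions(pk.annotation, tss, n_loops=n_loops,
                                    decay_exponent=decay, base_mean=base_mean,
                                    seed=seed)
    pairs = ix.extract_promoter_enhancer_pairs(inter, pk.annotation)
    return pk.annotation, pairs, loops


class TestDistanceTrend:
    def test_decay_slope_recovered(self):
        # deep coverage so the additive abundance prior cannot flatten
        # the low-count tail of the decay curve
        _, pairs, _ = _sim_pairs(4, base_mean=2000.0)
        trend = ix.fit_distance_trend(pairs)
        # fitted expected log2 abundance vs log2 distance: slope ~ exponent
        x = trend.log10_centers * np.log2(10)
        slope = np.polyfit(x, trend.expected, 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.1)

    def test_flat_for_distance_independent_counts(self, rng):
        n = 600
        d = rng.integers(20_000, 2_000_000, n)
        df = pd.DataFrame(
            {
                "bait_gene_id": "g", "chrom1": "chr1",
                "start1": 0, "end1": 4_000,
                "chrom2": "chr1", "start2": d, "end2": d + 2_000,
            }
        )
        for j in range(4):
            df[f"count_l{j}"] = rng.poisson(100, n)
        trend = ix.fit_distance_trend(df)
        x = trend.log10_centers * np.log2(10)
        slope = np.polyfit(x, trend.expected, 1)[0]
        assert abs(slope) < 0.05

    def test_expected_at_bin_center_is_bin_statistic(self):
        _, pairs, _ = _sim_pairs(8)
        trend = ix.fit_distance_trend(pairs)
        mid = len(trend.log10_centers) // 2
        d = 10 ** trend.log10_centers[mid]
        assert trend.expected_at(np.array([d]))[0] == pytest.approx(
            trend.expected[mid], abs=1e-9)

    def test_too_few_pairs_rejected(self):
        df = _toy_interactions()
        with pytest.raises(ValueError, match="cis pairs"):
            ix.fit_distance_trend(df.iloc[:2])


class TestFilterInteractions:
    def test_thresholds(self):
        # one pair exactly controllable: constant trend at 0 excess
        trend = ix.DistanceTrend(np.array([4.0, 6.0]), np.array([0.0, 0.0]))
        d = 100_000
        df = pd.DataFrame(
            {
                "bait_gene_id": ["g"] * 3, "chrom1": "chr1",
                "start1": 0, "end1": 2_000,
                "chrom2": "chr1", "start2": [d] * 3, "end2": [d + 2_000] * 3,
            }
        )
        df["count_a"] = [60, 40, 15]
        df["count_b"] = [60, 58, 15]
        ab = ix.pair_ave_log_cpm(df)
        kept = ix.filter_interactions(df, trend, min_ave_cpm=2 ** ab[1] - 1e-6, min_fold=1.0)
        assert len(kept) >= 2  # both above the abundance bar
        kept_hi = ix.filter_interactions(df, trend, min_ave_cpm=2 ** ab[0] + 1.0, min_fold=1.0)
        assert len(kept_hi) < len(kept)

    def test_raising_thresholds_is_monotone(self):
        _, pairs, _ = _sim_pairs(12)
        trend = ix.fit_distance_trend(pairs)
        base = ix.filter_interactions(pairs, trend, 5.0, 2.0)
        for cpm_t, fold_t in [(10.0, 2.0), (5.0, 3.0), (20.0, 4.0)]:
            sub = ix.filter_interactions(pairs, trend, cpm_t, fold_t)
            base_keys = set(zip(base["bait_gene_id"], base["enhancer_id"], base["start2"]))
            sub_keys = set(zip(sub["bait_gene_id"], sub["enhancer_id"], sub["start2"]))
            assert sub_keys <= base_keys

    def test_planted_loops_survive_and_background_does_not(self):
        ann, pairs, loops = _sim_pairs(3)
        trend = ix.fit_distance_trend(pairs)
        kept = ix.filter_interactions(pairs, trend)
        kept_keys = set(zip(kept["bait_gene_id"], kept["enhancer_id"]))
        loop_keys = set(zip(loops["gene_id"], loops["enhancer_id"]))
        all_keys = set(zip(pairs["bait_gene_id"], pairs["enhancer_id"]))
        sens = len(kept_keys & loop_keys) / len(loop_keys)
        bg_rate = len(kept_keys - loop_keys) / max(1, len(all_keys - loop_keys))
        assert sens >= 0.95
        assert bg_rate <= 0.05

    def test_kept_enhancers_existed_before_widening(self):
        ann, pairs, _ = _sim_pairs(3)
        kept = ix.filter_interactions(pairs, ix.fit_distance_trend(pairs))
        enh_ids = {eid for eid, _ in ann.enhancers}
        assert set(kept["enhancer_id"]) <= enh_ids


class TestDifferentialInteractions:
    def test_block_design_rejected(self):
        _, pairs, _ = _sim_pairs(2)
        design = DesignSpec(["a", "b", "c", "d"], ["A", "A", "B", "B"],
                            {"B": 1.0, "A": -1.0}, block=["x", "y", "x", "y"])
        with pytest.raises(ValueError, match="no-block"):
            ix.differential_interactions(pairs, design)

    def test_no_significant_pairs_on_pure_null(self, rng):
        n = 200
        d = rng.integers(50_000, 500_000, n)
        df = pd.DataFrame(
            {
                "bait_gene_id": [f"g{i}" for i in range(n)], "chrom1": "chr1",
                "start1": 0, "end1": 2_000, "chrom2": "chr1",
                "start2": d, "end2": d + 2_000,
                "enhancer_id": [f"e{i}" for i in range(n)],
            }
        )
        for j in range(6):
            df[f"count_l{j}"] = rng.poisson(80, n)
        design = DesignSpec([f"count_l{j}" for j in range(6)],
                            ["A"] * 3 + ["B"] * 3, {"B": 1.0, "A": -1.0})
        res = ix.differential_interactions(df, design, alpha=0.05)
        # expected false discoveries under BH at q=0.05 on 200 nulls
        assert (res.table["direction"] != "ns").sum() <= 3
        rej = (res.table.loc[res.table["tested"], "p_value"] < 0.05).mean()
        assert 0.0 <= rej <= 0.09


class TestStatsAndGroups:
    def test_median_of_toy_distances(self):
        ann = _toy_annotation()
        d = [10_000, 50_000, 30_000, 70_000, 20_000]
        kept = pd.DataFrame(
            {
                "bait_gene_id": ["gA", "gA", "gA", "gB", "gB"],
                "enhancer_id": ["e1", "e2", "e1", "e2", "e1"],
                "distance": d,
                "count_l0": 1,
            }
        )
        stats = ix.interaction_stats(kept, ann)
        assert stats["median_distance"] == sorted(d)[2]
        assert stats["median_links_per_promoter"] == pytest.approx(2.5)
        assert stats["promoter_coverage"] == 1.0
        assert stats["enhancer_coverage"] == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ix.interaction_stats(pd.DataFrame(), _toy_annotation())

    @pytest.mark.parametrize(
        "dirs,expected",
        [
            (("ns", "ns"), "None"),
            (("up", "ns"), "Up"),
            (("down", "ns"), "Down"),
            (("up", "down"), "Ambiguous"),
        ],
    )
    def test_promoter_group_rule(self, dirs, expected):
        pairs = pd.DataFrame(
            {"bait_gene_id": ["g", "g"], "enhancer_id": ["e1", "e2"]}
        )
        diff = DifferentialResult(
            pd.DataFrame({"feature_id": ["e1", "e2"], "direction": dirs}), 0.01
        )
        groups = ix.assign_promoter_groups(pairs, diff)
        assert groups.set_index("gene_id").loc["g", "group"] == expected


class TestKs:
    def test_identical_groups_give_zero_d(self):
        groups = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(8)],
             "group": ["Up"] * 4 + ["None"] * 4}
        )
        logfc = pd.Series(
            [1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0],
            index=[f"g{i}" for i in range(8)],
        )
        # Down group absent -> error for that comparison
        with pytest.raises(ValueError, match="Down"):
            ix.ecdf_ks_compare(groups, logfc)

    def test_separated_samples_give_d_of_one(self):
        groups = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(9)],
             "group": ["Up"] * 3 + ["Down"] * 3 + ["None"] * 3}
        )
        logfc = pd.Series([4.0, 5.0, 6.0, -4.0, -5.0, -6.0, 1.0, 2.0, 3.0],
                          index=[f"g{i}" for i in range(9)])
        out = ix.ecdf_ks_compare(groups, logfc).set_index("comparison")
        assert out.loc["Up_vs_None", "D"] == pytest.approx(1.0)
        assert out.loc["Down_vs_None", "D"] == pytest.approx(1.0)

    def test_d_matches_bruteforce_double_ecdf(self, rng):
        from scipy.stats import ks_2samp

        for _ in range(100):
            a = rng.normal(size=rng.integers(3, 25))
            b = rng.normal(size=rng.integers(3, 25))
            pts = np.concatenate([a, b])
            brute = max(
                abs((a <= t).mean() - (b <= t).mean()) for t in pts
            )
            assert ks_2samp(a, b).statistic == pytest.approx(brute, abs=1e-12)

    def test_shifted_up_group_detected(self, rng):
        n = 200
        genes = [f"g{i}" for i in range(2 * n)]
        groups = pd.DataFrame({"gene_id": genes, "group": ["Up"] * n + ["None"] * n})
        down = pd.DataFrame({"gene_id": ["d1", "d2", "d3"], "group": "Down"})
        logfc = pd.Series(
            np.concatenate([rng.normal(0.5, 1.0, n), rng.normal(0.0, 1.0, n),
                            rng.normal(0, 1, 3)]),
            index=genes + ["d1", "d2", "d3"],
        )
        out = ix.ecdf_ks_compare(pd.concat([groups, down]), logfc).set_index("comparison")
        assert out.loc["Up_vs_None", "p_value"] < 0.01
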