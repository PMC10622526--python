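from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from snloh import (
    ArmTable,
    Bin,
    InputError,
    SimConfig,
    VariantRecord,
    bonferroni,
    deletion_missingness_test,
    flag_confounded_snps,
    haplotype_bias,
    loh_test,
    make_arm_bins,
    make_snp_bins,
    partition_by_anchor,
    per_snp_het_proportion,
    prop_het,
    rank_sum_less_p,
    simulate_matrix,
)
from snloh.io import HET, HOM, MISSING, REF
from snloh.loh import CellPartition

from conftest import matrix_from_gt


def brute_force_one_sided_p(x, y):
    """Independent oracle: exhaustive relabeling using the Mann-Whitney
    U statistic computed by pairwise comparison (not midranks)."""
    pooled = list(x) + list(y)
    m = len(x)

    def u_stat(xs, ys):
        u = 0.0
        for a in xs:
            for b in ys:
                u += (a < b) + 0.5 * (a == b)
        return u

    # alternative "x smaller than y" => large U supports the alternative;
    # permutation p is the fraction of relabelings at least as extreme
    u_obs = u_stat(x, y)
    count = total = 0
    for idx in combinations(range(len(pooled)), m):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        count += u_stat(xs, ys) >= u_obs - 1e-9
        total += 1
    return count / total


class TestPartition:
    def test_partition_by_anchor_codes(self):
        gt = np.array([[HET, REF, HOM, MISSING]])
        m = matrix_from_gt(gt)
        m.variants[0].is_anchor = True
        part = partition_by_anchor(m, m.variants[0].key)
        assert part.gof_cells == ["cell0"]
        assert part.wt_cells == ["cell1"]
        assert set(part.excluded_cells) == {"cell2", "cell3"}

    def test_no_anchor_het_cells_errors(self):
        m = matrix_from_gt(np.array([[REF, REF, HOM]]))
        with pytest.raises(InputError, match="anchor-positive"):
            partition_by_anchor(m, m.variants[0].key)

    def test_overlapping_groups_rejected(self):
        with pytest.raises(InputError):
            CellPartition(gof_cells=["a"], wt_cells=["a"], excluded_cells=[])


class TestPropHet:
    def test_worked_example_three_het_two_hom_one_missing(self):
        gt = np.array([[HET], [HET], [HET], [HOM], [HOM], [MISSING]])
        m = matrix_from_gt(gt)
        assert prop_het("cell0", Bin("b", np.arange(6), "window"), m) == 0.6

    def test_all_het_no_missing(self):
        m = matrix_from_gt(np.full((4, 1), HET))
        assert prop_het("cell0", Bin("b", np.arange(4), "window"), m) == 1.0

    def test_all_missing_is_undefined(self):
        m = matrix_from_gt(np.full((4, 1), MISSING))
        assert prop_het("cell0", Bin("b", np.arange(4), "window"), m) is None

    def test_ref_counts_in_denominator_only(self):
        gt = np.array([[HET], [REF], [REF], [REF]])
        m = matrix_from_gt(gt)
        assert prop_het("cell0", Bin("b", np.arange(4), "window"), m) == 0.25


def arm_panel(n_p=6, n_q=5, chrom="7"):
    arms = ArmTable()
    cent = arms.centromere(chrom)
    variants = [
        VariantRecord(chrom=chrom, pos=1000 + 10 * i, ref="A", alt="G", in_dbsnp=True)
        for i in range(n_p)
    ] + [
        VariantRecord(chrom=chrom, pos=cent + 1000 + 10 * i, ref="A", alt="G", in_dbsnp=True)
        for i in range(n_q)
    ]
    return variants, arms


class TestBins:
    def test_sliding_window_count(self):
        variants, arms = arm_panel(n_p=6, n_q=0)
        m = matrix_from_gt(np.full((6, 2), HET), variants=variants)
        bins = make_snp_bins(m, arms, k=4, mode="sliding")
        assert len(bins) == 3  # 6 - 4 + 1

    def test_tiling_drops_remainder(self):
        variants, arms = arm_panel(n_p=6, n_q=0)
        m = matrix_from_gt(np.full((6, 2), HET), variants=variants)
        bins = make_snp_bins(m, arms, k=4, mode="tiling")
        assert len(bins) == 1

    def test_no_bin_spans_centromere(self):
        variants, arms = arm_panel(n_p=6, n_q=5)
        m = matrix_from_gt(np.full((11, 2), HET), variants=variants)
        bins = make_snp_bins(m, arms, k=4, mode="sliding")
        assert len(bins) == (6 - 4 + 1) + (5 - 4 + 1)
        cent = arms.centromere("7")
        for b in bins:
            sides = {m.variants[i].pos <= cent for i in b.snp_indices}
            assert len(sides) == 1

    def test_small_arm_yields_no_window_bins(self):
        variants, arms = arm_panel(n_p=3, n_q=0)
        m = matrix_from_gt(np.full((3, 2), HET), variants=variants)
        assert make_snp_bins(m, arms, k=4) == []

    def test_arm_bins_one_per_arm_incl_singletons(self):
        variants, arms = arm_panel(n_p=6, n_q=1)
        m = matrix_from_gt(np.full((7, 2), HET), variants=variants)
        bins = make_arm_bins(m, arms)
        assert [b.label for b in bins] == ["7p", "7q"]
        assert bins[1].snp_indices.size == 1


class TestRankSum:
    def test_complete_separation_tiny_p(self):
        gof = np.zeros(10)
        wt = np.ones(10)
        _, p = rank_sum_less_p(gof, wt)
        assert p < 1e-4

    def test_identical_groups_large_p(self):
        vals = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
        _, p = rank_sum_less_p(vals, vals.copy())
        assert p >= 0.5

    def test_exact_p_matches_enumeration_worked_case(self):
        gof = [0.25, 0.25, 0.5]
        wt = [0.75, 1.0, 1.0]
        _, p = rank_sum_less_p(np.array(gof), np.array(wt))
        assert p == pytest.approx(brute_force_one_sided_p(gof, wt))
        assert p == pytest.approx(1 / 20)  # C(6,3) relabelings, observed unique minimum

    @pytest.mark.parametrize("seed", range(12))
    def test_exact_p_matches_enumeration_random_ties(self, seed):
        rng = np.random.default_rng(seed)
        m, n = rng.integers(3, 9, size=2)
        grid = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        x = rng.choice(grid, size=m)
        y = rng.choice(grid, size=n)
        _, p = rank_sum_less_p(x, y)
        assert p == pytest.approx(brute_force_one_sided_p(x, y))

    def test_asymptotic_close_to_exact_at_boundary(self, rng):
        # group sizes just above the exact cutoff: the normal approximation
        # should be within a few percent of enumeration
        x = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=8)
        y = rng.choice([0.25, 0.5, 0.75, 1.0], size=8)
        _, p_exact = rank_sum_less_p(x, y)
        p_asym = stats.mannwhitneyu(x, y, alternative="less", method="asymptotic").pvalue
        assert abs(p_exact - p_asym) < 0.05


class TestLohTest:
    def make_partitioned(self, gof_prop, wt_prop, n_snps=4):
        """Matrix whose GoF/WT cells have deterministic Prop_het values."""
        cells = []
        gt_cols = []
        for i, v in enumerate(gof_prop):
            cells.append(f"g{i}")
            n_het = round(v * n_snps)
            gt_cols.append([HET] * n_het + [HOM] * (n_snps - n_het))
        for i, v in enumerate(wt_prop):
            cells.append(f"w{i}")
            n_het = round(v * n_snps)
            gt_cols.append([HET] * n_het + [HOM] * (n_snps - n_het))
        m = matrix_from_gt(np.array(gt_cols).T, cell_ids=cells)
        part = CellPartition(
            gof_cells=[c for c in cells if c.startswith("g")],
            wt_cells=[c for c in cells if c.startswith("w")],
            excluded_cells=[],
        )
        return m, part

    def test_insufficient_cells_flagged_untested(self):
        m, part = self.make_partitioned([0.5] * 3, [1.0] * 10)
        res = loh_test(m, part, Bin("b", np.arange(4), "window"), min_cells=5)
        assert not res.tested and np.isnan(res.p_raw)

    def test_all_missing_cells_excluded_from_samples(self):
        m, part = self.make_partitioned([0.0] * 6, [1.0] * 6)
        ci = m.cell_ids.index("g0")
        m.GT[:, ci] = MISSING
        res = loh_test(m, part, Bin("b", np.arange(4), "window"))
        assert res.n_gof == 5 and res.n_wt == 6

    def test_detects_reduction(self):
        m, part = self.make_partitioned([0.25] * 8, [1.0] * 8)
        res = loh_test(m, part, Bin("b", np.arange(4), "window"))
        assert res.tested and res.p_raw < 1e-3


class TestBonferroni:
    def fake_results(self, p_values, tested=None):
        from snloh import LohResult

        tested = tested or [True] * len(p_values)
        return [
            LohResult(
                bin=Bin("b", np.arange(2), "arm"), n_gof=5, n_wt=5,
                prop_het_gof=np.array([]), prop_het_wt=np.array([]),
                statistic=0.0, p_raw=p, tested=t,
            )
            for p, t in zip(p_values, tested)
        ]

    def test_single_test_unchanged(self):
        (res,) = bonferroni(self.fake_results([0.03]))
        assert res.p_adj == pytest.approx(0.03)

    def test_capped_at_one(self):
        results = bonferroni(self.fake_results([0.3] * 5))
        assert all(r.p_adj == 1.0 for r in results)

    def test_m_counts_only_tested_bins(self):
        results = bonferroni(self.fake_results([0.01, 0.01, np.nan], [True, True, False]))
        assert results[0].p_adj == pytest.approx(0.02)
        assert results[2].p_adj is None

    def test_adjusted_p_nondecreasing_in_family_size(self):
        p1 = bonferroni(self.fake_results([0.02] * 3))[0].p_adj
        p2 = bonferroni(self.fake_results([0.02] * 6))[0].p_adj
        assert p2 >= p1


class TestPerSnpProportion:
    def test_fraction_of_genotyped_cells(self):
        gt = np.array([[HET] * 8 + [HOM] * 2 + [REF] * 5])
        m = matrix_from_gt(gt, cell_ids=[f"c{i}" for i in range(15)])
        part = CellPartition(
            gof_cells=[f"c{i}" for i in range(10, 15)],
            wt_cells=[f"c{i}" for i in range(10)],
            excluded_cells=[],
        )
        tab = per_snp_het_proportion(m, part)
        assert tab["prop_wt"].iloc[0] == pytest.approx(0.8)
        assert tab["prop_gof"].iloc[0] == pytest.approx(0.0)

    def test_no_genotyped_cells_gives_nan(self):
        gt = np.array([[MISSING, HET]])
        m = matrix_from_gt(gt)
        part = CellPartition(gof_cells=["cell0"], wt_cells=["cell1"], excluded_cells=[])
        tab = per_snp_het_proportion(m, part)
        assert np.isnan(tab["prop_gof"].iloc[0])
        assert tab["prop_wt"].iloc[0] == 1.0


class TestDeletionMissingness:
    def build(self, gof_missing_cells, n_gof=12, n_wt=20, wt_missing_cells=0, n_snps=5):
        cells = [f"g{i}" for i in range(n_gof)] + [f"w{i}" for i in range(n_wt)]
        gt = np.full((n_snps, len(cells)), HET)
        for i in range(gof_missing_cells):
            gt[:, i] = MISSING
        for i in range(wt_missing_cells):
            gt[:, n_gof + i] = MISSING
        m = matrix_from_gt(gt, cell_ids=cells)
        part = CellPartition(
            gof_cells=cells[:n_gof], wt_cells=cells[n_gof:], excluded_cells=[]
        )
        return m, part

    def test_upper_tail_binomial_vs_direct_sum(self):
        m, part = self.build(gof_missing_cells=9, n_wt=10, wt_missing_cells=5)
        res = deletion_missingness_test(m, part, np.arange(5))
        assert res.p0 == pytest.approx(0.5)
        from math import comb
        direct = sum(comb(12, x) * 0.5**12 for x in range(9, 13))
        assert res.p_value == pytest.approx(direct)

    def test_zero_all_missing_gives_p_one(self):
        m, part = self.build(gof_missing_cells=0)
        res = deletion_missingness_test(m, part, np.arange(5))
        assert res.p_value == pytest.approx(1.0)

    def test_p0_floored_at_half_pseudocount(self):
        m, part = self.build(gof_missing_cells=9, n_wt=50)
        res = deletion_missingness_test(m, part, np.arange(5))
        assert res.p0_floored and res.p0 == pytest.approx(1 / 100)
        assert res.p_value < 0.01

    def test_partial_missingness_does_not_count(self):
        m, part = self.build(gof_missing_cells=0)
        m.GT[0, 0] = MISSING  # one of five SNPs missing: cell scores 0
        res = deletion_missingness_test(m, part, np.arange(5))
        assert res.k_all_missing == 0

    def test_empty_region_rejected(self):
        m, part = self.build(gof_missing_cells=1)
        with pytest.raises(InputError):
            deletion_missingness_test(m, part, [])


class TestHaplotypeBias:
    def build(self, gof_codes, wt_codes):
        n = len(gof_codes[0])
        cells = [f"g{i}" for i in range(n)] + [f"w{i}" for i in range(n)]
        gt = np.hstack([np.array(gof_codes), np.array(wt_codes)])
        m = matrix_from_gt(gt, cell_ids=cells)
        part = CellPartition(
            gof_cells=cells[:n], wt_cells=cells[n:], excluded_cells=[]
        )
        return m, part

    def test_single_parental_allele_ratio_one(self):
        m, part = self.build([[HOM] * 10], [[HET] * 10])
        tab = haplotype_bias(m, part, [0], germline_het_idx=np.array([0]))
        assert tab["ratio_gof"].iloc[0] == 1.0

    def test_balanced_hom_calls_ratio_half(self):
        m, part = self.build([[HOM] * 5 + [REF] * 5], [[HET] * 10])
        tab = haplotype_bias(m, part, [0], germline_het_idx=np.array([0]))
        assert tab["ratio_gof"].iloc[0] == 0.5

    def test_min_hom_cells_exclusion(self):
        m, part = self.build([[HOM] * 4 + [HET] * 6], [[HET] * 10])
        tab = haplotype_bias(m, part, [0], min_hom_cells=5,
                             germline_het_idx=np.array([0]))
        assert tab.empty

    def test_copy_neutral_simulation_bias_gof_above_wt(self):
        cfg = SimConfig(seed=7, n_wt=80, n_gof=40, loh_region="7q",
                        doublet_rate=0.0)
        matrix, truth = simulate_matrix(cfg)
        part = CellPartition(
            gof_cells=list(truth.cells.loc[truth.cells.clone == "GoF", "cell_id"]),
            wt_cells=list(truth.cells.loc[truth.cells.clone == "WT", "cell_id"]),
            excluded_cells=[],
        )
        tab = haplotype_bias(matrix, part, truth.region_idx)
        assert not tab.empty
        assert tab["ratio_gof"].mean() > tab["ratio_wt"].mean()
        assert ((tab["ratio_gof"] >= 0.5) & (tab["ratio_gof"] <= 1.0)).all()


class TestConfoundedFlags:
    def build_with_indel(self, snp_pos, indel_pos, multi_alt=False):
        variants = [
            VariantRecord(chrom="1", pos=min(snp_pos, indel_pos) - 500, ref="A",
                          alt="G", in_dbsnp=True),
            VariantRecord(chrom="1", pos=min(snp_pos, indel_pos), ref="A" if snp_pos < indel_pos else "CA",
                          alt="G" if snp_pos < indel_pos else "C", in_dbsnp=True),
            VariantRecord(chrom="1", pos=max(snp_pos, indel_pos), ref="CA" if snp_pos < indel_pos else "A",
                          alt="C" if snp_pos < indel_pos else "G", in_dbsnp=True),
        ]
        snp_row = 1 if snp_pos < indel_pos else 2
        variants[snp_row].multi_alt = multi_alt
        gt = np.full((3, 10), HET)
        m = matrix_from_gt(gt, variants=variants)
        part = CellPartition(
            gof_cells=m.cell_ids[:5], wt_cells=m.cell_ids[5:], excluded_cells=[]
        )
        bins = [Bin("region", np.arange(3), "arm")]
        return m, part, bins, snp_row

    def test_near_indel_within_ten_bp(self):
        m, part, bins, row = self.build_with_indel(1000, 1008)
        flags = flag_confounded_snps(m, bins, part)
        rec = flags[flags.variant == m.variants[row].key].iloc[0]
        assert rec["near_indel"]

    def test_indel_eleven_bp_away_not_flagged(self):
        m, part, bins, row = self.build_with_indel(1000, 1011)
        flags = flag_confounded_snps(m, bins, part)
        rec = flags[flags.variant == m.variants[row].key].iloc[0]
        assert not rec["near_indel"]

    def test_multi_alt_flag_propagates(self):
        m, part, bins, row = self.build_with_indel(1000, 2000, multi_alt=True)
        flags = flag_confounded_snps(m, bins, part)
        rec = flags[flags.variant == m.variants[row].key].iloc[0]
        assert rec["multi_alt_het"] and not rec["near_indel"]

    def test_only_high_het_snps_flagged(self):
        m, part, bins, row = self.build_with_indel(1000, 1005)
        gof_idx = m.cell_index(part.gof_cells)
        m.GT[row, gof_idx] = HOM  # GoF het proportion 0: below 0.8 gate
        flags = flag_confounded_snps(m, bins, part)
        assert m.variants[row].key not in set(flags.variant)
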