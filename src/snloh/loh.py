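"""Detection of somatic loss-of-heterozygosity from per-cell genotypes.

The test statistic is the per-cell proportion of heterozygous calls
(Prop_het) over a genomic bin: the fraction of non-missing genotypes in the
bin that are HET. Cells heterozygous for a known somatic anchor variant
(e.g. an activating PIK3CA hotspot) form the lesion-clone ("GoF") group;
cells called REF at the anchor are the wild-type group; HOM or MISSING
anchor calls are excluded because homozygous anchor calls are commonly
allelic-dropout artifacts. A one-sided Wilcoxon rank-sum test asks whether
GoF Prop_het is stochastically smaller than WT Prop_het, Bonferroni-adjusted
within each family of bins (all windows of k SNPs, or all chromosome arms).

The rank-sum p-value is computed by exhaustive permutation (midranks) when
both groups have at most 8 cells, and by the tie-corrected normal
approximation (with continuity correction) otherwise.

Companion statistics: a binomial test on region-wide genotype missingness
(evidence of a homozygous deletion); a per-SNP haplotype-bias ratio (true
LOH retains one parental haplotype, dropout picks alleles at random); and
annotation flags for SNPs whose apparent heterozygosity inside an LOH region
is confounded by indels or multi-allelic sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    HET,
    HOM,
    MISSING,
    REF,
    ArmTable,
    GenotypeMatrix,
    InputError,
    VariantRecord,
    assign_arm,
)

logger = logging.getLogger("snloh")

EXACT_MAX_GROUP = 8  # exhaustive permutation when both groups are this small


@dataclass
class CellPartition:
    """Anchor-defined cell groups: GoF (anchor HET), WT (anchor REF), excluded."""

    gof_cells: list[str]
    wt_cells: list[str]
    excluded_cells: list[str]

    def __post_init__(self) -> None:
        sets = [set(self.gof_cells), set(self.wt_cells), set(self.excluded_cells)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise InputError("partition groups overlap")


def partition_by_anchor(
    matrix: GenotypeMatrix, anchor: VariantRecord | str
) -> CellPartition:
    """Split cells by their genotype at the somatic anchor variant.

    Only cells heterozygous for the anchor enter the GoF group; HOM calls may
    be dropout artifacts and MISSING calls carry no clone information, so
    both are excluded rather than treated as WT.
    """
    idx = matrix.variant_index(anchor if isinstance(anchor, str) else anchor.key)
    codes = matrix.GT[idx]
    cells = np.asarray(matrix.cell_ids)
    gof = cells[codes == HET].tolist()
    wt = cells[codes == REF].tolist()
    excluded = cells[(codes == HOM) | (codes == MISSING)].tolist()
    if not gof:
        raise InputError("no anchor-positive (heterozygous) cells")
    return CellPartition(gof_cells=gof, wt_cells=wt, excluded_cells=excluded)


@dataclass
class Bin:
    """A set of consecutive within-arm SNPs tested as one region."""

    label: str
    snp_indices: np.ndarray
    kind: str  # "window" or "arm"

    def __post_init__(self) -> None:
        self.snp_indices = np.asarray(self.snp_indices, dtype=np.intp)
        if self.snp_indices.size and np.any(np.diff(self.snp_indices) <= 0):
            raise InputError(f"bin {self.label}: indices not strictly increasing")


@dataclass
class LohResult:
    """Rank-sum comparison of Prop_het between GoF and WT cells in one bin."""

    bin: Bin
    n_gof: int
    n_wt: int
    prop_het_gof: np.ndarray
    prop_het_wt: np.ndarray
    statistic: float
    p_raw: float
    tested: bool
    p_adj: float | None = None
    significant: bool | None = None

    @property
    def median_gof(self) -> float:
        return float(np.median(self.prop_het_gof)) if self.n_gof else float("nan")

    @property
    def median_wt(self) -> float:
        return float(np.median(self.prop_het_wt)) if self.n_wt else float("nan")


def prop_het(cell: str, bin: Bin, matrix: GenotypeMatrix) -> float | None:
    """Per-cell proportion of heterozygous calls over the bin's SNPs.

    Missing genotypes are excluded from the denominator: 3 HET, 2 HOM and 1
    MISSING over 6 SNPs gives 3/5 = 0.6. Returns None when every genotype in
    the bin is missing (the cell is then excluded from the bin's test).
    """
    ci = matrix.cell_ids.index(cell)
    codes = matrix.GT[bin.snp_indices, ci]
    n_called = int((codes != MISSING).sum())
    if n_called == 0:
        return None
    return float((codes == HET).sum() / n_called)


def _prop_het_values(
    matrix: GenotypeMatrix, bin: Bin, cell_idx: np.ndarray
) -> np.ndarray:
    """Defined Prop_het values for the given cells (all-missing cells dropped)."""
    codes = matrix.GT[np.ix_(bin.snp_indices, cell_idx)]
    called = (codes != MISSING).sum(axis=0)
    het = (codes == HET).sum(axis=0)
    defined = called > 0
    return het[defined] / called[defined]


def make_snp_bins(
    matrix: GenotypeMatrix,
    arms: ArmTable,
    k: int = 4,
    mode: str = "sliding",
) -> list[Bin]:
    """Bins of k consecutive SNPs within each chromosome arm.

    ``sliding`` emits every window of k consecutive SNPs (step 1), so any
    region encompassing k germline SNPs is tested; ``tiling`` emits disjoint
    blocks (remainder dropped) as a cheaper alternative. Bins never span a
    centromere. Arms with fewer than k SNPs yield no bins.
    """
    if k < 2:
        raise InputError("bin size k must be >= 2")
    if mode not in ("sliding", "tiling"):
        raise InputError(f"unknown bin mode {mode!r}")
    by_arm: dict[str, list[int]] = {}
    for i, v in enumerate(matrix.variants):
        by_arm.setdefault(assign_arm(v, arms), []).append(i)

    bins: list[Bin] = []
    for arm_label in sorted(by_arm):
        idx = by_arm[arm_label]
        if len(idx) < k:
            logger.info("arm %s has %d < %d SNPs; no window bins", arm_label, len(idx), k)
            continue
        starts = range(0, len(idx) - k + 1, 1 if mode == "sliding" else k)
        for s in starts:
            window = idx[s : s + k]
            if len(window) < k:
                break
            bins.append(
                Bin(label=f"{arm_label}:win{s}", snp_indices=np.array(window), kind="window")
            )
    return bins


def make_arm_bins(matrix: GenotypeMatrix, arms: ArmTable) -> list[Bin]:
    """One bin per chromosome arm holding all its retained SNPs."""
    by_arm: dict[str, list[int]] = {}
    for i, v in enumerate(matrix.variants):
        by_arm.setdefault(assign_arm(v, arms), []).append(i)
    return [
        Bin(label=arm_label, snp_indices=np.array(by_arm[arm_label]), kind="arm")
        for arm_label in sorted(by_arm)
    ]


# ---------------------------------------------------------------------------
# Rank-sum machinery
# ---------------------------------------------------------------------------

def rank_sum_less_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum: alternative 'x stochastically < y'.

    Returns (W, p) where W is the midrank sum of x. Exhaustive permutation
    over all C(n, m) group relabelings when both groups are small; otherwise
    the tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w_obs = float(ranks[:m].sum())

    if m <= EXACT_MAX_GROUP and n <= EXACT_MAX_GROUP:
        total = comb(m + n, m)
        count = 0
        for subset in combinations(range(m + n), m):
            if ranks[list(subset)].sum() <= w_obs + 1e-9:
                count += 1
        return w_obs, count / total

    res = stats.mannwhitneyu(x, y, alternative="less", method="asymptotic")
    return w_obs, float(res.pvalue)


def loh_test(
    matrix: GenotypeMatrix,
    partition: CellPartition,
    bin: Bin,
    min_cells: int = 5,
) -> LohResult:
    """One-sided rank-sum test of reduced Prop_het in GoF cells for one bin.

    Cells whose bin genotypes are all missing are dropped. When either group
    has fewer than ``min_cells`` defined values the result is flagged
    untested (p_raw = NaN) rather than raising.
    """
    gof_vals = _prop_het_values(matrix, bin, matrix.cell_index(partition.gof_cells))
    wt_vals = _prop_het_values(matrix, bin, matrix.cell_index(partition.wt_cells))
    if len(gof_vals) < min_cells or len(wt_vals) < min_cells:
        return LohResult(
            bin=bin,
            n_gof=len(gof_vals),
            n_wt=len(wt_vals),
            prop_het_gof=gof_vals,
            prop_het_wt=wt_vals,
            statistic=float("nan"),
            p_raw=float("nan"),
            tested=False,
        )
    w, p = rank_sum_less_p(gof_vals, wt_vals)
    return LohResult(
        bin=bin,
        n_gof=len(gof_vals),
        n_wt=len(wt_vals),
        prop_het_gof=gof_vals,
        prop_het_wt=wt_vals,
        statistic=w,
        p_raw=p,
        tested=True,
    )


def bonferroni(results: list[LohResult], alpha: float = 0.05) -> list[LohResult]:
    """Bonferroni adjustment within one family of bins.

    m is the number of bins actually tested (untested bins contribute no
    inference). Untested results keep p_adj = None.
    """
    m = sum(r.tested for r in results)
    out = []
    for r in results:
        if r.tested:
            p_adj = min(1.0, m * r.p_raw)
            out.append(replace(r, p_adj=p_adj, significant=bool(p_adj < alpha)))
        else:
            out.append(replace(r))
    return out


def results_table(results: list[LohResult]) -> pd.DataFrame:
    """Flat table of LOH test results, one row per bin."""
    return pd.DataFrame(
        {
            "bin": [r.bin.label for r in results],
            "kind": [r.bin.kind for r in results],
            "n_snps": [r.bin.snp_indices.size for r in results],
            "n_gof": [r.n_gof for r in results],
            "n_wt": [r.n_wt for r in results],
            "median_prop_het_gof": [r.median_gof for r in results],
            "median_prop_het_wt": [r.median_wt for r in results],
            "statistic": [r.statistic for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adj": [r.p_adj if r.p_adj is not None else float("nan") for r in results],
            "significant": [bool(r.significant) for r in results],
            "tested": [r.tested for r in results],
        }
    )


def per_snp_het_proportion(
    matrix: GenotypeMatrix, partition: CellPartition
) -> pd.DataFrame:
    """Per-variant fraction of genotyped cells called HET, per cell group.

    The basis of the per-SNP bar-chart comparison between GoF and WT cells;
    NaN where a group has no genotyped cell at the variant.
    """
    rows = []
    for group, cells in (("gof", partition.gof_cells), ("wt", partition.wt_cells)):
        ci = matrix.cell_index(cells)
        codes = matrix.GT[:, ci] if ci.size else np.empty((matrix.n_variants, 0), int)
        genotyped = (codes != MISSING).sum(axis=1)
        het = (codes == HET).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            prop = np.where(genotyped > 0, het / np.maximum(genotyped, 1), np.nan)
        rows.append((f"prop_{group}", prop, genotyped))
    return pd.DataFrame(
        {
            "variant": matrix.variant_keys,
            "var_id": [v.var_id for v in matrix.variants],
            rows[0][0]: rows[0][1],
            "n_gof_genotyped": rows[0][2],
            rows[1][0]: rows[1][1],
            "n_wt_genotyped": rows[1][2],
        }
    )


# ---------------------------------------------------------------------------
# Deletion-missingness test
# ---------------------------------------------------------------------------

@dataclass
class DeletionTestResult:
    k_all_missing: int
    n_gof: int
    p0: float
    p_value: float
    p0_floored: bool


def deletion_missingness_test(
    matrix: GenotypeMatrix,
    partition: CellPartition,
    region_variant_idx,
    p0_floor: float | None = None,
) -> DeletionTestResult:
    """Binomial test for region-wide genotype missingness in GoF cells.

    A homozygous deletion leaves no template, so every SNP inside the deleted
    region drops out. Each GoF cell is scored 1 if ALL region SNPs are
    MISSING, else 0; k of n such cells are compared against the wild-type
    all-missing rate p0 with an upper-tail binomial test P(X >= k | n, p0).
    When no WT cell is all-missing, p0 is floored at half a pseudo-count,
    1/(2*n_wt), to avoid a degenerate zero-probability null.
    """
    region = np.asarray(region_variant_idx, dtype=np.intp)
    if region.size == 0:
        raise InputError("empty region after QC")
    gof_idx = matrix.cell_index(partition.gof_cells)
    wt_idx = matrix.cell_index(partition.wt_cells)
    if gof_idx.size == 0 or wt_idx.size == 0:
        raise InputError("deletion test needs >= 1 cell in each group")

    all_missing_gof = (matrix.GT[np.ix_(region, gof_idx)] == MISSING).all(axis=0)
    all_missing_wt = (matrix.GT[np.ix_(region, wt_idx)] == MISSING).all(axis=0)
    k = int(all_missing_gof.sum())
    n = int(gof_idx.size)
    p0 = float(all_missing_wt.mean())
    floored = False
    if p0 == 0.0:
        p0 = p0_floor if p0_floor is not None else 1.0 / (2.0 * wt_idx.size)
        floored = True
    p_value = float(stats.binom.sf(k - 1, n, p0))
    return DeletionTestResult(k_all_missing=k, n_gof=n, p0=p0, p_value=p_value, p0_floored=floored)


# ---------------------------------------------------------------------------
# Haplotype bias
# ---------------------------------------------------------------------------

def germline_het_sites_from_wt(
    matrix: GenotypeMatrix, partition: CellPartition, min_het_frac: float = 0.5
) -> np.ndarray:
    """Variant indices called HET in >= min_het_frac of genotyped WT cells.

    Serves as the consensus set of true germline heterozygous sites when no
    external truth is available; at such sites a REF call in a single cell
    means homozygous-reference (dropout of the alternate allele, or LOH
    retaining the reference haplotype).
    """
    wt_idx = matrix.cell_index(partition.wt_cells)
    codes = matrix.GT[:, wt_idx]
    genotyped = (codes != MISSING).sum(axis=1)
    het = (codes == HET).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(genotyped > 0, het / np.maximum(genotyped, 1), 0.0)
    return np.flatnonzero(frac >= min_het_frac)


def haplotype_bias(
    matrix: GenotypeMatrix,
    partition: CellPartition,
    region_variant_idx,
    min_hom_cells: int = 5,
    germline_het_idx: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-SNP homozygous-call haplotype bias inside a called LOH region.

    For each germline-HET SNP, the ratio max(hom_ref, hom_alt) / total
    homozygous calls per cell group. True LOH retains one parental haplotype,
    so the ratio tends to 1 in GoF cells, while random allelic dropout gives
    ratios near 0.5. REF calls count as homozygous-reference only at known
    germline heterozygous sites (WT-consensus by default), since at other
    sites a REF call is simply the germline genotype. SNPs with fewer than
    ``min_hom_cells`` homozygous GoF calls are excluded.
    """
    region = np.asarray(region_variant_idx, dtype=np.intp)
    if germline_het_idx is None:
        germline_het_idx = germline_het_sites_from_wt(matrix, partition)
    het_sites = set(germline_het_idx.tolist())
    gof_idx = matrix.cell_index(partition.gof_cells)
    wt_idx = matrix.cell_index(partition.wt_cells)

    rows = []
    for i in region:
        if i not in het_sites:
            continue
        ratios = {}
        counts = {}
        for group, ci in (("gof", gof_idx), ("wt", wt_idx)):
            codes = matrix.GT[i, ci]
            hom_alt = int((codes == HOM).sum())
            hom_ref = int((codes == REF).sum())
            total = hom_alt + hom_ref
            counts[group] = total
            ratios[group] = max(hom_ref, hom_alt) / total if total > 0 else np.nan
        if counts["gof"] < min_hom_cells:
            continue
        rows.append(
            {
                "variant": matrix.variants[i].key,
                "ratio_gof": ratios["gof"],
                "n_hom_gof": counts["gof"],
                "ratio_wt": ratios["wt"],
                "n_hom_wt": counts["wt"],
            }
        )
    return pd.DataFrame(rows, columns=["variant", "ratio_gof", "n_hom_gof", "ratio_wt", "n_hom_wt"])


# ---------------------------------------------------------------------------
# Confounded-SNP flags
# ---------------------------------------------------------------------------

def flag_confounded_snps(
    matrix: GenotypeMatrix,
    loh_bins: list[Bin],
    partition: CellPartition,
    prop_het_threshold: float = 0.8,
    indel_distance: int = 10,
    panel_indels: list[VariantRecord] | None = None,
) -> pd.DataFrame:
    """Annotate suspiciously heterozygous SNPs inside called LOH regions.

    SNPs within an LOH region whose GoF heterozygous-call proportion exceeds
    ``prop_het_threshold`` are checked for three known confounders: overlap
    with a panel indel, heterozygosity for two alternate alleles at the
    locus, and proximity (<= ``indel_distance`` bp) to a panel indel. Flags
    are annotations only; no variant is removed.
    """
    if panel_indels is None:
        panel_indels = [v for v in matrix.variants if v.is_indel]
    prop = per_snp_het_proportion(matrix, partition)
    loh_snp_idx = sorted({int(i) for b in loh_bins for i in b.snp_indices})

    rows = []
    for i in loh_snp_idx:
        v = matrix.variants[i]
        if v.is_indel:
            continue
        p_gof = prop["prop_gof"].iloc[i]
        if not (p_gof > prop_het_threshold):
            continue
        span_hits = [
            d
            for d in panel_indels
            if d.chrom == v.chrom and d.pos <= v.pos <= d.pos + len(d.ref) - 1
        ]
        near_hits = [
            d
            for d in panel_indels
            if d.chrom == v.chrom and abs(d.pos - v.pos) <= indel_distance
        ]
        rows.append(
            {
                "variant": v.key,
                "prop_het_gof": float(p_gof),
                "overlaps_indel": bool(span_hits),
                "multi_alt_het": bool(v.multi_alt),
                "near_indel": bool(near_hits),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["variant", "prop_het_gof", "overlaps_indel", "multi_alt_het", "near_indel"],
    )
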