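"""Per-cell genotype refinement and germline-SNP selection.

Raw per-cell calls from a targeted single-nucleus panel are re-derived from
depth, genotype quality and alternate-allele fraction, then the panel is
reduced to well-genotyped germline SNPs. The default thresholds are the
mosaic-style values used for Tapestri data: depth >= 10, GQ >= 30, VAF bands
at 5 / 15 / 95 percent, variant genotyped in >= 75% of cells and mutant in
>= 50% of genotyped cells.

"Mutant in >= 50%" is counted among genotyped cells, not all cells: the
filter's purpose is to keep germline heterozygous SNPs, and missingness
varies strongly between cells. Whitelisted somatic anchor variants bypass
every criterion, since a subclonal somatic variant cannot meet filters
designed for germline sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import HET, HOM, MISSING, REF, GenotypeMatrix, InputError

logger = logging.getLogger("snloh")


@dataclass(frozen=True)
class FilterThresholds:
    """Genotype-call and germline-SNP selection thresholds.

    VAF bands are percentages of alternate reads: at or below ``vaf_ref_max``
    the call is REF, at or above ``vaf_hom_min`` HOM, at or above
    ``vaf_het_min`` HET; anything between the REF and HET bands is ambiguous
    and left MISSING rather than forced to the nearest code.
    """

    min_depth: int = 10
    min_gq: int = 30
    vaf_ref_max: float = 5.0
    vaf_hom_min: float = 95.0
    vaf_het_min: float = 15.0
    min_pct_cells_genotyped: float = 75.0
    min_pct_cells_mutant: float = 50.0

    def __post_init__(self) -> None:
        pcts = (
            self.vaf_ref_max,
            self.vaf_hom_min,
            self.vaf_het_min,
            self.min_pct_cells_genotyped,
            self.min_pct_cells_mutant,
        )
        if not all(0 <= p <= 100 for p in pcts):
            raise InputError("percent thresholds must lie in [0, 100]")
        if not (self.vaf_ref_max < self.vaf_het_min <= self.vaf_hom_min):
            raise InputError(
                "VAF bands must satisfy ref_max < het_min <= hom_min, got "
                f"{self.vaf_ref_max} / {self.vaf_het_min} / {self.vaf_hom_min}"
            )


def call_genotype(dp: int, gq: int, ad_alt: int, t: FilterThresholds) -> int:
    """Call one genotype from depth, quality and alternate-read count.

    MISSING when depth or quality fails; otherwise banded on the
    alternate-allele percentage v = 100*ad_alt/dp (REF band, ambiguous gap,
    HET band, HOM band).
    """
    if dp == 0 and ad_alt > 0:
        raise InputError(f"ad_alt={ad_alt} with zero depth")
    if ad_alt > dp:
        raise InputError(f"ad_alt={ad_alt} exceeds depth {dp}")
    if dp < t.min_depth or gq < t.min_gq:
        return MISSING
    v = 100.0 * ad_alt / dp
    if v <= t.vaf_ref_max:
        return REF
    if v >= t.vaf_hom_min:
        return HOM
    if v >= t.vaf_het_min:
        return HET
    return MISSING


def call_genotypes(
    dp: np.ndarray, gq: np.ndarray, ad_alt: np.ndarray, t: FilterThresholds
) -> np.ndarray:
    """Vectorized :func:`call_genotype` over arrays of identical shape."""
    dp = np.asarray(dp)
    ad_alt = np.asarray(ad_alt)
    if np.any((dp == 0) & (ad_alt > 0)):
        raise InputError("ad_alt > 0 at entries with zero depth")
    if np.any(ad_alt > dp):
        raise InputError("AD_ALT exceeds DP at some entries")
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(dp > 0, 100.0 * ad_alt / np.maximum(dp, 1), 0.0)
    gt = np.full(dp.shape, MISSING, dtype=np.int64)
    ok = (dp >= t.min_depth) & (np.asarray(gq) >= t.min_gq)
    gt[ok & (v <= t.vaf_ref_max)] = REF
    gt[ok & (v > t.vaf_ref_max) & (v >= t.vaf_hom_min)] = HOM
    gt[ok & (v > t.vaf_ref_max) & (v < t.vaf_hom_min) & (v >= t.vaf_het_min)] = HET
    return gt


def refine_matrix(matrix: GenotypeMatrix, t: FilterThresholds | None = None) -> GenotypeMatrix:
    """Recompute every genotype call from DP/GQ/AD_ALT. Idempotent."""
    t = t or FilterThresholds()
    out = matrix.copy()
    out.GT = call_genotypes(out.DP, out.GQ, out.AD_ALT, t)
    return out


def select_germline_snvs(
    matrix: GenotypeMatrix,
    t: FilterThresholds | None = None,
    snv_only: bool = True,
) -> GenotypeMatrix:
    """Reduce the panel to well-genotyped germline SNPs (plus anchors).

    Keeps variants that are (a) genotyped in >= min_pct_cells_genotyped of
    cells, (b) mutant (HET or HOM) in >= min_pct_cells_mutant of genotyped
    cells, and (c) present in dbSNP; indels are dropped when ``snv_only``.
    Whitelisted anchors are always retained.
    """
    t = t or FilterThresholds()
    gt = matrix.GT
    n_cells = matrix.n_cells
    genotyped = (gt != MISSING).sum(axis=1)
    mutant = ((gt == HET) | (gt == HOM)).sum(axis=1)
    pct_genotyped = 100.0 * genotyped / n_cells
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_mutant = np.where(genotyped > 0, 100.0 * mutant / np.maximum(genotyped, 1), 0.0)

    keep = []
    for i, v in enumerate(matrix.variants):
        if v.is_anchor:
            keep.append(i)
            continue
        if pct_genotyped[i] < t.min_pct_cells_genotyped:
            continue
        if pct_mutant[i] < t.min_pct_cells_mutant:
            continue
        if not v.in_dbsnp:
            continue
        if snv_only and v.is_indel:
            continue
        keep.append(i)
    if not keep:
        logger.warning("no variants pass germline-SNP selection")
    return matrix.subset(variant_idx=np.array(keep, dtype=np.intp))


def region_high_confidence(
    matrix: GenotypeMatrix,
    region_variant_idx,
    min_depth: float = 50.0,
    min_cell_genotyped_frac: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """High-confidence (variant, cell) subsets for a deletion region.

    Keeps region variants whose mean depth across cells is strictly above
    ``min_depth`` and cells with strictly more than ``min_cell_genotyped_frac``
    of genotypes present across the whole panel. Returns (variant indices,
    cell indices) into the input matrix.
    """
    region_variant_idx = np.asarray(region_variant_idx, dtype=np.intp)
    if region_variant_idx.size == 0:
        raise InputError("empty region")
    mean_depth = matrix.DP[region_variant_idx].mean(axis=1)
    keep_variants = region_variant_idx[mean_depth > min_depth]
    frac_genotyped = (matrix.GT != MISSING).mean(axis=0)
    keep_cells = np.flatnonzero(frac_genotyped > min_cell_genotyped_frac)
    return keep_variants, keep_cells
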