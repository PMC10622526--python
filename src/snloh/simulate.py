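"""Synthetic targeted single-nucleus DNA-seq genotype matrices.

The generator emulates the statistical structure the LOH analysis relies on:
a panel of germline heterozygous SNPs spread over chromosome arms, one
whitelisted somatic anchor variant defining the lesion clone, an optional
LOH subclone over one arm (copy-neutral or copy-loss), allelic dropout
(default rate 0.2, matching the ~80% heterozygous-call rate observed at
germline sites in real nuclei), random genotype missingness, negative-
binomial read depth, and Poisson-style droplet doublets that merge the reads
of two nuclei.

Read counts are generated first and genotypes are then called through the
standard filtering thresholds, so depth- and VAF-driven missingness reaches
the caller the same way it does in real data. All randomness flows from the
single seed in :class:`SimConfig`; identical configs give bitwise-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .filtering import FilterThresholds, call_genotypes
from .io import (
    ArmTable,
    GenotypeMatrix,
    InputError,
    VariantRecord,
    assign_arm,
    chrom_sort_key,
    parse_variant_key,
)

ANCHOR_KEY = "3:178952085:A:G"  # PIK3CA hotspot locus used as default anchor


def default_panel() -> list[VariantRecord]:
    """Default panel: 2 chromosomes x 2 arms x 25 germline-HET SNPs,
    one germline indel, and one anchor site on a third chromosome
    (mirroring an activating PIK3CA variant on chr3 with LOH sought on
    chr7)."""
    arms = ArmTable()
    records: list[VariantRecord] = []
    ridx = 0
    for chrom in ("2", "7"):
        cent = arms.centromere(chrom)
        p_pos = np.linspace(2_000_000, cent - 1_000_000, 25).astype(int)
        q_pos = np.linspace(cent + 1_000_000, cent + 90_000_000, 25).astype(int)
        for pos in np.concatenate([p_pos, q_pos]):
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=int(pos),
                    ref="A",
                    alt="G",
                    var_id=f"rs9{ridx:06d}",
                    in_dbsnp=True,
                )
            )
            ridx += 1
    # one germline heterozygous indel on 7p (CA/C, VCF left-aligned style)
    records.append(
        VariantRecord(
            chrom="7",
            pos=45_112_337,
            ref="CA",
            alt="C",
            var_id=f"rs9{ridx:06d}",
            in_dbsnp=True,
        )
    )
    chrom, pos, ref, alt = parse_variant_key(ANCHOR_KEY)
    records.append(
        VariantRecord(
            chrom=chrom, pos=pos, ref=ref, alt=alt,
            var_id=None, in_dbsnp=False, is_anchor=True,
        )
    )
    records.sort(key=lambda v: (chrom_sort_key(v.chrom), v.pos))
    return records


@dataclass
class SimConfig:
    """Study conditions for one synthetic lesion.

    ``ado_rate`` is the probability that a true heterozygous site loses one
    allele before amplification (the dominant single-cell artifact);
    ``loh_site_penetrance`` is the per-site probability that LOH manifests in
    a carrier cell, letting an absolute Prop_het reduction delta be injected
    as penetrance = delta / (1 - ado_rate) (see
    :func:`penetrance_for_reduction`). ``clones`` optionally replaces the
    anchor-vs-WT structure with explicit somatic clones for co-mutation
    scenarios: a list of (name, cell fraction, list of variant keys).
    """

    seed: int = 0
    n_wt: int = 100
    n_gof: int = 30
    frac_gof_loh: float = 1.0
    panel: list[VariantRecord] | None = None
    loh_region: str | None = None  # arm label, e.g. "7q"
    loh_region_indices: list[int] | None = None  # explicit panel rows; overrides arm
    loh_type: str = "copy_neutral"
    loh_site_penetrance: float = 1.0
    ado_rate: float = 0.2
    missing_rate: float = 0.05
    depth_mean: float = 80.0
    depth_dispersion: float = 4.0
    doublet_rate: float = 0.05
    seq_error: float = 0.001
    loss_missing_prob: float = 0.9
    full_region_dropout: bool = False
    retained_haplotype: str = "random"  # "random" | "ref" | "alt"
    clones: list[tuple[str, float, list[str]]] | None = None
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)

    def __post_init__(self) -> None:
        for name in ("frac_gof_loh", "ado_rate", "missing_rate", "doublet_rate",
                     "loh_site_penetrance", "loss_missing_prob"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise InputError(f"{name}={val} outside [0, 1]")
        if self.n_wt + self.n_gof < 2:
            raise InputError("need at least 2 cells")
        if self.loh_type not in ("copy_neutral", "copy_loss"):
            raise InputError(f"unknown loh_type {self.loh_type!r}")


def penetrance_for_reduction(delta: float, ado_rate: float = 0.2) -> float:
    """Per-site LOH penetrance that injects an absolute Prop_het reduction.

    The baseline heterozygous-call rate is 1 - ado_rate; forcing
    homozygosity at a fraction q of sites reduces it by q*(1 - ado_rate), so
    q = delta / (1 - ado_rate).
    """
    base = 1.0 - ado_rate
    if not 0 < delta <= base:
        raise InputError(f"delta must be in (0, {base}]")
    return delta / base


@dataclass
class SimTruth:
    """Ground truth for one simulated matrix."""

    cells: pd.DataFrame  # cell_id, clone, loh_carrier, retained_hap, doublet
    true_dosage: np.ndarray  # sites x cells alt-allele dosage in {0, .5, 1}
    alt_on_retained: np.ndarray  # per-site: retained haplotype carries ALT
    region_idx: np.ndarray  # panel indices of the LOH region (may be empty)


def _region_indices(
    panel: Sequence[VariantRecord],
    region: str | None,
    arms: ArmTable,
    explicit: list[int] | None = None,
) -> np.ndarray:
    if explicit is not None:
        idx = np.asarray(explicit, dtype=np.intp)
        if idx.size == 0 or idx.min() < 0 or idx.max() >= len(panel):
            raise InputError("loh_region_indices outside the panel")
        return idx
    if region is None:
        return np.array([], dtype=np.intp)
    idx = [
        i
        for i, v in enumerate(panel)
        if not v.is_anchor and assign_arm(v, arms) == region
    ]
    if not idx:
        raise InputError(f"LOH region {region!r} matches no panel site")
    return np.array(idx, dtype=np.intp)


def simulate_matrix(cfg: SimConfig, arms: ArmTable | None = None) -> tuple[GenotypeMatrix, SimTruth]:
    """Generate one synthetic genotype matrix plus its ground truth.

    Per cell x site: true alt dosage (0, 0.5 or 1) -> allelic dropout ->
    negative-binomial depth (halved in copy-loss regions of carrier cells)
    -> binomial alt reads -> doublet barcode merging -> genotype calling
    through the standard thresholds.
    """
    arms = arms or ArmTable()
    rng = np.random.default_rng(cfg.seed)
    panel = cfg.panel if cfg.panel is not None else default_panel()
    n_sites = len(panel)
    n_cells = cfg.n_wt + cfg.n_gof
    anchor_rows = [i for i, v in enumerate(panel) if v.is_anchor]

    # --- clone labels -----------------------------------------------------
    if cfg.clones is not None:
        names = [c[0] for c in cfg.clones]
        fracs = np.array([c[1] for c in cfg.clones], dtype=float)
        if fracs.sum() > 1.0 + 1e-9:
            raise InputError("clone fractions exceed 1")
        probs = np.concatenate([fracs, [1.0 - fracs.sum()]])
        labels = rng.choice(names + ["WT"], size=n_cells, p=probs)
        cell_ids = [f"cell{j:05d}" for j in range(n_cells)]
        key_to_row = {v.key: i for i, v in enumerate(panel)}
        clone_sites = {
            name: [key_to_row[k] for k in keys] for name, _, keys in cfg.clones
        }
        is_gof = np.zeros(n_cells, dtype=bool)
    else:
        labels = np.array(["WT"] * cfg.n_wt + ["GoF"] * cfg.n_gof)
        cell_ids = [f"{lab}_{j:05d}" for j, lab in enumerate(labels)]
        clone_sites = {}
        is_gof = labels == "GoF"

    # --- true dosage ------------------------------------------------------
    dosage = np.full((n_sites, n_cells), 0.5)  # germline sites are HET
    for i in anchor_rows:
        dosage[i] = np.where(is_gof, 0.5, 0.0)
    for name, sites in clone_sites.items():
        carrier = labels == name
        for i in sites:
            dosage[i] = np.where(carrier, 0.5, dosage[i])
    if cfg.clones is not None:
        # non-clone somatic sites stay REF in everyone else
        somatic_rows = {i for sites in clone_sites.values() for i in sites}
        for i in somatic_rows:
            non_carrier = ~np.isin(labels, [n for n in clone_sites if i in clone_sites[n]])
            dosage[i, non_carrier] = 0.0

    # --- LOH --------------------------------------------------------------
    region_idx = _region_indices(panel, cfg.loh_region, arms, cfg.loh_region_indices)
    carriers = np.zeros(n_cells, dtype=bool)
    retained_hap = np.array(["none"] * n_cells, dtype=object)
    alt_on_retained = np.zeros(n_sites, dtype=bool)
    if region_idx.size and cfg.frac_gof_loh > 0 and is_gof.any():
        gof_idx = np.flatnonzero(is_gof)
        n_carriers = int(round(cfg.frac_gof_loh * gof_idx.size))
        chosen = rng.choice(gof_idx, size=n_carriers, replace=False)
        carriers[chosen] = True
        # the LOH subclone retains one haplotype; per-site phase decides the
        # retained allele, so homozygous calls agree across carrier cells
        if cfg.retained_haplotype == "random":
            alt_on_retained[region_idx] = rng.random(region_idx.size) < 0.5
        elif cfg.retained_haplotype == "alt":
            alt_on_retained[region_idx] = True
        retained_hap[carriers] = "hap1"
        penetrant = (
            rng.random((region_idx.size, n_cells)) < cfg.loh_site_penetrance
        ) & carriers[None, :]
        loh_dosage = np.where(alt_on_retained[region_idx, None], 1.0, 0.0)
        block = dosage[region_idx]
        dosage[region_idx] = np.where(penetrant, np.broadcast_to(loh_dosage, block.shape), block)

    # --- allelic dropout --------------------------------------------------
    is_het = dosage == 0.5
    ado = is_het & (rng.random((n_sites, n_cells)) < cfg.ado_rate)
    ado_to_alt = rng.random((n_sites, n_cells)) < 0.5
    dosage = np.where(ado, np.where(ado_to_alt, 1.0, 0.0), dosage)

    # --- depth and reads --------------------------------------------------
    r = cfg.depth_dispersion
    mean = np.full((n_sites, n_cells), cfg.depth_mean)
    if cfg.loh_type == "copy_loss" and carriers.any() and region_idx.size:
        mean[np.ix_(region_idx, np.flatnonzero(carriers))] *= 0.5
    dp = rng.negative_binomial(r, r / (r + mean))
    dp[rng.random((n_sites, n_cells)) < cfg.missing_rate] = 0
    if cfg.loh_type == "copy_loss" and carriers.any() and region_idx.size:
        carrier_cols = np.flatnonzero(carriers)
        if cfg.full_region_dropout:
            dp[np.ix_(region_idx, carrier_cols)] = 0
        else:
            drop = rng.random((region_idx.size, carrier_cols.size)) < cfg.loss_missing_prob
            sub = dp[np.ix_(region_idx, carrier_cols)]
            sub[drop] = 0
            dp[np.ix_(region_idx, carrier_cols)] = sub
    p_alt = dosage * (1.0 - 2.0 * cfg.seq_error) + cfg.seq_error
    ad = rng.binomial(dp, p_alt)

    # --- doublets: merge a barcode's reads with a random partner cell -----
    n_doublets = int(round(cfg.doublet_rate * n_cells))
    doublet = np.zeros(n_cells, dtype=bool)
    if n_doublets:
        barcodes = rng.choice(n_cells, size=n_doublets, replace=False)
        doublet[barcodes] = True
        for b in barcodes:
            partner = int(rng.integers(n_cells - 1))
            partner += partner >= b
            dp[:, b] = dp[:, b] + dp[:, partner]
            ad[:, b] = ad[:, b] + ad[:, partner]

    gq = np.full((n_sites, n_cells), 99, dtype=np.int64)
    gq[dp == 0] = 0
    gt = call_genotypes(dp, gq, ad, cfg.thresholds)

    matrix = GenotypeMatrix(
        variants=[v for v in panel],
        cell_ids=cell_ids,
        GT=gt,
        DP=dp.astype(np.int64),
        AD_ALT=ad.astype(np.int64),
        GQ=gq,
    )
    truth = SimTruth(
        cells=pd.DataFrame(
            {
                "cell_id": cell_ids,
                "clone": labels,
                "loh_carrier": carriers,
                "retained_hap": retained_hap,
                "doublet": doublet,
            }
        ),
        true_dosage=dosage,
        alt_on_retained=alt_on_retained,
        region_idx=region_idx,
    )
    return matrix, truth


def simulate_null(cfg: SimConfig, arms: ArmTable | None = None) -> tuple[GenotypeMatrix, SimTruth]:
    """A lesion with an anchor clone but no LOH anywhere (type-I error suites)."""
    from dataclasses import replace

    return simulate_matrix(replace(cfg, frac_gof_loh=0.0), arms)


def simulate_deletion_lesion(cfg: SimConfig, arms: ArmTable | None = None) -> tuple[GenotypeMatrix, SimTruth]:
    """A copy-loss lesion whose carrier cells lose the whole region.

    Carrier cells have every region site forced to zero depth (the
    direct-assignment fast path), reproducing the all-SNPs-missing signature
    of a homozygous deletion that the binomial missingness test targets.
    """
    from dataclasses import replace

    return simulate_matrix(
        replace(cfg, loh_type="copy_loss", full_region_dropout=True), arms
    )
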