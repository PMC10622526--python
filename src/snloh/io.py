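"""Data model and I/O for targeted single-nucleus DNA-seq genotype matrices.

The central container is :class:`GenotypeMatrix`: variants x cells matrices of
genotype codes, read depths, alternate-allele counts and genotype qualities,
plus per-variant metadata. Matrices are read either from a multi-sample VCF
(one sample column per nucleus) or from a quartet of plain TSV files, the
package's canonical interchange format.

Coordinates are 1-based (VCF convention) throughout; intervals are closed.
The genome build is metadata only (default ``hg19``); no liftover is done.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("snloh")

# Genotype codes. MISSING is 3 (not -1) so the GT matrix stays unsigned and
# matches the mosaic/Tapestri convention.
REF = 0
HET = 1
HOM = 2
MISSING = 3

GT_TOKENS = {REF: "0", HET: "1", HOM: "2", MISSING: "NA"}
_TOKEN_TO_GT = {"0": REF, "1": HET, "2": HOM, "NA": MISSING}


class InputError(ValueError):
    """Malformed or inconsistent input data."""


class ConfigError(ValueError):
    """Invalid configuration (thresholds, arm tables, region definitions)."""


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Sort chromosomes numerically, then X, Y, MT, then everything else."""
    c = chrom.removeprefix("chr")
    if c.isdigit():
        return (int(c), "")
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if c in special:
        return (special[c], "")
    return (100, c)


@dataclass
class VariantRecord:
    """One biallelic variant site on the panel.

    ``is_indel`` is derived from the allele lengths when not given.
    ``multi_alt`` marks sites where at least one cell was heterozygous for two
    different alternate alleles in the source VCF (the record having been
    split into biallelic rows); such sites confound heterozygosity-based LOH
    calls and are flagged downstream.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    var_id: str | None = None
    in_dbsnp: bool = False
    is_indel: bool | None = None
    is_anchor: bool = False
    multi_alt: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputError(f"variant position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise InputError(f"empty allele at {self.chrom}:{self.pos}")
        if self.ref == self.alt:
            raise InputError(f"ref == alt at {self.chrom}:{self.pos}")
        indel = len(self.ref) != len(self.alt)
        if self.is_indel is None:
            self.is_indel = indel
        elif self.is_indel != indel:
            raise InputError(
                f"is_indel={self.is_indel} inconsistent with alleles "
                f"{self.ref}/{self.alt} at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


def parse_variant_key(key: str) -> tuple[str, int, str, str]:
    parts = key.split(":")
    if len(parts) != 4:
        raise InputError(f"variant key {key!r} is not chrom:pos:ref:alt")
    chrom, pos, ref, alt = parts
    return chrom, int(pos), ref, alt


@dataclass
class GenotypeMatrix:
    """Variants x cells genotype data from a targeted single-nucleus run.

    All four matrices share shape ``(n_variants, n_cells)``. GT holds the
    codes REF/HET/HOM/MISSING; DP total depth; AD_ALT alternate-allele reads;
    GQ genotype quality (99 used when the source format carried none).
    """

    variants: list[VariantRecord]
    cell_ids: list[str]
    GT: np.ndarray
    DP: np.ndarray
    AD_ALT: np.ndarray
    GQ: np.ndarray
    build: str = "hg19"

    def __post_init__(self) -> None:
        shape = (len(self.variants), len(self.cell_ids))
        for name in ("GT", "DP", "AD_ALT", "GQ"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise InputError(
                    f"{name} has shape {arr.shape}, expected {shape}"
                )
            setattr(self, name, arr.astype(np.int64, copy=False))
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise InputError("cell ids are not unique")
        if np.any(self.AD_ALT > self.DP):
            raise InputError("AD_ALT exceeds DP at some entries")
        keys = [(chrom_sort_key(v.chrom), v.pos) for v in self.variants]
        if keys != sorted(keys):
            raise InputError("variants are not sorted by (chrom, pos)")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def variant_keys(self) -> list[str]:
        return [v.key for v in self.variants]

    def variant_index(self, key_or_record: str | VariantRecord) -> int:
        key = (
            key_or_record.key
            if isinstance(key_or_record, VariantRecord)
            else key_or_record
        )
        for i, v in enumerate(self.variants):
            if v.key == key or (v.var_id is not None and v.var_id == key):
                return i
        raise KeyError(f"variant {key!r} not in matrix")

    def cell_index(self, cell_ids) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        return np.array([lookup[c] for c in cell_ids], dtype=np.intp)

    def subset(self, variant_idx=None, cell_idx=None) -> "GenotypeMatrix":
        vi = (
            np.arange(self.n_variants)
            if variant_idx is None
            else np.asarray(variant_idx, dtype=np.intp)
        )
        ci = (
            np.arange(self.n_cells)
            if cell_idx is None
            else np.asarray(cell_idx, dtype=np.intp)
        )
        return GenotypeMatrix(
            variants=[self.variants[i] for i in vi],
            cell_ids=[self.cell_ids[i] for i in ci],
            GT=self.GT[np.ix_(vi, ci)],
            DP=self.DP[np.ix_(vi, ci)],
            AD_ALT=self.AD_ALT[np.ix_(vi, ci)],
            GQ=self.GQ[np.ix_(vi, ci)],
            build=self.build,
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            variants=[replace(v) for v in self.variants],
            cell_ids=list(self.cell_ids),
            GT=self.GT.copy(),
            DP=self.DP.copy(),
            AD_ALT=self.AD_ALT.copy(),
            GQ=self.GQ.copy(),
            build=self.build,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.variants == other.variants
            and self.cell_ids == other.cell_ids
            and np.array_equal(self.GT, other.GT)
            and np.array_equal(self.DP, other.DP)
            and np.array_equal(self.AD_ALT, other.AD_ALT)
            and np.array_equal(self.GQ, other.GQ)
        )


# hg19 centromere boundaries (gap-table midpoints, 1-based). Positions at or
# below the boundary are on the p arm. A user-supplied UCSC cytoBand.txt
# overrides these.
HG19_CENTROMERES = {
    "1": 125_000_000, "2": 93_300_000, "3": 91_000_000, "4": 50_400_000,
    "5": 48_400_000, "6": 61_000_000, "7": 59_900_000, "8": 45_600_000,
    "9": 49_000_000, "10": 40_200_000, "11": 53_700_000, "12": 35_800_000,
    "13": 17_900_000, "14": 17_600_000, "15": 19_000_000, "16": 36_600_000,
    "17": 24_000_000, "18": 17_200_000, "19": 26_500_000, "20": 27_500_000,
    "21": 13_200_000, "22": 14_700_000, "X": 60_600_000,
}


@dataclass
class ArmTable:
    """Chromosome -> centromere position, defining p/q arm assignment."""

    centromeres: dict[str, int] = field(
        default_factory=lambda: dict(HG19_CENTROMERES)
    )

    @staticmethod
    def _norm(chrom: str) -> str:
        return chrom.removeprefix("chr")

    @classmethod
    def from_cytoband(cls, path: str | os.PathLike) -> "ArmTable":
        """Build an arm table from a UCSC cytoBand.txt file.

        The centromere boundary is the end of the p-side acrocentric (acen)
        band, i.e. the p/q junction.
        """
        bands = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "name", "stain"],
        )
        acen = bands[bands["stain"] == "acen"]
        cents: dict[str, int] = {}
        for chrom, grp in acen.groupby("chrom"):
            p_side = grp[grp["name"].str.startswith("p")]
            if p_side.empty:
                raise ConfigError(f"no p-side acen band for {chrom}")
            cents[cls._norm(str(chrom))] = int(p_side["end"].max())
        if not cents:
            raise ConfigError(f"no acen bands found in {path}")
        return cls(centromeres=cents)

    def centromere(self, chrom: str) -> int:
        c = self._norm(chrom)
        if c not in self.centromeres:
            raise ConfigError(f"chromosome {chrom!r} not in arm table")
        return self.centromeres[c]


def assign_arm(variant: VariantRecord, arms: ArmTable) -> str:
    """Arm label for a variant: chrom + 'p' if pos <= centromere else 'q'.

    A position exactly at the centromere boundary is assigned to the p arm.
    """
    cent = arms.centromere(variant.chrom)
    arm = "p" if variant.pos <= cent else "q"
    return f"{ArmTable._norm(variant.chrom)}{arm}"


# ---------------------------------------------------------------------------
# VCF ingestion
# ---------------------------------------------------------------------------

def read_cell_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a multi-sample VCF with one sample column per nucleus.

    FORMAT must contain GT; AD, DP and GQ are used when present (entries
    absent from the source become 0 depth / MISSING genotype, counted in the
    log). Multi-allelic records are split into biallelic rows; a cell
    heterozygous for two alternate alleles is HET on both rows and the rows
    are flagged ``multi_alt``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise InputError(f"{path}: VCF has no sample columns")

    rows: list[tuple[VariantRecord, np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
    n_absent_format = 0
    for rec in vcf:
        gts = np.array([g[:2] for g in rec.genotypes], dtype=np.int64)
        dp = rec.format("DP")
        ad = rec.format("AD")
        gq = rec.format("GQ")
        dp_col = (
            dp[:, 0].astype(np.int64)
            if dp is not None
            else np.zeros(len(samples), dtype=np.int64)
        )
        if dp is None or gq is None:
            n_absent_format += 1
        dp_col = np.where(dp_col < 0, 0, dp_col)
        gq_col = (
            np.where(gq[:, 0] < 0, 0, gq[:, 0]).astype(np.int64)
            if gq is not None
            else np.full(len(samples), 99, dtype=np.int64)
        )
        for j, alt in enumerate(rec.ALT):
            allele = j + 1
            n_alt = (gts == allele).sum(axis=1)
            missing = (gts < 0).any(axis=1)
            gt_codes = np.full(len(samples), REF, dtype=np.int64)
            gt_codes[n_alt == 1] = HET
            gt_codes[n_alt == 2] = HOM
            gt_codes[missing] = MISSING
            other_alt = ((gts > 0) & (gts != allele)).any(axis=1)
            multi = bool(np.any((n_alt == 1) & other_alt))
            if ad is not None and ad.shape[1] > allele:
                ad_col = ad[:, allele].astype(np.int64)
                ad_col = np.where(ad_col < 0, 0, ad_col)
            else:
                ad_col = np.zeros(len(samples), dtype=np.int64)
            ad_col = np.minimum(ad_col, dp_col)
            rec_out = VariantRecord(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=alt,
                var_id=rec.ID,
                multi_alt=multi,
            )
            rows.append((rec_out, gt_codes, dp_col.copy(), ad_col, gq_col.copy()))

    if not rows:
        raise InputError(f"{path}: no variant records")
    if n_absent_format:
        logger.warning(
            "%s: %d records lacked DP and/or GQ FORMAT fields", path, n_absent_format
        )
    rows.sort(key=lambda r: (chrom_sort_key(r[0].chrom), r[0].pos))
    return GenotypeMatrix(
        variants=[r[0] for r in rows],
        cell_ids=samples,
        GT=np.vstack([r[1] for r in rows]),
        DP=np.vstack([r[2] for r in rows]),
        AD_ALT=np.vstack([r[3] for r in rows]),
        GQ=np.vstack([r[4] for r in rows]),
    )


# ---------------------------------------------------------------------------
# TSV quartet interchange format
# ---------------------------------------------------------------------------

_TSV_NAMES = {"GT": "GT.tsv", "DP": "DP.tsv", "AD": "AD.tsv", "GQ": "GQ.tsv"}
_META_NAME = "variants.tsv"


def write_matrix_tsv(matrix: GenotypeMatrix, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write the TSV quartet (GT/DP/AD/GQ) plus a variant-metadata table.

    Rows are keyed ``chrom:pos:ref:alt``; columns are cell ids; MISSING
    genotypes are the literal token ``NA``. Output is deterministic for a
    fixed matrix.
    """
    os.makedirs(out_dir, exist_ok=True)
    keys = matrix.variant_keys
    paths: dict[str, str] = {}

    if matrix.GT.size:
        gt_tokens = np.vectorize(GT_TOKENS.get)(matrix.GT)
    else:
        gt_tokens = np.empty(matrix.GT.shape, dtype=object)
    frames = {
        "GT": pd.DataFrame(gt_tokens, index=keys, columns=matrix.cell_ids),
        "DP": pd.DataFrame(matrix.DP, index=keys, columns=matrix.cell_ids),
        "AD": pd.DataFrame(matrix.AD_ALT, index=keys, columns=matrix.cell_ids),
        "GQ": pd.DataFrame(matrix.GQ, index=keys, columns=matrix.cell_ids),
    }
    for name, frame in frames.items():
        p = os.path.join(out_dir, _TSV_NAMES[name])
        frame.to_csv(p, sep="\t", index_label="variant")
        paths[name] = p

    meta = pd.DataFrame(
        {
            "variant": keys,
            "var_id": [v.var_id if v.var_id is not None else "NA" for v in matrix.variants],
            "in_dbsnp": [int(v.in_dbsnp) for v in matrix.variants],
            "is_indel": [int(v.is_indel) for v in matrix.variants],
            "is_anchor": [int(v.is_anchor) for v in matrix.variants],
            "multi_alt": [int(v.multi_alt) for v in matrix.variants],
        }
    )
    meta_path = os.path.join(out_dir, _META_NAME)
    meta.to_csv(meta_path, sep="\t", index=False)
    paths["variants"] = meta_path
    return paths


def read_matrix_tsv(
    gt_path: str | os.PathLike,
    dp_path: str | os.PathLike,
    ad_path: str | os.PathLike,
    gq_path: str | os.PathLike | None = None,
    variants_path: str | os.PathLike | None = None,
) -> GenotypeMatrix:
    """Read a GenotypeMatrix from the TSV quartet written by write_matrix_tsv.

    The four files must agree exactly on variant keys (row order) and cell
    ids (column order); any mismatch is an error naming the offending keys.
    When ``gq_path`` is None, GQ is filled with 99 (quality gate passes) and
    a warning is logged. ``variants_path`` restores variant metadata; when
    absent, metadata defaults are used.
    """
    def load(p):
        # keep_default_na: the literal token "NA" is our MISSING code, not NaN
        return pd.read_csv(p, sep="\t", index_col="variant", dtype=str,
                           keep_default_na=False)

    gt = load(gt_path)
    dp = load(dp_path)
    ad = load(ad_path)
    frames = {"DP": dp, "AD": ad}
    if gq_path is not None:
        frames["GQ"] = gq = load(gq_path)
    else:
        logger.warning("no GQ file given; genotype-quality gate will pass all calls")
        gq = pd.DataFrame("99", index=gt.index, columns=gt.columns)

    for name, frame in frames.items():
        if list(frame.index) != list(gt.index):
            bad = sorted(set(frame.index).symmetric_difference(gt.index))
            raise InputError(
                f"{name} variant keys disagree with GT (order-sensitive); "
                f"differing keys: {bad[:10] or list(gt.index[:10])}"
            )
        if list(frame.columns) != list(gt.columns):
            bad = sorted(set(frame.columns).symmetric_difference(gt.columns))
            raise InputError(
                f"{name} cell columns disagree with GT (order-sensitive); "
                f"differing/reordered ids: {bad[:10] or list(gt.columns[:10])}"
            )

    meta: dict[str, dict] = {}
    if variants_path is not None and os.path.exists(variants_path):
        mdf = pd.read_csv(variants_path, sep="\t", dtype=str, keep_default_na=False)
        for _, row in mdf.iterrows():
            meta[row["variant"]] = {
                "var_id": None if row["var_id"] == "NA" else row["var_id"],
                "in_dbsnp": bool(int(row["in_dbsnp"])),
                "is_indel": bool(int(row["is_indel"])),
                "is_anchor": bool(int(row["is_anchor"])),
                "multi_alt": bool(int(row["multi_alt"])),
            }

    variants = []
    for key in gt.index:
        chrom, pos, ref, alt = parse_variant_key(key)
        kwargs = meta.get(key, {})
        variants.append(VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, **kwargs))

    try:
        gt_codes = gt.map(_TOKEN_TO_GT.get).to_numpy(dtype=object)
    except AttributeError:  # pandas < 2.1
        gt_codes = gt.applymap(_TOKEN_TO_GT.get).to_numpy(dtype=object)
    if any(v is None for v in gt_codes.ravel()):
        raise InputError(f"{gt_path}: unrecognized genotype token (expected 0/1/2/NA)")

    return GenotypeMatrix(
        variants=variants,
        cell_ids=list(gt.columns),
        GT=gt_codes.astype(np.int64),
        DP=dp.to_numpy(dtype=np.int64),
        AD_ALT=ad.to_numpy(dtype=np.int64),
        GQ=gq.to_numpy(dtype=np.int64),
    )


def read_matrix_dir(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a matrix from a directory produced by write_matrix_tsv."""
    return read_matrix_tsv(
        os.path.join(path, _TSV_NAMES["GT"]),
        os.path.join(path, _TSV_NAMES["DP"]),
        os.path.join(path, _TSV_NAMES["AD"]),
        os.path.join(path, _TSV_NAMES["GQ"]),
        variants_path=os.path.join(path, _META_NAME),
    )


def annotate_dbsnp(matrix: GenotypeMatrix, id_set) -> GenotypeMatrix:
    """Set the in_dbsnp flag from a membership set of rsIDs or variant keys.

    The matrix content is otherwise unchanged; an empty set flags everything
    False. Anchor variants keep is_anchor and are retained downstream even
    when absent from dbSNP.
    """
    ids = set(id_set)
    out = matrix.copy()
    for v in out.variants:
        v.in_dbsnp = v.key in ids or (v.var_id is not None and v.var_id in ids)
    return out
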