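"""Co-mutation enrichment with a doublet-aware null.

Two somatic variants driving the same lesion should co-occur in the same
nuclei. Observed co-occurrence is tested two ways, following the
read-count-based calling used for Tapestri data (depth > 20 at all tested
loci, alternate count > 10, alternate fraction > 0.1; heterozygous and
homozygous calls are treated identically as mutant):

* a two-tailed Pearson chi-squared test of independence on the 2x2
  co-occurrence table; and
* an upper-tail Poisson test of the observed multi-mutant count against the
  number expected from droplet doublets alone, under the null that the
  variants live in exclusive clonal populations. A clone carrying a
  heterozygous variant has cell fraction f = 2 * VAF. With Poisson(lambda)
  droplet loading, a fraction P(N>=2 | N>=1) of observed barcodes are
  multiplets; a doublet is a cross-clone (A, B) pair with probability
  2 * f_A * f_B.

The pairing factor 2 (unordered pair of one A-clone and one B-clone nucleus)
is validated against a brute-force droplet simulation in the test-suite, not
taken on authority. The loading rate lambda is configuration; the default
0.1 corresponds to ~5% multiplet barcodes, typical of droplet platforms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import GenotypeMatrix, InputError, VariantRecord

logger = logging.getLogger("snloh")

MUTANT = 1
WILDTYPE = 0
UNEVALUABLE = -1


@dataclass(frozen=True)
class ComutConfig:
    """Thresholds for read-count-based somatic mutant calling (all strict >)."""

    min_depth: int = 20
    min_alt_count: int = 10
    min_aaf: float = 0.1
    loading_lambda: float = 0.1

    def __post_init__(self) -> None:
        if min(self.min_depth, self.min_alt_count) <= 0 or self.min_aaf <= 0:
            raise InputError("comut thresholds must be positive")
        if self.loading_lambda <= 0:
            raise InputError("loading_lambda must be positive")


@dataclass
class ComutResult:
    """Co-occurrence of 2 (or 3) somatic variants over evaluable cells."""

    variant_keys: list[str]
    n_cells: int
    counts: np.ndarray  # 2x2 or 2x2x2, index 0 = mutant, 1 = wildtype
    observed_multimutants: int
    expected_multimutants: float
    clone_fractions: list[float]
    chi2_p: float
    poisson_p: float


def mutant_status(
    matrix: GenotypeMatrix, variant: VariantRecord | str, cfg: ComutConfig | None = None
) -> np.ndarray:
    """Per-cell mutant / wildtype / unevaluable status at one variant locus.

    Unevaluable when depth fails the (strict) minimum; mutant when both the
    alternate count and the alternate fraction clear their strict thresholds.
    Joint analyses then drop cells unevaluable at ANY tested locus, which
    implements the depth-at-all-loci rule.
    """
    cfg = cfg or ComutConfig()
    idx = matrix.variant_index(variant if isinstance(variant, str) else variant.key)
    dp = matrix.DP[idx].astype(float)
    ad = matrix.AD_ALT[idx].astype(float)
    status = np.full(matrix.n_cells, WILDTYPE, dtype=np.int64)
    status[dp <= cfg.min_depth] = UNEVALUABLE
    with np.errstate(divide="ignore", invalid="ignore"):
        aaf = np.where(dp > 0, ad / np.maximum(dp, 1.0), 0.0)
    mutant = (dp > cfg.min_depth) & (ad > cfg.min_alt_count) & (aaf > cfg.min_aaf)
    status[mutant] = MUTANT
    return status


def cooccurrence_table(*statuses: np.ndarray) -> np.ndarray:
    """Joint mutant/wildtype counts over cells evaluable at every locus.

    For two status vectors returns the 2x2 table [[A+B+, A+B-], [A-B+, A-B-]];
    for three, the analogous 2x2x2 array. Index 0 = mutant, 1 = wildtype.
    """
    if not 2 <= len(statuses) <= 3:
        raise InputError("cooccurrence_table takes 2 or 3 status vectors")
    statuses = [np.asarray(s) for s in statuses]
    n = statuses[0].shape[0]
    if any(s.shape[0] != n for s in statuses):
        raise InputError("status vectors differ in length")
    evaluable = np.all([s != UNEVALUABLE for s in statuses], axis=0)
    if evaluable.sum() < 2:
        raise InputError("fewer than 2 cells evaluable at all loci")
    table = np.zeros((2,) * len(statuses), dtype=np.int64)
    for cell_status in zip(*(s[evaluable] for s in statuses)):
        idx = tuple(0 if s == MUTANT else 1 for s in cell_status)
        table[idx] += 1
    return table


def chi_squared_cooccurrence(table: np.ndarray) -> float:
    """Two-tailed Pearson chi-squared p for a 2x2 table (no Yates correction).

    Returns NaN (with a warning) when any expected count is zero, where the
    statistic is undefined.
    """
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise InputError("chi-squared co-occurrence needs a 2x2 table")
    expected = stats.contingency.expected_freq(table)
    if np.any(expected == 0):
        logger.warning("zero expected count in co-occurrence table; chi2 undefined")
        return float("nan")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.pvalue)


def doublet_fraction(loading_lambda: float) -> float:
    """Fraction of observed barcodes holding >= 2 nuclei under Poisson loading."""
    lam = loading_lambda
    if lam <= 0:
        raise InputError("loading_lambda must be positive")
    p_ge1 = 1.0 - math.exp(-lam)
    p_ge2 = p_ge1 - lam * math.exp(-lam)
    return p_ge2 / p_ge1


def triplet_fraction(loading_lambda: float) -> float:
    """Fraction of observed barcodes holding >= 3 nuclei under Poisson loading."""
    lam = loading_lambda
    if lam <= 0:
        raise InputError("loading_lambda must be positive")
    p_ge1 = 1.0 - math.exp(-lam)
    p_ge3 = p_ge1 - lam * math.exp(-lam) - lam**2 / 2.0 * math.exp(-lam)
    return p_ge3 / p_ge1


def expected_doublet_multimutants(
    n_cells: int, vaf_a: float, vaf_b: float, doublet_frac: float
) -> float:
    """Expected double-mutant barcodes from doublets under exclusive clones.

    Clone fractions are f = 2*VAF (heterozygous-clone assumption); a doublet
    barcode is double-mutant when it co-encapsulates one nucleus from each
    clone, probability 2*f_A*f_B.
    """
    f_a, f_b = 2.0 * vaf_a, 2.0 * vaf_b
    if f_a + f_b > 1.0 + 1e-12:
        raise InputError(
            f"clone fractions {f_a:.3f} + {f_b:.3f} exceed 1: clones cannot be exclusive"
        )
    return n_cells * doublet_frac * 2.0 * f_a * f_b


def expected_multimutants(
    n_cells: int, vafs, loading_lambda: float
) -> float:
    """Doublet/triplet-null expectation for 2 or 3 variants.

    Variants carried by (essentially) every cell constrain nothing and are
    dropped before the computation, so the triple case reduces to the
    pairwise one when a variant is ubiquitous. Three exclusive clones can
    only be covered by a triplet droplet (3! orderings of one nucleus from
    each clone).
    """
    fracs = [2.0 * v for v in vafs if 2.0 * v < 1.0 - 1e-9]
    if len(fracs) <= 1:
        # 0 or 1 non-ubiquitous variant: no exclusivity constraint, the
        # expectation is just the marginal mutant count.
        return float(n_cells) * math.prod(fracs)
    if sum(fracs) > 1.0 + 1e-12:
        raise InputError("clone fractions exceed 1: clones cannot be exclusive")
    if len(fracs) == 2:
        return n_cells * doublet_fraction(loading_lambda) * 2.0 * fracs[0] * fracs[1]
    return (
        n_cells
        * triplet_fraction(loading_lambda)
        * 6.0
        * fracs[0]
        * fracs[1]
        * fracs[2]
    )


def poisson_pvalue(observed: int, expected: float, floor: float = 1e-6) -> float:
    """Upper-tail Poisson p-value P(X >= observed) with X ~ Poisson(expected).

    A zero expectation is floored (configurable) to avoid a degenerate null.
    """
    if observed < 0:
        raise InputError("observed count must be >= 0")
    expected = max(expected, floor)
    return float(stats.poisson.sf(observed - 1, expected))


def comut_test(
    matrix: GenotypeMatrix,
    variants,
    cfg: ComutConfig | None = None,
) -> ComutResult:
    """Full co-mutation enrichment test for 2 or 3 somatic variants.

    Clone fractions are estimated from the data as the per-variant mutant
    fraction among evaluable cells (homozygous calls count as mutant, so the
    mutant fraction approximates 2*VAF directly). The chi-squared test is
    reported for the pairwise table (first two variants when three are
    given); the Poisson test compares the observed all-mutant count against
    the doublet/triplet-null expectation.
    """
    cfg = cfg or ComutConfig()
    statuses = [mutant_status(matrix, v, cfg) for v in variants]
    table = cooccurrence_table(*statuses)
    n_cells = int(table.sum())
    observed = int(table[(0,) * len(statuses)])
    evaluable = np.all([s != UNEVALUABLE for s in statuses], axis=0)
    clone_fracs = [float((s[evaluable] == MUTANT).mean()) for s in statuses]
    expected = expected_multimutants(
        n_cells, [f / 2.0 for f in clone_fracs], cfg.loading_lambda
    )
    chi2_p = chi_squared_cooccurrence(
        table if table.ndim == 2 else table.sum(axis=tuple(range(2, table.ndim)))
    )
    return ComutResult(
        variant_keys=[v if isinstance(v, str) else v.key for v in variants],
        n_cells=n_cells,
        counts=table,
        observed_multimutants=observed,
        expected_multimutants=expected,
        clone_fractions=clone_fracs,
        chi2_p=chi2_p,
        poisson_p=poisson_pvalue(observed, expected),
    )
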