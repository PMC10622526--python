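import numpy as np
import pytest

from snloh import GenotypeMatrix, VariantRecord
from snloh.io import HET, HOM, MISSING, REF


def matrix_from_gt(gt, cell_ids=None, variants=None, chrom="1", start_pos=1000,
                   depth=50):
    """Build a consistent GenotypeMatrix from a genotype-code array.

    DP/AD are filled so that re-calling genotypes from reads reproduces gt
    (HET -> half-alt reads, HOM -> all-alt, REF -> none, MISSING -> zero
    depth).
    """
    gt = np.asarray(gt, dtype=np.int64)
    n_var, n_cells = gt.shape
    if variants is None:
        variants = [
            VariantRecord(chrom=chrom, pos=start_pos + 10 * i, ref="A", alt="G",
                          var_id=f"rs{i}", in_dbsnp=True)
            for i in range(n_var)
        ]
    if cell_ids is None:
        cell_ids = [f"cell{j}" for j in range(n_cells)]
    dp = np.full(gt.shape, depth, dtype=np.int64)
    dp[gt == MISSING] = 0
    ad = np.zeros_like(dp)
    ad[gt == HET] = depth // 2
    ad[gt == HOM] = depth
    gq = np.where(dp > 0, 99, 0)
    return GenotypeMatrix(variants=variants, cell_ids=list(cell_ids),
                          GT=gt, DP=dp, AD_ALT=ad, GQ=gq)


@pytest.fixture
def gt_codes():
    return dict(REF=REF, HET=HET, HOM=HOM, MISSING=MISSING)


@pytest.fixture
def rng():
    return np.random.default_rng(20230701)
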