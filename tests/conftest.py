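"""Shared fixtures: hand-built summary-statistic tables and LD scores."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ddnplus.sumstats import LDScoreTable, SumStatTable


def make_table(phenotype_id: str,
               variant_ids,
               beta=None,
               se=0.01,
               z=None,
               eaf=0.3,
               pval=None,
               n=10_000,
               chrom="1",
               pos=None,
               effect_allele="A",
               other_allele="G") -> SumStatTable:
    """Build a SumStatTable from scalars or arrays (scalars are broadcast)."""
    m = len(variant_ids)

    def arr(x, dtype=float):
        a = np.asarray(x)
        return np.full(m, x, dtype=dtype) if a.ndim == 0 else a.astype(dtype)

    se_arr = arr(se)
    if z is not None:
        beta_arr = arr(z) * se_arr
    else:
        beta_arr = arr(0.0 if beta is None else beta)
    zval = beta_arr / se_arr
    if pval is None:
        from scipy.special import erfc
        pval_arr = np.maximum(erfc(np.abs(zval) / np.sqrt(2)), np.finfo(float).tiny)
    else:
        pval_arr = arr(pval)
    df = pd.DataFrame({
        "variant_id": [str(v) for v in variant_ids],
        "chrom": arr(chrom, dtype=object) if not np.isscalar(chrom) else [str(chrom)] * m,
        "pos": arr(1_000_000 + 1_000 * np.arange(m) if pos is None else pos, dtype=np.int64),
        "effect_allele": arr(effect_allele, dtype=object) if not np.isscalar(effect_allele)
        else [effect_allele] * m,
        "other_allele": arr(other_allele, dtype=object) if not np.isscalar(other_allele)
        else [other_allele] * m,
        "eaf": arr(eaf),
        "beta": beta_arr,
        "se": se_arr,
        "pval": pval_arr,
        "n": arr(n),
    })
    return SumStatTable(phenotype_id, df)


def make_ld(variant_ids, scores=None, m_total=None, seed=0) -> LDScoreTable:
    m = len(variant_ids)
    if scores is None:
        scores = np.random.default_rng(seed).gamma(6.0, 100.0 / 6.0, size=m)
    return LDScoreTable(
        scores=pd.Series(np.asarray(scores, float),
                         index=pd.Index([str(v) for v in variant_ids],
                                        name="variant_id")),
        m_total=int(m_total if m_total is not None else 500 * m),
    )


@pytest.fixture
def table_factory():
    return make_table


@pytest.fixture
def ld_factory():
    return make_ld
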