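"""LD-score regression: SNP-heritability, genetic correlation, FDR calling.

Under the polygenic model behind LD-score regression, a variant j with LD
score l_j contributes E[z_j^2] = N*h2*l_j/M + 1 for a trait with SNP
heritability h2 estimated from N samples over M SNPs, and for two traits
E[z1_j*z2_j] = sqrt(N1*N2)*rg*sqrt(h2_1*h2_2)*l_j/M + c, where the intercept
c absorbs sample overlap and confounding.  Heritability is therefore the
slope of a weighted regression of z^2 on N*l/M, genetic covariance the slope
of z1*z2 on sqrt(N1*N2)*l/M, and the genetic correlation rg their ratio
normalized by the geometric mean of the heritabilities.  Standard errors come
from a delete-one block jackknife over contiguous variant blocks, which is
robust to residual local dependence along the genome.

Weighting is two-step: a unit-weight pass gives fitted means, and the second
pass uses inverse-variance weights 1/(2*v^2) for z^2 (v the fitted mean
floored at 1) and 1/(v1*v2 + c^2) for z1*z2.  The floors keep weights bounded
and make the bivariate regression of a trait with itself coincide exactly
with its heritability regression, so rg(t, t) = 1 identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as student_t
from statsmodels.stats.multitest import multipletests

from .sumstats import LDScoreTable, SumStatTable

log = logging.getLogger(__name__)

_TINY = np.finfo(float).tiny

#: Reported rg values are clipped to this magnitude in output files; noise can
#: push the raw ratio outside [-1, 1] and the raw value is kept internally.
RG_REPORT_CLAMP = 1.25


@dataclass
class H2Estimate:
    """Observed-scale SNP heritability with jackknife uncertainty."""

    phenotype_id: str
    h2: float
    se: float
    z: float
    intercept: float
    n_blocks: int


@dataclass
class RgEstimate:
    """A disease-trait pair's genetic covariance and correlation."""

    disease_id: str
    trait_id: str
    gcov: float
    rg: float
    se: float
    z: float
    pval: float
    h2_disease: float
    h2_trait: float
    h2_disease_z: float
    h2_trait_z: float
    heritable: bool
    intercept: float
    n_blocks: int

    @property
    def rg_clamped(self) -> float:
        if not np.isfinite(self.rg):
            return self.rg
        return float(np.clip(self.rg, -RG_REPORT_CLAMP, RG_REPORT_CLAMP))


def _block_offsets(m: int, n_blocks: int) -> np.ndarray:
    return np.linspace(0, m, n_blocks + 1).astype(int)


def _sums(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    return np.array([w.sum(), (w * x).sum(), (w * x * x).sum(),
                     (w * y).sum(), (w * x * y).sum()])


def _block_sums(x: np.ndarray, y: np.ndarray, w: np.ndarray,
                offsets: np.ndarray) -> np.ndarray:
    terms = np.stack([w, w * x, w * x * x, w * y, w * x * y], axis=1)
    return np.add.reduceat(terms, offsets[:-1], axis=0)


def _fit(s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted least-squares intercept and slope from sufficient statistics."""
    sw, sx, sxx, sy, sxy = (s[..., k] for k in range(5))
    d = sw * sxx - sx * sx
    slope = (sw * sxy - sx * sy) / d
    intercept = (sxx * sy - sx * sxy) / d
    return intercept, slope


def _jackknife_se(deleted: np.ndarray) -> float:
    g = len(deleted)
    mean = deleted.mean()
    return float(np.sqrt((g - 1) / g * ((deleted - mean) ** 2).sum()))


def _unit_fitted(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    a, b = _fit(_sums(x, y, np.ones_like(x)))
    return a + b * x


def _check_regression_inputs(m: int, n_blocks: int, l: np.ndarray) -> None:
    if n_blocks < 2:
        raise ValueError("n_blocks must be at least 2")
    if n_blocks > m:
        raise ValueError(f"n_blocks={n_blocks} exceeds the {m} available variants")
    if np.ptp(l) == 0:
        raise ValueError("LD scores are constant; the regression has no signal")


def estimate_h2(table: SumStatTable, ld: LDScoreTable,
                n_blocks: int = 200) -> H2Estimate:
    """SNP heritability of one phenotype via LD-score regression.

    The slope of the two-step weighted regression of z^2 on N*l/M is h2; the
    SE is a delete-one block jackknife over ``n_blocks`` contiguous variant
    blocks, with second-pass weights held fixed.
    """
    z = table.z
    m = len(z)
    l = ld.aligned(table.variant_ids)
    _check_regression_inputs(m, n_blocks, l)

    x = table.df["n"].to_numpy(float) * l / ld.m_total
    y = z * z
    v = np.maximum(np.abs(_unit_fitted(x, y)), 1.0)
    w = 1.0 / (2.0 * v * v)

    offsets = _block_offsets(m, n_blocks)
    bs = _block_sums(x, y, w, offsets)
    total = bs.sum(axis=0)
    intercept, h2 = _fit(total)
    _, deleted = _fit(total[None, :] - bs)
    se = _jackknife_se(deleted)
    if se > 0:
        zscore = float(h2) / se
    else:
        zscore = 0.0 if h2 == 0 else float(np.sign(h2) * np.inf)
    return H2Estimate(phenotype_id=table.phenotype_id, h2=float(h2), se=se,
                      z=zscore, intercept=float(intercept), n_blocks=n_blocks)


def estimate_rg(t1: SumStatTable, t2: SumStatTable, ld: LDScoreTable,
                n_blocks: int = 200) -> RgEstimate:
    """Genetic correlation between two phenotypes from harmonized tables.

    Requires identical variant order in both tables.  The genetic covariance
    is the slope of z1*z2 on sqrt(N1*N2)*l/M (the intercept absorbs sample
    overlap); rg = gcov / sqrt(h2_1*h2_2).  The SE comes from jackknifing the
    full ratio (all three regressions re-fit per deleted block with fixed
    weights); the two-sided p-value refers rg/se to a Student-t distribution
    with n_blocks - 1 degrees of freedom, the jackknife's effective degrees
    of freedom (a normal reference is slightly anti-conservative in the far
    tail, which is exactly where FDR calls live).  If either heritability
    estimate is non-positive the pair is flagged non-heritable and rg left
    undefined.
    """
    ids = t1.variant_ids
    if not np.array_equal(ids, t2.variant_ids):
        raise ValueError("variant order mismatch between tables; run harmonize first")
    m = len(ids)
    l = ld.aligned(ids)
    _check_regression_inputs(m, n_blocks, l)

    n1 = t1.df["n"].to_numpy(float)
    n2 = t2.df["n"].to_numpy(float)
    z1, z2 = t1.z, t2.z
    x1 = n1 * l / ld.m_total
    x2 = n2 * l / ld.m_total
    x12 = np.sqrt(n1 * n2) * l / ld.m_total
    y1, y2, y12 = z1 * z1, z2 * z2, z1 * z2

    v1 = np.maximum(np.abs(_unit_fitted(x1, y1)), 1.0)
    v2 = np.maximum(np.abs(_unit_fitted(x2, y2)), 1.0)
    c2 = np.maximum(_unit_fitted(x12, y12) ** 2, 1.0)
    w1 = 1.0 / (2.0 * v1 * v1)
    w2 = 1.0 / (2.0 * v2 * v2)
    w12 = 1.0 / (v1 * v2 + c2)

    offsets = _block_offsets(m, n_blocks)
    bs1 = _block_sums(x1, y1, w1, offsets)
    bs2 = _block_sums(x2, y2, w2, offsets)
    bs12 = _block_sums(x12, y12, w12, offsets)
    tot1, tot2, tot12 = bs1.sum(0), bs2.sum(0), bs12.sum(0)
    _, h2_1 = _fit(tot1)
    _, h2_2 = _fit(tot2)
    intercept12, gcov = _fit(tot12)

    _, del1 = _fit(tot1[None, :] - bs1)
    _, del2 = _fit(tot2[None, :] - bs2)
    _, del12 = _fit(tot12[None, :] - bs12)
    h2_1_se = _jackknife_se(del1)
    h2_2_se = _jackknife_se(del2)
    h2_1_z = float(h2_1) / h2_1_se if h2_1_se > 0 else float(np.sign(h2_1) * np.inf)
    h2_2_z = float(h2_2) / h2_2_se if h2_2_se > 0 else float(np.sign(h2_2) * np.inf)

    heritable = bool(h2_1 > 0 and h2_2 > 0)
    if heritable:
        denom = float(h2_1) if h2_1 == h2_2 else float(np.sqrt(h2_1 * h2_2))
        rg = float(gcov) / denom
        denom_del = np.where(del1 == del2, np.abs(del1),
                             np.sqrt(np.maximum(del1 * del2, 1e-300)))
        ratios = del12 / denom_del
        se = _jackknife_se(ratios)
        if se > 0:
            zscore = rg / se
            pval = float(max(2.0 * student_t.sf(abs(zscore), n_blocks - 1), _TINY))
        else:
            zscore = float(np.sign(rg) * np.inf) if rg != 0 else 0.0
            pval = _TINY if rg != 0 else 1.0
    else:
        rg = se = zscore = pval = float("nan")

    return RgEstimate(
        disease_id=t1.phenotype_id, trait_id=t2.phenotype_id,
        gcov=float(gcov), rg=rg, se=se, z=zscore, pval=pval,
        h2_disease=float(h2_1), h2_trait=float(h2_2),
        h2_disease_z=h2_1_z, h2_trait_z=h2_2_z,
        heritable=heritable, intercept=float(intercept12), n_blocks=n_blocks,
    )


def bh_fdr(pvals: Sequence[float], alpha: float = 0.05
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection flags, q-values).

    q-values are the BH-adjusted p-values; the rejected set is exactly the
    indices with q <= alpha.  Empty input yields empty output.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject.astype(bool), q


@dataclass
class AssociationMatrix:
    """Binary disease x trait association calls with their provenance.

    ``r_hat[i, k] = 1`` iff the (disease i, trait k) pair passed the
    heritability filter and its BH q-value is at most alpha; ``rg_values`` and
    ``q_values`` keep the underlying estimates (NaN where undefined or
    filtered out).
    """

    diseases: list[str]
    traits: list[str]
    r_hat: np.ndarray
    rg_values: np.ndarray
    q_values: np.ndarray
    alpha: float
    h2_z_min: float

    def r_hat_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r_hat, index=self.diseases, columns=self.traits)

    def trait_disease_sets(self) -> dict[str, list[str]]:
        """For each trait, the diseases significantly correlated with it."""
        out = {}
        for k, trait in enumerate(self.traits):
            out[trait] = [d for i, d in enumerate(self.diseases) if self.r_hat[i, k]]
        return out

    def to_tsv(self, path) -> None:
        self.r_hat_frame().to_csv(path, sep="\t")


def build_association_matrix(estimates: Iterable[RgEstimate],
                             alpha: float = 0.05,
                             h2_z_min: float = 4.0) -> AssociationMatrix:
    """Threshold rg estimates into the binary association matrix.

    Pairs failing the heritability filter (either h2 non-positive or its
    jackknife z below ``h2_z_min``) are excluded *before* FDR; one BH
    procedure then runs jointly across all surviving disease x trait pairs.
    """
    estimates = list(estimates)
    diseases: list[str] = []
    traits: list[str] = []
    seen: set[tuple[str, str]] = set()
    for e in estimates:
        key = (e.disease_id, e.trait_id)
        if key in seen:
            raise ValueError(f"duplicate estimate for pair {key}")
        seen.add(key)
        if e.disease_id not in diseases:
            diseases.append(e.disease_id)
        if e.trait_id not in traits:
            traits.append(e.trait_id)

    di = {d: i for i, d in enumerate(diseases)}
    ti = {t: k for k, t in enumerate(traits)}
    shape = (len(diseases), len(traits))
    r_hat = np.zeros(shape, dtype=int)
    rg_values = np.full(shape, np.nan)
    q_values = np.full(shape, np.nan)

    def passes(e: RgEstimate) -> bool:
        return (e.heritable and e.h2_disease > 0 and e.h2_trait > 0
                and np.isfinite(e.pval)
                and e.h2_disease_z >= h2_z_min and e.h2_trait_z >= h2_z_min)

    surviving = [e for e in estimates if passes(e)]
    if surviving:
        reject, q = bh_fdr([e.pval for e in surviving], alpha=alpha)
        for e, rej, qv in zip(surviving, reject, q):
            i, k = di[e.disease_id], ti[e.trait_id]
            r_hat[i, k] = int(rej)
            q_values[i, k] = qv
    for e in estimates:
        if np.isfinite(e.rg):
            rg_values[di[e.disease_id], ti[e.trait_id]] = e.rg

    n_tested = len(surviving)
    log.info("association matrix: %d of %d pairs passed the heritability filter, "
             "%d significant at FDR %.3g", n_tested, len(estimates),
             int(r_hat.sum()), alpha)
    return AssociationMatrix(diseases=diseases, traits=traits, r_hat=r_hat,
                             rg_values=rg_values, q_values=q_values,
                             alpha=alpha, h2_z_min=h2_z_min)


def write_rg_table(estimates: Iterable[RgEstimate], path,
                   assoc: AssociationMatrix | None = None) -> None:
    """Write per-pair rg estimates as TSV (rg clamped for reporting)."""
    rows = []
    qlookup = {}
    if assoc is not None:
        for i, d in enumerate(assoc.diseases):
            for k, t in enumerate(assoc.traits):
                qlookup[(d, t)] = assoc.q_values[i, k]
    for e in estimates:
        rows.append({
            "disease": e.disease_id, "trait": e.trait_id,
            "rg": e.rg_clamped, "se": e.se, "z": e.z, "pval": e.pval,
            "qval": qlookup.get((e.disease_id, e.trait_id), np.nan),
            "gcov": e.gcov,
            "h2_disease": e.h2_disease, "h2_trait": e.h2_trait,
            "h2_disease_z": e.h2_disease_z, "h2_trait_z": e.h2_trait_z,
            "heritable": e.heritable,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
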