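"""Synthetic GWAS fixture bundles with planted network truth.

The generator draws per-variant z-score vectors over all phenotypes from the
moment structure that LD-score regression assumes:

    Var(z_pj)       = N_p * h2_p * l_j / M + 1
    Cov(z_pj, z_qj) = sqrt(N_p * N_q) * rg_pq * sqrt(h2_p * h2_q) * l_j / M

with z independent across variants (LD enters only through the LD scores
l_j).  Direct-edge truth is planted separately by boosting selected variants'
|z| above the genome-wide threshold in both diseases of a pair; boosted
variants are disjoint across pairs and recorded, so shared-SNP truth is exact
and independent of the correlation machinery.

LD scores are drawn from a right-skewed Gamma with mean ~100 and the total
panel size defaults to M = 500 * m: the m simulated variants play the role of
regression SNPs subsampled from a dense panel, which keeps the per-variant
signal N*h2*l/M at a realistic (slightly conservative) magnitude and makes
chance co-significance between unrelated diseases negligible, so planted
shared-SNP truth stays exact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import erfc
from scipy.stats import norm

from .network import pair_key
from .sumstats import LDScoreTable, SumStatTable, write_ldscores, write_sumstats

log = logging.getLogger(__name__)

_TINY = np.finfo(float).tiny
#: |z| above which a two-sided p-value is genome-wide significant (5e-8).
Z_GENOME_WIDE = float(norm.isf(2.5e-8))
#: Default ratio of total panel size M to the number of regression SNPs.
#: Chosen so that the per-variant polygenic signal N*h2*l/M stays small enough
#: that unrelated diseases essentially never share a chance genome-wide hit,
#: keeping planted direct-edge truth exact (see docs/methods.md).
M_TOTAL_RATIO = 500
#: Default detectability bound for expected indirect edges: planted |rg| at or
#: above this is comfortably detectable at the default scenario sizes
#: (roughly 4-5x the asymptotic rg standard error at N=5e4, m=5e3).
DEFAULT_RG_BOUND = 0.3

_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                 ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]


@dataclass(frozen=True)
class DiseaseSpec:
    phecode: str
    category: str
    case_count: int
    h2: float
    n_samples: int


@dataclass(frozen=True)
class TraitSpec:
    trait_id: str
    h2: float
    n_samples: int


@dataclass
class SimulationScenario:
    """Full specification of one synthetic study.

    ``planted_rg`` maps (disease phecode, trait id) to the genetic correlation
    to plant; unlisted pairs are uncorrelated.  ``planted_shared_snps`` maps
    an unordered disease pair to the number of jointly genome-wide-significant
    variants to plant.  A fixed seed makes the generated bundle byte-identical
    across runs.
    """

    m_variants: int
    diseases: list[DiseaseSpec]
    traits: list[TraitSpec]
    planted_rg: dict[tuple[str, str], float] = field(default_factory=dict)
    planted_shared_snps: dict[tuple[str, str], int] = field(default_factory=dict)
    seed: int = 0
    n_low_maf: int = 0
    mean_ld: float = 100.0
    ld_shape: float = 6.0
    m_total: int | None = None

    @property
    def resolved_m_total(self) -> int:
        return self.m_total if self.m_total is not None else M_TOTAL_RATIO * self.m_variants

    @property
    def phenotype_ids(self) -> list[str]:
        return [d.phecode for d in self.diseases] + [t.trait_id for t in self.traits]

    def rg_matrix(self) -> np.ndarray:
        """Phenotype-level genetic correlation matrix (unit diagonal)."""
        pids = self.phenotype_ids
        idx = {p: i for i, p in enumerate(pids)}
        r = np.eye(len(pids))
        for (d, t), rg in self.planted_rg.items():
            i, j = idx[d], idx[t]
            r[i, j] = r[j, i] = rg
        return r

    def validate(self) -> None:
        pids = self.phenotype_ids
        if len(set(pids)) != len(pids):
            raise ValueError("phenotype ids are not unique")
        if self.m_variants < 10:
            raise ValueError("m_variants must be at least 10")
        disease_ids = {d.phecode for d in self.diseases}
        trait_ids = {t.trait_id for t in self.traits}
        for spec in [*self.diseases, *self.traits]:
            if not (0 <= spec.h2 < 1):
                raise ValueError(f"h2 out of [0, 1) for {spec}")
        for (d, t), rg in self.planted_rg.items():
            if d not in disease_ids or t not in trait_ids:
                raise ValueError(f"planted_rg names unknown pair ({d}, {t})")
            if not (-1 <= rg <= 1):
                raise ValueError(f"planted rg {rg} outside [-1, 1]")
        for (a, b), c in self.planted_shared_snps.items():
            if a not in disease_ids or b not in disease_ids or a == b:
                raise ValueError(f"planted_shared_snps names invalid pair ({a}, {b})")
            if c < 0:
                raise ValueError("planted shared-SNP counts must be non-negative")
        eigmin = float(np.linalg.eigvalsh(self.rg_matrix()).min())
        if eigmin < -1e-9:
            raise ValueError(
                f"planted correlations are not jointly realizable (min eigenvalue "
                f"{eigmin:.3g} < 0); offending pairs: {sorted(self.planted_rg)}")

    @classmethod
    def from_yaml(cls, path) -> "SimulationScenario":
        cfg = yaml.safe_load(Path(path).read_text())
        diseases = [DiseaseSpec(phecode=str(d["phecode"]), category=d["category"],
                                case_count=int(d["case_count"]), h2=float(d["h2"]),
                                n_samples=int(d["n_samples"]))
                    for d in cfg["diseases"]]
        traits = [TraitSpec(trait_id=str(t["trait_id"]), h2=float(t["h2"]),
                            n_samples=int(t["n_samples"]))
                  for t in cfg["traits"]]
        planted_rg = {(str(e["disease"]), str(e["trait"])): float(e["rg"])
                      for e in cfg.get("planted_rg", [])}
        planted_shared = {pair_key(str(e["pair"][0]), str(e["pair"][1])): int(e["count"])
                          for e in cfg.get("planted_shared_snps", [])}
        kwargs = {k: cfg[k] for k in
                  ("n_low_maf", "mean_ld", "ld_shape", "m_total") if k in cfg}
        return cls(m_variants=int(cfg["m_variants"]), diseases=diseases,
                   traits=traits, planted_rg=planted_rg,
                   planted_shared_snps=planted_shared, seed=int(cfg["seed"]),
                   **kwargs)


def simulate_ld_scores(m: int, seed: int, mean_ld: float = 100.0,
                       shape: float = 6.0, m_total: int | None = None
                       ) -> LDScoreTable:
    """Right-skewed (Gamma) LD scores for m regression SNPs.

    ``m_total`` is the size of the panel the scores notionally summarize
    (default ``220 * m``); it becomes the regression M.
    """
    if m < 10:
        raise ValueError("m must be at least 10")
    rng = np.random.default_rng([seed, 11])
    scores = rng.gamma(shape, mean_ld / shape, size=m)
    ids = pd.Index([f"rs{i + 1}" for i in range(m)], name="variant_id")
    return LDScoreTable(scores=pd.Series(scores, index=ids),
                        m_total=int(m_total if m_total is not None else M_TOTAL_RATIO * m))


def _variant_layout(m: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic chromosome/position grid (autosomes, outside the MHC)."""
    per_chrom = -(-m // 22)
    idx = np.arange(m)
    chrom = (idx // per_chrom + 1).astype(str)
    pos = 40_000_000 + (idx % per_chrom) * 3_000
    return chrom, pos


def simulate_sumstats(scenario: SimulationScenario, ld: LDScoreTable
                      ) -> tuple[dict[str, SumStatTable], dict[tuple[str, str], list[str]]]:
    """Draw summary statistics for every phenotype in the scenario.

    Returns the per-phenotype tables plus the map of boosted (planted
    shared-significant) variants per disease pair.
    """
    scenario.validate()
    if ld.n_variants != scenario.m_variants:
        raise ValueError(f"LD table has {ld.n_variants} variants, scenario "
                         f"expects {scenario.m_variants}")
    m = scenario.m_variants
    M = ld.m_total
    l = ld.scores.to_numpy(float)
    ids = ld.scores.index.to_numpy()
    pids = scenario.phenotype_ids
    n_samples = np.array([s.n_samples for s in [*scenario.diseases, *scenario.traits]],
                         dtype=float)
    h2 = np.array([s.h2 for s in [*scenario.diseases, *scenario.traits]])

    # per-variant covariance: Sigma_j = I + (l_j / M) * A, A = S R S
    s_vec = np.sqrt(n_samples * h2)
    a_mat = scenario.rg_matrix() * np.outer(s_vec, s_vec)
    lam, q_mat = np.linalg.eigh(a_mat)
    lam = np.clip(lam, 0.0, None)

    rng = np.random.default_rng([scenario.seed, 23])
    eps = rng.standard_normal((m, len(pids)))
    z = (eps * np.sqrt(1.0 + np.outer(l, lam) / M)) @ q_mat.T

    eaf = rng.uniform(0.0505, 0.5, size=m)
    if scenario.n_low_maf:
        low = rng.choice(m, size=scenario.n_low_maf, replace=False)
        eaf[low] = 0.01

    allele_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    ea = np.array([_ALLELE_PAIRS[k][0] for k in allele_idx])
    oa = np.array([_ALLELE_PAIRS[k][1] for k in allele_idx])

    col = {p: j for j, p in enumerate(pids)}
    boosted: dict[tuple[str, str], list[str]] = {}
    used: set[int] = set(np.flatnonzero(np.minimum(eaf, 1 - eaf) <= 0.05).tolist())
    for pair in sorted(scenario.planted_shared_snps):
        count = scenario.planted_shared_snps[pair]
        if count == 0:
            continue
        candidates = np.array(sorted(set(range(m)) - used))
        if len(candidates) < count:
            raise ValueError(f"not enough free variants to plant {count} shared "
                             f"SNPs for pair {pair}")
        pick = rng.choice(candidates, size=count, replace=False)
        used.update(pick.tolist())
        for pid in pair:
            j = col[pid]
            sign = np.where(z[pick, j] >= 0, 1.0, -1.0)
            z[pick, j] = sign * (Z_GENOME_WIDE * 1.2 + rng.exponential(1.0, size=count))
        boosted[pair] = sorted(str(v) for v in ids[pick])

    pvals = np.maximum(erfc(np.abs(z) / np.sqrt(2.0)), _TINY)
    chrom, pos = _variant_layout(m)
    tables: dict[str, SumStatTable] = {}
    for j, pid in enumerate(pids):
        se = 1.0 / np.sqrt(n_samples[j])
        df = pd.DataFrame({
            "variant_id": ids, "chrom": chrom, "pos": pos,
            "effect_allele": ea, "other_allele": oa, "eaf": eaf,
            "beta": z[:, j] * se, "se": np.full(m, se),
            "pval": pvals[:, j], "n": np.full(m, int(n_samples[j])),
        })
        tables[pid] = SumStatTable(pid, df)
    return tables, boosted


@dataclass
class ScenarioTruth:
    """Planted edge sets a correct pipeline should recover."""

    direct_edges: set[tuple[str, str]]
    indirect_edges: set[tuple[str, str]]
    detectable_per_trait: dict[str, list[str]]
    detectability_bound: float

    def to_dict(self) -> dict:
        return {
            "direct_edges": sorted(list(e) for e in self.direct_edges),
            "indirect_edges": sorted(list(e) for e in self.indirect_edges),
            "detectable_per_trait": self.detectable_per_trait,
            "detectability_bound": self.detectability_bound,
        }


def scenario_truth(scenario: SimulationScenario,
                   detectability_bound: float = DEFAULT_RG_BOUND) -> ScenarioTruth:
    """Expected direct and indirect edge sets.

    Expected E: pairs with at least one planted shared SNP.  Expected E+: per
    trait, a clique on the diseases whose planted |rg| reaches the
    detectability bound (correlations below the bound are not promised to be
    found at the scenario's sample sizes and do not enter the truth).
    """
    direct = {pair_key(a, b) for (a, b), c in scenario.planted_shared_snps.items()
              if c >= 1}
    detectable: dict[str, list[str]] = {t.trait_id: [] for t in scenario.traits}
    for (d, t), rg in scenario.planted_rg.items():
        if abs(rg) >= detectability_bound:
            detectable[t].append(d)
    indirect: set[tuple[str, str]] = set()
    for t, ds in detectable.items():
        ds.sort()
        indirect.update(pair_key(a, b) for a, b in combinations(ds, 2))
    return ScenarioTruth(direct_edges=direct, indirect_edges=indirect,
                         detectable_per_trait=detectable,
                         detectability_bound=detectability_bound)


def default_scenario(seed: int, m_variants: int = 5000) -> SimulationScenario:
    """The reference synthetic study: 6 diseases, 5 biomarkers.

    Two disjoint biomarker cliques (|rg| = 0.5, a mix of signs) plus three
    null biomarkers that correlate with nothing — the analogue of lab
    measurements that contribute no network edges.  Disease heritability 0.3
    at N = 50,000; three planted direct edges, one of which coincides with an
    indirect edge so the merged graph exercises the "both" class.
    """
    h2, n = 0.3, 50_000
    diseases = [
        DiseaseSpec("272.1", "endocrine/metabolic", 40_000, h2, n),   # hyperlipidemia
        DiseaseSpec("250.2", "endocrine/metabolic", 20_000, h2, n),   # type 2 diabetes
        DiseaseSpec("428.2", "circulatory system", 10_000, h2, n),    # heart failure
        DiseaseSpec("401.1", "circulatory system", 60_000, h2, n),    # hypertension
        DiseaseSpec("530.1", "digestive", 15_000, h2, n),             # esophagitis/GERD
        DiseaseSpec("715.3", "musculoskeletal", 8_000, h2, n),        # osteoarthrosis
    ]
    traits = [TraitSpec(t, h2, n) for t in ("HDL_C", "TG", "ALB", "VITD", "CRP")]
    planted_rg = {
        ("272.1", "HDL_C"): -0.5,
        ("250.2", "HDL_C"): -0.5,
        ("428.2", "HDL_C"): 0.5,
        ("401.1", "TG"): 0.5,
        ("530.1", "TG"): 0.5,
        ("715.3", "TG"): 0.5,
    }
    planted_shared = {
        pair_key("250.2", "272.1"): 3,   # overlaps the HDL_C clique -> "both"
        pair_key("401.1", "428.2"): 2,
        pair_key("530.1", "715.3"): 2,
    }
    return SimulationScenario(m_variants=m_variants, diseases=diseases,
                              traits=traits, planted_rg=planted_rg,
                              planted_shared_snps=planted_shared, seed=seed,
                              n_low_maf=50)


def paired_trait_scenario(seed: int, rg: float = 0.5, h2_a: float = 0.3,
                          h2_b: float = 0.3, n_samples: int = 20_000,
                          m_variants: int = 5000) -> SimulationScenario:
    """Minimal one-disease/one-trait scenario for estimator calibration."""
    return SimulationScenario(
        m_variants=m_variants,
        diseases=[DiseaseSpec("008", "infectious diseases", 5000, h2_a, n_samples)],
        traits=[TraitSpec("T1", h2_b, n_samples)],
        planted_rg={("008", "T1"): rg} if rg else {},
        seed=seed,
    )


def null_pairs_scenario(seed: int, n_pairs: int, h2: float = 0.3,
                        n_samples: int = 50_000, m_variants: int = 5000
                        ) -> SimulationScenario:
    """``n_pairs`` heritable disease-trait pairs with zero genetic correlation.

    Defaults match the reference scenario's sample size, i.e. the confidently
    heritable regime (h2 z-score well above the pipeline's filter) in which
    the rg test's p-values are actually consumed downstream.
    """
    diseases = [DiseaseSpec(f"{100 + i}", "circulatory system", 5000, h2, n_samples)
                for i in range(n_pairs)]
    traits = [TraitSpec(f"T{i}", h2, n_samples) for i in range(n_pairs)]
    return SimulationScenario(m_variants=m_variants, diseases=diseases,
                              traits=traits, seed=seed)


def write_fixture_bundle(scenario: SimulationScenario, out_dir,
                         detectability_bound: float = DEFAULT_RG_BOUND
                         ) -> dict[str, Path]:
    """Write the full text fixture bundle for a scenario.

    Emits one summary-statistic TSV per phenotype, the LD-score file and its
    ``.M`` sidecar, the phenotype metadata CSV, the variant whitelist, and
    ``truth.json`` (planted edges, planted rg, boosted variants, bound).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ld = simulate_ld_scores(scenario.m_variants, seed=scenario.seed,
                            mean_ld=scenario.mean_ld, shape=scenario.ld_shape,
                            m_total=scenario.resolved_m_total)
    tables, boosted = simulate_sumstats(scenario, ld)

    paths: dict[str, Path] = {"sumstats_dir": out / "sumstats"}
    paths["sumstats_dir"].mkdir(exist_ok=True)
    for pid, table in tables.items():
        p = paths["sumstats_dir"] / f"{pid}.tsv"
        write_sumstats(table, p)
        paths[pid] = p

    paths["ldscores"] = out / "ldscores.tsv"
    write_ldscores(ld, paths["ldscores"])

    meta_rows = [{"phecode": d.phecode, "description": f"synthetic disease {d.phecode}",
                  "case_count": d.case_count, "category": d.category,
                  "is_binary": True} for d in scenario.diseases]
    meta_rows += [{"phecode": t.trait_id, "description": f"synthetic biomarker {t.trait_id}",
                   "case_count": t.n_samples, "category": "biomarker",
                   "is_binary": False} for t in scenario.traits]
    paths["meta"] = out / "metadata.csv"
    pd.DataFrame(meta_rows).to_csv(paths["meta"], index=False)

    paths["whitelist"] = out / "whitelist.txt"
    paths["whitelist"].write_text("\n".join(ld.scores.index) + "\n")

    truth = scenario_truth(scenario, detectability_bound)
    payload = truth.to_dict()
    payload["planted_rg"] = [{"disease": d, "trait": t, "rg": rg}
                             for (d, t), rg in sorted(scenario.planted_rg.items())]
    payload["boosted_variants"] = {f"{a}|{b}": v for (a, b), v in boosted.items()}
    payload["seed"] = scenario.seed
    paths["truth"] = out / "truth.json"
    paths["truth"].write_text(json.dumps(payload, indent=2) + "\n")
    return paths
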