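"""Reading, validation, and harmonization of GWAS summary statistics.

Per-phenotype association tables (one row per variant: alleles, effect size,
standard error, p-value, sample size) are validated into :class:`SumStatTable`
objects and then harmonized — restricted to a common whitelisted variant set,
purged of the MHC region and of strand-ambiguous variants, and allele-aligned
to a single reference orientation — so that every downstream step (LD-score
regression, shared-SNP intersection) operates on one identical, ordered
variant space.  LD scores arrive as a :class:`LDScoreTable` holding the
per-variant score and the total SNP count ``M`` over which the scores were
computed.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Canonical column names of a summary-statistic table.
CANONICAL_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

VALID_BASES = frozenset("ACGT")
_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_SMALLEST_P = np.finfo(float).tiny


def _norm_chrom(c) -> str:
    s = str(c).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s.upper()


def _chrom_sort_key(c: str) -> tuple[int, str]:
    s = _norm_chrom(c)
    if s.isdigit():
        return (int(s), "")
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    return (special.get(s, 99), s)


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, closed genomic interval ``chrom:start-end``."""

    chrom: str
    start: int
    end: int

    def contains(self, chrom, pos) -> np.ndarray:
        chrom = np.asarray([_norm_chrom(c) for c in np.atleast_1d(chrom)])
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        return (chrom == _norm_chrom(self.chrom)) & (pos >= self.start) & (pos <= self.end)


#: Extended MHC on GRCh37 — the conventional chr6:25-35 Mb exclusion window
#: used by LD-score analyses because of the region's extreme LD.
MHC_GRCH37 = GenomicInterval("6", 25_000_000, 35_000_000)


@dataclass
class SumStatTable:
    """One phenotype's per-variant GWAS summary statistics.

    ``df`` carries :data:`CANONICAL_COLUMNS`; ``variant_id`` is unique,
    ``se`` positive, ``pval`` in (0, 1], alleles single bases from {A,C,G,T}.
    """

    phenotype_id: str
    df: pd.DataFrame

    @property
    def n_variants(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.df["variant_id"].to_numpy()

    @property
    def z(self) -> np.ndarray:
        """Per-variant z-scores beta/se."""
        return self.df["beta"].to_numpy(float) / self.df["se"].to_numpy(float)

    @property
    def maf(self) -> np.ndarray:
        eaf = self.df["eaf"].to_numpy(float)
        return np.minimum(eaf, 1.0 - eaf)

    def copy(self) -> "SumStatTable":
        return SumStatTable(self.phenotype_id, self.df.copy())


@dataclass
class LDScoreTable:
    """Per-variant LD scores plus the total SNP count M underlying them."""

    scores: pd.Series  # index: variant_id, values: float >= 0
    m_total: int

    @property
    def n_variants(self) -> int:
        return len(self.scores)

    def aligned(self, variant_ids: Sequence[str]) -> np.ndarray:
        """LD scores in the order of ``variant_ids``; error if any are missing."""
        vals = self.scores.reindex(variant_ids).to_numpy(float)
        if np.isnan(vals).any():
            missing = np.asarray(variant_ids)[np.isnan(vals)]
            raise ValueError(
                f"{len(missing)} variants lack LD scores (first: {missing[0]}); "
                "harmonize tables against the LD-score variant space first"
            )
        return vals


@dataclass
class HarmonizationReport:
    """Bookkeeping of what harmonization kept, flipped and dropped."""

    n_input_per_table: dict[str, int]
    n_whitelist: int
    n_mhc_removed: int
    n_final: int
    n_flipped: int
    n_dropped_ambiguous: int
    n_dropped_irreconcilable: int = 0

    def to_dict(self) -> dict:
        return {
            "n_input_per_table": dict(self.n_input_per_table),
            "n_whitelist": self.n_whitelist,
            "n_mhc_removed": self.n_mhc_removed,
            "n_final": self.n_final,
            "n_flipped": self.n_flipped,
            "n_dropped_ambiguous": self.n_dropped_ambiguous,
            "n_dropped_irreconcilable": self.n_dropped_irreconcilable,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def validate_sumstat_frame(df: pd.DataFrame, phenotype_id: str) -> pd.DataFrame:
    """Coerce and row-filter a raw summary-statistic frame.

    Rows violating invariants (non-positive se, p outside (0,1], malformed
    alleles, missing values, duplicate variant ids) are dropped with a logged
    warning; p-values of exactly 0 are clamped to the smallest positive float
    so z-scores stay finite.  Raises ``ValueError`` if a required column is
    missing or if nothing survives.
    """
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{phenotype_id}: missing required column(s): {', '.join(missing)}")

    df = df.loc[:, CANONICAL_COLUMNS].copy()
    df["variant_id"] = df["variant_id"].astype(str)
    df["chrom"] = df["chrom"].map(_norm_chrom)
    for col in ("eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    n0 = len(df)
    zero_p = df["pval"] == 0
    if zero_p.any():
        log.warning("%s: clamped %d zero p-values to %.3g",
                    phenotype_id, int(zero_p.sum()), _SMALLEST_P)
        df.loc[zero_p, "pval"] = _SMALLEST_P

    ok = (
        df[CANONICAL_COLUMNS].notna().all(axis=1)
        & (df["se"] > 0)
        & (df["pval"] > 0) & (df["pval"] <= 1)
        & (df["eaf"] >= 0) & (df["eaf"] <= 1)
        & (df["n"] > 0)
        & df["effect_allele"].isin(VALID_BASES)
        & df["other_allele"].isin(VALID_BASES)
        & (df["effect_allele"] != df["other_allele"])
    )
    if (~ok).any():
        log.warning("%s: dropped %d invalid rows of %d", phenotype_id, int((~ok).sum()), n0)
    df = df.loc[ok]

    dup = df["variant_id"].duplicated(keep="first")
    if dup.any():
        log.warning("%s: dropped %d duplicate variant ids (kept first occurrence)",
                    phenotype_id, int(dup.sum()))
        df = df.loc[~dup]

    if df.empty:
        raise ValueError(f"{phenotype_id}: no valid rows remain after validation")

    df = df.reset_index(drop=True)
    df["pos"] = df["pos"].astype(np.int64)
    return df


def read_sumstats(path, column_map: Mapping[str, str] | None = None,
                  phenotype_id: str | None = None) -> SumStatTable:
    """Read a delimited summary-statistic file into a validated table.

    Parameters
    ----------
    path
        Whitespace/tab-delimited text file, optionally gzipped.
    column_map
        Mapping of canonical name -> file column name for columns whose header
        differs from :data:`CANONICAL_COLUMNS`.  The special key
        ``"transform"`` with value ``"log"`` takes the natural log of the
        mapped ``beta`` column (for files reporting odds ratios).
    phenotype_id
        Defaults to the file stem (``.tsv``/``.gz`` extensions stripped).
    """
    path = Path(path)
    if phenotype_id is None:
        phenotype_id = re.sub(r"\.(tsv|txt|csv)(\.gz)?$", "", path.name)
    column_map = dict(column_map or {})
    transform = column_map.pop("transform", None)

    raw = pd.read_csv(path, sep=r"\s+")
    rename = {src: canon for canon, src in column_map.items()}
    missing_src = [src for src in rename if src not in raw.columns]
    if missing_src:
        raise ValueError(f"{phenotype_id}: mapped column(s) not in file: {', '.join(missing_src)}")
    raw = raw.rename(columns=rename)

    if transform == "log":
        raw["beta"] = np.log(pd.to_numeric(raw["beta"], errors="coerce"))
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r} (only 'log' is supported)")

    df = validate_sumstat_frame(raw, phenotype_id)
    return SumStatTable(phenotype_id, df)


def write_sumstats(table: SumStatTable, path) -> None:
    """Write a table as tab-delimited text (gzipped if the path ends in .gz)."""
    table.df.loc[:, CANONICAL_COLUMNS].to_csv(path, sep="\t", index=False)


def _complement(alleles: np.ndarray) -> np.ndarray:
    return pd.Series(alleles).map(_COMPLEMENT).to_numpy()


def harmonize(tables: Sequence[SumStatTable], whitelist: Iterable[str],
              mhc: GenomicInterval | None = MHC_GRCH37,
              ) -> tuple[list[SumStatTable], HarmonizationReport]:
    """Restrict tables to a shared, allele-aligned, ordered variant space.

    The returned tables all carry the identical variant list: the intersection
    of every table's variants with the whitelist, minus variants inside the
    MHC interval, minus strand-ambiguous (A/T, C/G) variants, minus variants
    whose allele pairs cannot be reconciled across tables.  Alleles are
    aligned to the first table's orientation; a swapped effect/other pair
    negates beta and reflects the allele frequency, leaving |z| unchanged.
    Variants are sorted by (chromosome, position, id).
    """
    tables = list(tables)
    if len(tables) < 2:
        raise ValueError("harmonize requires at least two tables")
    wl = {str(v) for v in whitelist}
    if not wl:
        raise ValueError("whitelist is empty")

    common = set(tables[0].df["variant_id"])
    for t in tables[1:]:
        common &= set(t.df["variant_id"])
    common &= wl

    ref_frame = tables[0].df.set_index("variant_id", drop=False)
    ids = np.array(sorted(common), dtype=object)
    ref = ref_frame.loc[ids]

    n_mhc = 0
    if mhc is not None and len(ref):
        in_mhc = mhc.contains(ref["chrom"].to_numpy(), ref["pos"].to_numpy())
        n_mhc = int(in_mhc.sum())
        ids = ids[~in_mhc]
        ref = ref.loc[ids]

    amb = np.array([(ea, oa) in _AMBIGUOUS_PAIRS
                    for ea, oa in zip(ref["effect_allele"], ref["other_allele"])])
    n_ambiguous = int(amb.sum()) if len(ref) else 0
    ids = ids[~amb] if len(ref) else ids
    ref = ref.loc[ids]

    ref_ea = ref["effect_allele"].to_numpy()
    ref_oa = ref["other_allele"].to_numpy()

    aligned: list[pd.DataFrame] = []
    irreconcilable: set[str] = set()
    n_flipped = 0
    for i, t in enumerate(tables):
        sub = t.df.set_index("variant_id", drop=False).loc[ids].copy()
        if i == 0:
            aligned.append(sub)
            continue
        ea = sub["effect_allele"].to_numpy()
        oa = sub["other_allele"].to_numpy()
        cea = _complement(ea)
        coa = _complement(oa)
        direct = (ea == ref_ea) & (oa == ref_oa)
        swap = (ea == ref_oa) & (oa == ref_ea)
        strand = (cea == ref_ea) & (coa == ref_oa) & ~(direct | swap)
        strand_swap = (cea == ref_oa) & (coa == ref_ea) & ~(direct | swap | strand)
        bad = ~(direct | swap | strand | strand_swap)
        irreconcilable.update(ids[bad].tolist())
        flip = swap | strand_swap
        n_flipped += int(flip.sum())
        sub.loc[flip, "beta"] = -sub.loc[flip, "beta"]
        sub.loc[flip, "eaf"] = 1.0 - sub.loc[flip, "eaf"]
        sub["effect_allele"] = ref_ea
        sub["other_allele"] = ref_oa
        # position/chromosome follow the reference table's annotation
        sub["chrom"] = ref["chrom"].to_numpy()
        sub["pos"] = ref["pos"].to_numpy()
        aligned.append(sub)

    if irreconcilable:
        log.warning("harmonize: dropped %d variants with irreconcilable allele pairs",
                    len(irreconcilable))
        keep = ~np.isin(ids.astype(str), sorted(irreconcilable))
        ids = ids[keep]
        ref = ref.loc[ids]
        aligned = [a.loc[ids] for a in aligned]

    if len(ids) == 0:
        raise ValueError("harmonization left no variants (empty intersection)")

    chrom_keys = [_chrom_sort_key(c) for c in ref["chrom"]]
    order = sorted(range(len(ids)),
                   key=lambda k: (chrom_keys[k], int(ref["pos"].iloc[k]), str(ids[k])))
    ids = ids[order]

    out = [SumStatTable(t.phenotype_id, a.loc[ids].reset_index(drop=True))
           for t, a in zip(tables, aligned)]
    report = HarmonizationReport(
        n_input_per_table={t.phenotype_id: t.n_variants for t in tables},
        n_whitelist=len(wl),
        n_mhc_removed=n_mhc,
        n_final=len(ids),
        n_flipped=n_flipped,
        n_dropped_ambiguous=n_ambiguous,
        n_dropped_irreconcilable=len(irreconcilable),
    )
    return out, report


def read_ldscores(path, m_total: int | None = None) -> LDScoreTable:
    """Read a tab-delimited LD-score file (columns ``SNP`` and ``L2``).

    The total SNP count M is taken from ``m_total`` if given, otherwise from a
    companion ``<path>.M`` file (whitespace-separated integer tokens, summed,
    so per-chromosome M files concatenate naturally).  Negative scores are a
    hard error naming the first offending variant.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+")
    cols = {c.upper(): c for c in df.columns}
    snp_col = cols.get("SNP") or cols.get("VARIANT_ID") or cols.get("RSID")
    l2_col = cols.get("L2") or cols.get("LDSCORE") or cols.get("LD_SCORE")
    if snp_col is None or l2_col is None:
        raise ValueError(f"{path}: LD-score file needs SNP and L2 columns "
                         f"(found: {list(df.columns)})")
    snp = df[snp_col].astype(str)
    l2 = pd.to_numeric(df[l2_col], errors="coerce")
    if l2.isna().any():
        raise ValueError(f"{path}: non-numeric LD score for variant "
                         f"{snp[l2.isna()].iloc[0]}")
    if (l2 < 0).any():
        raise ValueError(f"{path}: negative LD score for variant "
                         f"{snp[(l2 < 0)].iloc[0]}")
    dup = snp.duplicated(keep="first")
    if dup.any():
        log.warning("%s: dropped %d duplicate LD-score rows", path, int(dup.sum()))
        snp, l2 = snp[~dup], l2[~dup]

    if m_total is None:
        candidates = [Path(str(path) + ".M"),
                      Path(re.sub(r"\.ldscore(\.gz)?$", ".M", str(path)))]
        for cand in candidates:
            if cand != path and cand.exists():
                tokens = cand.read_text().split()
                m_total = int(sum(float(tok) for tok in tokens))
                break
    if m_total is None:
        raise ValueError(f"{path}: total SNP count M not supplied "
                         "(pass m_total= or provide a companion .M file)")

    scores = pd.Series(l2.to_numpy(float), index=pd.Index(snp, name="variant_id"))
    return LDScoreTable(scores=scores, m_total=int(m_total))


def write_ldscores(table: LDScoreTable, path) -> None:
    """Write ``SNP\\tL2`` plus the companion ``<path>.M`` sidecar."""
    path = Path(path)
    pd.DataFrame({"SNP": table.scores.index, "L2": table.scores.to_numpy()}
                 ).to_csv(path, sep="\t", index=False)
    Path(str(path) + ".M").write_text(f"{table.m_total}\n")
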