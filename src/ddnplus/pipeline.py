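"""End-to-end network construction from files on disk.

``run_pipeline`` chains: read + curate phenotypes -> harmonize all summary
statistics into one variant space -> per-disease significant SNP sets ->
direct edges -> bivariate LD-score regression for every disease x trait pair
-> FDR-thresholded association matrix -> indirect edges -> merged ssDDN+.
Everything is deterministic given the input files and configuration.
"""

from __future__ import annotations

import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import yaml

from . import analysis, curation, ldsc, network, sumstats

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage '{name}' failed: {exc}") from exc


@dataclass
class PipelineConfig:
    """Inputs and thresholds for one network build."""

    sumstats: Mapping[str, Path] | Path | str
    ldscores: Path | str
    meta: Path | str
    whitelist: Path | str
    out_dir: Path | str | None = None
    p_threshold: float = network.GENOME_WIDE_P
    maf_threshold: float = network.DEFAULT_MAF
    fdr_alpha: float = 0.05
    h2_z_min: float = 4.0
    min_cases: int = 1000
    excluded_categories: frozenset[str] = curation.DEFAULT_EXCLUDED_CATEGORIES
    manual_exclusions: frozenset[str] = frozenset()
    mhc: sumstats.GenomicInterval | None = sumstats.MHC_GRCH37
    n_blocks: int = 200
    m_total: int | None = None
    column_map: dict | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        cfg = yaml.safe_load(Path(path).read_text())
        kwargs = {}
        for key in ("sumstats", "ldscores", "meta", "whitelist", "out_dir",
                    "p_threshold", "maf_threshold", "fdr_alpha", "h2_z_min",
                    "min_cases", "n_blocks", "m_total", "column_map"):
            if key in cfg:
                kwargs[key] = cfg[key]
        if "excluded_categories" in cfg:
            kwargs["excluded_categories"] = frozenset(cfg["excluded_categories"])
        if "manual_exclusions" in cfg:
            kwargs["manual_exclusions"] = frozenset(
                str(p) for p in cfg["manual_exclusions"])
        if "mhc" in cfg:
            m = cfg["mhc"]
            kwargs["mhc"] = (sumstats.GenomicInterval(str(m["chrom"]),
                                                      int(m["start"]), int(m["end"]))
                             if m else None)
        return cls(**kwargs)

    def resolve_sumstat_paths(self) -> dict[str, Path]:
        if isinstance(self.sumstats, (str, Path)):
            folder = Path(self.sumstats)
            paths = sorted(list(folder.glob("*.tsv")) + list(folder.glob("*.tsv.gz")))
            out = {}
            for p in paths:
                pid = p.name
                for suffix in (".gz", ".tsv"):
                    if pid.endswith(suffix):
                        pid = pid[: -len(suffix)]
                out[pid] = p
            return out
        return {str(k): Path(v) for k, v in self.sumstats.items()}


@dataclass
class PipelineResult:
    config: PipelineConfig
    tables: dict[str, sumstats.SumStatTable]
    harmonization: sumstats.HarmonizationReport
    curation_result: curation.CurationResult
    diseases: list[str]
    traits: list[str]
    sig_sets: dict[str, set[str]]
    direct_edges: dict[tuple[str, str], list[str]]
    indirect_edges: dict[tuple[str, str], list[str]]
    rg_estimates: list[ldsc.RgEstimate]
    assoc: ldsc.AssociationMatrix
    ssddn: nx.Graph
    ssddnplus: nx.Graph
    summary: dict


def run_pipeline(config: PipelineConfig | Path | str | Mapping) -> PipelineResult:
    """Execute the full build; see the module docstring for the stage order."""
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, Mapping):
        config = PipelineConfig(**config)

    with _stage("load inputs"):
        metas = curation.read_phenotype_meta(config.meta)
        whitelist = [line.strip() for line in
                     Path(config.whitelist).read_text().splitlines() if line.strip()]
        ld = sumstats.read_ldscores(config.ldscores, m_total=config.m_total)
        paths = config.resolve_sumstat_paths()
        raw_tables = {pid: sumstats.read_sumstats(p, column_map=config.column_map,
                                                  phenotype_id=pid)
                      for pid, p in paths.items()}

    with _stage("curate phenotypes"):
        binary = [m for m in metas if m.is_binary]
        cur = curation.curate(binary, min_cases=config.min_cases,
                              excluded_categories=config.excluded_categories,
                              manual_exclusions=config.manual_exclusions)
        diseases = [p for p in cur.kept if p in raw_tables]
        skipped = [p for p in cur.kept if p not in raw_tables]
        if skipped:
            log.warning("no summary statistics for %d curated diseases "
                        "(first: %s)", len(skipped), skipped[0])
        traits = [m.phecode for m in metas
                  if not m.is_binary and m.phecode in raw_tables]
        if len(diseases) < 2:
            raise ValueError("fewer than two curated diseases with summary statistics")

    with _stage("harmonize"):
        order = diseases + traits
        harmonized, report = sumstats.harmonize([raw_tables[p] for p in order],
                                                whitelist, mhc=config.mhc)
        tables = {t.phenotype_id: t for t in harmonized}
        n_blocks = min(config.n_blocks, report.n_final)

    with _stage("direct edges"):
        sig_sets = {d: network.significant_snps(tables[d], config.p_threshold,
                                                config.maf_threshold)
                    for d in diseases}
        direct = network.build_direct_edges(sig_sets)

    with _stage("genetic correlations"):
        rgs = [ldsc.estimate_rg(tables[d], tables[t], ld, n_blocks=n_blocks)
               for d in diseases for t in traits]
        assoc = ldsc.build_association_matrix(rgs, alpha=config.fdr_alpha,
                                              h2_z_min=config.h2_z_min)

    with _stage("merge networks"):
        indirect = network.build_indirect_edges(assoc)
        node_attrs = {curation.canonical_phecode(m.phecode):
                      {"category": m.category, "case_count": m.case_count,
                       "description": m.description}
                      for m in metas if m.is_binary}
        ssddn = network.direct_graph(direct, nodes=diseases, node_attrs=node_attrs)
        ssddnplus = network.merge(direct, indirect, nodes=diseases,
                                  node_attrs=node_attrs)
        summary = analysis.compare_networks(ssddn, ssddnplus, traits=traits)

    result = PipelineResult(
        config=config, tables=tables, harmonization=report, curation_result=cur,
        diseases=diseases, traits=traits, sig_sets=sig_sets, direct_edges=direct,
        indirect_edges=indirect, rg_estimates=rgs, assoc=assoc,
        ssddn=ssddn, ssddnplus=ssddnplus, summary=summary,
    )
    if config.out_dir is not None:
        with _stage("write outputs"):
            write_outputs(result, config.out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "harmonization": out / "harmonization_report.json",
        "curation": out / "curation.json",
        "rg_table": out / "rg_estimates.tsv",
        "assoc": out / "association_matrix.tsv",
        "assoc_meta": out / "association_matrix.json",
        "ssddn": out / "ssddn.graphml",
        "ssddnplus": out / "ssddnplus.graphml",
        "edges": out / "ssddnplus_edges.csv",
        "netmage": out / "ssddnplus_netmage.csv",
        "summary": out / "summary.json",
    }
    result.harmonization.to_json(paths["harmonization"])
    result.curation_result.to_json(paths["curation"])
    ldsc.write_rg_table(result.rg_estimates, paths["rg_table"], assoc=result.assoc)
    result.assoc.to_tsv(paths["assoc"])
    paths["assoc_meta"].write_text(json.dumps({
        "diseases": result.assoc.diseases, "traits": result.assoc.traits,
        "alpha": result.assoc.alpha, "h2_z_min": result.assoc.h2_z_min,
        "n_significant": int(result.assoc.r_hat.sum()),
    }, indent=2) + "\n")
    network.write_graphml(result.ssddn, paths["ssddn"])
    network.write_graphml(result.ssddnplus, paths["ssddnplus"])
    network.write_edgelist_csv(result.ssddnplus, paths["edges"])
    network.write_netmage_csv(result.ssddnplus, paths["netmage"])
    paths["summary"].write_text(json.dumps(result.summary, indent=2, default=float)
                                + "\n")
    return paths
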