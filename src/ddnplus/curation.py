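"""Phenotype curation: phecode filtering rules and category assignment.

Phecodes are hierarchical disease codes derived from ICD billing codes; the
number of digits after the decimal point encodes specificity (428 is an organ
system level diagnosis, 428.2 a disease, 428.21 a hyper-specific subtype).
Disease nodes for the network are selected by case-count, hierarchy-depth and
category rules, with an optional user-supplied manual exclusion list for
hierarchically related codes that would carry duplicated signal.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

log = logging.getLogger(__name__)

#: The standard phecode chapters (organ systems and related groupings).
PHECODE_CATEGORIES = [
    "circulatory system",
    "congenital anomalies",
    "dermatologic",
    "digestive",
    "endocrine/metabolic",
    "genitourinary",
    "hematopoietic",
    "infectious diseases",
    "injuries & poisonings",
    "mental disorders",
    "musculoskeletal",
    "neoplasms",
    "neurological",
    "pregnancy complications",
    "respiratory",
    "sense organs",
    "symptoms",
]

#: Chapters excluded from disease networks by default: symptom codes and
#: injury/poisoning codes carry little stable genetic signal.
DEFAULT_EXCLUDED_CATEGORIES = frozenset({"symptoms", "injuries & poisonings"})

#: Chapters whose diseases are treated as cardiometabolic.
CARDIOMETABOLIC_CATEGORIES = frozenset({"endocrine/metabolic", "circulatory system"})

_PHECODE_RE = re.compile(r"^\d+(\.\d{1,2})?$")


def canonical_phecode(phecode) -> str:
    """Canonical phecode string: trailing zeros after the point stripped.

    ``"250.20"`` and ``"250.2"`` denote the same code; registries differ in
    formatting, so comparisons happen on the canonical form.
    """
    s = str(phecode).strip()
    if "." in s:
        s = s.rstrip("0").rstrip(".")
    if not s or not _PHECODE_RE.match(s):
        raise ValueError(f"unparseable phecode: {phecode!r}")
    return s


def phecode_depth(phecode) -> int:
    """Number of significant digits after the decimal point (0, 1 or 2)."""
    s = canonical_phecode(phecode)
    return len(s.split(".")[1]) if "." in s else 0


@dataclass(frozen=True)
class PhenotypeMeta:
    """Identity and bookkeeping for one phenotype.

    ``phecode`` doubles as the phenotype id; for quantitative biomarkers
    (``is_binary=False``) it holds the trait id and the phecode rules do not
    apply.
    """

    phecode: str
    description: str
    case_count: int
    category: str
    is_binary: bool = True


@dataclass
class CurationResult:
    kept: list[str]
    dropped_reasons: dict[str, str]

    def to_dict(self) -> dict:
        return {"kept": list(self.kept), "dropped_reasons": dict(self.dropped_reasons)}

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def read_phenotype_meta(path) -> list[PhenotypeMeta]:
    """Read a phenotype metadata CSV.

    Required columns: ``phecode, description, case_count, category``; an
    optional ``is_binary`` column (true/false) marks quantitative biomarkers.
    """
    df = pd.read_csv(path, dtype={"phecode": str})
    required = ["phecode", "description", "case_count", "category"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata column(s): {', '.join(missing)}")
    metas = []
    for row in df.itertuples(index=False):
        is_binary = bool(getattr(row, "is_binary", True))
        metas.append(PhenotypeMeta(
            phecode=str(row.phecode),
            description=str(row.description),
            case_count=int(row.case_count),
            category=str(row.category),
            is_binary=is_binary,
        ))
    return metas


def curate(metas: Iterable[PhenotypeMeta],
           min_cases: int = 1000,
           excluded_categories: Iterable[str] = DEFAULT_EXCLUDED_CATEGORIES,
           manual_exclusions: Iterable[str] = (),
           auto_hierarchy: bool = False,
           hierarchy_tolerance: float = 0.10) -> CurationResult:
    """Apply the disease inclusion rules.

    A phenotype is kept iff its case count is at least ``min_cases``, its
    phecode depth is at most 1 (no hundredths-digit codes), its category is
    not excluded, and it is not manually excluded.  Each drop records the
    first matching reason in the order LOW_CASES, HUNDREDTHS,
    EXCLUDED_CATEGORY, MANUAL.

    ``auto_hierarchy`` optionally also drops (tagged MANUAL) the deeper member
    of a surviving parent/child phecode pair — same integer part, depth
    differing by one — whose case counts differ by less than
    ``hierarchy_tolerance`` of the larger count.  This is a heuristic
    stand-in for manual curation of hierarchically duplicated signals and is
    off by default.
    """
    if min_cases < 0:
        raise ValueError("min_cases must be non-negative")
    excluded = {str(c) for c in excluded_categories}
    manual = {canonical_phecode(p) for p in manual_exclusions}

    metas = list(metas)
    kept: dict[str, PhenotypeMeta] = {}
    dropped: dict[str, str] = {}
    for m in metas:
        code = canonical_phecode(m.phecode)
        if m.case_count < min_cases:
            dropped[code] = "LOW_CASES"
        elif phecode_depth(code) > 1:
            dropped[code] = "HUNDREDTHS"
        elif m.category in excluded:
            dropped[code] = "EXCLUDED_CATEGORY"
        elif code in manual:
            dropped[code] = "MANUAL"
        else:
            kept[code] = m

    if auto_hierarchy:
        for code in sorted(kept):
            if "." not in code:
                continue
            parent = code.split(".")[0] if phecode_depth(code) == 1 else code.rsplit(".", 1)[0]
            parent = canonical_phecode(parent)
            if parent not in kept or code not in kept:
                continue
            a, b = kept[parent].case_count, kept[code].case_count
            if abs(a - b) < hierarchy_tolerance * max(a, b, 1):
                log.info("auto hierarchy rule drops %s (parent %s, cases %d vs %d)",
                         code, parent, b, a)
                dropped[code] = "MANUAL"
                del kept[code]

    if not kept:
        log.warning("curation kept no phenotypes")
    return CurationResult(kept=sorted(kept), dropped_reasons=dropped)


def assign_cardiometabolic(metas: Iterable[PhenotypeMeta]) -> set[str]:
    """Phecodes in the endocrine/metabolic and circulatory-system chapters."""
    return {canonical_phecode(m.phecode) for m in metas
            if m.category in CARDIOMETABOLIC_CATEGORIES}
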