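"""Annotation confidence scoring.

Combines three independent lines of evidence about a predicted protein --
ortholog gene names from proteome comparison against related Mollicutes,
structural-homology reliability of a reconstructed 3D model, and enzyme
commission (EC) numbers from several prediction methods -- into a single
0-9 annotation score and a basic/medium/high confidence bin.

Component scales:

* proteome comparison: identical gene name = 3, similar (shared 3-character
  prefix) = 2, named orthologs that differ = 1, no named ortholog = 0;
* structural homology: reliable structure = 3 (sequence pre-screen passed
  and C-score > -1.5 and TM-score > 0.5), otherwise 0;
* EC cross-validation: identical 4-digit EC in >=2 methods = 3, first three
  digits identical in >=2 methods = 2, >=2 methods disagree = 1, at most
  one method = 0.

The final score is the plain sum; bins are basic (< 3), medium (>= 3 and
< 7) and high (>= 7).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

__all__ = [
    "StructureMetrics",
    "EvidenceRecord",
    "AnnotationScore",
    "score_proteome",
    "score_structure",
    "score_ec",
    "final_score",
    "score_table",
    "read_evidence_tsv",
    "write_scores_tsv",
]

EC_PATTERN = re.compile(r"^\d+\.\d+\.\d+\.(\d+|-)$")

#: DETECT v2 default probability above which an EC call is flagged gold
#: standard (carried through to the output, not weighted in the score).
GOLD_STANDARD_PROBABILITY = 0.90

STRUCTURE_EVALUE_MAX = 1e-4
STRUCTURE_IDENTITY_MIN = 0.10
STRUCTURE_SIMILARITY_MIN = 0.30
C_SCORE_MIN = -1.5
TM_SCORE_MIN = 0.5

BIN_MEDIUM = 3
BIN_HIGH = 7


@dataclass
class StructureMetrics:
    """Reliability metrics of a reconstructed protein structure."""

    e_value: float
    domain_identity: float
    domain_similarity: float
    is_transmembrane: bool
    c_score: float
    tm_score: float

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise ValueError("e_value must be positive")
        if not 0.0 <= self.tm_score <= 1.0:
            raise ValueError("tm_score must lie in [0, 1]")


@dataclass
class EvidenceRecord:
    """Per-gene annotation evidence."""

    gene: str
    name: str | None = None
    ortholog_names: Mapping[str, str] = field(default_factory=dict)
    ec_by_method: Mapping[str, str] = field(default_factory=dict)
    detect_probability: float | None = None
    structure: StructureMetrics | None = None


@dataclass
class AnnotationScore:
    gene: str
    proteome_score: int
    structure_score: int
    ec_score: int
    final_score: int
    bin: str
    gold_standard: bool = False


def _bin(score: int) -> str:
    if score >= BIN_HIGH:
        return "high"
    if score >= BIN_MEDIUM:
        return "medium"
    return "basic"


def _normalize(name: str) -> str:
    # gene-name capitalization varies across annotations; locus-tag style
    # prefixes ("MFL_eno") are stripped before comparison
    name = name.strip()
    if "_" in name:
        name = name.split("_")[-1]
    return name.lower()


def score_proteome(
    focal_name: str | None, ortholog_names: Mapping[str, str]
) -> int:
    """Score ortholog gene-name agreement across comparator species.

    3 when the focal gene name is identical in at least two comparator
    species, 2 when at least two comparators share the focal 3-character
    prefix, 1 when named orthologs exist but differ, 0 when no named
    ortholog was found.
    """
    names = [_normalize(n) for n in ortholog_names.values() if n and n.strip()]
    if not names:
        return 0
    if focal_name and focal_name.strip():
        focal = _normalize(focal_name)
        if sum(n == focal for n in names) >= 2:
            return 3
        prefix = focal[:3]
        if len(prefix) == 3 and sum(n.startswith(prefix) for n in names) >= 2:
            return 2
    return 1


def score_structure(metrics: StructureMetrics | None) -> int:
    """3 iff the structure passes the pre-screen and quality thresholds."""
    if metrics is None:
        return 0
    prescreen = (
        metrics.e_value < STRUCTURE_EVALUE_MAX
        and metrics.domain_identity > STRUCTURE_IDENTITY_MIN
        and metrics.domain_similarity > STRUCTURE_SIMILARITY_MIN
        and not metrics.is_transmembrane
    )
    if prescreen and metrics.c_score > C_SCORE_MIN and metrics.tm_score > TM_SCORE_MIN:
        return 3
    return 0


def _validate_ec(ec: str) -> str:
    ec = ec.strip()
    if not EC_PATTERN.match(ec):
        raise ValueError(f"malformed EC number {ec!r}")
    return ec


def score_ec(ec_by_method: Mapping[str, str]) -> int:
    """Cross-validate EC predictions between methods.

    Partial ECs (trailing ``-``) participate only in the 3-digit rule.
    """
    ecs = {m: _validate_ec(e) for m, e in ec_by_method.items() if e and e.strip()}
    if len(ecs) <= 1:
        return 0
    full = [e for e in ecs.values() if not e.endswith("-")]
    counts: dict[str, int] = {}
    for e in full:
        counts[e] = counts.get(e, 0) + 1
    if any(c >= 2 for c in counts.values()):
        return 3
    prefixes: dict[str, int] = {}
    for e in ecs.values():
        p = ".".join(e.split(".")[:3])
        prefixes[p] = prefixes.get(p, 0) + 1
    if any(c >= 2 for c in prefixes.values()):
        return 2
    return 1


def final_score(record: EvidenceRecord) -> AnnotationScore:
    """Sum the three component scores and assign the confidence bin."""
    p = score_proteome(record.name, record.ortholog_names)
    s = score_structure(record.structure)
    e = score_ec(record.ec_by_method)
    total = p + s + e
    return AnnotationScore(
        gene=record.gene,
        proteome_score=p,
        structure_score=s,
        ec_score=e,
        final_score=total,
        bin=_bin(total),
        gold_standard=(
            record.detect_probability is not None
            and record.detect_probability >= GOLD_STANDARD_PROBABILITY
        ),
    )


# ---------------------------------------------------------------------------
# tabular interface

_STRUCTURE_COLS = (
    "e_value",
    "domain_identity",
    "domain_similarity",
    "is_transmembrane",
    "c_score",
    "tm_score",
)


def _row_to_record(row: pd.Series) -> EvidenceRecord:
    orthologs = {
        col[len("name_") :]: row[col]
        for col in row.index
        if col.startswith("name_") and isinstance(row[col], str) and row[col].strip()
    }
    ecs = {
        col[len("ec_") :]: row[col]
        for col in row.index
        if col.startswith("ec_") and isinstance(row[col], str) and row[col].strip()
    }
    structure = None
    if all(c in row.index for c in _STRUCTURE_COLS) and pd.notna(row["c_score"]):
        structure = StructureMetrics(
            e_value=float(row["e_value"]),
            domain_identity=float(row["domain_identity"]),
            domain_similarity=float(row["domain_similarity"]),
            is_transmembrane=bool(row["is_transmembrane"]),
            c_score=float(row["c_score"]),
            tm_score=float(row["tm_score"]),
        )
    prob = None
    if "detect_probability" in row.index and pd.notna(row["detect_probability"]):
        prob = float(row["detect_probability"])
    name = row.get("name")
    return EvidenceRecord(
        gene=str(row["gene"]),
        name=name if isinstance(name, str) else None,
        ortholog_names=orthologs,
        ec_by_method=ecs,
        detect_probability=prob,
        structure=structure,
    )


def score_table(evidence: pd.DataFrame) -> pd.DataFrame:
    """Score every row of a wide evidence table.

    Expected columns: ``gene``, ``name``, one ``name_<species>`` column per
    comparator, one ``ec_<method>`` column per EC method, optionally
    ``detect_probability`` and the six structure-metric columns.
    """
    scores = [final_score(_row_to_record(row)) for _, row in evidence.iterrows()]
    return pd.DataFrame(
        {
            "gene": [s.gene for s in scores],
            "proteome_score": [s.proteome_score for s in scores],
            "structure_score": [s.structure_score for s in scores],
            "ec_score": [s.ec_score for s in scores],
            "final_score": [s.final_score for s in scores],
            "bin": [s.bin for s in scores],
            "gold_standard": [s.gold_standard for s in scores],
        }
    )


def read_evidence_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene": str})


def write_scores_tsv(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index=False)
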