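"""Minimal-genome prediction by iterative longest-deletion search.

The genome is a linear sequence of genes, promoters and transcription
units (TUs). Deleting a contiguous DNA segment removes the genes it
overlaps and silences every gene transcribed from a promoter inside the
segment (promoter loss turns off the whole downstream unit). A candidate
deletion is feasible when no experimentally essential gene is removed or
silenced, and when knocking the silenced model genes out of the metabolic
model keeps FBA growth at or above a floor expressed as a fraction of the
unreduced optimum.

Each iteration commits the longest feasible segment (ties broken to the
leftmost genome coordinate); iterating until no feasible segment remains
traces out the reduced genome. The search enumerates candidate segments
bounded by genomic elements and verifies each by FBA, which for
single-segment steps is equivalent to the bi-level MILP formulation of
iterative deletion design but is solver-free and deterministic.

Coordinates are 1-based inclusive base pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Gene",
    "Promoter",
    "TranscriptionUnit",
    "GenomeLayout",
    "DeletionSegment",
    "ReductionTrace",
    "functional_loss",
    "longest_deletion",
    "iterate_reduction",
    "compare_gene_sets",
    "read_layout",
    "write_layout",
]


@dataclass(frozen=True)
class Gene:
    id: str
    start: int
    end: int
    strand: str = "+"
    protein_coding: bool = True
    essential: bool = False
    model_gene: bool = False

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"gene {self.id}: end < start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be + or -")


@dataclass(frozen=True)
class Promoter:
    id: str
    position: int
    tu_id: str


@dataclass(frozen=True)
class TranscriptionUnit:
    id: str
    gene_ids: tuple[str, ...]
    promoter_id: str


@dataclass
class GenomeLayout:
    genes: list[Gene]
    promoters: list[Promoter]
    tus: list[TranscriptionUnit]
    genome_length: int

    def __post_init__(self) -> None:
        gene_ids = {g.id for g in self.genes}
        if len(gene_ids) != len(self.genes):
            raise ValueError("duplicate gene ids in layout")
        for g in self.genes:
            if g.start < 1 or g.end > self.genome_length:
                raise ValueError(f"gene {g.id} outside genome coordinates")
        for p in self.promoters:
            if not 1 <= p.position <= self.genome_length:
                raise ValueError(f"promoter {p.id} outside genome coordinates")
        tu_by_id = {t.id: t for t in self.tus}
        for t in self.tus:
            for gid in t.gene_ids:
                if gid not in gene_ids:
                    raise ValueError(f"TU {t.id} references unknown gene {gid}")
        for p in self.promoters:
            if p.tu_id not in tu_by_id:
                raise ValueError(f"promoter {p.id} references unknown TU {p.tu_id}")

    def gene(self, gid: str) -> Gene:
        return next(g for g in self.genes if g.id == gid)


@dataclass
class DeletionSegment:
    start: int
    end: int
    removed_genes: list[str]
    removed_promoters: list[str]
    silenced_genes: list[str]

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ReductionTrace:
    segments: list[DeletionSegment] = field(default_factory=list)
    genome_sizes: list[int] = field(default_factory=list)
    retained_genes: list[int] = field(default_factory=list)
    deleted_genes: list[int] = field(default_factory=list)
    growth: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": range(1, len(self.segments) + 1),
                "segment_start": [s.start for s in self.segments],
                "segment_end": [s.end for s in self.segments],
                "segment_length": [s.length for s in self.segments],
                "genome_size": self.genome_sizes,
                "retained_genes": self.retained_genes,
                "deleted_genes": self.deleted_genes,
                "growth": self.growth,
            }
        )


def functional_loss(layout: GenomeLayout, start: int, end: int) -> set[str]:
    """Genes lost or silenced by deleting [start, end].

    Overlapping genes are removed; genes downstream of a deleted promoter
    (strand-aware) are silenced even when their sequence is intact.
    """
    if start > end:
        raise ValueError("segment start exceeds end")
    lost = {
        g.id for g in layout.genes if not (g.end < start or g.start > end)
    }
    tu_by_id = {t.id: t for t in layout.tus}
    for prom in layout.promoters:
        if start <= prom.position <= end:
            tu = tu_by_id[prom.tu_id]
            for gid in tu.gene_ids:
                gene = layout.gene(gid)
                downstream = (
                    gene.start >= prom.position
                    if gene.strand == "+"
                    else gene.end <= prom.position
                )
                if downstream:
                    lost.add(gid)
    return lost


def _elements(layout: GenomeLayout) -> list[tuple[int, int]]:
    """Sorted (start, end) spans of all genes and promoters."""
    spans = [(g.start, g.end) for g in layout.genes]
    spans += [(p.position, p.position) for p in layout.promoters]
    return sorted(spans)


def _candidate_segments(
    layout: GenomeLayout, blocked: Sequence[tuple[int, int]] = ()
) -> list[tuple[int, int]]:
    """Maximal-extent segments for every contiguous run of elements.

    For a run of elements i..j the candidate spans from just after the
    previous element to just before the next one; gaps between elements
    (and the genome ends) yield element-free candidates. Every possible
    silenced-gene set is realized by one of these segments at maximal
    base-pair length, so searching them finds the global longest feasible
    deletion. ``blocked`` intervals act as boundaries and are never
    overlapped.
    """
    spans = sorted(_elements(layout) + list(blocked))
    n = len(spans)
    out: list[tuple[int, int]] = []
    if not n:
        return [(1, layout.genome_length)] if layout.genome_length else []
    # element-free gaps
    if spans[0][0] > 1:
        out.append((1, spans[0][0] - 1))
    for k in range(n - 1):
        lo = spans[k][1] + 1
        hi = spans[k + 1][0] - 1
        if lo <= hi:
            out.append((lo, hi))
    if spans[-1][1] < layout.genome_length:
        out.append((spans[-1][1] + 1, layout.genome_length))
    # runs of elements i..j at maximal extent
    for i in range(n):
        start = spans[i - 1][1] + 1 if i else 1
        start = min(start, spans[i][0])
        hi_end = 0
        for j in range(i, n):
            hi_end = max(hi_end, spans[j][1])
            end = spans[j + 1][0] - 1 if j + 1 < n else layout.genome_length
            end = max(end, hi_end)
            if start <= end:
                out.append((start, end))
    if blocked:
        out = [
            (s, e)
            for s, e in out
            if not any(not (e < bs or s > be) for bs, be in blocked)
        ]
    return out


def longest_deletion(
    layout: GenomeLayout,
    knockout_growth,
    min_growth_fraction: float,
    baseline_growth: float,
    forbidden: set[str] | None = None,
    blocked: Sequence[tuple[int, int]] = (),
) -> DeletionSegment | None:
    """Longest contiguous deletion preserving essentials and growth.

    ``knockout_growth`` is a callable mapping a frozenset of silenced
    model-gene ids to the FBA optimum of the model with those genes
    knocked out; results are cached by the caller. ``forbidden`` genes
    (experimentally essential) may be neither removed nor silenced;
    ``blocked`` intervals (already-committed deletions, in original
    coordinates) may not be overlapped. Ties between equal-length feasible
    segments break to the leftmost start. Returns None when no feasible
    segment exists.
    """
    if not 0 < min_growth_fraction <= 1:
        raise ValueError("min_growth_fraction must lie in (0, 1]")
    forbidden = forbidden if forbidden is not None else {
        g.id for g in layout.genes if g.essential
    }
    floor = min_growth_fraction * baseline_growth - 1e-9
    model_genes = {g.id for g in layout.genes if g.model_gene}
    best: tuple[int, int, int] | None = None  # (-length, start, end)
    best_silenced: set[str] = set()
    for start, end in _candidate_segments(layout, blocked):
        length = end - start + 1
        if best is not None and length < -best[0]:
            continue
        silenced = functional_loss(layout, start, end)
        if silenced & forbidden:
            continue
        growth = knockout_growth(frozenset(silenced & model_genes))
        if growth < floor:
            continue
        key = (-length, start, end)
        if best is None or key < best:
            best = key
            best_silenced = silenced
    if best is None:
        return None
    length, start, end = -best[0], best[1], best[2]
    removed = [
        g.id for g in layout.genes if not (g.end < start or g.start > end)
    ]
    removed_proms = [
        p.id for p in layout.promoters if start <= p.position <= end
    ]
    return DeletionSegment(
        start=start,
        end=end,
        removed_genes=removed,
        removed_promoters=removed_proms,
        silenced_genes=sorted(best_silenced),
    )


def _commit(layout: GenomeLayout, segment: DeletionSegment) -> GenomeLayout:
    """Remove the segment's genes and promoters from the layout.

    Coordinates stay in the original frame so committed segments remain
    non-overlapping; silenced-but-intact genes are dropped from the layout
    as functional elements (their DNA may be deleted later for free).
    """
    silenced = set(segment.silenced_genes)
    genes = [g for g in layout.genes if g.id not in silenced]
    removed_proms = set(segment.removed_promoters)
    promoters = [p for p in layout.promoters if p.id not in removed_proms]
    tus = []
    for tu in layout.tus:
        kept = tuple(g for g in tu.gene_ids if g not in silenced)
        if kept and any(p.tu_id == tu.id for p in promoters):
            tus.append(replace(tu, gene_ids=kept))
    return GenomeLayout(
        genes=genes,
        promoters=promoters,
        tus=tus,
        genome_length=layout.genome_length,
    )


def iterate_reduction(
    layout: GenomeLayout,
    model,
    min_growth_fraction: float,
    n_iter: int = 100,
    forbidden: set[str] | None = None,
) -> ReductionTrace:
    """Iteratively commit longest deletions until none remains.

    The metabolic model accumulates knockouts of every silenced model gene;
    the genome size decreases by each committed segment's length. The trace
    records the per-iteration genome size, retained/deleted gene counts and
    the verified growth after each commit.
    """
    baseline = float(model.slim_optimize(error_value=0.0))
    if baseline <= 0:
        raise ValueError("unreduced model does not grow")
    if forbidden is None:
        forbidden = {g.id for g in layout.genes if g.essential}

    total_genes = len(layout.genes)
    knocked: set[str] = set()
    cache: dict[frozenset, float] = {}

    def knockout_growth(extra: frozenset) -> float:
        key = frozenset(knocked | set(extra))
        if key not in cache:
            with model:
                for gid in key:
                    model.genes.get_by_id(gid).knock_out()
                cache[key] = max(float(model.slim_optimize(error_value=0.0)), 0.0)
        return cache[key]

    trace = ReductionTrace()
    current = layout
    genome_size = layout.genome_length
    deleted = 0
    committed: list[tuple[int, int]] = []
    for _ in range(n_iter):
        segment = longest_deletion(
            current,
            knockout_growth,
            min_growth_fraction,
            baseline,
            forbidden,
            blocked=committed,
        )
        if segment is None:
            break
        model_gene_ids = {g.id for g in current.genes if g.model_gene}
        knocked |= set(segment.silenced_genes) & model_gene_ids
        deleted += len(segment.silenced_genes)
        genome_size -= segment.length
        committed.append((segment.start, segment.end))
        current = _commit(current, segment)
        trace.segments.append(segment)
        trace.genome_sizes.append(genome_size)
        trace.retained_genes.append(total_genes - deleted)
        trace.deleted_genes.append(deleted)
        trace.growth.append(knockout_growth(frozenset()))
    return trace


def compare_gene_sets(
    retained: set[str],
    deleted: set[str],
    references: Mapping[str, set[str]],
    categories: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Overlap report of retained/deleted genes against reference gene sets.

    For each named reference (an ortholog map rendered as the set of focal
    genes with an ortholog) the Venn regions of the deleted and retained
    sets are counted. With ``categories`` (gene -> function category) a
    per-category breakdown row is emitted per reference.
    """
    rows = []
    for name, ref in references.items():
        rows.append(
            {
                "reference": name,
                "category": "(all)",
                "deleted_in_reference": len(deleted & ref),
                "deleted_not_in_reference": len(deleted - ref),
                "retained_in_reference": len(retained & ref),
                "retained_not_in_reference": len(retained - ref),
                "reference_only": len(ref - retained - deleted),
            }
        )
        if categories:
            for cat in sorted(set(categories.values())):
                members = {g for g, c in categories.items() if c == cat}
                rows.append(
                    {
                        "reference": name,
                        "category": cat,
                        "deleted_in_reference": len(deleted & ref & members),
                        "deleted_not_in_reference": len((deleted - ref) & members),
                        "retained_in_reference": len(retained & ref & members),
                        "retained_not_in_reference": len((retained - ref) & members),
                        "reference_only": len((ref - retained - deleted) & members),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TSV persistence (genes/promoters/TUs in one tab-separated file per table)


def write_layout(layout: GenomeLayout, genes_path, promoters_path, tus_path) -> None:
    pd.DataFrame(
        {
            "id": [g.id for g in layout.genes],
            "start": [g.start for g in layout.genes],
            "end": [g.end for g in layout.genes],
            "strand": [g.strand for g in layout.genes],
            "protein_coding": [int(g.protein_coding) for g in layout.genes],
            "essential": [int(g.essential) for g in layout.genes],
            "model_gene": [int(g.model_gene) for g in layout.genes],
            "genome_length": [layout.genome_length] * len(layout.genes),
        }
    ).to_csv(genes_path, sep="\t", index=False)
    pd.DataFrame(
        {
            "id": [p.id for p in layout.promoters],
            "position": [p.position for p in layout.promoters],
            "tu_id": [p.tu_id for p in layout.promoters],
        }
    ).to_csv(promoters_path, sep="\t", index=False)
    pd.DataFrame(
        {
            "id": [t.id for t in layout.tus],
            "gene_ids": [",".join(t.gene_ids) for t in layout.tus],
            "promoter_id": [t.promoter_id for t in layout.tus],
        }
    ).to_csv(tus_path, sep="\t", index=False)


def read_layout(genes_path, promoters_path, tus_path) -> GenomeLayout:
    genes_df = pd.read_csv(genes_path, sep="\t", dtype={"id": str})
    promoters_df = pd.read_csv(promoters_path, sep="\t", dtype={"id": str, "tu_id": str})
    tus_df = pd.read_csv(tus_path, sep="\t", dtype=str)
    genes = [
        Gene(
            id=row["id"],
            start=int(row["start"]),
            end=int(row["end"]),
            strand=row["strand"],
            protein_coding=bool(int(row["protein_coding"])),
            essential=bool(int(row["essential"])),
            model_gene=bool(int(row["model_gene"])),
        )
        for _, row in genes_df.iterrows()
    ]
    promoters = [
        Promoter(id=row["id"], position=int(row["position"]), tu_id=row["tu_id"])
        for _, row in promoters_df.iterrows()
    ]
    tus = [
        TranscriptionUnit(
            id=row["id"],
            gene_ids=tuple(row["gene_ids"].split(",")),
            promoter_id=row["promoter_id"],
        )
        for _, row in tus_df.iterrows()
    ]
    return GenomeLayout(
        genes=genes,
        promoters=promoters,
        tus=tus,
        genome_length=int(genes_df["genome_length"].iloc[0]),
    )
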