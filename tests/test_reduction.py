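"""Genome layout coupling rules and the longest-deletion search."""

import numpy as np
import pytest

from minigem.reduction import (
    Gene,
    GenomeLayout,
    Promoter,
    TranscriptionUnit,
    compare_gene_sets,
    functional_loss,
    iterate_reduction,
    longest_deletion,
    read_layout,
    write_layout,
)
from minigem.synth import SyntheticScenario, make_toy_layout, make_toy_model

from _oracles import brute_force_longest_deletion


def three_gene_tu_layout() -> GenomeLayout:
    genes = [
        Gene("gA", 100, 400),
        Gene("gB", 500, 800),
        Gene("gC", 900, 1200),
    ]
    promoters = [Promoter("p1", 50, "tu1")]
    tus = [TranscriptionUnit("tu1", ("gA", "gB", "gC"), "p1")]
    return GenomeLayout(genes=genes, promoters=promoters, tus=tus, genome_length=2000)


class TestFunctionalLoss:
    def test_promoter_loss_silences_whole_unit(self):
        layout = three_gene_tu_layout()
        assert functional_loss(layout, 40, 60) == {"gA", "gB", "gC"}

    def test_intergenic_segment_silences_nothing(self):
        layout = three_gene_tu_layout()
        assert functional_loss(layout, 1300, 1900) == set()

    def test_internal_gene_only(self):
        layout = three_gene_tu_layout()
        assert functional_loss(layout, 450, 850) == {"gB"}

    def test_minus_strand_downstream_rule(self):
        genes = [Gene("gA", 100, 400, strand="-"), Gene("gB", 500, 800, strand="-")]
        promoters = [Promoter("p1", 850, "tu1")]
        tus = [TranscriptionUnit("tu1", ("gB", "gA"), "p1")]
        layout = GenomeLayout(genes=genes, promoters=promoters, tus=tus, genome_length=1000)
        assert functional_loss(layout, 840, 860) == {"gA", "gB"}


def random_layout(seed: int, model):
    """Layout over the toy model genes plus random extras and essentials."""
    rng = np.random.default_rng(seed)
    scenario = SyntheticScenario(seed=seed)
    layout = make_toy_layout(model, scenario, extra_genes=int(rng.integers(4, 12)))
    model_gene_ids = {g.id for g in model.genes}
    genes = []
    for g in layout.genes:
        essential = (
            bool(rng.random() < 0.3) if g.id not in model_gene_ids else False
        )
        genes.append(
            Gene(
                id=g.id,
                start=g.start,
                end=g.end,
                strand=g.strand,
                protein_coding=g.protein_coding,
                essential=essential,
                model_gene=g.model_gene,
            )
        )
    return GenomeLayout(
        genes=genes,
        promoters=layout.promoters,
        tus=layout.tus,
        genome_length=layout.genome_length,
    )


@pytest.fixture(scope="module")
def ko_oracle(chain_model):
    """Cached knockout-growth evaluator over the shared toy model."""
    model, _ = chain_model
    cache: dict[frozenset, float] = {}

    def knockout_growth(silenced: frozenset) -> float:
        if silenced not in cache:
            with model:
                for gid in silenced:
                    model.genes.get_by_id(gid).knock_out()
                cache[silenced] = max(float(model.slim_optimize(error_value=0.0)), 0.0)
        return cache[silenced]

    return knockout_growth


class TestLongestDeletion:
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_oracle(self, seed, chain_model, ko_oracle):
        model, _ = chain_model
        layout = random_layout(seed, model)
        baseline = float(model.slim_optimize())
        forbidden = {g.id for g in layout.genes if g.essential}
        segment = longest_deletion(layout, ko_oracle, 0.6, baseline, forbidden)
        oracle_len = brute_force_longest_deletion(
            layout, ko_oracle, 0.6, baseline, forbidden
        )
        if segment is None:
            assert oracle_len == 0
        else:
            assert segment.length == oracle_len

    def test_all_essential_genome_has_no_deletion(self, ko_oracle):
        genes = [Gene("gA", 1, 500, essential=True), Gene("gB", 501, 1000, essential=True)]
        layout = GenomeLayout(genes=genes, promoters=[], tus=[], genome_length=1000)
        assert (
            longest_deletion(layout, ko_oracle, 1.0, 1.0, {"gA", "gB"}) is None
        )

    def test_single_dispensable_island_is_found_exactly(self, ko_oracle):
        genes = [
            Gene("gA", 1, 1000, essential=True),
            Gene("island", 2001, 2500, essential=False),
            Gene("gB", 6001, 7000, essential=True),
        ]
        layout = GenomeLayout(genes=genes, promoters=[], tus=[], genome_length=8000)
        segment = longest_deletion(layout, ko_oracle, 0.6, 1.0, {"gA", "gB"})
        assert segment is not None
        assert segment.start == 1001
        assert segment.end == 6000
        assert segment.silenced_genes == ["island"]


class TestIterateReduction:
    def test_trace_invariants(self, chain_model):
        model, _ = chain_model
        layout = random_layout(3, model)
        baseline = float(model.slim_optimize())
        trace = iterate_reduction(layout, model, 0.6, n_iter=50)
        assert trace.segments, "expected at least one committed deletion"
        # genome size strictly decreasing
        sizes = [layout.genome_length] + trace.genome_sizes
        assert all(a > b for a, b in zip(sizes, sizes[1:]))
        # growth floor respected after every commit
        assert all(g >= 0.6 * baseline - 1e-6 for g in trace.growth)
        # no forbidden gene ever silenced
        forbidden = {g.id for g in layout.genes if g.essential}
        silenced = {g for s in trace.segments for g in s.silenced_genes}
        assert not silenced & forbidden
        # segments non-overlapping in original coordinates
        spans = sorted((s.start, s.end) for s in trace.segments)
        assert all(a[1] < b[0] for a, b in zip(spans, spans[1:]))

    def test_final_size_monotone_in_growth_floor(self, chain_model):
        model, _ = chain_model
        layout = random_layout(5, model)
        finals = []
        for fraction in (0.6, 0.9, 1.0):
            trace = iterate_reduction(layout, model, fraction, n_iter=50)
            finals.append(
                trace.genome_sizes[-1] if trace.genome_sizes else layout.genome_length
            )
        assert finals[0] <= finals[1] <= finals[2]

    def test_full_growth_floor_spares_growth_coupled_genes(self, chain_model):
        model, truth = chain_model
        layout = random_layout(7, model)
        trace = iterate_reduction(layout, model, 1.0, n_iter=50)
        silenced = {g for s in trace.segments for g in s.silenced_genes}
        # every model gene whose loss reduces growth must survive
        for gid, essential in truth.items():
            if essential:
                assert gid not in silenced


class TestGeneSetComparison:
    def test_reference_equal_to_retained_set(self):
        retained = {"a", "b"}
        report = compare_gene_sets(retained, {"c"}, {"self": set(retained)})
        row = report.iloc[0]
        assert row["retained_in_reference"] == 2
        assert row["deleted_in_reference"] == 0
        assert row["reference_only"] == 0

    def test_disjoint_reference(self):
        report = compare_gene_sets({"a"}, {"b"}, {"other": {"x", "y"}})
        row = report.iloc[0]
        assert row["retained_in_reference"] == 0
        assert row["deleted_in_reference"] == 0
        assert row["reference_only"] == 2

    def test_category_breakdown_rows(self):
        report = compare_gene_sets(
            {"a"}, {"b"}, {"ref": {"a", "b"}}, categories={"a": "cat1", "b": "cat2"}
        )
        assert set(report["category"]) == {"(all)", "cat1", "cat2"}


class TestLayoutPersistence:
    def test_tsv_round_trip_identical(self, tmp_path, chain_model):
        model, _ = chain_model
        layout = make_toy_layout(model, SyntheticScenario(seed=2))
        paths = [tmp_path / n for n in ("g.tsv", "p.tsv", "t.tsv")]
        write_layout(layout, *paths)
        loaded = read_layout(*paths)
        assert loaded == layout

    def test_every_model_gene_appears_once(self, chain_model):
        model, _ = chain_model
        layout = make_toy_layout(model, SyntheticScenario(seed=2))
        placed = [g.id for g in layout.genes if g.model_gene]
        assert sorted(placed) == sorted(g.id for g in model.genes)
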