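"""Expression thresholds, confusion matrices, essentiality revision, screen."""

import numpy as np
import pandas as pd
import pytest

from minigem.biomass import mcc
from minigem.model import active_genes, pfba
from minigem.synth import (
    SyntheticScenario,
    make_toy_layout,
    make_toy_model,
    simulate_omics,
    simulate_tnseq,
)
from minigem.validate import (
    EssentialityCall,
    TnMutantTable,
    carbohydrate_screen,
    essentiality_confusion,
    expression_calls,
    flux_expression_confusion,
    optimal_thresholds,
    revise_essentiality,
    viability_threshold,
)

from _oracles import brute_force_thresholds


class TestOptimalThresholds:
    def test_planted_thresholds_recovered_with_perfect_mcc(self):
        scenario = SyntheticScenario(seed=4, discordant_fraction=0.0)
        genes = [f"g{i:03d}" for i in range(40)]
        omics, truth = simulate_omics(scenario, genes)
        pair = optimal_thresholds(omics)
        assert pair.mcc == pytest.approx(1.0, abs=1e-12)
        assert pair.rna_threshold == pytest.approx(scenario.rna_threshold)
        assert pair.protein_threshold == pytest.approx(scenario.protein_threshold)
        calls = expression_calls(omics, pair)
        assert {g: v for g, v in calls.items()} == truth

    def test_two_concordant_genes_pick_separating_pair(self):
        omics = pd.DataFrame(
            {
                "gene": ["a", "b"],
                "fpkm": [10.0, 100.0],
                "proteins_per_cell": [1.0, 50.0],
            }
        )
        pair = optimal_thresholds(omics)
        # calling both genes expressed has a degenerate margin (MCC 0), so
        # the unique separating pair wins with MCC 1
        assert pair.rna_threshold == 100.0
        assert pair.protein_threshold == 50.0
        assert pair.mcc == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        omics = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(n)],
                "fpkm": rng.lognormal(4.0, 1.5, n).round(1),
                "proteins_per_cell": rng.lognormal(2.5, 1.2, n).round(1),
            }
        )
        pair = optimal_thresholds(omics)
        p, r, score = brute_force_thresholds(
            omics["fpkm"].to_numpy(), omics["proteins_per_cell"].to_numpy()
        )
        assert pair.score == pytest.approx(score, abs=1e-9)
        assert (pair.protein_threshold, pair.rna_threshold) == (p, r)

    def test_degenerate_dataset_rejected(self):
        omics = pd.DataFrame(
            {"gene": ["a", "b"], "fpkm": [0.0, 0.0], "proteins_per_cell": [1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="distinct"):
            optimal_thresholds(omics)


class TestFluxExpressionConfusion:
    def test_all_four_combinations(self):
        counts = flux_expression_confusion(
            active_genes={"g1", "g2"},
            expression={"g1": True, "g2": False, "g3": True, "g4": False},
        )
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (1, 1, 1, 1)
        assert counts.accuracy == pytest.approx(50.0)

    def test_perfect_agreement(self):
        counts = flux_expression_confusion(
            active_genes={"g1"}, expression={"g1": True, "g2": False}
        )
        assert counts.accuracy == pytest.approx(100.0)

    def test_empty_expression_rejected(self):
        with pytest.raises(ValueError, match="no genes"):
            flux_expression_confusion(set(), {})

    def test_toy_model_active_genes_feed_confusion(self, chain_model):
        model, _ = chain_model
        state = pfba(model)
        active = active_genes(model, state)
        # every gene on the flux-carrying path is active
        assert {"g000", "g001", "g002"} <= active
        counts = flux_expression_confusion(
            active, {g: True for g in sorted(active)}
        )
        assert counts.accuracy == pytest.approx(100.0)


def tn_table(insertions, growth=None):
    return TnMutantTable(
        insertions=pd.DataFrame(
            insertions, columns=["gene", "position_fraction", "mutant_id"]
        ),
        growth=pd.DataFrame(
            growth or [], columns=["mutant_id", "doubling_time", "sd"]
        ),
    )


class TestReviseEssentiality:
    def test_never_hit_gene_is_essential(self):
        calls = revise_essentiality(tn_table([]), genes=["gA"])
        assert calls["gA"].essential
        assert calls["gA"].label == "likely essential"

    def test_terminal_only_hits_keep_gene_essential(self):
        calls = revise_essentiality(tn_table([("gA", 0.95, "m1")]))
        assert calls["gA"].essential

    def test_boundary_of_terminal_region(self):
        # position 0.80 sits in the last 20% of the gene (terminal), while
        # 0.79 is internal and disproves essentiality
        assert revise_essentiality(tn_table([("gA", 0.80, "m1")]))["gA"].essential
        assert not revise_essentiality(tn_table([("gA", 0.79, "m1")]))["gA"].essential

    def test_internal_viable_hit_is_non_essential(self):
        calls = revise_essentiality(
            tn_table([("gA", 0.5, "m1")], [("m1", 1.0, 0.05)])
        )
        assert not calls["gA"].essential
        assert calls["gA"].label == "likely non-essential"

    def test_median_plus_mad_cohort(self):
        # doubling times {1.0 x8, 3.0 x2}: median 1.0, MAD 0 -> the 3.0 h
        # mutants are non-viable, so genes hit only by them stay essential
        growth = [(f"m{i}", 1.0, 0.05) for i in range(8)]
        growth += [("s0", 3.0, 0.05), ("s1", 3.0, 0.05)]
        insertions = [(f"gv{i}", 0.5, f"m{i}") for i in range(8)]
        insertions += [("gn0", 0.5, "s0"), ("gn1", 0.4, "s1")]
        cutoff = viability_threshold(np.array([1.0] * 8 + [3.0] * 2))
        assert cutoff == pytest.approx(1.0)
        calls = revise_essentiality(tn_table(insertions, growth))
        for i in range(8):
            assert not calls[f"gv{i}"].essential
        assert calls["gn0"].essential
        assert calls["gn1"].essential

    def test_unreliable_sd_mutants_are_filtered(self):
        # the noisy mutant (sd 50% of mean) must not enter the cohort: with
        # it, the 3.0 h mutant would sit below median+MAD and flip viable
        growth = [(f"m{i}", 1.0, 0.05) for i in range(4)]
        growth += [("noisy", 9.0, 4.5), ("slow", 3.0, 0.05)]
        insertions = [("gA", 0.5, "slow")]
        calls = revise_essentiality(tn_table(insertions, growth))
        assert calls["gA"].essential

    def test_internal_hit_without_growth_data_defaults_non_essential(self):
        calls = revise_essentiality(tn_table([("gA", 0.5, "unknown")]))
        assert not calls["gA"].essential
        assert calls["gA"].label == "putative non-essential"

    def test_adding_internal_viable_insertion_is_monotone(self):
        base = tn_table([("gA", 0.95, "m1")], [("m1", 1.0, 0.05)])
        assert revise_essentiality(base)["gA"].essential
        more = tn_table(
            [("gA", 0.95, "m1"), ("gA", 0.4, "m2")],
            [("m1", 1.0, 0.05), ("m2", 1.0, 0.05)],
        )
        assert not revise_essentiality(more)["gA"].essential

    def test_planted_sets_recovered_from_synthetic_cohort(self):
        scenario = SyntheticScenario(seed=13)
        model, truth = make_toy_model(10, "chain", seed=1)
        layout = make_toy_layout(model, scenario, extra_genes=8)
        essential = dict(truth)
        for g in layout.genes:
            essential.setdefault(g.id, g.id.endswith(("0", "3")))
        tn, planted = simulate_tnseq(layout, essential, scenario)
        calls = revise_essentiality(tn, genes=[g.id for g in layout.genes])
        recovered = {g: calls[g].essential for g in planted}
        assert recovered == planted


class TestEssentialityConfusion:
    def test_perfect_agreement(self):
        predicted = {"a": True, "b": False}
        observed = {"a": True, "b": False}
        counts, triage = essentiality_confusion(predicted, observed)
        assert counts.accuracy == pytest.approx(100.0)
        assert triage == {"false_positive": [], "false_negative": []}

    def test_complement_predictions_on_balanced_set(self):
        observed = {"a": True, "b": True, "c": False, "d": False}
        predicted = {g: not v for g, v in observed.items()}
        counts, triage = essentiality_confusion(predicted, observed)
        assert counts.accuracy == pytest.approx(0.0)
        assert mcc(counts) == pytest.approx(-1.0)
        assert set(triage["false_positive"]) == {"c", "d"}
        assert set(triage["false_negative"]) == {"a", "b"}

    def test_accepts_revision_labels(self):
        observed = {
            "a": EssentialityCall("a", "likely essential"),
            "b": EssentialityCall("b", "putative non-essential"),
        }
        counts, _ = essentiality_confusion({"a": True, "b": False}, observed)
        assert counts.accuracy == pytest.approx(100.0)

    def test_disjoint_gene_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            essentiality_confusion({"a": True}, {"b": False})


class TestCarbohydrateScreen:
    def test_reference_normalizes_to_one_and_dead_end_to_zero(self, chain_model):
        model, _ = chain_model
        table = carbohydrate_screen(
            model,
            {"substrate": "EX_s_e", "dead_end": "EX_x_e"},
            reference="substrate",
        )
        by_sugar = dict(zip(table["sugar"], table["normalized_growth"]))
        assert by_sugar["substrate"] == pytest.approx(1.0)
        assert by_sugar["dead_end"] == pytest.approx(0.0, abs=1e-9)

    def test_phenotype_match_count(self, chain_model):
        model, _ = chain_model
        table = carbohydrate_screen(
            model,
            {"substrate": "EX_s_e", "dead_end": "EX_x_e"},
            reference="substrate",
            phenotypes={"substrate": True, "dead_end": True},
        )
        assert int(table["match"].sum()) == 1  # dead end contradicts phenotype

    def test_zero_growth_reference_rejected(self, chain_model):
        model, _ = chain_model
        with pytest.raises(ValueError, match="no growth"):
            carbohydrate_screen(
                model, {"dead_end": "EX_x_e", "s": "EX_s_e"}, reference="dead_end"
            )
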