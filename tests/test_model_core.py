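"""Model I/O, FBA/pFBA, deletions and minimal medium."""

import json

import numpy as np
import pytest
from cobra import Metabolite, Model, Reaction
from cobra.io import save_json_model

from minigem.model import (
    ModelValidationError,
    count_orphans,
    fba,
    minimal_medium,
    pfba,
    read_model_json,
    single_gene_deletions,
)
from minigem.synth import network_to_cobra, random_medium_model, random_network

from _oracles import dense_lp_fba, dense_lp_min_total_flux, enumerate_minimal_media


def linear_chain_model() -> Model:
    """EX_A(lb=-10) -> A -> B -> biomass with unit stoichiometry."""
    m = Model("chain_lp")
    a_e = Metabolite("a_e", compartment="e")
    a_c = Metabolite("a_c", compartment="c")
    b_c = Metabolite("b_c", compartment="c")
    ex = Reaction("EX_a_e", lower_bound=-10, upper_bound=1000)
    ex.add_metabolites({a_e: -1})
    t = Reaction("T_a", lower_bound=0, upper_bound=1000)
    t.add_metabolites({a_e: -1, a_c: 1})
    r = Reaction("R_ab", lower_bound=0, upper_bound=1000)
    r.add_metabolites({a_c: -1, b_c: 1})
    bio = Reaction("BIOMASS", lower_bound=0, upper_bound=1000)
    bio.add_metabolites({b_c: -1})
    m.add_reactions([ex, t, r, bio])
    m.objective = "BIOMASS"
    return m


class TestReadModelJson:
    def test_minimal_well_formed_model(self, tmp_path):
        m = Model("one")
        met = Metabolite("x_e", compartment="e")
        ex = Reaction("EX_x_e", lower_bound=-1, upper_bound=1)
        ex.add_metabolites({met: -1})
        m.add_reactions([ex])
        path = tmp_path / "one.json"
        save_json_model(m, str(path))
        loaded = read_model_json(path)
        assert len(loaded.reactions) == 1
        assert len(loaded.metabolites) == 1

    def test_round_trip_preserves_counts(self, tmp_path, chain_model):
        model, _ = chain_model
        path = tmp_path / "toy.json"
        save_json_model(model, str(path))
        loaded = read_model_json(path)
        assert len(loaded.reactions) == len(model.reactions)
        assert len(loaded.metabolites) == len(model.metabolites)
        assert {g.id for g in loaded.genes} == {g.id for g in model.genes}

    def test_dangling_metabolite_reference_rejected(self, tmp_path, chain_model):
        model, _ = chain_model
        path = tmp_path / "toy.json"
        save_json_model(model, str(path))
        payload = json.loads(path.read_text())
        payload["reactions"][0]["metabolites"]["ghost_c"] = -1.0
        bad = tmp_path / "bad.json"
        bad.write_text(json.dumps(payload))
        with pytest.raises(ModelValidationError, match="ghost_c"):
            read_model_json(bad)

    def test_malformed_json_rejected(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text("{not json")
        with pytest.raises(ModelValidationError, match="malformed"):
            read_model_json(path)

    def test_oversized_bounds_clamped(self, tmp_path, chain_model):
        model, _ = chain_model
        path = tmp_path / "toy.json"
        save_json_model(model, str(path))
        payload = json.loads(path.read_text())
        payload["reactions"][0]["upper_bound"] = 99999.0
        big = tmp_path / "big.json"
        big.write_text(json.dumps(payload))
        loaded = read_model_json(big)
        assert max(r.upper_bound for r in loaded.reactions) <= 1000.0


class TestOrphanCensus:
    def test_all_gene_associated_means_no_orphans(self):
        m = Model("allgpr")
        a = Metabolite("a_c", compartment="c")
        r1 = Reaction("R1", lower_bound=-10, upper_bound=10)
        r1.add_metabolites({a: 1})
        r1.gene_reaction_rule = "g1"
        r2 = Reaction("R2", lower_bound=0, upper_bound=10)
        r2.add_metabolites({a: -1})
        r2.gene_reaction_rule = "g2"
        m.add_reactions([r1, r2])
        census = count_orphans(m)
        assert census.orphan == 0
        assert census.gene_associated == 2

    def test_hand_counted_partition(self):
        # 2 exchanges + 1 biomass + 1 gene-bearing reaction: 3 orphans, all pseudo
        m = Model("census")
        a_e = Metabolite("a_e", compartment="e")
        b_e = Metabolite("b_e", compartment="e")
        a_c = Metabolite("a_c", compartment="c")
        ex_a = Reaction("EX_a_e", lower_bound=-10, upper_bound=10)
        ex_a.add_metabolites({a_e: -1})
        ex_b = Reaction("EX_b_e", lower_bound=-10, upper_bound=10)
        ex_b.add_metabolites({b_e: -1})
        t = Reaction("T_a", lower_bound=0, upper_bound=10)
        t.add_metabolites({a_e: -1, a_c: 1})
        t.gene_reaction_rule = "g1"
        bio = Reaction("BIOMASS_x", lower_bound=0, upper_bound=10)
        bio.add_metabolites({a_c: -1})
        m.add_reactions([ex_a, ex_b, t, bio])
        m.objective = "BIOMASS_x"
        census = count_orphans(m)
        assert census.total == 4
        assert census.gene_associated == 1
        assert census.orphan == 3
        assert census.orphan_pseudo == 3
        assert census.gene_associated + census.orphan == census.total

    def test_toy_model_census(self, chain_model):
        model, _ = chain_model
        census = count_orphans(model)
        # EX_s_e, EX_x_e, T_x, ATPM, BIOMASS lack GPRs; T_x is a necessary orphan
        assert census.orphan == 5
        assert census.orphan_pseudo == 4
        assert census.necessary_orphans == 1


class TestFBA:
    def test_linear_chain_analytic_optimum(self):
        state = fba(linear_chain_model())
        assert state.ok
        assert state.objective_value == pytest.approx(10.0, abs=1e-9)

    def test_closed_exchanges_mean_zero_growth(self):
        m = linear_chain_model()
        m.reactions.EX_a_e.lower_bound = 0.0
        state = fba(m)
        assert state.ok
        assert state.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_forced_flux_through_blocked_reaction_is_infeasible(self):
        m = linear_chain_model()
        m.reactions.EX_a_e.lower_bound = 0.0
        m.reactions.BIOMASS.lower_bound = 5.0
        state = fba(m)
        assert state.status == "infeasible"
        assert state.objective_value is None

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_dense_lp_oracle_on_random_networks(self, seed):
        S, lb, ub, obj = random_network(8, seed=seed)
        model = network_to_cobra(S, lb, ub, obj)
        state = fba(model)
        oracle = dense_lp_fba(S, lb, ub, obj)
        assert state.ok and oracle is not None
        assert state.objective_value == pytest.approx(oracle, abs=1e-6)
        # steady state and bounds invariants on the returned vertex
        v = np.array([state.fluxes[f"r{j}"] for j in range(S.shape[1])])
        assert np.max(np.abs(S @ v)) <= 1e-6
        assert np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9)


class TestPFBA:
    def test_unique_path_equals_fba(self):
        m = linear_chain_model()
        plain = fba(m)
        parsim = pfba(m)
        assert parsim.objective_value == pytest.approx(plain.objective_value, abs=1e-6)
        for rid, flux in plain.fluxes.items():
            assert parsim.fluxes[rid] == pytest.approx(flux, abs=1e-6)

    def test_parallel_paths_cost_one_routing(self):
        # diamond: A -> B via two parallel unit reactions; total |flux| must
        # equal the single-path routing total regardless of the split
        m = linear_chain_model()
        a = m.metabolites.get_by_id("a_c")
        b = m.metabolites.get_by_id("b_c")
        alt = Reaction("R_ab_alt", lower_bound=0, upper_bound=1000)
        alt.add_metabolites({a: -1, b: 1})
        m.add_reactions([alt])
        single_total = pfba(linear_chain_model()).total_flux()
        state = pfba(m)
        assert state.total_flux() == pytest.approx(single_total, abs=1e-6)

    def test_futile_cycle_carries_no_flux(self):
        m = linear_chain_model()
        b = m.metabolites.get_by_id("b_c")
        c = Metabolite("c_c", compartment="c")
        fwd = Reaction("CYC_f", lower_bound=0, upper_bound=1000)
        fwd.add_metabolites({b: -1, c: 1})
        rev = Reaction("CYC_r", lower_bound=0, upper_bound=1000)
        rev.add_metabolites({c: -1, b: 1})
        m.add_reactions([fwd, rev])
        state = pfba(m)
        assert abs(state.fluxes["CYC_f"]) <= 1e-8
        assert abs(state.fluxes["CYC_r"]) <= 1e-8

    @pytest.mark.parametrize("seed", range(10))
    def test_total_flux_minimal_against_lp_oracle(self, seed):
        S, lb, ub, obj = random_network(8, seed=seed)
        model = network_to_cobra(S, lb, ub, obj)
        state = pfba(model)
        assert state.ok
        oracle = dense_lp_min_total_flux(S, lb, ub, obj, state.objective_value)
        assert oracle is not None
        assert state.total_flux() == pytest.approx(oracle, abs=1e-5)


class TestGeneDeletions:
    def test_construction_truth_recovered(self, chain_model):
        model, truth = chain_model
        calls = single_gene_deletions(model)
        assert {g: essential for g, (_, essential) in calls.items()} == truth

    def test_isozyme_pair_individually_dispensable(self, chain_model):
        model, _ = chain_model
        calls = single_gene_deletions(model, genes=["g003", "g004"])
        assert not calls["g003"][1]
        assert not calls["g004"][1]

    def test_unused_gene_does_not_change_objective(self, chain_model):
        model, _ = chain_model
        model = model.copy()
        baseline = model.slim_optimize()
        spare = Reaction("R_spare", lower_bound=0, upper_bound=0)
        spare.add_metabolites({model.metabolites.get_by_id("b_c"): -1})
        spare.gene_reaction_rule = "g_unused"
        model.add_reactions([spare])
        calls = single_gene_deletions(model, genes=["g_unused"])
        assert calls["g_unused"][0] == pytest.approx(baseline, abs=1e-9)
        assert not calls["g_unused"][1]


class TestMinimalMedium:
    def test_single_carbon_source(self, chain_model):
        model, _ = chain_model
        assert minimal_medium(model, 1.0) == {"EX_s_e"}

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration(self, seed):
        model, optimum = random_medium_model(seed)
        assert optimum > 0
        target = 0.5 * optimum
        chosen = minimal_medium(model, target)
        winners = enumerate_minimal_media(model, target)
        sizes = {len(w) for w in winners}
        assert len(chosen) == min(sizes)
        assert frozenset(chosen) in winners

    def test_unreachable_growth_raises(self, chain_model):
        model, _ = chain_model
        with pytest.raises(ValueError, match="attainable"):
            minimal_medium(model, 1e6)
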