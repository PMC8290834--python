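"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is fully determined by an integer seed and emits its
ground truth alongside the data, so recovery tests can assert against the
planted values. Defaults mirror the study conditions of a fast-growing
Mollicute in semi-defined medium: maximal growth rate 0.44 1/h, maximal
sucrose-specific uptake 5.26 mmol/gDW/h, combined fermentation-product
secretion 8.69 mmol/gDW/h, per-cell dry mass 2.18e-14 g, expression
thresholds of 168 FPKM and 23 protein molecules per cell, and a biomass
carrying capacity of 5.95e8 CFU/ml.

Noise models: multiplicative lognormal for counts and concentrations,
truncated normal for doubling times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from cobra import Metabolite, Model, Reaction

from .kinetics import CELL_DRY_MASS_G, TimeSeries, cfu_to_gdw
from .reduction import Gene, GenomeLayout, Promoter, TranscriptionUnit

__all__ = [
    "SyntheticScenario",
    "GrowthTruth",
    "make_toy_model",
    "random_network",
    "random_medium_model",
    "simulate_growth_experiment",
    "simulate_omics",
    "simulate_tnseq",
    "make_toy_layout",
]


@dataclass
class SyntheticScenario:
    """Knobs and planted truths shared by the generators."""

    seed: int = 0
    n_genes: int = 30
    genome_length: int = 40000
    essential_fraction: float = 0.4
    expressed_fraction: float = 0.6
    rna_threshold: float = 168.0
    protein_threshold: float = 23.0
    discordant_fraction: float = 0.0
    growth_rate: float = 0.44
    qS: float = 5.26
    product_yield: float = 8.69 / 5.26
    cell_dry_mass: float = CELL_DRY_MASS_G
    initial_cfu: float = 1e5
    carrying_capacity_cfu: float = 5.95e8
    cfu_noise: float = 0.0
    conc_noise: float = 0.0
    doubling_time_noise: float = 0.0
    unreliable_sd_fraction: float = 0.1

    def __post_init__(self) -> None:
        for name in ("essential_fraction", "expressed_fraction", "discordant_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


# ---------------------------------------------------------------------------
# metabolic models


def make_toy_model(
    n_genes: int = 8, topology: str = "chain", seed: int = 0
) -> tuple[Model, dict[str, bool]]:
    """Feasible toy model with a known-by-construction essential set.

    A substrate is imported (transport gated by a two-gene complex),
    converted through a linear chain that also generates ATP, and drained
    by a biomass reaction with an ATP-maintenance term. One conversion is
    catalyzed by an isozyme pair (chain topology: one reaction with an OR
    rule; branched: two parallel reactions), so those genes are
    individually dispensable while every other gene is essential.

    Returns the model and the gene -> essential truth map.
    """
    if n_genes < 6:
        raise ValueError("need at least 6 genes for the toy topology")
    if topology not in ("chain", "branched"):
        raise ValueError(f"unknown topology {topology!r}")
    model = Model(f"toy_{topology}_{n_genes}_{seed}")
    genes = [f"g{i:03d}" for i in range(n_genes)]

    def met(mid: str, compartment: str = "c") -> Metabolite:
        return Metabolite(mid, compartment=compartment)

    s_e, s_c = met("s_e", "e"), met("s_c")
    atp, adp, pi = met("atp_c"), met("adp_c"), met("pi_c")
    reactions = []

    ex = Reaction("EX_s_e", lower_bound=-10.0, upper_bound=1000.0)
    ex.add_metabolites({s_e: -1})
    reactions.append(ex)

    # alternative sugar with no catabolic route (negative screen control)
    x_e, x_c = met("x_e", "e"), met("x_c")
    ex_x = Reaction("EX_x_e", lower_bound=0.0, upper_bound=1000.0)
    ex_x.add_metabolites({x_e: -1})
    t_x = Reaction("T_x", lower_bound=0.0, upper_bound=1000.0)
    t_x.add_metabolites({x_e: -1, x_c: 1})
    reactions += [ex_x, t_x]

    t1 = Reaction("T_s", lower_bound=0.0, upper_bound=1000.0)
    t1.add_metabolites({s_e: -1, s_c: 1})
    t1.gene_reaction_rule = f"{genes[0]} and {genes[1]}"
    reactions.append(t1)

    # energy branch: substrate can be burned for ATP (2 per substrate) ...
    r1 = Reaction("R_atp", lower_bound=0.0, upper_bound=1000.0)
    r1.add_metabolites({s_c: -1, adp: -2, pi: -2, atp: 2})
    r1.gene_reaction_rule = genes[2]
    reactions.append(r1)

    # ... or routed into the biomass-precursor branch, so growth responds
    # continuously to maintenance costs instead of stepping
    b = met("b_c")
    if topology == "chain":
        r2 = Reaction("R_iso", lower_bound=0.0, upper_bound=1000.0)
        r2.add_metabolites({s_c: -1, b: 1})
        r2.gene_reaction_rule = f"{genes[3]} or {genes[4]}"
        reactions.append(r2)
    else:
        for k, gid in enumerate((genes[3], genes[4])):
            rk = Reaction(f"R_par{k}", lower_bound=0.0, upper_bound=1000.0)
            rk.add_metabolites({s_c: -1, b: 1})
            rk.gene_reaction_rule = gid
            reactions.append(rk)

    # remaining genes form a linear chain of singly-catalyzed conversions
    prev = b
    for i, gid in enumerate(genes[5:]):
        nxt = met(f"c{i:02d}_c")
        rx = Reaction(f"R_chain{i:02d}", lower_bound=0.0, upper_bound=1000.0)
        rx.add_metabolites({prev: -1, nxt: 1})
        rx.gene_reaction_rule = gid
        reactions.append(rx)
        prev = nxt

    atpm = Reaction("ATPM", lower_bound=0.0, upper_bound=1000.0)
    atpm.add_metabolites({atp: -1, adp: 1, pi: 1})
    reactions.append(atpm)

    biomass = Reaction("BIOMASS", lower_bound=0.0, upper_bound=1000.0)
    biomass.add_metabolites({prev: -1, atp: -2, adp: 2, pi: 2})
    reactions.append(biomass)

    model.add_reactions(reactions)
    model.objective = "BIOMASS"

    truth = {gid: True for gid in genes}
    truth[genes[3]] = truth[genes[4]] = False  # isozymes / parallel paths
    return model, truth


def make_fermentation_model() -> Model:
    """Toy fermenting cell with lactate/acetate secretion and an O2 branch.

    Glycolysis converts substrate to two pyruvate plus 2 ATP and 2 NADH;
    pyruvate leaves as lactate or acetate (each re-oxidizing one NADH), and
    an NADH oxidase can spend oxygen instead. A separate precursor branch
    feeds biomass. Growth is ATP-limited at
    ``(lactate + acetate - NGAM) / GAM`` when forced secretions fix the
    glycolytic flux, which gives every calibration stage a well-defined
    response.
    """
    model = Model("fermentation_toy")

    def met(mid: str, comp: str = "c") -> Metabolite:
        return Metabolite(mid, compartment=comp)

    s_e, s_c = met("s_e", "e"), met("s_c")
    atp, adp, pi = met("atp_c"), met("adp_c"), met("pi_c")
    nad, nadh = met("nad_c"), met("nadh_c")
    pyr = met("pyr_c")
    lac_c, lac_e = met("lac_c"), met("lac_e", "e")
    ac_c, ac_e = met("ac_c"), met("ac_e", "e")
    o2_e, o2_c = met("o2_e", "e"), met("o2_c")
    prev = met("prec_c")

    def rxn(rid, stoich, lb=0.0, ub=1000.0, gpr=""):
        r = Reaction(rid, lower_bound=lb, upper_bound=ub)
        r.add_metabolites(stoich)
        if gpr:
            r.gene_reaction_rule = gpr
        return r

    reactions = [
        rxn("EX_s_e", {s_e: -1}, lb=-10.0),
        rxn("T_s", {s_e: -1, s_c: 1}, gpr="gT"),
        rxn(
            "GLYC",
            {s_c: -1, adp: -2, pi: -2, nad: -2, pyr: 2, atp: 2, nadh: 2},
            gpr="gG",
        ),
        rxn("LDH", {pyr: -1, nadh: -1, lac_c: 1, nad: 1}, gpr="gL"),
        rxn("ACE", {pyr: -1, nadh: -1, ac_c: 1, nad: 1}, gpr="gA"),
        rxn("NOX2", {nadh: -1, o2_c: -0.5, nad: 1}),
        rxn("T_lac", {lac_c: -1, lac_e: 1}),
        rxn("T_ac", {ac_c: -1, ac_e: 1}),
        rxn("T_o2", {o2_e: -1, o2_c: 1}),
        rxn("EX_lac_e", {lac_e: -1}),
        rxn("EX_ac_e", {ac_e: -1}),
        rxn("EX_o2_e", {o2_e: -1}, lb=-10.0),
        rxn("PREV", {s_c: -1, prev: 1}, gpr="gP"),
        rxn("ATPM", {atp: -1, adp: 1, pi: 1}),
        rxn("BIOMASS", {prev: -1, atp: -2, adp: 2, pi: 2}),
    ]
    model.add_reactions(reactions)
    model.objective = "BIOMASS"
    return model


def random_network(
    n_reactions: int = 8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Random dense stoichiometric LP instance.

    Returns ``(S, lb, ub, objective_column)`` with finite bounds, suitable
    both for building a cobra model and for an independent dense-LP solve.
    The first two columns are boundary reactions (single metabolite) so
    mass can enter and leave.
    """
    rng = np.random.default_rng(seed)
    n_mets = max(2, n_reactions - 3)
    S = np.zeros((n_mets, n_reactions))
    S[0, 0] = 1.0  # inflow
    S[n_mets - 1, 1] = -1.0  # outflow
    for j in range(2, n_reactions):
        consumed = rng.integers(0, n_mets - 1)
        produced = rng.integers(consumed + 1, n_mets)
        S[consumed, j] = -float(rng.integers(1, 3))
        S[produced, j] = float(rng.integers(1, 3))
        if n_mets > 2 and rng.random() < 0.3:
            other = rng.integers(0, n_mets)
            if S[other, j] == 0:
                S[other, j] = float(rng.choice([-1.0, 1.0]))
    lb = np.where(rng.random(n_reactions) < 0.3, -10.0, 0.0)
    ub = np.full(n_reactions, 10.0)
    lb[0], ub[0] = 0.0, 10.0
    lb[1], ub[1] = 0.0, 10.0
    return S, lb, ub, 1


def network_to_cobra(
    S: np.ndarray, lb: np.ndarray, ub: np.ndarray, objective: int
) -> Model:
    """Materialize a dense stoichiometric instance as a cobra model."""
    n_mets, n_rxns = S.shape
    model = Model("random_network")
    mets = [Metabolite(f"m{i}", compartment="c") for i in range(n_mets)]
    rxns = []
    for j in range(n_rxns):
        rxn = Reaction(f"r{j}", lower_bound=float(lb[j]), upper_bound=float(ub[j]))
        rxn.add_metabolites(
            {mets[i]: float(S[i, j]) for i in range(n_mets) if S[i, j] != 0}
        )
        rxns.append(rxn)
    model.add_reactions(rxns)
    model.objective = f"r{objective}"
    return model


def random_medium_model(seed: int = 0) -> tuple[Model, float]:
    """Model with 3-6 exchanges, some redundant, for minimal-medium tests.

    Returns the model and its fully-open FBA optimum. Each exchange feeds a
    nutrient; a random subset of nutrients is individually convertible to
    the biomass precursor (redundant carbon sources) while the rest are
    jointly required cofactor-style inputs.
    """
    rng = np.random.default_rng(seed)
    n_exchanges = int(rng.integers(3, 7))
    n_redundant = int(rng.integers(1, max(2, n_exchanges - 1)))
    model = Model(f"medium_{seed}")
    precursor = Metabolite("prec_c", compartment="c")
    reactions = []
    required_mets = []
    for i in range(n_exchanges):
        ext = Metabolite(f"n{i}_e", compartment="e")
        cyt = Metabolite(f"n{i}_c", compartment="c")
        ex = Reaction(f"EX_n{i}_e", lower_bound=-10.0, upper_bound=1000.0)
        ex.add_metabolites({ext: -1})
        tr = Reaction(f"T_n{i}", lower_bound=0.0, upper_bound=1000.0)
        tr.add_metabolites({ext: -1, cyt: 1})
        reactions += [ex, tr]
        if i < n_redundant:
            conv = Reaction(f"C_n{i}", lower_bound=0.0, upper_bound=1000.0)
            conv.add_metabolites({cyt: -1, precursor: 1})
            reactions.append(conv)
        else:
            required_mets.append(cyt)
    biomass = Reaction("BIOMASS", lower_bound=0.0, upper_bound=1000.0)
    stoich = {precursor: -1.0}
    for met in required_mets:
        stoich[met] = -0.1
    biomass.add_metabolites(stoich)
    reactions.append(biomass)
    model.add_reactions(reactions)
    model.objective = "BIOMASS"
    return model, float(model.slim_optimize())


# ---------------------------------------------------------------------------
# growth experiments


@dataclass
class GrowthTruth:
    """Planted kinetic parameters of one simulated culture."""

    growth_rate: float
    qS: float
    product_yield: float
    initial_substrate_mmol_l: float
    cell_dry_mass: float


def simulate_growth_experiment(
    scenario: SyntheticScenario,
    initial_substrate_mmol_l: float = 2.92,
    times: Sequence[float] | None = None,
) -> tuple[dict[str, TimeSeries], GrowthTruth]:
    """Exponential culture with substrate uptake and product secretion.

    Biomass grows at the planted rate up to a carrying capacity; substrate
    falls according to the planted constant specific uptake rate
    (dS/dt = -qS X) and the combined product mirrors consumption at the
    planted yield. Lognormal noise is applied per observation when the
    scenario's noise scales are non-zero.
    """
    times = np.asarray(
        times if times is not None else np.arange(0.0, 18.5, 1.0), dtype=float
    )
    rng = scenario.rng(1)
    r = scenario.growth_rate
    cfu = scenario.initial_cfu * np.exp(r * times)
    cfu = np.minimum(cfu, scenario.carrying_capacity_cfu)
    x = np.array([cfu_to_gdw(c, scenario.cell_dry_mass) for c in cfu])
    x0 = x[0]
    # S(t) = S0 - qS/r * (X(t) - X0), exact integral of dS/dt = -qS X
    substrate = initial_substrate_mmol_l - scenario.qS / r * (x - x0)
    substrate = np.maximum(substrate, 0.0)
    product = scenario.product_yield * (initial_substrate_mmol_l - substrate)

    if scenario.cfu_noise > 0:
        cfu = cfu * rng.lognormal(0.0, scenario.cfu_noise, size=cfu.size)
    if scenario.conc_noise > 0:
        substrate = substrate * rng.lognormal(0.0, scenario.conc_noise, size=times.size)
        product = product * rng.lognormal(0.0, scenario.conc_noise, size=times.size)

    bundle = {
        "cfu_per_ml": TimeSeries(times, cfu, "CFU/ml"),
        "substrate_mmol_l": TimeSeries(times, substrate, "substrate (mmol/l)"),
        "product_mmol_l": TimeSeries(times, product, "combined products (mmol/l)"),
    }
    truth = GrowthTruth(
        growth_rate=r,
        qS=scenario.qS,
        product_yield=scenario.product_yield,
        initial_substrate_mmol_l=float(initial_substrate_mmol_l),
        cell_dry_mass=scenario.cell_dry_mass,
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# omics


def simulate_omics(
    scenario: SyntheticScenario, genes: Sequence[str]
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Bimodal expressed/silent abundance table with planted thresholds.

    Expressed genes draw both abundances at or above the planted
    thresholds (the first expressed gene sits exactly on them so the
    threshold value occurs in the data); silent genes draw strictly below.
    A ``discordant_fraction`` of genes has its protein call flipped.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("no genes supplied")
    rng = scenario.rng(2)
    n = len(genes)
    n_expressed = int(round(n * scenario.expressed_fraction))
    order = rng.permutation(n)
    expressed_idx = set(order[:n_expressed].tolist())

    rna = np.empty(n)
    prot = np.empty(n)
    truth: dict[str, bool] = {}
    first_expressed = True
    silent_indices = [i for i in range(n) if i not in expressed_idx]
    # silent abundances are assigned with reversed rank orders between the
    # two datasets: lowering both thresholds to admit silent genes then
    # always produces discordant calls, so the planted pair is the unique
    # optimum of the X * MCC score at zero discordance
    k = len(silent_indices)
    silent_rna = np.sort(rng.uniform(-2.0, -0.1, size=k))
    silent_prot = np.sort(rng.uniform(-2.0, -0.1, size=k))[::-1]
    for idx, i in enumerate(silent_indices):
        rna[i] = scenario.rna_threshold * 10 ** silent_rna[idx]
        prot[i] = scenario.protein_threshold * 10 ** silent_prot[idx]
    for i, gene in enumerate(genes):
        on = i in expressed_idx
        truth[gene] = on
        if on and first_expressed:
            rna[i] = scenario.rna_threshold
            prot[i] = scenario.protein_threshold
            first_expressed = False
        elif on:
            rna[i] = scenario.rna_threshold * 10 ** rng.uniform(0.05, 1.5)
            prot[i] = scenario.protein_threshold * 10 ** rng.uniform(0.05, 1.5)
    if scenario.discordant_fraction > 0:
        n_flip = int(round(n * scenario.discordant_fraction))
        for i in rng.permutation(n)[:n_flip]:
            if prot[i] >= scenario.protein_threshold:
                prot[i] = scenario.protein_threshold * 10 ** rng.uniform(-2.0, -0.1)
            else:
                prot[i] = scenario.protein_threshold * 10 ** rng.uniform(0.05, 1.5)
    table = pd.DataFrame(
        {"gene": genes, "fpkm": rna, "proteins_per_cell": prot}
    )
    return table, truth


# ---------------------------------------------------------------------------
# annotation evidence

_PROTEOME_PATTERNS: dict[int, tuple[str | None, dict[str, str]]] = {
    3: ("eno", {"sp1": "eno", "sp2": "eno"}),
    2: ("pgiC", {"sp1": "pgiA", "sp2": "pgiB"}),
    1: ("abc", {"sp1": "xyz"}),
    0: (None, {}),
}
_EC_PATTERNS: dict[int, dict[str, str]] = {
    3: {"RefSeq": "4.2.1.11", "DETECT": "4.2.1.11"},
    2: {"DETECT": "2.7.1.1", "PATRIC": "2.7.1.4"},
    1: {"RefSeq": "1.1.1.1", "PATRIC": "2.2.2.2"},
    0: {"COFACTOR": "1.1.1.1"},
}


def simulate_evidence(
    scenario: SyntheticScenario, genes: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wide evidence table with planted per-component annotation scores.

    Each gene draws a proteome score in 0-3, a structure score in {0, 3}
    and an EC score in 0-3, then receives evidence constructed to yield
    exactly those component scores. Returns the evidence table and the
    planted truth (gene, proteome_score, structure_score, ec_score).
    """
    rng = scenario.rng(5)
    rows = []
    truth_rows = []
    for gene in genes:
        p = int(rng.integers(0, 4))
        s = int(rng.choice([0, 3]))
        e = int(rng.integers(0, 4))
        focal, orthologs = _PROTEOME_PATTERNS[p]
        row: dict[str, object] = {"gene": gene, "name": focal}
        for sp, nm in orthologs.items():
            row[f"name_{sp}"] = nm
        for method, ec in _EC_PATTERNS[e].items():
            row[f"ec_{method}"] = ec
        if s == 3:
            row.update(
                e_value=1e-10,
                domain_identity=0.4,
                domain_similarity=0.6,
                is_transmembrane=False,
                c_score=1.2,
                tm_score=0.8,
            )
        rows.append(row)
        truth_rows.append(
            {"gene": gene, "proteome_score": p, "structure_score": s, "ec_score": e}
        )
    evidence = pd.DataFrame(rows)
    return evidence, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# transposon mutagenesis


def simulate_tnseq(
    layout: GenomeLayout,
    essential: Mapping[str, bool],
    scenario: SyntheticScenario,
) -> tuple["TnMutantTable", dict[str, bool]]:
    """Insertion table with planted essential genes.

    Essential genes receive, in rotation, no insertion, terminal-only
    insertions, or internal insertions whose mutants are non-viable
    (doubling time triple the cohort base, far above median + MAD).
    Non-essential genes receive internal insertions with viable mutants. A
    fraction of extra duplicate mutants gets an unreliable SD (above 30%
    of the mean) and must be filtered before thresholding.
    """
    from .validate import TnMutantTable  # local import to avoid a cycle

    rng = scenario.rng(3)
    base_dt = float(np.log(2.0) / scenario.growth_rate)
    ins_rows = []
    growth_rows = []
    mutant_counter = 0

    def new_mutant(doubling: float, reliable: bool) -> str:
        nonlocal mutant_counter
        mutant_counter += 1
        mid = f"mut{mutant_counter:04d}"
        noise = rng.normal(0.0, scenario.doubling_time_noise * doubling)
        dt = max(doubling + noise, 0.05)
        sd = (
            abs(rng.normal(0.05, 0.02)) * dt
            if reliable
            else (0.35 + abs(rng.normal(0.1, 0.05))) * dt
        )
        growth_rows.append({"mutant_id": mid, "doubling_time": dt, "sd": sd})
        return mid

    mode = 0
    for gene in layout.genes:
        if essential.get(gene.id, False):
            if mode == 0:
                pass  # never hit
            elif mode == 1:
                for _ in range(int(rng.integers(1, 3))):
                    ins_rows.append(
                        {
                            "gene": gene.id,
                            "position_fraction": float(rng.uniform(0.85, 0.99)),
                            "mutant_id": new_mutant(base_dt, reliable=True),
                        }
                    )
            else:
                ins_rows.append(
                    {
                        "gene": gene.id,
                        "position_fraction": float(rng.uniform(0.1, 0.7)),
                        "mutant_id": new_mutant(3.0 * base_dt, reliable=True),
                    }
                )
            mode = (mode + 1) % 3
        else:
            for _ in range(int(rng.integers(1, 4))):
                ins_rows.append(
                    {
                        "gene": gene.id,
                        "position_fraction": float(rng.uniform(0.05, 0.75)),
                        "mutant_id": new_mutant(base_dt, reliable=True),
                    }
                )
            if rng.random() < scenario.unreliable_sd_fraction:
                # duplicate unreliable measurement; filtered downstream
                ins_rows.append(
                    {
                        "gene": gene.id,
                        "position_fraction": float(rng.uniform(0.05, 0.75)),
                        "mutant_id": new_mutant(base_dt, reliable=False),
                    }
                )
    table = TnMutantTable(
        insertions=pd.DataFrame(
            ins_rows, columns=["gene", "position_fraction", "mutant_id"]
        ),
        growth=pd.DataFrame(
            growth_rows, columns=["mutant_id", "doubling_time", "sd"]
        ),
    )
    truth = {g.id: bool(essential.get(g.id, False)) for g in layout.genes}
    return table, truth


# ---------------------------------------------------------------------------
# genome layout


def make_toy_layout(
    model, scenario: SyntheticScenario, extra_genes: int = 4
) -> GenomeLayout:
    """Place model genes (plus non-coding extras) on a toy genome.

    Genes are laid out left to right without overlap, separated by
    intergenic spacers, and grouped into transcription units of 1-3
    consecutive genes, each with a single promoter 50 bp upstream.
    """
    gene_ids = sorted(g.id for g in model.genes)
    if len(gene_ids) < 3:
        raise ValueError("model must carry at least 3 genes")
    rng = scenario.rng(4)
    all_ids = gene_ids + [f"nc{i:02d}" for i in range(extra_genes)]
    genes: list[Gene] = []
    promoters: list[Promoter] = []
    tus: list[TranscriptionUnit] = []
    pos = 200
    i = 0
    tu_idx = 0
    while i < len(all_ids):
        tu_size = int(min(rng.integers(1, 4), len(all_ids) - i))
        tu_id = f"tu{tu_idx:02d}"
        prom_pos = pos - 50
        member_ids = []
        for k in range(tu_size):
            gid = all_ids[i + k]
            length = int(rng.integers(300, 1500))
            genes.append(
                Gene(
                    id=gid,
                    start=pos,
                    end=pos + length - 1,
                    strand="+",
                    protein_coding=not gid.startswith("nc"),
                    essential=False,
                    model_gene=gid in gene_ids,
                )
            )
            member_ids.append(gid)
            pos += length + int(rng.integers(20, 80))
        promoters.append(Promoter(id=f"p{tu_idx:02d}", position=prom_pos, tu_id=tu_id))
        tus.append(
            TranscriptionUnit(id=tu_id, gene_ids=tuple(member_ids), promoter_id=f"p{tu_idx:02d}")
        )
        tu_idx += 1
        i += tu_size
        pos += int(rng.integers(200, 800))  # inter-TU spacer
    return GenomeLayout(
        genes=genes,
        promoters=promoters,
        tus=tus,
        genome_length=pos + 500,
    )
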