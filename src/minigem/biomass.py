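"""Biomass objective function (BOF) construction.

The BOF is a pseudo-reaction consuming biomass precursors in proportions
measured from the cell's dry-mass composition; its flux is the growth
rate. It is assembled in three steps:

1. macromolecule coefficients -- each macromolecule's dry-mass fraction is
   apportioned among its monomers by abundance share and converted to
   mmol/gDW by molecular weight;
2. soluble pool -- cofactors and inorganic ions share a small residual
   mass fraction equally;
3. metabolite search -- a genetic algorithm (GA) explores candidate
   metabolite additions, scoring each candidate composition by the
   Matthews correlation coefficient (MCC) between in-silico single-gene
   essentiality and experimental essentiality calls; metabolites that
   recur in the per-evolution Hall of Fame are adopted into their
   dry-mass category.

Coefficients are stored as positive magnitudes in mmol/gDW (the metabolite
is consumed by growth); the growth-associated maintenance (GAM) ATP term is
carried separately so calibration can vary it without touching mass
closure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import single_gene_deletions

__all__ = [
    "ConfusionCounts",
    "BiomassReaction",
    "GAConfig",
    "mcc",
    "step1_macromolecules",
    "step2_soluble_pool",
    "step3_ga_search",
    "apply_step3_selection",
    "set_biomass_reaction",
]


@dataclass
class ConfusionCounts:
    """Binary-classification confusion matrix."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        """Percent of agreeing calls."""
        if self.total == 0:
            raise ValueError("empty confusion matrix")
        return 100.0 * (self.tp + self.tn) / self.total


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1].

    ``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``; a zero
    denominator (a degenerate margin) returns 0 by convention.
    """
    num = c.tp * c.tn - c.fp * c.fn
    denom = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return num / denom


@dataclass
class BiomassReaction:
    """Precursor coefficients (mmol/gDW, consumed) plus the GAM ATP term."""

    coefficients: dict[str, float] = field(default_factory=dict)
    gam_atp: float = 0.0

    def mass(self, molecular_weights: Mapping[str, float]) -> float:
        """Total precursor dry mass in g/gDW (coefficients x MW / 1000)."""
        return sum(
            coeff * molecular_weights[met] / 1000.0
            for met, coeff in self.coefficients.items()
        )

    def merged(self, other: Mapping[str, float]) -> "BiomassReaction":
        out = dict(self.coefficients)
        for met, coeff in other.items():
            out[met] = out.get(met, 0.0) + coeff
        return BiomassReaction(coefficients=out, gam_atp=self.gam_atp)


def step1_macromolecules(
    fractions: Mapping[str, float],
    monomer_shares: Mapping[str, Mapping[str, float]],
    molecular_weights: Mapping[str, float],
) -> BiomassReaction:
    """Convert macromolecule dry-mass fractions to monomer coefficients.

    ``fractions`` maps macromolecule name (DNA, RNA, protein, lipid,
    carbohydrate, ...) to its g/gDW share; ``monomer_shares`` maps each
    macromolecule to its monomer mass shares (summing to 1). The
    coefficient of monomer m in macromolecule M is
    ``fraction_M * share_m / MW_m * 1000`` mmol/gDW, so mass closure per
    macromolecule is exact.
    """
    coeffs: dict[str, float] = {}
    for macro, fraction in fractions.items():
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(f"fraction for {macro!r} outside [0, 1]: {fraction}")
        if fraction == 0.0:
            continue
        shares = monomer_shares.get(macro)
        if not shares:
            raise ValueError(f"no monomer shares given for macromolecule {macro!r}")
        total = sum(shares.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"monomer shares for {macro!r} sum to {total}, expected 1"
            )
        for met, share in shares.items():
            mw = molecular_weights.get(met)
            if mw is None or mw <= 0:
                raise ValueError(f"missing molecular weight for {met!r}")
            coeffs[met] = coeffs.get(met, 0.0) + fraction * share / mw * 1000.0
    return BiomassReaction(coefficients=coeffs)


def step2_soluble_pool(
    metabolites: Sequence[str],
    pool_fraction: float,
    molecular_weights: Mapping[str, float],
) -> dict[str, float]:
    """Equal mass shares of ``pool_fraction`` g/gDW across the pool."""
    if not metabolites:
        raise ValueError("soluble pool is empty")
    share = pool_fraction / len(metabolites)
    out: dict[str, float] = {}
    for met in metabolites:
        mw = molecular_weights.get(met)
        if mw is None or mw <= 0:
            raise ValueError(f"missing molecular weight for {met!r}")
        out[met] = share / mw * 1000.0
    return out


@dataclass
class GAConfig:
    """Hyperparameters of the metabolite-search GA."""

    n_evolutions: int = 50
    n_generations: int = 200
    population_size: int = 50
    tournament_size: int = 3
    crossover_rate: float = 0.8
    hall_of_fame_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_evolutions, self.n_generations, self.population_size) <= 0:
            raise ValueError("GA sizes must be positive")


def set_biomass_reaction(model, bof: BiomassReaction, reaction_id: str) -> None:
    """Write a BiomassReaction into a cobra model reaction in place.

    Precursors are consumed (negative stoichiometry); the GAM term consumes
    ATP + H2O and releases ADP + Pi + H when those metabolites exist.
    """
    rxn = model.reactions.get_by_id(reaction_id)
    stoich = {met: -coeff for met, coeff in bof.coefficients.items()}
    gam_partners = {"atp_c": -1.0, "h2o_c": -1.0, "adp_c": 1.0, "pi_c": 1.0, "h_c": 1.0}
    met_ids = {m.id for m in model.metabolites}
    for met, sign in gam_partners.items():
        if met in met_ids:
            stoich[met] = stoich.get(met, 0.0) + sign * bof.gam_atp
    rxn.subtract_metabolites(rxn.metabolites)  # clear
    rxn.add_metabolites(
        {model.metabolites.get_by_id(met): coeff for met, coeff in stoich.items()}
    )


def _essentiality_fitness(
    model,
    biomass_id: str,
    candidate_coeffs: Mapping[str, float],
    experimental: Mapping[str, bool],
) -> float:
    """MCC of single-gene essentiality predictions vs experimental calls."""
    with model:
        if candidate_coeffs:
            rxn = model.reactions.get_by_id(biomass_id)
            rxn.add_metabolites(
                {
                    model.metabolites.get_by_id(met): -coeff
                    for met, coeff in candidate_coeffs.items()
                }
            )
        if model.slim_optimize(error_value=0.0) <= 1e-9:
            return -2.0  # infeasible composition: worse than any real MCC
        calls = single_gene_deletions(model, genes=list(experimental))
    tp = fp = tn = fn = 0
    for gene, observed in experimental.items():
        predicted = calls[gene][1]
        if predicted and observed:
            tp += 1
        elif predicted and not observed:
            fp += 1
        elif not predicted and not observed:
            tn += 1
        else:
            fn += 1
    return mcc(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))


def step3_ga_search(
    model,
    candidates: Sequence[str],
    experimental_essentiality: Mapping[str, bool],
    cfg: GAConfig,
    biomass_id: str | None = None,
    candidate_coefficient: float = 0.05,
) -> list[tuple[str, float]]:
    """GA search for biomass metabolites that improve essentiality calls.

    Individuals are binary inclusion vectors over ``candidates``; a set
    member is added to the BOF at ``candidate_coefficient`` mmol/gDW during
    evaluation. Fitness is the MCC between in-silico knockout essentiality
    and ``experimental_essentiality``. Each evolution archives its best
    individuals in a Hall of Fame; the result ranks candidates by their
    appearance frequency across evolutions (descending, then by name).

    Fully deterministic for a fixed ``cfg.seed``.
    """
    if not candidates:
        raise ValueError("no candidate metabolites supplied")
    biomass_id = biomass_id or next(
        r.id for r in model.reactions if r.objective_coefficient != 0
    )
    met_ids = {m.id for m in model.metabolites}
    missing = [c for c in candidates if c not in met_ids]
    if missing:
        raise ValueError(f"candidates absent from model: {missing}")

    n = len(candidates)
    cache: dict[frozenset, float] = {}

    def fitness(mask: np.ndarray) -> float:
        key = frozenset(np.nonzero(mask)[0].tolist())
        if key not in cache:
            coeffs = {candidates[i]: candidate_coefficient for i in key}
            cache[key] = _essentiality_fitness(
                model, biomass_id, coeffs, experimental_essentiality
            )
        return cache[key]

    def ranking_keys(pop: np.ndarray, fits: np.ndarray) -> np.ndarray:
        # parsimony tie-break: at equal MCC, smaller compositions win, so
        # fitness-neutral candidates cannot drift into the Hall of Fame
        sizes = pop.sum(axis=1)
        return fits - 1e-9 * sizes

    hall_of_fame: list[np.ndarray] = []
    best_curves: list[list[float]] = []
    for evo in range(cfg.n_evolutions):
        rng = np.random.default_rng((cfg.seed, evo))
        pop = rng.random((cfg.population_size, n)) < 0.5
        fits = np.array([fitness(ind) for ind in pop])
        curve = [float(fits.max())]
        for _ in range(cfg.n_generations):
            keys = ranking_keys(pop, fits)
            new_pop = np.empty_like(pop)
            # elitism: carry the best individual over unchanged
            new_pop[0] = pop[int(np.argmax(keys))]
            for i in range(1, cfg.population_size):
                a = _tournament(rng, keys, cfg.tournament_size)
                b = _tournament(rng, keys, cfg.tournament_size)
                if rng.random() < cfg.crossover_rate:
                    cross = rng.random(n) < 0.5
                    child = np.where(cross, pop[a], pop[b])
                else:
                    child = pop[a].copy()
                flip = rng.random(n) < (1.0 / n)
                child = np.logical_xor(child, flip)
                new_pop[i] = child
            pop = new_pop
            fits = np.array([fitness(ind) for ind in pop])
            curve.append(max(curve[-1], float(fits.max())))
        best_curves.append(curve)
        order = np.argsort(-ranking_keys(pop, fits), kind="stable")[
            : cfg.hall_of_fame_size
        ]
        hall_of_fame.extend(pop[i].copy() for i in order)

    if all(cache[k] == -2.0 for k in cache):
        raise ValueError("no feasible biomass composition found by the GA")

    counts = np.zeros(n)
    for ind in hall_of_fame:
        counts += ind
    freqs = counts / len(hall_of_fame)
    ranked = sorted(zip(candidates, freqs), key=lambda kv: (-kv[1], kv[0]))
    return [(name, float(freq)) for name, freq in ranked]


def _tournament(rng: np.random.Generator, fits: np.ndarray, k: int) -> int:
    contenders = rng.integers(0, len(fits), size=k)
    return int(contenders[np.argmax(fits[contenders])])


def apply_step3_selection(
    bof: BiomassReaction,
    molecular_weights: Mapping[str, float],
    existing_pool: Sequence[str],
    pool_adds: Sequence[str] = (),
    existing_lipids: Sequence[str] = (),
    lipid_adds: Sequence[str] = (),
    capsule_add: str | None = None,
    pool_fraction: float = 0.012,
    lipid_fraction: float = 0.183,
    carbohydrate_fraction: float = 0.041,
) -> BiomassReaction:
    """Fold the GA-selected metabolites into their dry-mass categories.

    Pool and lipid categories are fully recomputed over old plus new
    members at their molecular-weight fractions (equal mass shares), so
    prior members are rescaled; the capsule polysaccharide takes the whole
    carbohydrate fraction. Unknown metabolites (no molecular weight) raise.
    """
    coeffs = dict(bof.coefficients)

    def recompute(members: Sequence[str], fraction: float) -> None:
        for met in members:
            coeffs.pop(met, None)
        if members:
            coeffs.update(step2_soluble_pool(members, fraction, molecular_weights))

    pool_members = list(dict.fromkeys([*existing_pool, *pool_adds]))
    if pool_adds:
        recompute(pool_members, pool_fraction)
    lipid_members = list(dict.fromkeys([*existing_lipids, *lipid_adds]))
    if lipid_adds:
        recompute(lipid_members, lipid_fraction)
    if capsule_add is not None:
        mw = molecular_weights.get(capsule_add)
        if mw is None or mw <= 0:
            raise ValueError(f"missing molecular weight for {capsule_add!r}")
        coeffs[capsule_add] = carbohydrate_fraction / mw * 1000.0
    return BiomassReaction(coefficients=coeffs, gam_atp=bof.gam_atp)
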