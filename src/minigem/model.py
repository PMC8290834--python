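"""Core constraint-based simulation layer.

A genome-scale model (GEM) is a stoichiometric matrix S over metabolites
(rows) and reactions (columns) with flux bounds ``a_i <= v_i <= b_i`` and
gene-protein-reaction (GPR) boolean rules. Flux-balance analysis (FBA)
maximizes an objective flux (typically the biomass pseudo-reaction, whose
flux is the growth rate in 1/h) subject to the steady state ``S.v = 0``.

This module wraps cobrapy for the standard operations -- model I/O, FBA,
parsimonious FBA, gene deletions, and minimal-medium search -- and adds the
validation, classification, and activity-call conventions used throughout
the package. All fluxes are in mmol/gDW/h and growth rates in 1/h.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import cobra
from cobra.flux_analysis import pfba as _cobra_pfba
from cobra.io import model_from_dict
from cobra.medium import minimal_medium as _cobra_minimal_medium
from cobra.util.solver import OptimizationError

__all__ = [
    "FluxState",
    "OrphanCensus",
    "PseudoReactionConfig",
    "ModelValidationError",
    "ACTIVE_FLUX_THRESHOLD",
    "BOUND_SENTINEL",
    "read_model_json",
    "validate_model",
    "count_orphans",
    "fba",
    "pfba",
    "active_reactions",
    "active_genes",
    "single_gene_deletions",
    "minimal_medium",
]

#: Flux magnitude above which a reaction (and the genes able to catalyze it)
#: is called active in a parsimonious flux state. Fluxes below this are
#: numerical noise of the LP solver.
ACTIVE_FLUX_THRESHOLD = 1e-8

#: Finite stand-in for "unbounded" flux bounds (BiGG convention).
BOUND_SENTINEL = 1000.0


class ModelValidationError(ValueError):
    """Raised when a model JSON violates the structural contract."""


@dataclass
class FluxState:
    """Result of one LP solve over a metabolic model.

    ``status`` is one of ``optimal``, ``infeasible``, ``unbounded``.
    ``fluxes`` and ``objective_value`` are only meaningful when optimal.
    """

    fluxes: dict[str, float]
    objective_value: float | None
    status: str

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def total_flux(self) -> float:
        """Sum of absolute fluxes (the pFBA objective)."""
        return sum(abs(v) for v in self.fluxes.values())


@dataclass
class OrphanCensus:
    """Partition of the reaction set by gene association.

    ``gene_associated + orphan == total``; ``orphan_pseudo`` counts the
    orphans that are pseudo-reactions (exchanges, sinks, demands, ATP
    maintenance, biomass objectives) rather than genuinely unassigned
    enzymatic steps.
    """

    total: int
    gene_associated: int
    orphan: int
    orphan_pseudo: int

    @property
    def necessary_orphans(self) -> int:
        return self.orphan - self.orphan_pseudo


@dataclass
class PseudoReactionConfig:
    """Id conventions used to classify pseudo-reactions."""

    prefixes: tuple[str, ...] = ("EX_", "SK_", "DM_")
    substrings: tuple[str, ...] = ("ATPM",)
    include_objective: bool = True

    def is_pseudo(self, reaction: cobra.Reaction, objective_ids: set[str]) -> bool:
        rid = reaction.id
        if any(rid.startswith(p) for p in self.prefixes):
            return True
        if any(s in rid for s in self.substrings):
            return True
        if self.include_objective and rid in objective_ids:
            return True
        # boundary reactions with a single metabolite are exchanges/sinks
        # regardless of naming
        return len(reaction.metabolites) == 1


def _objective_reaction_ids(model: cobra.Model) -> set[str]:
    return {
        r.id
        for r in model.reactions
        if getattr(r, "objective_coefficient", 0.0) != 0.0
    }


def validate_model(model: cobra.Model) -> None:
    """Check the structural invariants of a loaded model.

    Every reaction must reference declared metabolites, every GPR gene must
    be declared, bounds must be ordered, and compartments must be set.
    Raises :class:`ModelValidationError` on the first violation.
    """
    met_ids = {m.id for m in model.metabolites}
    gene_ids = {g.id for g in model.genes}
    for met in model.metabolites:
        if not met.compartment:
            raise ModelValidationError(f"metabolite {met.id!r} has no compartment")
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelValidationError(
                f"reaction {rxn.id!r}: lower bound {rxn.lower_bound} exceeds "
                f"upper bound {rxn.upper_bound}"
            )
        for met in rxn.metabolites:
            if met.id not in met_ids:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references undeclared metabolite {met.id!r}"
                )
        for gene in rxn.genes:
            if gene.id not in gene_ids:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references undeclared gene {gene.id!r}"
                )


def _clamp_bounds(model: cobra.Model, sentinel: float = BOUND_SENTINEL) -> None:
    for rxn in model.reactions:
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if lb < -sentinel or math.isinf(lb):
            lb = -sentinel
        if ub > sentinel or math.isinf(ub):
            ub = sentinel
        rxn.bounds = (lb, ub)


def read_model_json(path, bound_sentinel: float = BOUND_SENTINEL) -> cobra.Model:
    """Load and validate a BiGG-dialect JSON model.

    Parameters
    ----------
    path:
        Filesystem path to a JSON file with ``metabolites``, ``reactions``
        and ``genes`` arrays; reactions carry ``lower_bound``,
        ``upper_bound`` and ``gene_reaction_rule``.
    bound_sentinel:
        Bounds whose magnitude exceeds this value (or infinities) are
        clamped to +/- this value on read.

    Returns
    -------
    cobra.Model
        Fully validated model. The gene list is the union of genes declared
        in the JSON and genes appearing in any GPR (cobrapy registers GPR
        genes automatically).
    """
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelValidationError(f"malformed model JSON at {path}: {exc}") from exc
    for key in ("metabolites", "reactions"):
        if key not in payload:
            raise ModelValidationError(f"model JSON at {path} lacks {key!r} array")
    try:
        model = model_from_dict(payload)
    except KeyError as exc:
        raise ModelValidationError(
            f"model JSON at {path} contains a dangling reference: {exc}"
        ) from exc
    _clamp_bounds(model, bound_sentinel)
    validate_model(model)
    return model


def count_orphans(
    model: cobra.Model, pseudo: PseudoReactionConfig | None = None
) -> OrphanCensus:
    """Census of gene-associated vs orphan vs pseudo reactions.

    A reaction is gene-associated iff its GPR is non-empty; the remaining
    orphans are split into pseudo-reactions (by id convention and
    single-metabolite stoichiometry) and necessary orphans.
    """
    pseudo = pseudo or PseudoReactionConfig()
    objective_ids = _objective_reaction_ids(model)
    gene_associated = 0
    orphan = 0
    orphan_pseudo = 0
    for rxn in model.reactions:
        if rxn.gene_reaction_rule.strip():
            gene_associated += 1
        else:
            orphan += 1
            if pseudo.is_pseudo(rxn, objective_ids):
                orphan_pseudo += 1
    return OrphanCensus(
        total=len(model.reactions),
        gene_associated=gene_associated,
        orphan=orphan,
        orphan_pseudo=orphan_pseudo,
    )


def _solution_to_state(model: cobra.Model, solution) -> FluxState:
    status = solution.status
    if status != "optimal":
        return FluxState(fluxes={}, objective_value=None, status=status)
    return FluxState(
        fluxes={r: float(v) for r, v in solution.fluxes.items()},
        objective_value=float(solution.objective_value),
        status="optimal",
    )


def fba(
    model: cobra.Model,
    objective: str | None = None,
    direction: str = "max",
) -> FluxState:
    """Solve the FBA linear program.

    ``objective`` defaults to the model's configured objective reaction.
    Infeasible and unbounded problems are reported through ``status``,
    never as zero growth.
    """
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    with model:
        if objective is not None:
            model.objective = model.reactions.get_by_id(objective)
        model.objective_direction = direction
        solution = model.optimize(raise_error=False)
        return _solution_to_state(model, solution)


def pfba(model: cobra.Model, objective: str | None = None) -> FluxState:
    """Parsimonious FBA: fix the FBA optimum, then minimize total |flux|.

    The returned ``objective_value`` is the plain FBA optimum; ``fluxes``
    are the enzyme-parsimonious flux distribution. Infeasibility is
    propagated through ``status``.
    """
    with model:
        if objective is not None:
            model.objective = model.reactions.get_by_id(objective)
        plain = model.optimize(raise_error=False)
        if plain.status != "optimal":
            return FluxState(fluxes={}, objective_value=None, status=plain.status)
        try:
            solution = _cobra_pfba(model)
        except OptimizationError:
            return FluxState(fluxes={}, objective_value=None, status="infeasible")
        return FluxState(
            fluxes={r: float(v) for r, v in solution.fluxes.items()},
            objective_value=float(plain.objective_value),
            status="optimal",
        )


def active_reactions(
    state: FluxState, threshold: float = ACTIVE_FLUX_THRESHOLD
) -> set[str]:
    """Reactions whose flux magnitude exceeds the numerical-noise threshold."""
    return {r for r, v in state.fluxes.items() if abs(v) > threshold}


def active_genes(
    model: cobra.Model,
    state: FluxState,
    threshold: float = ACTIVE_FLUX_THRESHOLD,
) -> set[str]:
    """Genes able to catalyze at least one active reaction.

    Activity is attributed to every gene appearing in the GPR of a reaction
    carrying flux above ``threshold``, i.e. every gene that *could* catalyze
    the active step.
    """
    active = active_reactions(state, threshold)
    genes: set[str] = set()
    for rid in active:
        rxn = model.reactions.get_by_id(rid)
        genes.update(g.id for g in rxn.genes)
    return genes


def single_gene_deletions(
    model: cobra.Model,
    genes: Iterable[str] | None = None,
    essentiality_cutoff: float = 0.01,
) -> dict[str, tuple[float, bool]]:
    """Knock out each gene in turn and record the resulting growth.

    Reactions whose GPR evaluates to false without the gene are closed
    (bounds 0,0) inside a model context. A gene is essential iff the
    knockout optimum falls below ``essentiality_cutoff`` times the
    wild-type optimum (default 1%).

    Returns a map ``gene -> (growth, essential)``.
    """
    wild_type = model.slim_optimize(error_value=float("nan"))
    if math.isnan(wild_type):
        raise ValueError("wild-type model is infeasible; cannot assess deletions")
    cutoff = essentiality_cutoff * wild_type
    gene_ids = list(genes) if genes is not None else [g.id for g in model.genes]
    out: dict[str, tuple[float, bool]] = {}
    for gid in gene_ids:
        with model:
            model.genes.get_by_id(gid).knock_out()
            growth = model.slim_optimize(error_value=0.0)
        growth = max(float(growth), 0.0)
        out[gid] = (growth, growth < cutoff)
    return out


def minimal_medium(
    model: cobra.Model, min_growth: float
) -> set[str]:
    """Smallest set of open exchange reactions sustaining ``min_growth``.

    Solved as a MILP with one binary indicator per exchange (cobrapy's
    ``minimize_components`` formulation). Raises ``ValueError`` when even
    the fully open medium cannot reach ``min_growth``.
    """
    attainable = model.slim_optimize(error_value=0.0)
    if attainable < min_growth:
        raise ValueError(
            f"requested growth {min_growth} exceeds the attainable maximum "
            f"{attainable:.6g} with all exchanges open"
        )
    medium = _cobra_minimal_medium(model, min_growth, minimize_components=True)
    if medium is None:
        raise ValueError("minimal-medium MILP reported infeasible")
    return {rid for rid, flux in medium.items() if abs(flux) > 1e-9}
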