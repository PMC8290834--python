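"""Flux-balance analysis on a toy metabolic model.

Builds an 8-gene toy cell, runs FBA and parsimonious FBA, and prints the
orphan-reaction census. The FBA objective value is the growth rate the
stoichiometry supports; pFBA keeps that optimum while minimizing total
flux, yielding a unique enzyme-efficient flux state.
"""

from minigem.model import count_orphans, fba, pfba
from minigem.synth import make_toy_model

model, essential = make_toy_model(n_genes=8, topology="chain", seed=0)

state = fba(model)
print(f"FBA growth rate:        {state.objective_value:.3f} (arbitrary units/h)")

parsimonious = pfba(model)
print(f"pFBA growth rate:       {parsimonious.objective_value:.3f}")
print(f"pFBA total |flux|:      {parsimonious.total_flux():.3f} mmol/gDW/h")

census = count_orphans(model)
print(
    f"reactions: {census.total} total, {census.gene_associated} gene-associated, "
    f"{census.orphan} orphans ({census.orphan_pseudo} pseudo-reactions)"
)
# The pseudo-reactions are the exchanges, the ATP maintenance and the
# biomass drain; the one necessary orphan is a transporter without a gene.
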