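# Methods

This note records the models, conventions, parameter choices and known
limitations behind each stage of the package. Units throughout: fluxes
and specific rates in mmol/gDW/h, growth rates in h⁻¹, concentrations in
mmol/l, biomass in gDW/l, genome coordinates in 1-based inclusive base
pairs.

## Constraint-based layer

Models are BiGG-dialect JSON handled by cobrapy with the GLPK backend;
LP/MILP solves are deterministic for a fixed model. Bounds whose
magnitude exceeds 1000 mmol/gDW/h (or infinities) are clamped to ±1000 on
read. Validation rejects dangling metabolite/gene references, inverted
bounds and missing compartments before any simulation.

Pseudo-reactions are classified by id convention (`EX_`/`SK_`/`DM_`
prefixes, an `ATPM` substring, the objective reaction) plus
single-metabolite stoichiometry; the convention is overridable through
`PseudoReactionConfig`.

pFBA fixes the FBA optimum and minimizes total absolute flux. A reaction
is *active* when |v| exceeds 1e-8 mmol/gDW/h — the numerical-noise floor
of the LP solver, configurable — and activity is attributed to every gene
appearing in the reaction's GPR (any gene that could catalyze the step).
Gene essentiality uses a knockout-growth cutoff of 1% of the wild-type
optimum; the cutoff is a parameter because near-zero optima are
solver-tolerance-limited. Alternate optima are accepted: tests and
downstream logic only consume objective values, activity calls and
invariants, never specific vertex fluxes, except where uniqueness is
guaranteed by construction.

Minimal media are found with the MILP formulation (one binary per
exchange, minimize the number open subject to a growth floor). On
instances small enough to enumerate, the result is verified against
exhaustive subset enumeration in the test suite.

## Annotation confidence

Component scores follow fixed rules: gene names are compared
case-insensitively after stripping locus-tag-style prefixes, "identical"
requires the focal name to match in at least two comparator species and
"similar" requires a shared 3-character prefix in at least two; a
structure scores 3 only if the sequence pre-screen (E < 1e-4, identity
> 10%, similarity > 30%, not transmembrane) and both quality thresholds
(C-score > −1.5, TM-score > 0.5) pass; EC agreement needs two methods at
four digits (3) or three digits (2), partial ECs (`d.d.d.-`) joining only
the 3-digit rule. An EC probability ≥ 0.90 raises a gold-standard flag
carried in the output but deliberately not weighted in the score, since
the scoring ledger treats all methods equally. Bins are basic (< 3),
medium (3–6), high (≥ 7); the monotonicity of improving evidence is a
tested invariant.

## Growth kinetics

Exponential fits are log-linear least squares: exact on noiseless data,
initializer-free, hence bit-deterministic. Hyperbola fits
(y = vmax·x/(k + x)) use nonlinear least squares with the fixed
initialization vmax = max(y), k = median(x). Colony counts convert to
biomass with a per-cell dry mass of 2.18e-14 g (0.013 gDW/l at
5.95e8 CFU/ml), overridable.

Specific rates take the concentration slope from a linear regression over
the 14–16 h exponential window and evaluate, per 1-h interval,
qS = ΔS·r/X(t₂). This end-point form systematically under-reads a
constant true rate: with dS/dt = −q·X(t) the exact relation is
q = ΔS·r/ΔX, and the literal rule returns q·(1 − e^{−rΔt}) ≈ 0.36·q at
r = 0.44 h⁻¹, Δt = 1 h. The package therefore provides both forms — the
literal rule as the documented default and the exact-integral variant
behind `exact_integral=True` — and the test suite pins the bias to its
closed form rather than hiding it. Averaging the exact-integral estimates
over the two 1-h windows recovers a planted constant rate to within ~5%
(the residual is the linear smoothing of an exponentially accelerating
depletion). The maximal rate qS_max is the mean over the two highest
initial-substrate conditions, where the rate has plateaued.

## Biomass objective

Step 1 converts macromolecule dry-mass fractions into monomer
coefficients, coefficient = fraction × share / MW × 1000 (mmol/gDW), with
monomer shares required to sum to 1 (±1e-6) so per-category mass closure
is exact. Step 2 spreads a pool fraction equally by mass over its
members. Step 3 runs a genetic algorithm over candidate-metabolite
inclusion vectors: fitness is the MCC between single-gene-knockout
essentiality and the experimental calls with the candidates added to the
biomass reaction at a small fixed search coefficient (0.05 mmol/gDW);
infeasible compositions score −2, below any attainable MCC. GA operators:
tournament selection (size 3), uniform crossover (rate 0.8), per-bit
mutation 1/L, one elitist survivor, population 50, with 50 evolutions of
200 generations as the default protocol (all in `GAConfig`; tests and the
acceptance run use scaled-down GA sizes since the planted scenarios
separate in a few generations). Selection ranks by MCC with a parsimony
tie-break (1e-9 per included metabolite) so fitness-neutral candidates
cannot drift into the Hall of Fame; recorded fitnesses are unmodified
MCCs. Candidate subsets are cached, every evolution is seeded
independently from the run seed, and the whole output is reproducible
bit-for-bit. The Hall of Fame keeps the best individual per evolution
(size configurable); reported frequencies are appearances divided by
evolutions. Adopting selected metabolites recomputes their whole dry-mass
category (old plus new members at equal mass shares of the category
fraction — 1.2% pool, 18.3% lipids, 4.1% carbohydrate/capsule), the
reading of category bookkeeping that keeps mass closure exact. MCC uses
the zero-denominator → 0 convention. The GAM ATP term is stored apart
from precursor coefficients so calibration can vary it without touching
mass closure.

## Constraint calibration

Stages run in impact order: GAM (scan 0–50) and NGAM (0–30) matched to
the target growth rate by linear interpolation plus bisection refinement
to 1e-4 around the crossing (coarse grids at 1.0 mmol/gDW/h; the
refinement supplies the resolution); substrate uptake fixed at the
measured maximum; lactate as the *smallest* forced secretion reaching the
target on 0–40; acetate as the residual of the measured combined
secretion; the NADH-oxidase capped at (0, 5); oxygen on a 0.1-resolution
scan 0–30 at the plateau onset — the smallest uptake within 1e-6 of the
plateau growth, a deterministic realization of "choose the uptake
matching the target". Initial magnitudes: GAM 5, NGAM 3, substrate 5.26,
lactate 7.65, acetate 0.96, oxygen 10; target growth 0.44 h⁻¹; combined
secretion 8.69 mmol/gDW/h. Uptakes are negative exchange lower bounds;
measured secretions are forced with equal lower and upper bounds. Note
that the summed initial secretions (8.61) differ from the measured
combined rate (8.69); the combined rate is treated as authoritative, so
the final growth overshoots the target by the corresponding margin
(~0.006 h⁻¹ on the fermentation toy). Infeasible scan points are recorded
as zero growth with a flag, never conflated with true zero-growth
solutions.

## Validation

Expression thresholds: candidate grids are the sorted unique observed
values (calls use ≥), scored S = X·MCC with the transcriptomic calls as
reference and X the number of genes expressed in *both* datasets — the
reading under which S rewards concordant expressed sets; ties break
toward lower thresholds (the larger expressed set). The optimizer is
vectorized but exactly equals the double-loop brute force, which the test
suite asserts. Genes enter the flux–expression comparison only when both
omics calls agree; the confusion convention is prediction = flux
activity, observation = expression.

Essentiality revision: mutants with doubling-time SD above 30% of their
mean are dropped; remaining mutants are non-viable above the cohort
median + MAD (unscaled median absolute deviation); a gene is essential
when never hit, hit only in its terminal 20% (position ≥ 0.8 of gene
length), or hit internally only by non-viable mutants. Insertions without
growth data count as viable evidence (the tree's default branch); the
four-way labels record whether a call rests on measured growth (likely)
or its absence (putative), and collapse with every *essential* label
counted as essential. One property worth knowing: under any symmetric
doubling-time noise the median + MAD rule flags roughly a quarter of
single-insertion viable mutants (P(z > 0.6745)), so it is only sharp when
the viable cohort is tightly clustered, as in colorimetric doubling-time
data; the synthetic generator therefore defaults to noise-free doubling
times, with noise opt-in.

The carbohydrate screen opens each sugar's exchange alone at −10
mmol/gDW/h, closing all other screened exchanges, and normalizes growth
over the reference sugar.

## Genome reduction

Deleting a segment removes overlapping genes and silences every gene
downstream of a promoter inside the segment (strand-aware; promoter loss
turns off the whole transcription unit — polar effects beyond promoter
loss are not modeled by default). The longest-deletion search enumerates
the maximal-extent segment of every contiguous run of genomic elements
plus all element-free gaps — every distinct silenced-gene set at its
maximal base-pair length — and verifies each candidate by FBA knockout of
the silenced model genes, with results cached by silenced set. For
single-segment steps this is equivalent to the bi-level MILP formulation
of iterative deletion design while remaining solver-free and
deterministic; ties break to the leftmost coordinate. Committed segments
are blocked intervals in original coordinates: later candidates may not
overlap them, so traces are non-overlapping by construction (merging
regions across an earlier deletion is deliberately not attempted).
Experimentally essential genes (and essential non-coding elements flagged
in the layout) may be neither removed nor silenced; growth floors of
0.6/0.9/1.0 × the unreduced optimum are the low/intermediate/optimal
presets, and iteration runs up to 100 deletions or exhaustion.

## Synthetic data

Every generator is a pure function of an integer seed (integer-indexed
numpy Generators, no set-iteration order dependence) and emits its ground
truth beside the data. Defaults are the study conditions of a fast-growing
Mollicute in semi-defined medium: growth rate 0.44 h⁻¹ (doubling 1.58 h),
maximal sucrose-specific uptake 5.26 mmol/gDW/h, combined
fermentation-product yield 8.69/5.26 per substrate, carrying capacity
5.95e8 CFU/ml, per-cell dry mass 2.18e-14 g, expression thresholds
168 FPKM and 23 proteins/cell, initial substrate 1.46–2.92 mmol/l
(0.05–0.1% w/v sucrose). Noise models are multiplicative lognormal for
counts and concentrations and truncated normal for doubling times, all
defaulting to zero so recovery tests are exact; noisy variants are
opt-in.

Two structural choices matter for exact recovery. Silent genes in the
omics generator carry anti-correlated abundance ranks between the two
datasets, which makes the planted threshold pair the provably unique
optimum of X·MCC at zero discordance (independent silent draws can be
rank-concordant by chance, letting a lower pair win on small tables). The
transposon generator assigns essential genes, in rotation, one of the
three signatures the decision tree recognizes — never hit, terminal-only
hits, internal hits with growth-impaired mutants (3× the cohort doubling
time, safely above median + MAD) — and gives a configurable fraction of
non-essential genes an extra unreliable-SD mutant that the 30% filter
must remove.

The toy metabolic model splits substrate between an ATP-yielding branch
(2 ATP per substrate) and a precursor branch, so the FBA optimum responds
continuously to maintenance parameters — growth = (2u − NGAM)/(GAM + 2) —
and planted GAM/NGAM values are recoverable analytically; a two-gene
complex, an isozyme pair and a gene-free dead-end sugar route provide the
essentiality and screen edge cases. A separate fermentation toy adds
glycolysis with redox balance (NADH re-oxidized by lactate/acetate export
or an oxygen-dependent NADH oxidase) to exercise every calibration stage.

What the synthetic data do *not* emulate: genuine biological dispersion
(replicate structure, batch effects), heavy-tailed omics abundance
distributions, transposon insertion-site bias, or a realistic genome
scale (toy genomes are tens of kilobases). Passing recovery tests
demonstrates correctness of the procedures under their stated
assumptions, not performance on real datasets; the published-data runner
(`scripts/reproduce_published.py`) exists for the latter.

## Problem sizes

Default verification sizes: 20 random networks of 8–10 reactions for the
dense-LP comparison, 50 random instances each for the minimal-medium and
longest-deletion enumerations, 40–100-gene tables for threshold and
annotation recovery, 10 GA evolutions of 8 generations on the planted
two-candidate scenario, and toy genomes of ~16–30 genes for reduction
traces. These sizes make every oracle exhaustive while keeping the whole
suite and the acceptance run interactive.
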