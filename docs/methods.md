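# Methods

## Model representation and FBA

A `MetabolicModel` stores the stoichiometric matrix S (metabolites ×
reactions), per-reaction bounds in µmol min⁻¹ gDW⁻¹, reversibility flags
(irreversible ⇒ lb ≥ 0), per-metabolite compartment labels and named
reaction sets ("biomass", "inputs", …).  Exchange reactions carry a single
−1 coefficient on the exchanged metabolite, so negative flux is uptake and
positive flux is production.

Flux balance analysis solves `opt wᵀv s.t. S v = 0, lb ≤ v ≤ ub`.  The
reference solver is scipy's HiGHS interface; infeasibility and
unboundedness are reported through an explicit status, never as silent
zeros.  An optimal distribution satisfies ‖S v‖∞ ≤ 10⁻⁶·max(1, ‖v‖∞).
Because LP optima can be degenerate, every downstream contract is written
against the objective value, never a particular flux vector — except the
scan routines, which pin fluxes explicitly.  The inner loops of the
optimizers and scans route through a warm-started GLPK problem (`swiglpk`,
shipped with cobrapy) that reuses the factorized basis between bound
changes; the two solvers are cross-checked against each other and against
an exhaustive basic-feasible-solution enumeration on a 6-reaction fixture
in the test suite.

Model I/O: SBML through cobrapy (read/write only — no cobra solving in the
library paths), and a flat tabular dialect `id TAB formula TAB lb TAB ub`
with formulas like `2 A + B -> C` (`<->` marks reversibility; reversibility
is otherwise inferred from lb < 0).

## The toy mitochondrion fixture

`make_toy_mitochondrion(seed)` builds a deterministic 19-reaction,
11-metabolite stand-in for a genome-scale mitochondrial model: lumped
glycolysis (glc → 2 pyr + 2 NADH + 2 ATP), reversible lactate
dehydrogenase plus a lactate exchange (fermentative overflow), pyruvate
oxidation and a lumped TCA reaction (4 NADH per acetyl-CoA), an
electron-transport reaction (NADH + ½ O2 → 2.5 ATP), amino-acid and
ketone-body catabolism, two biomass component reactions, an ATP drain and
seven substrate exchanges.  The seed jitters the uptake capacities ±10%;
the topology is fixed, so a seed pins the model bitwise.

Three properties are built in deliberately, because the analyses are
validated against them: (i) wild-type max-ATP is strictly positive and
collapses ~30× when the O2 exchange closes; (ii) the O2 capacity is the
single most influential uptake bound for ATP (the respiratory chain
delivers 5 ATP per O2, an order of magnitude above any substrate's marginal
value per unit of its capacity range); (iii) the NADH exchange is
export-only — physiologically, the inner membrane is impermeable to NADH —
with a capacity above the attainable redox supply (~250 µmol min⁻¹ gDW⁻¹),
so the ATP/NADH-export trade-off is governed by the redox budget and spans
essentially the full ATP range.  Point (iii) matters for optimizer
validation: the scalar fitness F (below) is roughly constant along that
front, so the evolutionary search is not biased toward either end.  What
the fixture does *not* emulate: genome-scale redundancy (hundreds of
alternative pathways), compartment transport chains, cofactor pools other
than NADH/ATP, or realistic biomass stoichiometry — conclusions from
passing tests are about algorithmic correctness, not mitochondrial
physiology.

## The evolutionary optimizer

Candidates are real vectors x within a box, with self-adaptive step sizes
σ (initialised to 0.4·(x_max − x_min)/n) and an age τ starting at 0.  One
generation executes, in order: copying (each member copied `dup` times,
copies inherit the age, the parent ages by one), local search, global
search, evaluation, age update (reset to 0 when the mutant improves on its
pre-mutation fitness, +1 otherwise), diversity enforcement (members older
than τ_B + 1 move into the archive; exactly τ_B + 1 survives), an archive
union (all current candidates are inserted: first free slot, else a
uniformly random slot — a reservoir over the run), and selection.

Local search fires per candidate with probability e^{−ρF}; it picks one
variable, perturbs its σ_i log-normally with learning rates
γ = γ′ = 1/(2n) (the classical 1/√(2n), 1/√(2√n) rates are available
behind `classical_es_rates`) and moves x_i by σ_i·N(0,1), clipped to the
box.  Global search fires with probability e^{−F}/β and replaces x_i by
(1−γ)x_i + γ·x_k with γ ~ N(0,1), where x_k is the value at a random other
index of a random other member (resampled once on a tie); since γ can
leave [0,1] the result is clipped rather than resampled.

The fitness F = (Σᵢ fᵢ/f_maxᵢ)/r is clamped to [0,1]; f_max tracks the best
oriented objective values over all generations, with non-positive
coordinates replaced by 1 so F is defined at startup.  Two numerical
choices beyond the printed rules: (i) when every objective is non-positive
the clamp makes F identically 0, so tournament comparisons fall back to the
oriented raw-objective mean as a tie-break — without this the algorithm
cannot optimize a negative-valued function at all; (ii) selection
("picking the best individuals") is implemented as repeated random
pairwise-tournament elimination rounds, one knockout per pair played, until
the population is back to d — a deterministic best-F truncation was
rejected because it collapses the population to the fitness-maximal corner
of a front.  Feasibility dominates the tournament: feasible beats
infeasible, feasibles compare by F, infeasibles by constraint violation;
if fewer than d candidates remain, the deficit is drawn uniformly from the
archive, then from fresh random candidates.

Reported results are the non-dominated set over *all* feasible evaluations
of a run (matching the practice of reading fronts off the archive plus all
generations), alongside per-generation fronts, the final population and
the archive.  A single seeded generator drives every stochastic operator,
so runs are bit-reproducible.

## Decision encodings over fluxes

Input-flux mode: each decision variable is the uptake capacity of one
exchange reaction (applied as lb = −x, clipped to a global 1000 µmol min⁻¹
gDW⁻¹ cap, with per-variable caps such as +33% of nominal expressible
through the decision box); targets listed as *pinned* have their exchange
flux fixed at the decision value instead, which is how a produced
metabolite (e.g. NADH export) becomes both a decision and an objective.
Each candidate is scored by one FBA solve maximizing the non-pinned
objectives; an infeasible pin makes the candidate infeasible with maximal
violation.

Internal-flux mode: the candidate *is* a full flux vector; objectives are
read off directly and the constraint value is the steady-state residual,
so the feasibility threshold acts on mass balance.  Its companion mutation
operator draws k ~ U{1..C} fluxes, redraws them uniformly inside their own
bounds (irreversible reactions therefore never receive negative values),
fixes them as equalities and repairs the remaining fluxes by an LP
feasibility solve; after N failed draws the parent is kept.  Fixing and
repairing is the minimal scheme that keeps S v = 0 exact; defaults C = 5,
N = 20 are artifact choices (no published values exist).

## Protein-abundance design

The multiplier f(y) (README) scales both stored *wild-type* bounds of a
controlled reaction, so repeated scaling never compounds and y = 0 closes
the reaction — a knockout search is the {0,1}-restricted special case.
The search box is [0, y_max] with y_max = 100 by default: the logarithmic
form of f exists precisely to discourage implausibly large abundances, and
an explicit ceiling keeps the box testable.  One abundance maps to one
reaction (the identity protein→reaction mapping); each objective of a
candidate profile is scored by its own FBA solve, so the wild-type
reference point is computable by r independent LPs on the unscaled model.

## Identifiability analysis

`disease_scan` pins lb = ub = g on the impaired reaction over a caller-
supplied grid (the printed step/interval combinations are inconsistent, so
no grid is hard-coded) and stores one optimal flux vector per feasible
value; infeasible pins become flagged all-NaN columns, dropped listwise
before fitting.  Stages: healthy/inflammation/disease at ATP ratios
> 0.66 / (0.33, 0.66] / ≤ 0.33 of the unpinned optimum, or by explicit
descending flux breakpoints (b1, b2) with the half-open convention that
puts a column at exactly b1 into the inflammation interval.

ACE starts from α = x_i/‖x_i‖, β_j = 0 and alternates
β_j ← E[α − Σ_{l≠j} β_l | x_j] and α ← E[Σ β_j | x_i] (renormalized to unit
variance), with conditional expectations computed by a local-linear
Gaussian-kernel smoother, bandwidth 1.06·σ·n^{−1/5} per column
(configurable).  Convergence: relative SSE change < 10⁻⁶ or 100
iterations; non-convergence returns the last iterate, flagged.  r² = 1 −
SS_res/Var(α̂); the maximal correlation is corr(α̂, Σβ̂), which for jointly
linear data equals the absolute Pearson correlation.  Because the
local-linear smoother is not a projection, the SSE can rise by a few
percent between iterations; the non-increase property is therefore
enforced (and tested) only up to that smoother jitter.

MOTA: every non-constant column (constancy judged at relative tolerance
10⁻⁹) is taken once as response; predictors from a full ACE fit are ranked
by the variance of their fitted transformations; the shortest top-ranked
prefix reaching r² ≥ 0.8 (default) forms a group with the response, capped
at 10 members.  Groups recovered from ≥ 2 of their own members are flagged
strong; cv = std/mean annotates practical identifiability but never
filters (no published cutoff exists).

## Sensitivity analysis

Morris screening unit-scales all inputs (otherwise μ* is incomparable
across inputs and a ranking is meaningless), uses p = 4 levels,
Δ = p/(2(p−1)) and r = 20 trajectories by default, and reports μ, μ* and σ
per input; trajectories on which the evaluator fails are resampled (≤ 3r
attempts).  Ranking: μ* descending, ties by σ then input order.  Local
robustness perturbs one input at a time uniformly within a relative step
and reports the fraction of draws keeping the output within a relative
tolerance band.  First-order Sobol indices use the pick-freeze estimator
S1_i = mean(y_B(y_{AB_i} − y_A))/Var(y) on the two halves of a scrambled
Sobol sequence (quasi-Monte Carlo; plain Monte Carlo at n = 4096 leaves
~0.04 standard error, too coarse for the analytics it must reproduce),
clamped to [−0.05, 1].

## Validation problem sizes

The test suite runs at desk scale: dominance filters are verified against
an O(n²) brute force at 500 points; FBA against exhaustive vertex
enumeration on a 6-reaction network and against an independent GLPK route
on the 19-reaction toy; front recovery uses 10 seeded runs of 60
generations with population 200 (a 1/5 scale-down of the published
1000-individual runs) against a 101-weight scalarization sweep, compared
by objective-range-normalized Hausdorff distance to the front polyline;
ACE/MOTA recovery uses 500–1000 samples; knockout equivalence enumerates
all 22 single/double-knockout profiles over six controlled reactions.

## Known limitations

No thermodynamic/loopless FBA, flux variability analysis or dynamic FBA;
no GPR Boolean logic (abundances map to reactions, not genes); no
hypervolume or crowding indicators; Sobol indices are first-order only.
The scalar-fitness selection follows the published design and is not a
Pareto-ranked selection (NSGA-style crowding is deliberately out of
scope); front coverage therefore relies on the archive, age-based
diversity and the cumulative front over evaluations.
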