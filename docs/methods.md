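# Methods

This note documents the models, parameter defaults and numerical choices
behind `sgprflux`, in the order data flows through the package.

## S-GPR rules

An S-GPR is a boolean gene-to-reaction rule whose gene leaves carry the
number of transcript copies needed per functional catalytic unit,
written `n*gene`. The grammar: `and` binds tighter than `or`,
parentheses override, and a coefficient attaches only to the immediately
following gene leaf — `2*(a and b)` is rejected. This keeps the
classical GPR recoverable from any S-GPR by dropping coefficients
(serialization in GPR mode), and the mapping lossless in the other
direction.

Evaluation against an expression profile replaces leaves by expression
values — divided by the copy number in S-GPR mode — and operators by
arithmetic: AND → minimum (fixed; the scarcest subunit limits complex
assembly), OR → mean (default) or maximum per configuration. The mean
default treats isoenzymes as contributing pooled capacity; max is
available for winner-take-all readings, and neither choice is prescribed
per integration method, so it is exposed in `GprConfig`. Useful
consequences, all property-tested: with unit copy numbers S-GPR and GPR
scores coincide; the S-GPR score never exceeds the GPR score on
non-negative profiles; evaluation is monotone in every gene.

Missing genes are skipped by default: an operator node aggregates over
its measured children only, and a rule with no measured leaf returns
undefined rather than silencing the reaction. Expression platforms
reporting several probes per gene must collapse them before profile
construction; `ExpressionProfile.from_records` collapses by maximum
(conservative toward detecting activity).

## Rule construction from a composition table

Live database retrieval is deliberately out of scope; rules are built
from a user-curated TSV of (EC code, compartment, catalytic unit, gene,
copies) rows. Per reaction: rows are filtered to the reaction's
compartment (inferred from its metabolites; transport reactions spanning
several compartments match any of them), each catalytic unit becomes an
AND of its gene leaves with copy numbers, units of one EC join by OR
(isoenzymes), and multiple EC codes on one reaction join by AND (they
describe sequential activities that are all required). Units and genes
are canonically sorted, so construction is deterministic regardless of
table order. Conflicting stoichiometries for the same complex must be
reconciled by the user before the table is written; the uniqueness check
on (EC, compartment, unit, gene) enforces at most one copy number per
slot.

## Model container and preprocessing

The model is a plain container: metabolites with compartments, reactions
with stoichiometry, bounds, optional pathway label, optional rule tree,
optional EC codes, and one objective reaction. Bounds are capped at
±1000 model units on load (the usual constraint-based convention for
"unbounded"); |flux| < 1e-9 counts as numerically zero throughout, and
1e-6 is the activity-classification tolerance (two decades above solver
noise). The native JSON dialect round-trips everything; SBML Level 3 +
fbc is supported for interchange, with the S-GPR string and pathway
label stored in reaction notes (`sgpr`, `pathway`) because fbc
gene-product associations cannot carry coefficients. A model imported
from plain fbc therefore has rules but no copy-number knowledge, and
S-GPR-mode scoring refuses it explicitly.

Exchange augmentation adds, per measured metabolite, an irreversible
uptake written `∅ → M` (uptake flux positive) and an irreversible
secretion `M → ∅`, skipping any direction an existing exchange already
covers (a reversible exchange covers both). Writing uptake as production
keeps all boundary fluxes non-negative and pushes direction handling
into the classification layer.

Pruning iterates to a fixed point: reactions whose FVA range is [0, 0]
are removed, reversible reactions with exactly one feasible direction
are tightened to it, and metabolites left without reactions are dropped.
Because a blocked reaction carries zero flux in every feasible state,
removal never changes the flux polytope's projection onto the retained
reactions — FVA ranges before and after are identical, and pruning is
idempotent (both are acceptance-tested). A blocked objective reaction is
an error: such a model cannot express its phenotype.

## Solver layer

All LPs and MILPs are assembled as sparse problems and solved by HiGHS
through `scipy.optimize.milp`. HiGHS is deterministic for a fixed
formulation, and formulations are built from canonically ordered
containers, so repeated runs are bit-identical. Indicator constraints
use big-M equal to the bound cap (tight and valid given capped bounds).
Every method resolves optimizer degeneracy the same way: after its own
objective is optimized, the objective is fixed (within a 1e-9 relative
slack) and total absolute flux is minimized (a parsimonious second
stage) before any activity classification. Activity states are then
reproducible wherever the parsimonious optimum is unique; on degenerate
networks with exactly interchangeable routes the solver's (deterministic)
choice among them is still stable across reruns.

## Integration methods

All four consume reaction scores from either rule mode.

**GIMME.** Threshold `t` = mean + sample SD of the defined scores by
default (percentile and absolute modes available). Penalty
`c_r = max(0, t − score_r)`; the LP minimizes `Σ c_r·|v_r|` subject to
steady state, bounds, and objective flux ≥ 0.9 × the FBA optimum (the
required metabolic functionality, RMF; fraction configurable). The
optimal value is the inconsistency score: zero exactly when a flux
meeting the RMF exists using only adequately expressed reactions.

**iMAT.** Scored reactions are partitioned by the 40th/60th percentiles
(linear interpolation over the defined scores of the integrated
condition): above the upper → highly expressed, below the lower → lowly
expressed. The MILP rewards each high reaction carrying |v| ≥ ε in
either direction and each low reaction carrying none; ε defaults to 1.0
(the original iMAT flux-forcing convention, distinct from the 1e-6
classification tolerance). Strict inequalities mean a score sitting
exactly on a quantile is moderate — relevant for noiseless synthetic
score distributions with only two values, where thresholds should be
placed inside the gap.

**Gonçalves-style relative integration.** Step 1: parsimonious FBA on
the unmodified model gives control fluxes v_c. Step 2: each reaction
with a defined treated/control expression ratio r has its treated flux
confined to the closed interval between v_c and r·v_c (sign preserved),
intersected with its original bounds — so down-regulation (r < 1) caps
flux below control and up-regulation (r > 1) licenses flux above it,
saturating at capacity. Step 3 computes the treated state as the
minimum-total-flux distribution under those bounds. The treated step
deliberately does not re-maximize the phenotype objective: the interval
lower ends (min(v_c, r·v_c)) already keep the control phenotype flowing,
and re-maximization would make every down-regulation constraint vacuous
(the objective would climb back to the control optimum through the upper
end of each interval). A reaction inactive in control stays inactive
whatever its ratio — users integrating conditions that activate entirely
new routes should prefer iMAT or MADE. When v_c < 0 the interval is
applied to the signed flux, preserving direction.

**MADE.** Per-reaction desired transitions come from propagating gene
log-fold-changes through the rule tree with the same operators as
expression (S-GPR mode divides leaf log-fold-changes by copy number —
a deliberate mechanical application of the copy-number scaling, which
shrinks the magnitude of multi-copy genes' changes and can shift which
leaf is limiting). The p-value carried to the reaction is that of the
leaf selected by the min/max aggregation (mean of branch p-values under
OR-mean): the limiting subunit decides both the direction and the
confidence. Transitions: up if log-fc > 0 at p < 0.05, down if < 0 at
p < 0.05, otherwise same; weight w = 1 − p (the simplest monotone
significance weight). The MILP holds one flux vector and one binary
activity vector per condition, each meeting its own RMF (0.9 of that
condition's FBA optimum), and maximizes `Σ w_r · [realized transition
matches desired]`. Identical profiles give all-zero weights and, after
the parsimonious second stage, identical condition states.

## Evaluation

Measured consumption/production calls: exact two-sided Mann-Whitney
between the t0 and t5h replicate peak areas (exact up to 25 replicates
per group, normal approximation above; fewer than 2 replicates in either
group is untestable), direction by median change. Predictions and calls
meet in a 2×2 table — rows predicted active/inactive (a metabolite is
predicted-active when either of its exchange directions is), columns
measured exchange/no-exchange — summarized by the right-prediction
proportion (a+d)/n and a two-sided Fisher exact p.

The Fisher test is computed by hypergeometric tail sum in exact integer
arithmetic: all tables sharing the observed margins are enumerated and
those whose (integer-numerator) probability does not exceed the observed
one are summed. Integer comparison makes probability ties exact, which
is what lets the implementation match an independent rational-arithmetic
oracle to 1e-12 on every table with N ≤ 40.

The S-GPR improvement is reported as the percentage-point difference of
right-prediction proportions (S-GPR minus GPR, sign preserved); the
network-level effect of the rule mode as the percentage of reactions
whose activity label differs. Pathway over-activation compares
active-reaction counts per pathway between exactly two conditions:
relative weight = treated/reference count, an EXCLUSIVE flag when only
the treated condition has active reactions, and a two-sample t-test on
the per-reaction 0/1 activity indicators (chosen over a per-method unit
because the package compares one pair of states at a time; identical
indicator vectors get p = 1, constant-but-different ones p = 0).

## Synthetic studies

The fixture generator emulates the target study design at desk scale:
irreversible uptake→chain→secretion pathways with isoenzyme and
multi-copy complex motifs, a planted active sub-network, log-normal
expression (positivity matches intensity data) with sd 0.1 on the log
scale, a two-fold high/low separation, five replicates, and 10% of genes
changed between conditions — small numbers chosen to mirror
two-condition designs where conditions are nearly isogenic. A gene
contributing k copies to a planted complex draws around k times the high
mean, so its per-complex level stays high. Replicate draws yield
per-gene log2 fold changes and Welch-t p-values. Peak-area tables use
multiplicative noise around a base area, shifted three-fold at t5h for
metabolites whose exchange is active. Same seed, same bytes.

What the fixtures do **not** emulate: probe-level microarray structure
and normalization, chromatographic artifacts, correlated gene noise,
reversible internal reactions, and realistic genome-scale network
topology. Passing tests on these fixtures therefore demonstrate
correctness of the formalism and the optimization machinery, not
predictive performance on real transcriptomes.

The deterministic discriminating case is constructed, not sampled: two
routes from substrate to secreted product, the complex route (S-GPR
`2*g1 and g2`, co-producing a side metabolite) scoring 2.0 classically
and 1.5 stoichiometrically against thresholds placed in between, and
measurements showing the side metabolite unchanged. It realizes the
scenario where copy-number information flips a downstream exchange call
from wrong to right.

## Problem sizes and limitations

The shipped tests and the acceptance script use toy networks of ≤ 12
reactions, 20-seed batteries for stochastic properties, and exhaustive
enumeration oracles (all 135,750 2×2 tables with N ≤ 40; all activity
assignments of ≤ 10-reaction iMAT instances) — sizes at which every
optimization can be cross-checked against brute force. The formulations
themselves are generic sparse LPs/MILPs; genome-scale use is limited
mainly by the per-reaction FVA loop and MILP solve times, not by the
formalism. Constraint-based solutions are generally non-unique: the
parsimonious tie-break makes reported states reproducible, but a
robustness analysis over alternate optima is out of scope.
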