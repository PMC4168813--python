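# Methods

## The model and its constraints

A metabolic model is a stoichiometric matrix `S` (metabolites × reactions),
per-reaction flux bounds `v_min ≤ v ≤ v_max`, optional boolean
gene–protein–reaction (GPR) rules, and an optional linear objective.  All
analysis happens on the steady-state flux polytope `{v : S·v = 0,
v_min ≤ v ≤ v_max}`.  A reaction is *reversible* when `v_min < 0 < v_max`,
*blocked* when its flux is confined to zero over the whole polytope, and a
model is *flux-consistent* when it has no blocked reaction.  Exchange and
sink reactions are recognized structurally (a single non-zero stoichiometric
entry); no annotation is required.

Every extraction method in the package is an LP or MILP over this polytope,
solved through one wrapper around scipy's HiGHS interface with fixed,
deterministic options.

## Evidence mapping

Gene intensities map to reaction-level data through the GPR rules with
AND = min (an enzyme complex is limited by its scarcest subunit) and
OR = max (isoenzymes provide alternative routes).  Penalty mapping uses the
order-reversed convention (AND = max, OR = min), which preserves the duality
`penalty = I_max − expression` on single-gene rules.  A gene absent from the
data makes its subexpression drop out (neutral element); a rule whose genes
are all absent yields "no data", never a fabricated value, and a strict mode
raises instead.  Partial omics coverage is the norm, so the lenient mode is
the default.

Discretization into highly/lowly expressed sets uses empirical quantiles
with linear interpolation, or absolute thresholds; when a tie would place a
reaction in both sets, high wins, keeping the sets disjoint.  Near-constant
data makes quantile thresholds coincide and is rejected with a pointer to
absolute thresholds.

## The three families

**GIMME-like.**  Step 1 computes `RMF_opt` by FBA; step 2 minimizes
`IS = Σ pᵢ·|vᵢ|` subject to `RMF(v) ≥ k·RMF_opt`.  `|v|` is realized by
splitting reversible reactions into non-negative forward/reverse columns, so
GIMME remains an LP.  The operability constraint is implemented as an
inequality (at least the stated fraction of the optimum), the standard
reading that also keeps `k = 1` feasible.  The retained set for GIMME —
above-threshold plus flux-carrying reactions — is a policy choice exposed to
the caller, since the method's raw output is a flux distribution.  GIM³E
adds one binary per reversible reaction (`y = 1` selects the forward sense:
`v_for ≤ ub·y`, `v_rev ≤ ub_rev·(1−y)`) and lower-bounds the sinks of
metabolites with evidence of synthesis at `ε`.  Infeasibility is diagnosed
per sink so the error names the offending metabolite.

**iMAT-like.**  iMAT rewards, with one binary each, `vᵢ ≥ ε` (and, for
reversible reactions, `vᵢ ≤ −ε`) for highly expressed reactions and
`vᵢ = 0` for lowly expressed ones, with big-M couplings built from the
reaction's own bounds; the objective is the number of satisfied reactions.
The classification pass re-solves the MILP twice per reaction (forced
active / forced silent) and labels it by which forcing scores higher, with
ties mapped to "undetermined" and an infeasible forcing scoring −∞.  INIT
couples an inclusion binary to activity on the split form (`ε·y ≤
v_for + v_rev ≤ M·y`) together with a direction binary per reversible
reaction — without the direction binary a futile forward+reverse pair could
fake `|v| ≥ ε` at zero net flux.  Net production enters as `Sₘ·v ≥ δ` for
supported metabolites (zero, or ≥ 0 in a relaxed mode, elsewhere).  tINIT
shares the same MILP and adds, per metabolic task, an auxiliary steady-state
flux vector confined to the retained reactions (`u ≤ ub·y`) whose task
combination must reach the task's lower bound — i.e. the *submodel admits*
the task, jointly optimized with the direction binaries.  With no tasks the
tINIT system is identical to INIT's, which makes the reduction exact.

**MBA-like.**  All three pruners guarantee a flux-consistent result.
`mba_single` scans a permutation of the non-core, tentatively removes a
reaction, and commits the removal together with the moderate-core and
non-core reactions it blocks only when no high-likelihood core reaction
blocks and `|e_M| < k·|e_Nc|`; a removal that blocks nothing is always
committed (the literal ratio test would read `0 < 0` and freeze the model,
contradicting the method's purpose).  The population run ranks all
reactions outside the high-likelihood core by occurrence across seeded
permutations, rebuilds from C_H by adding ranked reactions until the core
is unblocked, then drops any still-blocked extras — removing a blocked
reaction cannot block others, so one pass suffices.  mCADRE scores
reactions by expressed-state frequency over binarized profiles
(GPR-mapped per sample), neighborhood connectivity (mean expression score
of reactions sharing a metabolite; 0 for isolated reactions — the exact
formula is not standardized, this choice is documented here), and a
pass-through confidence level; binarization is the caller's job (a
thresholder is provided).  Removals must never block a key-metabolite
producer nor make a key metabolite unproducible (the production check runs
on the tentative submodel, which also protects sole producers), and only
negative-evidence reactions may sacrifice core reactions, under the same
ratio test.  FastCORE alternates two LPs — cardinality maximization over
the unactivated core (auxiliary `z ∈ [0, ε]`, `v ≥ z`) and genuine L1-norm
minimization over the penalized set (`−z ≤ v ≤ z`, minimize `Σz`) — and
flips the sign of reversible core columns that resist forward activation.

## Consistency checking

Three interchangeable detectors, with FVA as the exact reference:

* `find_blocked_fva` — two LPs per reaction; blocked when the interval lies
  within ±1e-6.
* `check_model_consistency_mba` — iterated maximization of the summed flux
  over unresolved reactions, then minimization over unresolved reversibles,
  with a seeded random single-reaction FVA fallback when an iteration
  resolves nothing.  The LPs run on net fluxes, not split senses, because a
  split futile pair would fake activity for blocked reversible reactions.
* `check_model_consistency_fastcore` — the sparse-mode sweep: LP-based
  cardinality activation with reversible-sense flipping and a singleton
  fallback; reactions resisting every orientation are blocked.

The same futile-pair observation applies to reversible splitting itself:
blockedness is a property of the net flux `v_for − v_rev`, so invariance of
the blocked set under splitting is asserted on net-flux ranges computed in
the split polytope, not on the split columns individually.

## Numerical choices

* Flux bounds default to ±1000 when a file omits them; unbounded FVA
  directions are reported clipped at that magnitude so intervals stay
  comparable.
* Activation threshold `ε = 1e-4` (sinks, iMAT/INIT activity, sparse
  modes); blocked classification at `1e-6`, one order below `ε`, to avoid
  boundary flapping; sparse-mode support extraction at `1e-2·ε`.
* `k = 0.9` as the default RMF fraction, `δ = 0.1` for net production —
  conventional values, always caller-settable.  No canonical numeric value
  exists for `ε`; it is exposed everywhere.
* MILP exactness: HiGHS's integrality tolerance (~1e-6) multiplied by a
  big-M of 1000 exceeds `ε`, so a binary can "leak" — e.g. a reaction
  counted as silent while carrying 1e-4 flux.  Every MILP solution is
  therefore verified by re-solving an LP with the rounded integers fixed;
  when the exact value does not reproduce the claim, the problem is
  re-solved by an exact branch-and-bound over the binaries whose leaves are
  hard-fixed LPs.  MILPs also run with presolve disabled (presolve was
  observed to lose incumbents on these systems) and a zero relative gap.
* Determinism: HiGHS with fixed options is deterministic; all sampling
  (permutations, fixtures, evidence) flows through seeded numpy generators,
  and mCADRE breaks score ties lexicographically by reaction id.
* MBA's population default is 1000 iterations (the conventional count);
  tests and the acceptance script use 10–50 iterations on toy fixtures,
  which is ample for networks of ~10 reactions.

## What the synthetic generator emulates — and what it does not

`make_toy_model` builds a linear pathway with uptake and export, parallel
detours around its middle step, and dead-end branches; the dead ends are
exactly the blocked set and the chain plus exchanges form the simulated
context.  `make_random_model` draws random 1-to-1 conversion networks in
which blocked pockets arise naturally.  Evidence draws gene intensities
from Normal(8, sd) for context-active reactions and Normal(2, sd)
otherwise, truncated at zero, with binary profiles thresholded at the
midpoint 5 — a two-population caricature of log-scale expression chosen to
make the test regime explicit, not a biological claim.

Real data differ in every inconvenient way: dense loops and cofactor
coupling, incomplete and noisy GPRs, intensity distributions without a
clean bimodal gap, partial proteome coverage.  Passing tests therefore
demonstrate algorithmic correctness (oracle equivalence, constraint
satisfaction, consistency guarantees, determinism), not recovery
performance on genome-scale data.

## Oracles

Brute-force references are exact and deliberately small: consistent-subset
enumeration (≤ 14 reactions) with an ascending-cardinality variant for
minimum supersets; iMAT pattern enumeration (≤ 10 labelled reactions,
direction-resolved); GIM³E direction-fixing enumeration (2^|Rev| LPs built
independently of the MILP code path); and cobrapy serves as an independent
FBA cross-check in one test.  Fixture sizes keep the full suite under a few
minutes on one CPU.

## Known limitations

* No thermodynamic (loopless) constraints, gap-filling, or kinetics.
* iMAT's classification pass costs two MILPs per reaction — fine at toy
  scale, expensive at genome scale.
* FastCORE is near-minimal by construction, not minimal; tests allow one
  excess reaction on random fixtures.
* `mba_single` output is order-dependent (documented nondeterminism); only
  the population-consolidated result is guaranteed consistent.
* The exact branch-and-bound fallback is designed for the small MILPs this
  package builds (tens of binaries), not for genome-scale instances.
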