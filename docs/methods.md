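# Methods

## Model

The community lives in a well-mixed chemostat with dilution rate δ.
Nutrients come in two essential, non-substitutable types — "carbon" and
"nitrogen", standing for any pair of elements required for growth — each
represented by several distinct metabolites (K carbons, M nitrogens)
supplied at constant rates φ. Every species is a specialist consuming
exactly one carbon and one nitrogen metabolite, with four traits:
competitive abilities λ^(c), λ^(n) (growth rate per unit concentration of
the respective resource) and yields Y^(c), Y^(n) (biomass per unit
resource consumed). Growth obeys Liebig's law of the minimum,
g = min(λ^(c) c, λ^(n) n), so each growing species has exactly one
limiting resource at any time; ties are measure-zero for generic traits
and are flagged rather than resolved.

A community steady state is identified by its surviving species together
with each one's limiting nutrient — abundances are not part of the label.
Two rules of competitive exclusion restrict the labels:

1. a metabolite limits at most one species;
2. every species using a metabolite non-limitingly must have a strictly
   larger λ for it than the species it limits.

Consequently a state holds at most K + M species, and the label space of
size 3^S (absent / C-limited / N-limited per species) collapses to a much
smaller set of lawful states.

## Enumeration and invadability

All lawful states are enumerated by a two-step structured search: choose
at most one C-limited species per carbon metabolite (∏(consumers+1)
selections), eliminate species out-competed on carbon, then per nitrogen
metabolite add any one admissible N-limited species or none. In the
high-supply regime (below) invadability is a pure rank-order test: an
absent species invades iff each of its two resources is either limited by
a strictly weaker competitor or not limited at all. For each C-limited
selection at most one uninvadable state exists; it is built greedily by
adding, per nitrogen metabolite, the most competitive carbon-admissible
consumer, and fails exactly when that candidate out-competes a C-limited
species sharing its nitrogen source. `enumerate_uninvadable` sweeps all
C-selections with this construction, vectorized over chunks of the
cartesian product; the scalar `construct_uninvadable` implements the same
logic readably and the two are cross-checked against each other and
against brute-force invasion testing on small pools. The brute-force
3^S stream is guarded at S ≤ 16; the structured search handles the 6×6
(36-species) scale in well under a second.

## Feasibility and structural stability

At steady state each metabolite obeys a conservation law
c_i + Σ B_α/Y_α^(c) = φ_i^(c)/δ. In the **high-supply limit**
(φ ≫ δ²/λ; with the defaults δ = 1, λ ≥ 10 and φ ≥ 10 the worst case is
δ²/λ = 0.1 ≪ 10) the concentration δ/λ of any limiting nutrient is
negligible, so a state's unknowns reduce to the K+M vector X of
abundances and non-limiting concentrations solving the linear system
φ/δ = R_p X. R_p holds inverse yields where a species consumes the row's
metabolite and a 1 on each non-limiting metabolite's own concentration
column. A state is feasible at φ iff every entry of X exceeds a
positivity tolerance of 1e-12 (guarding against round-off at feasibility
boundaries); singular R_p (possible only for non-generic yields) marks a
degenerate state, feasible at most on a measure-zero set and skipped.
An exact mode keeps the δ/λ terms on the right-hand side, which makes the
solution an exact fixed point of the ODEs — used to seed perturbation
tests and to cross-validate against integration.

Structural stability is the normalized feasible range: the fraction of
supply vectors, drawn i.i.d. uniform on [10, 1000] per metabolite, at
which the state is feasible. The default Monte-Carlo size is 1e5 samples
(binomial standard errors are reported alongside); one LU factorization
per state is reused across all samples. The classification threshold for
"structurally stable" defaults to 0.1 of supply space.

## Dynamics

The ODE system is stiff near extinction events; integration uses scipy's
BDF with rtol 1e-8 / atol 1e-10, splitting the horizon into legs and
clamping abundances below the extinction threshold (1e-9) to exactly
zero between legs (B = 0 is invariant, so extinctions are permanent).
Endpoint classification requires the maximum relative change of every
live variable over the last 10% of the window to fall below 1e-6,
then labels each surviving species with its Liebig-limiting resource.

Dynamic stability of small systems is tested operationally: start at the
exact fixed point, apply 1% multiplicative perturbations (uniform in
±1%) to the abundances of the species present and to all nutrient
concentrations, integrate (doubling the horizon on slow transients, base
60/δ), and demand return to the same state with abundances within 1e-4
relative L∞. Twenty perturbations per supply point and three supply
points are the defaults; absent species are *not* perturbed, since
susceptibility to invasion is a separate notion of (in)stability. The
Liebig minimum makes the right-hand side non-smooth, so no Jacobian
eigenvalue analysis is attempted; the perturbation test is the
definition.

## Stability inference at scale and the V/(V−1) rule

For pools whose uninvadable states are too numerous for direct testing,
stability is inferred from the Monte-Carlo feasibility pattern. Any state
that is the *unique* feasible uninvadable state at some sampled supply
must be dynamically stable (every environment needs a stable endpoint);
remaining feasible states are potentially unstable; never-feasible states
stay unknown. Empirically, V feasible stable states are accompanied by
V−1 feasible unstable ones at the same supply point. Violations of this
rule mostly indicate stable states that were never sampled as unique, and
an iterative repair reclassifies them: each step applies the single
promotion (unstable → stable) or demotion (of a previously promoted
state) that removes the most violations, stopping when no move helps.
Unique-point stable states are never demoted. The step count strictly
decreases the violation total, so the procedure terminates and is
deterministic given the report.

Residual violations can be genuine: on one random 6×6 pool a single
sample out of 1e5 carried three stable states (two of them certain) and
no feasible unstable one, and direct ODE testing confirmed the labels.
The rule is an empirical regularity of the model, not a theorem, and the
inference reports initial and final violation counts rather than forcing
zero. A property of the model worth noting: when every species has the
same stoichiometry Y^(n)/Y^(c), every sampled environment has exactly one
feasible uninvadable state and no instability — multistability requires
stoichiometric diversity (this is asserted as a test).

## Regime-shift networks

Among uninvadable dynamically stable states, a regime shift (red edge)
connects two states co-feasible at ≥ 1 sampled supply vector — crossing
the overlap produces a discontinuous, hysteretic change of composition. A
smooth transition (blue edge) connects states whose feasible ranges share
a boundary. Boundaries are probed by sampling each state's X vector
uniformly on (0,1], pushing one entry to −0.01, mapping through
φ = δ R_p X and testing which other stable states are feasible there
(1000 draws per entry by default). Pushing an abundance negative probes
extinction boundaries; pushing a non-limiting concentration negative
probes limitation-switch boundaries, which is what joins e.g. the
C-limited and N-limited states of a single species along the
φ^(n)/φ^(c) = Y^(c)/Y^(n) hyperplane. Because the feasibility sign
pattern of R_p⁻¹φ is invariant under scaling φ, boundary vectors need not
be normalized into the sampling box. Modules of the resulting network are
found by Louvain modularity maximisation (resolution 1.5, fixed seed);
greedy modularity is not unique, so module counts are approximate.

## Downstream statistics

Multistability is summarized by the per-sample count V of feasible stable
states; V−1 is fitted by a Poisson maximum-likelihood rate (its mean).
The supply balance of a sample is Σφ^(c)/Σφ^(n), binned in log space for
the balance scans. Species prevalence is the fraction of sampled
environments where the species is present in at least one feasible
uninvadable state (a stricter "present in every feasible state" variant
is emitted alongside, since either reading is defensible). Competitive
ranks order λ within each resource column (rank 1 = largest). The
yield-variation sweep holds a pool's λ (hence its uninvadable state set)
fixed and redraws all yields from nested intervals U(0.45,0.55),
U(0.3,0.7), U(0.1,0.9), U(0.01,1.0) — 1000 variants each and 1e5 supply
samples per variant by default — recording each variant's multistable
fraction against the standard deviation of log stoichiometry; the
acceptance script runs 100 variants per interval at 1e4 samples, which
resolves the same trends at desk scale. PCA of the states feasible around
a chosen environment (supply jittered ±10%) uses relative abundances
with centering only.

## Random pools and the study conditions

The generator draws full K×M grids of specialists with λ uniform on
[10, 100] and Y uniform on [0.1, 1]; ties within a resource column
(measure-zero) are redrawn, and loaded pools with ties are rejected,
since every algorithm above assumes strict rank orders. δ is not varied:
δ = 1 together with these ranges places every experiment in the
high-supply regime. A uniformly random 2×2 λ draw usually lacks the
keystone bistable switch (no four-species uninvadable state and hence no
multistability for any yields); the acceptance script therefore draws 2×2
realizations until one carries the switch and shows pilot multistability,
which is the interesting regime for that geometry — its state counts
(34 lawful states, 7 uninvadable, 1 dynamically unstable, 9 regime-shift
pairs) are determined by the rank structure alone and are reproduced
identically across such realizations.

## What the synthetic pools do and do not show

All tests run on generator-drawn pools, which capture the model's
combinatorial and dynamical structure but idealize real communities:
traits are i.i.d. with no growth-yield or λ–λ trade-offs, every species
is a strict specialist, supply is constant in time, and there is no
cross-feeding, death rate, or saturating (Monod) kinetics. Passing tests
demonstrate the correctness of the enumeration, feasibility and
stability machinery and the model's qualitative phenomenology
(bistability, hysteresis, the diversity–balance relationship), not
quantitative predictions for any particular real ecosystem.

## Numerical choices

- positivity tolerance 1e-12 for feasibility; LU factorizations cached
  per state;
- BDF, rtol 1e-8, atol 1e-10, extinction threshold 1e-9, ten legs per
  integration window;
- endpoint convergence 1e-6 relative over the trailing 10% of the
  window; stability return tolerance 1e-4 relative L∞;
- repair-loop tie-breaks by smallest state index; Louvain seed recorded;
- Monte-Carlo sizes: 1e5 supply samples by default (1e4–3e4 in fast
  tests), 1e4 per yield-sweep variant in the acceptance script, 1000
  boundary draws per X entry.
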