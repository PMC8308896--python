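# Methods

## The model

Two diploid species — a host and its parasite — co-evolve in infinite,
obligately sexual populations with non-overlapping generations.  Each
species carries two linked interaction-mediating loci `A` and `B` with two
alleles each; at every locus one allele is completely dominant, the same
way at both loci within a species.  The parasite's dominant allele is
allele 2; the host's is allele 2 under *in-phase* dominance and allele 1
under *anti-phase* dominance.  An encounter leads to infection iff the two
phenotypes match at both loci (matching-phenotype rule); otherwise the
host resists.  Fitness consequences are `ω_h = 1 − s_h` for an infected
host and `ω_p = 1 − s_p` for a parasite that fails to infect; `s_p = 1` is
obligate parasitism.  Encounters happen proportionally to class
frequencies, so the class fitnesses are

    W_h(i) = 1 − s_h · p_i ,      W_p(j) = 1 − s_p · (1 − q_j),

where `p_i` is the total frequency of parasite classes whose phenotype
matches host class `i` (its *danger frequency*) and `q_j` the total
frequency of host classes parasite class `j` can infect.  Both mean
fitnesses are tied to the same joint infection probability `Q`:
`W̄_h = 1 − s_h·Q`, `W̄_p = 1 − s_p·(1−Q)` — an identity the test suite
checks every generation.

One generation is: viability selection `a = z·W/W̄`, meiosis
`g_k = Σ a_ij P(ij→k)`, random union of gametes `z'_ij = g_i·g_j`.  Both
species' fitnesses are evaluated on the same generation-*t* state before
either advances (one parasite generation per host generation).  States are
symmetric matrices of zygote frequencies over *ordered* haplotype pairs
(8×8 for the host: 4 AB haplotypes × 2 modifier alleles; 4×4 for the
parasite), which makes random mating an outer product.

The host also carries a selectively neutral modifier locus, unlinked to
the `A–B` block, whose alleles set the recombination rate between `A` and
`B`.  "Unlinked" is implemented as independent segregation of the modifier
allele from the AB gamete, equivalent to gene order M–A–B with
`r_MA = 0.5` and no interference (the test suite holds the meiosis
operator against an exhaustive enumeration of that three-locus meiosis).
Modifier alleles interact purely co-dominantly: the genotype's rate is the
arithmetic mean of its two allele rates in the same context.

## Recombination strategies

* **constant** — rate `r` regardless of the parasite;
* **prevention** — pre-encounter, risk-proportional plasticity:
  `r = r_min + p·(r_max − r_min)` with `p` the class's danger frequency in
  the *current* generation (the same state used for fitness);
* **remediation** — post-encounter, status-conditional plasticity:
  infected hosts recombine at `r_max`, resistant ones at `r_min`.

Because infection is realized during maturation, a class carrying a
remediation allele consists, after selection, of an infected fraction
`p(1−s_h)/W` and a resistant fraction `(1−p)/W`.  The meiosis operator is
linear in the recombination rate, so this split is exactly equivalent to a
single effective rate — the share-weighted mean — which is what the
compiled kernel uses; the decomposition itself is exposed by
`strategies.resolve_policy` and verified against an explicit two-subclass
selection oracle.  Weighting infected adults by their survival `1−s_h`
(rather than treating status as independent of survival) was chosen
because gametes are produced by surviving adults; a pre-selection
weighting would count gametes of dead hosts.

## Experimental design

Strategies are compared by the modifier approach with the study's
constants: 10,000 generations of burn-in with the resident allele fixed,
injection of the competitor at frequency 0.05 in Hardy–Weinberg
proportions and linkage equilibrium with both selected loci, and 10,000
further generations.  The invader's frequency is averaged over the final
1,000 generations; it *spreads* if that mean exceeds the injection
frequency by more than δ, *fails* if it falls short by more than δ.  A
strategy is favored totally if its allele spreads while the reciprocal
invasion fails, partially if both spread (protected polymorphism).

**Choice of δ.**  Selection on the modifier is indirect and second-order:
measured tail-mean displacements after the horizon are ~1e-5 per 0.001 of
rate difference under strong selection and ~1e-8 under weak selection,
while the deterministic recursion reproduces the windowed mean to
~1e-12.  δ therefore only needs to absorb floating-point drift; the
default is δ = 1e-9, effectively the sign test "did the invader rise above
its injection frequency".  Any coarser band (e.g. 5e-3) would render every
near-optimum comparison inconclusive and no regime could ever satisfy the
ε ≤ 0.001 regularity requirement.  A deviation below 1e-12 (`freeze_tol`)
marks the invader as bit-frozen: one frozen direction counts as a
definitive failure to spread — this happens when the resident's haplotype
diversity has collapsed (typical for a no-recombination resident under
strong selection, where complementary haplotype frequencies underflow to
~1e-275 and the modifier has nothing to act on) — while *both* directions
frozen mark exact neutrality and an inconclusive comparison (e.g.
`s_h = 0`, or competing strategies that are functionally identical).

**Optimal constant rate.**  Two series of pairwise competitions climb an
integer grid of milli-rates: one from 0 upward, one from 0.5 downward,
with step schedule {0.05, 0.02, 0.008, 0.003, 0.001} — a coarse pass plus
four refinements, each restarting one previous-step inside the last
bracket.  The sought optimum is a rate favored over both lower and higher
rates, so a series advances until the incumbent rate *strictly* wins the
reciprocal test against the moving rate, walking through protected
polymorphism (coexistence) bands and neutral stretches; stopping at the
first non-win instead would truncate the climb at coexistence bands that
occur well below the optimum in rugged regimes.  Any inconclusive
comparison voids the whole search.  The two endpoints are the lower and
upper estimates of `r_opt` (they may cross by one terminal step, each
overshooting into the optimum's coexistence band; estimates are reported
sorted); the regime is *regular* when their gap ε ≤ 0.001.  If the series
diverge
further, each endpoint must be confirmed as a local optimum at 0.001
resolution (no strict improvement one step to either side); only then is
the regime recorded as *bistable*, with the two endpoints as the lower and
upper local optima.  Regimes that are regular or bistable are *usable* and
all downstream analysis of a bistable regime uses the upper optimum, which
is the well-estimated one (the lower one is typically ≅ 0 with degenerate
dynamics).  Diverged-but-unconfirmed searches are recorded as failures.

**Plasticity tests.**  For usable regimes, prevention and remediation
strategies spanning `[r_opt − Δr, r_opt + Δr]` (the *fringe*; `[0, Δr]`
when the optimum is zero; clipped to [0, 0.5]) compete against
`constant(r_opt)` for each magnitude Δr ∈ {0.001, 0.0025, 0.005, 0.01}.
Where a fringe strategy is favored, the two *one-sided* variants
(`[r_opt − Δr, r_opt]` and `[r_opt, r_opt + Δr]`) are also run; a regime
passes the two-reference test when, for some favored (form, Δr), both
one-sided variants are favored as well — the strict criterion that
isolates the benefit of plasticity per se from a shift of the mean rate.

**Sweeps.**  Regime sweeps draw `s_h, s_p ~ U(0,1)` and `r_p ~ U(0, 0.5)`
from a seeded generator, apply each triple to both dominance schemes, and
record the full search outcome and every plasticity verdict per regime;
individual failures are recorded, never fatal.  Identical seed and
configuration reproduce the output byte for byte.  Two restricted
samplers serve the focused questions: `s_p = 1` (obligate parasitism) and
`s_h·s_p < 0.1` (the weak-overall-selection region where constant
recombination is typically rejected and plasticity can act as an
evolutionary rescue).  A regime counts as *zero-optimum* when its
estimated optimum is at most 0.001, i.e. indistinguishable from zero at
the search's terminal resolution.

**Relative effects.**  The dependence of `r_opt` on the regime parameters
is summarized by OLS on z-score-standardized response and predictors:
Model A uses {s_h, s_p, r_p}, Model B {r_p, s_h·s_p}, Model C all four.
Coefficients are standardized betas; the fit reports adjusted R².

**Oscillation period.**  The period diagnostic lightly smooths an
allele-frequency trajectory (centered moving average, default window 5),
finds strict local maxima, and returns the mean peak-to-peak spacing.

## Initial conditions and numerics

The recursion starts from linkage equilibrium with allele
frequencies 0.5 at all loci, plus a deterministic excess of 0.01 on the
A1B1 haplotype of both species (renormalized) to leave the symmetric
unstable equilibrium reproducibly; the perturbation is configurable.
Exact trajectory shapes therefore match the published phase portraits
qualitatively, not point-wise (the published runs' initial conditions are
not available).  Gamete pools are renormalized every generation, so
frequency matrices stay normalized to ~1e-12 over 10,000 generations and
symmetric by construction.  The hot loop is a numba-compiled kernel with
explicit scalar arithmetic (no BLAS), bit-reproducible across runs; a
pure-numpy reference implementation of the same generation step is part of
the public API and the two are held to 1e-12 agreement in tests.  Rates in
the optimum search live on an integer milli-grid, so search points and
cache keys are exact.  Burn-in states and competition outcomes are
memoised per regime; since the dynamics are deterministic this is
observationally identical to independent recomputation.

## Problem sizes used by the test suite

Single-regime checks run at full scale (10,000 + 10,000 generations).
The sweep-level statistics are computed on seeded scaled-down samples —
120 random regimes per dominance scheme for the main sweep, 60 obligate
regimes, and 50 weak-selection regimes per scheme for the rescue analysis
— and compared with the study-scale values under binomial/standard-error
tolerances derived from those sample sizes.  At these sizes the whole
suite completes in well under half an hour on one core.

## Known limitations

* No finite-population drift, mutation, selfing, crossover interference,
  overlapping generations, or multi-generation parasite cycles.
* Two alleles per locus, complete dominance at the interaction loci, and
  purely co-dominant modifier alleles only.
* Under strong selection with very low host recombination, haplotype
  frequencies underflow double precision (~1e-275 and below); the frozen
  classification makes this regime well-defined, but the true
  infinite-precision dynamics near `r_h = 0` are not representable.
* The invasion criterion is an operational definition (the source study
  does not state one); all of its pieces (δ, window, freeze tolerance)
  are configurable.
* With the near-sign-test δ, weak-overall-selection regimes
  (`s_h·s_p < 0.3`) resolve cleanly and enter the regular set in large
  numbers, whereas the published analysis evidently lost most of them to
  its regularity filter.  Summary statistics that depend on the
  composition of that set — the regular fraction, the mean non-zero
  optimum, the favoring fractions and the additive-model R² — shift
  accordingly relative to the published values, while single-regime
  optima, the obligate-parasitism scan, the rescue and two-reference
  analyses and the product-model coefficients agree well.
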