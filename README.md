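# redqueen

A deterministic simulator for the co-evolution of a diploid host and its
diploid parasite under a matching-phenotype infection rule, built to ask
one question: **when is plastic, pathogen-inducible recombination in the
host favored over the best constant recombination rate?**

Antagonistic co-evolution drives sustained oscillations in the genetic
composition of both species (Red Queen dynamics).  Such oscillations can
select — indirectly, through linkage disequilibrium — on a neutral
*modifier* locus that sets the host's recombination rate between two
pathogen-recognition loci.  The package implements the exact
genotype-frequency recursion for this system and the full modifier
analysis around it, for researchers in evolutionary genetics who want a
reproducible, scriptable version of this class of models.

## The model in brief

Each species carries two linked diallelic loci `A`, `B` with complete
dominance (the same within a species; *in-phase* or *anti-phase* between
the species).  A parasite infects a host iff their phenotypes match at
both loci; infection costs the host `s_h`, failing to infect costs the
parasite `s_p`.  With class frequencies `h_i`, `p_j` the fitnesses are
frequency dependent:

    W_h(i) = 1 − s_h · p_i          p_i = Σ_{j matches i} p_j
    W_p(j) = 1 − s_p · (1 − q_j)    q_j = Σ_{i matched by j} h_i

and one generation is selection → meiosis → random mating,

    a_ij = z_ij W_ij / W̄ ,   g_k = Σ_ij a_ij P(ij→k) ,   z'_ij = g_i g_j ,

iterated simultaneously for both species.  The host's recombination rate
`r_h` between `A` and `B` is set by an unlinked, selectively neutral,
co-dominant modifier locus.  Modifier alleles encode strategies:

* `constant(r)` — pathogen-independent rate;
* `prevention(r_min, r_max)` — rate rises with the infection *risk*:
  `r = r_min + p·(r_max − r_min)`;
* `remediation(r_min, r_max)` — rate conditioned on the infection *fact*:
  `r_max` if infected, `r_min` if resistant.

Competitions between modifier alleles (burn-in, low-frequency injection,
reciprocal invasion) decide which strategy is favored; a two-sided search
over constant rates finds the optimal `r_opt`; sweeps over random
regimes `(s_h, s_p, r_p, dominance)` map where plasticity wins.

## Worked example

The extreme-selection regime (`s_h = 0.98`, `s_p = 0.995`, anti-phase
dominance, `r_p = 0.3`):

```python
from redqueen import Dominance, Regime, Strategy, initial_state, run
from redqueen.experiments import Runner, estimate_period

regime = Regime(s_h=0.98, s_p=0.995, r_p=0.3, dominance=Dominance.ANTI_PHASE)
runner = Runner(regime)

search = runner.find_optimal_constant_rate()
print(search.r_opt, search.eps, search.regular)

_, trace = run(initial_state(), regime, Strategy.constant(search.r_opt),
               None, 10_000)
print(estimate_period(trace[-2000:, 0]))

print(runner.test_plasticity(search.r_opt, 0.0025, "prevention").value)
```

prints

```
0.322 0.001 True
27.690140845070424
favored_totally
```

The two search series bracket the optimal constant host recombination
rate between 0.321 and 0.322 (a high optimum — strong antagonistic
selection maintains large-amplitude oscillations that favor substantial
recombination); the host allele-frequency oscillation at that optimum has
a ~28-generation period; and risk-proportional (prevention) plasticity of
magnitude Δr = 0.0025 around the optimum invades and expels the optimal
constant strategy.

The same analyses run from the shell:

```bash
redqueen optimal-rate --s-h 0.98 --s-p 0.995 --r-p 0.3 \
    --dominance anti_phase -o opt.json
redqueen sweep -n 100 --seed 1 -o sweep.csv
redqueen regress sweep.csv --dominance in_phase -o table.csv
redqueen magnitude-scan sweep.csv -o scan.csv
```

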