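# locuspair

Population-genetic analysis of *locus-pair* resequencing studies: paired
short gene segments (A and B, a known physical distance apart) directly
sequenced in diploid individuals of one or two closely related species.
The package was built around a two-willow study design (*Salix
viminalis* / *S. schwerinii*: 18 nuclear genes, ~150–900 analyzed bp per
segment, 24 diploids per species) but the machinery is generic.

It covers the full analysis path:

* **alignment IO** — FASTA in, IUPAC-ambiguity diploid consensus expanded
  to haplotypes, complete-deletion site filtering;
* **diversity** — S and singletons, Watterson's θ_W = S/(a₁L), π,
  Tajima's D, haplotype number/diversity, synonymous/nonsynonymous sites
  and diversity by Nei–Gojobori pathway counting;
* **divergence** — shared/fixed/private polymorphism classification,
  Hudson's F_ST = 1 − H_w/H_b with a 10,000-permutation significance
  test, exact Hardy–Weinberg tests per SNP;
* **LD** — pairwise r² with Fisher/Bonferroni significance and a
  nonlinear least-squares fit of the Hill–Weir expectation
  E[r²](C = ρ·d) yielding the population recombination rate ρ per bp;
* **coalescent simulation** — an ms-style simulator (infinite sites,
  intra-locus recombination; θ = 4N₀μ, ρ = 4N₀r per site, time in 4N₀
  generations) under neutral, exponential-growth, bottleneck and
  two-population-split (± migration) demographies;
* **ABC inference** — `DemographicABC` / `ABCResults`: prior sampling,
  summary statistics, MAD-standardized Euclidean rejection at proportion
  P_δ, local-linear (or FFNN) regression adjustment, multinomial-logistic
  model probabilities, posterior modes with 95% credible intervals, and
  conversions N_e = θ/4μg and t_years = t_s·4N_e·g;
* **model validation** — posterior predictive tail probabilities,
  outlier-locus flags, and two-component PCA envelopes per model;
* **synthetic data** — a generator that emulates the full study design so
  the whole pipeline runs with no external data.

## Worked example

Generate a synthetic single-species study, estimate its diversity, and
fit the neutral model by ABC:

```bash
locuspair synth --out demo --single-species --theta 0.003 --rho 0.007 \
    --genes 6 --diploids 12 --seed 1
locuspair stats --data demo --species schwerinii --out demo/stats.tsv
locuspair abc-fit --data demo --species schwerinii \
    --models neutral --models growth \
    --draws 4000 --p-delta 0.02 --seed 1 --out demo/abc.txt
```

`demo/stats.tsv` holds one row per segment in the familiar table layout
(θ and π printed ×10³); the first rows of this run are

```
segment  n   L    S_singleton  theta_e3  pi_e3  Nh  He     D
G01A     24  584  7 (1)        3.21      4.39   11  0.891  1.15
G01B     24  607  6 (2)        2.65      2.27   9   0.844  -0.43
```

meaning, for G01A: 24 haplotypes, 584 analyzed sites, 7 segregating sites
of which 1 singleton, θ_W = 0.0032 and π = 0.0044 per site, 11 distinct
haplotypes, haplotype diversity 0.89, Tajima's D 1.15 (not significant).
The ABC report gives, per model, the posterior mode and 95% credible
interval of each parameter and the posterior model probability; this run
prints

```
Model: neutral   P = 0.53 (rejection estimate 0.56)
     theta: 0.002176 (0.001016-0.002903)
       rho: 0.07825 (0.008712-0.7308)
```

— the generating model (neutral) edges out growth.  The interval for θ
ends just below the generating 0.003: six loci and 4,000 draws make a
deliberately small demo, and ρ is only weakly identified at this size.
The full-scale recovery study (14 loci, 10⁵ draws) run by the test suite
covers the generating θ in at least 18 of 20 repetitions.  In library
code the
same fit is three lines: build `DemographicABC(loci, models, specs)`,
call `.fit(n_draws=..., seed=...)`, and read `.summary()`,
`.posterior_summary(model, param)` or `.ppc_report(model)` off the
results object.

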