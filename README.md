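# longimap

Multipoint linkage-disequilibrium mapping of disease loci from longitudinal
nuclear-family (trio) data.

`longimap` is for statistical geneticists analyzing family studies with a
binary trait measured at repeated visits (the motivating application is
hypertension in nuclear families).  Instead of testing markers one at a
time, it estimates the *map position* τ of an untyped disease locus inside
a gene region — with a standard error and 95% confidence interval — and the
locus's *genetic effect* C, using the preferential transmission of marker
alleles from parents to offspring at every marker, every visit, and every
family simultaneously.

## The model

For each trio, marker, and visit, a transmission statistic is scored per
parental side: +1 if the target allele H was transmitted and the nontarget
allele h retained, −1 for the reverse, 0 if the parent is homozygous (the
sign is reversed for unaffected offspring).  The paternal and maternal
statistics sum to Z for the offspring.  Under a single disease variant at
position τ that arose N generations ago, the expected one-side statistic at
a marker located t is

    μ₁(t) = (1 − 2θ) · C · (1 − θ)^N · π      (affected offspring)
    μ₂(t) = (1 − 2θ) · C* · (1 − θ)^N · π     (unaffected offspring)

where θ = θ(|t − τ|) is the recombination fraction from a map function
(Haldane by default), π is the frequency of h on non-disease haplotypes
(estimated from nontransmitted parental alleles), and C = E[Y_T(τ) | affected]
is the transmission distortion at the disease locus itself.  The parameter
vector δ = (τ, N, C, C*) solves the stacked estimating equations

    S(δ) = Σ_families Σ_visits Σ_offspring (∂μ/∂δ)ᵀ Cov⁻¹(Z) {Z − 2μ} = 0

and the sandwich estimator A⁻¹BA⁻ᵀ with families as independent clusters
provides standard errors that respect sibling, visit, and marker
correlation.  A longitudinal binary trait enters through four phenotype
constructions — **ever**, **progression** (incident cases), **baseline**,
and **longitudinal** (all visits) — so the efficiency gained from repeated
measurements can be compared directly.

## Worked example

Simulate a 20-marker, 2-cM gene region with a rare recessive-leaning
variant (frequency 0.05, N = 50 generations old, transmission distortion
C = 0.6) at the region midpoint, ascertain 600 affected and 600 unaffected
trios, and fit:

```python
from longimap.simulate import recovery_config, simulate_dataset

sim = simulate_dataset(recovery_config(), 1)
fit = sim.analyze("baseline")
print(f"tau_hat = {fit.params.tau:.4f} cM  (SE {fit.se_tau:.4f}, "
      f"95% CI {fit.ci_tau_95[0]:.4f}-{fit.ci_tau_95[1]:.4f})")
print(f"C_hat   = {fit.params.c_eff:.3f}  (SE {fit.se_c:.3f}, "
      f"Wald p = {fit.p_value_c:.2e})")
print(f"N_hat   = {fit.params.n_gen:.1f} generations; converged = {fit.converged}")
```

prints

```
tau_hat = 1.0212 cM  (SE 0.0205, 95% CI 0.9811-1.0613)
C_hat   = 0.670  (SE 0.015, Wald p = 0.00e+00)
N_hat   = 54.4 generations; converged = True
```

The disease locus (simulated at 1.0 cM but withheld from the marker panel)
is localized to within ~0.02 cM; the genetic effect is estimated near its
true value of 0.6 (the small upward shift is the expected plug-in bias of
π̂ under case ascertainment, see `docs/methods.md`) and is overwhelmingly
significant.

### Command line

The same pipeline runs from the shell on PLINK PED/MAP files, a visit
table, and a gene annotation table:

```bash
longimap fixture longitudinal-demo --out-dir demo/
longimap fit --ped demo/longitudinal_demo.ped --map demo/longitudinal_demo.map \
    --visits demo/longitudinal_demo.visits.tsv --genes demo/longitudinal_demo.genes.tsv \
    --phenotype ever --out results.tsv
longimap compare --ped ... --out comparison.tsv   # all four schemes side by side
```

`longimap fit` writes one row per gene (τ̂, SE, Ĉ, SE, Wald p, convergence)
and logs the Bonferroni threshold over the genes fit; `longimap compare`
reports SE(τ̂) per scheme and the fraction of genes where the longitudinal
analysis is more precise than baseline-only.  `longimap qc` runs the exact
Hardy–Weinberg founder filter on its own, and `longimap simulate` generates
synthetic datasets from a YAML config.

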