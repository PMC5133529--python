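# Methods

## Model and estimating equations

`longimap` implements multipoint linkage-disequilibrium mapping for
nuclear-family trio data with a longitudinal binary phenotype.  The data
unit is an offspring–visit pair.  At each biallelic marker with designated
target allele H (nontarget h), each resolvable parental side contributes a
preferential-transmission statistic: for an affected offspring +1 if H was
transmitted and h retained, −1 for the reverse, 0 for a homozygous parent;
for an unaffected offspring the coding is sign-reversed.  Z is the sum of
the two sides.

The model assumes a single disease variant at map position τ (cM) that
entered the population N generations ago on one founder haplotype.  Its
expected one-side statistic at marker position t is

    μ_c(t) = (1 − 2θ) · coef_c · (1 − θ)^N · π_j,

with coef = C for the affected class and C* for the unaffected class,
θ the recombination fraction between t and τ, and π_j the probability of
the nontarget allele on a non-disease haplotype.  (1 − 2θ) accounts for
the one observed parent-to-offspring meiosis; (1 − θ)^N is the decay of
the ancestral haplotype over N generations; both use the same map
function.  C is the transmission distortion at the disease locus itself
for affected offspring — the primary effect measure — and C* its
(typically small, opposite-signed) unaffected-offspring counterpart.

δ = (τ, N, C, C*) solves the stacked estimating equations: each
offspring–visit row contributes (∂μ/∂δ)ᵀ W {Z − m∘μ}, summed over classes,
visits, and families, where W is the inverse of a working covariance of
the Z rows and m ∈ {0, 1, 2} counts resolvable parental sides per entry
(entries with m = 0 are dropped together with the matching rows/columns of
W; rows with one informative parent use μ instead of 2μ).  Only the mean
structure must be correct for consistency; the working covariance affects
efficiency only.

π_j is plugged in once per gene as the frequency of h among nontransmitted
parental alleles (both parents, all trios, resolvable sides), with the
overall parental h frequency as a fallback for markers with no resolvable
transmission.  Its sampling variability is ignored in the variance
estimator, matching the plug-in form of the equations.

## Tunable parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| map function | θ from map distance | Haldane | no-interference standard; makes (1−θ)^N exponential in distance; Kosambi available |
| τ box | scanned interval | [t₁, t_M] of the gene | the estimand is defined within the region |
| N box | decay-rate range | [1, 500] | N is a nuisance decay rate, not a literal generation count |
| N₀ | grid-stage N | 20 | geometric midpoint of the N box |
| HWE α | founder filter | 1e-4 | conventional family-GWAS threshold |
| shrinkage λ | Cov(Z) regularization | smallest in {0, 0.05, …} with cond < 1e8 | genes can have more markers than informative rows |
| convergence | ‖Δδ‖∞ | 1e-6 (≤100 iterations) | τ is reported to ~1e-4 cM |

## Numerical design

**Working covariance.**  Per affection class, the pooled empirical
covariance of Z rows (pairwise-complete over missing entries), floored on
degenerate variances, then shrunk toward its diagonal just enough to be
positive-definite with condition number below 1e8.  All-missing marker
columns receive inert unit-diagonal placeholders that no missingness
pattern ever touches.

**Sufficient statistics.**  Rows are grouped by missingness pattern and
the covariance sub-block inverse of each pattern is cached; the entire
estimating function then reduces to S_c = D_c (ṽ_c − coef·K_c g), two small
matrix products per class, which makes the profile grid and Newton
iterations essentially free and lets the test suite run hundreds of
replicate fits.

**Solver.**  The τ surface is piecewise-smooth with knots at marker
positions (|t − τ| is not differentiable there, and the τ-component of S
jumps sign across a knot).  The solver (i) profiles over a τ grid — every
marker position plus 10 interior points per interval, at N₀ — solving
(C, C*) in closed form and scoring by ‖S‖², ties broken toward the
leftmost τ; (ii) refines with a damped Newton iteration (numeric Jacobian,
affine-invariant backtracking, box projection); (iii) recognizes *kink
roots*: if the iteration stalls, and the profile GLS objective
Σ rows (Z − m∘μ)ᵀW(Z − m∘μ) has a one-sided local minimum at the nearest
marker knot or region bound, τ is pinned there and the reduced system is
solved in the remaining parameters.  Derivative stencils near knots are
one-sided, taken on the side away from the knot.  Fits where every
affected-class statistic is zero are flagged non-identifiable rather than
fit.

**Sandwich variance.**  A = ∂S/∂δ at δ̂ (numeric, knot-aware); B = Σᵢ SᵢSᵢᵀ
over per-family contributions, so siblings and repeat visits stay inside
their family's block.  The system is diagonally equilibrated before
inversion; condition numbers above 1e12 yield "SE not estimable".  The
95% CI for τ is τ̂ ± 1.96·SE and the genetic effect is tested by the
two-sided Wald statistic Ĉ/SE(Ĉ).  At kink roots the locally computed
SE(τ̂) can be very small — the position is pinned by a sign change rather
than a smooth slope — which matches the characteristically tiny position
SEs this class of multipoint estimators reports on real data.

**Gene scan.**  Markers are assigned to genes by cM-interval overlap;
genes with fewer than two markers are skipped; the family-wise threshold
is 0.05 Bonferroni-divided by the number of genes actually fit.

## Phenotype constructions

From per-visit binary statuses: **ever** (affected at any visit; requires
at least two non-missing visits so its eligible set is comparable with
progression), **progression** (prevalent cases — affected at the first
non-missing visit — are excluded; affected means converting later),
**baseline** (first non-missing visit), **longitudinal** (all visits, one
analysis row per non-missing visit).  Prevalent cases are *excluded* from
progression rather than recoded unaffected: with recoding the progression
cohort would equal the ever cohort, whereas excluding them matches the
strictly smaller progression cohort observed in longitudinal family
studies of this design.  "Unaffected" under ever/progression requires
being unaffected at every non-missing visit.

## Synthetic data generator

The generator mirrors the model's own premises so that estimator
calibration can be measured against known truth:

* one founder haplotype carries the disease allele and the target allele
  at every marker (complete initial LD); each of N generations it
  recombines against a background haplotype (independent per-interval
  crossovers, Haldane), keeping the τ-carrying recombinant, which induces
  Pr[H(t) | disease] decaying toward background exactly as (1 − θ)^N;
* background haplotypes sit at the background target frequency (0.2) in
  linkage equilibrium;
* parents draw haplotypes at disease-allele frequency p; offspring receive
  one further recombined haplotype per parent; the disease-locus column is
  withheld from the marker panel and written to the truth record;
* the phenotype is an absorbing incidence process: visit-1 status from the
  penetrance of the offspring's disease genotype, later visits convert
  unaffected → affected with a genotype-dependent hazard, affected is
  absorbing, and optional dropout is absorbing missingness.  The monotone
  structure makes all four phenotype schemes derivable from one dataset.

The effect size is controlled exactly: the heterozygote penetrance is
solved (by enumeration of parental genotypes and transmissions) so that
E[Y_T(τ) | affected] equals the requested C.  Under the default recovery
setting, C = 0.6 with p = 0.05, f₀ = 0, f₂ = 1.

**Why the disease variant is rare.**  The plug-in π̂ uses nontransmitted
parental alleles as a stand-in for non-disease haplotypes.  In an
affected-enriched sample a fraction w of nontransmitted haplotypes are
themselves disease haplotypes, so near τ, π̂ ≈ π(1 − w): with a common
variant this deflates π̂ and inflates Ĉ by construction.  With p = 0.05
and balanced case/control ascertainment the residual inflation of Ĉ is
about +0.07 (observed mean Ĉ ≈ 0.67 for C = 0.6), while τ̂ is essentially
unbiased and its CI coverage is nominal.

**Calibration settings** (encoded as config factories and used by the test
suite at these sizes, chosen to keep hundreds of replicates cheap while
leaving Monte-Carlo error well inside the tested margins):

* *recovery*: 20 markers / 2 cM, τ at 1.0 cM, N = 50, C = 0.6, 600
  affected + 600 unaffected trios (ascertained; marker haplotypes are
  generated only for sampled trios, conditional on the disease-locus
  alleles — exact, since marker content is independent of affection given
  those).  200 replicates: τ̂ within 3·SE of truth ≈ 95%, 95% CI coverage
  ≈ 93–95%.
* *null*: flat penetrances (0.25), 10 markers, 200 + 200 trios; the Wald
  test for C rejects at the 5% level in ≈ 3–5% of replicates (slightly
  conservative).
* *longitudinal efficiency*: p = 0.1, penetrances (0.02, 0.5, 0.95),
  4 visits with conversion hazards (0.04, 0.6, 0.95), 800 families —
  a persistent (stationary) genetic effect on incidence, with per-visit
  affected fractions rising ≈ 0.10 → 0.25 as in the motivating cohort.
  The longitudinal analysis's median SE(τ̂) is smaller than baseline-only's
  on the same data, and smaller per-gene in roughly 60–78% of replicates.
  If instead later-visit conversions are dominated by phenocopies (a weak
  genotype–incidence link), repeats carry little association information
  and the longitudinal gain disappears — the comparison is a statement
  about persistent genetic effects, not about repeated measurement per se.

**What the generator does not emulate:** background LD between markers
(background haplotypes are in linkage equilibrium, so real gene regions
with strong inter-marker LD will show more correlated Z columns than the
tests exercise), allelic heterogeneity (a single founder variant is
assumed, as in the model), genotyping error beyond what the Mendelian
screen can see, covariates, and informative dropout.  Passing tests
demonstrate calibration under the model's own assumptions, not robustness
to their violation.

## Known limitations

* Under the null (C = 0), τ and N are unidentified; τ̂ is then arbitrary
  within the region and many null fits legitimately end non-converged or
  pinned at a bound.  The Wald test for C remains approximately calibrated
  (slightly conservative) because its variance is computed at whatever
  point the solver reports.
* Kink-root SEs for τ reflect the local sign-change pinning and can
  understate replicate-to-replicate variability when the signal is weak;
  CI coverage statements in the tests apply to the identified
  (clear-signal) regime.
* The common C across visits is a working assumption; when the true
  per-visit distortion varies strongly, the longitudinal Ĉ is an
  attenuated average.
* Covariate adjustment, X-linked markers, multiallelic markers, and
  likelihood-based genotyping-error detection are out of scope; extended
  pedigrees must be split into nuclear families upstream.
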