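# Methods

## Demographic factors from census data

The census is a site × year table of plant counts. A site is *occupied* in
a year if its count is ≥ 1; a single unoccupied year is treated as an
extinction, and later occupancy as a recolonisation. Recolonisation from a
seed bank is not distinguished from recolonisation by immigrants — both
are assumed to pass through a comparable founder bottleneck.

* **Age** is the length of the run of consecutive occupied years ending at
  the reference (collection) year, inclusive, so a first-year colonist has
  age 1 and a site occupied for the whole of a 21-year census has age 21.
  Requesting the age of a site unoccupied at the reference year is an
  error, not zero.
* **Harmonic mean size** is k / Σ 1/N<sub>t</sub> over the k occupied
  years across the *full* census period, not just the current
  post-recolonisation run. Zero-count years are excluded (they would make
  the harmonic mean undefined); the harmonic mean is the
  effective-size-relevant average and is always ≤ the arithmetic mean.
* **Connectivity** S<sub>i</sub> = Σ<sub>j≠i, extant</sub> w<sub>j</sub>
  exp(−α d<sub>ij</sub>). "Extant" means occupied in the reference year.
  Two weightings are computed: occupancy proportion (fraction of census
  years occupied, S<sub>t</sub>) and harmonic mean size (S<sub>s</sub>);
  the weight vector is also user-suppliable for other conventions (e.g. a
  lifetime plant total). Distances are shortest paths on a user-supplied
  road network (or an explicit matrix); disconnected pairs get infinite
  distance and a warning, contributing zero to connectivity.

**The dispersal scale α** (units 1/m) has no canonical value; the default
is 0.05 m⁻¹ ≈ 1/20 m, motivated by field evidence in the target system
that populations 20 m apart are nearly panmictic while 80 m apart are
nearly isolated. Every feature table records the α used. Connectivity is
non-increasing in α; α = 0 degenerates to the plain sum of weights.

## Diversity statistics

Populations are weighted equally throughout. Per locus: H<sub>O</sub> is
the fraction of heterozygous individuals averaged over populations;
H<sub>S</sub> is the mean of the unbiased within-population gene diversity
(1 − Σp²)·n/(n−1) with n gene copies; H<sub>T</sub> = 1 − Σp̄² +
H<sub>S</sub>/(ñ·s) with ñ the harmonic mean gene-copy count and s the
number of populations (Nei & Chesser small-sample correction); F<sub>ST</sub>
is the G<sub>ST</sub> form (H<sub>T</sub> − H<sub>S</sub>)/H<sub>T</sub>
per locus and a ratio of across-locus sums overall; Jost's D is
[(H<sub>T</sub> − H<sub>S</sub>)/(1 − H<sub>S</sub>)]·s/(s−1), reported
overall both as the across-locus mean and as a sums ratio (both conventions
circulate). Negative estimates — possible by sampling noise under unbiased
estimators — are floored at 0. Individuals missing at a locus are excluded
from that locus only; populations with fewer than 2 gene copies at a locus
are dropped from that locus with a warning. Other programs use related but
not identical estimators (e.g. Weir–Cockerham); exact numerical agreement
with them is not claimed.

Rarefied allelic richness uses the exact combinatorial form
Σ<sub>a</sub>[1 − C(N−N<sub>a</sub>, g)/C(N, g)], evaluated in log space;
the default depth g is the smallest per-population per-locus gene-copy
count, so all populations are comparable.

## The hierarchical F-model

The likelihood is the Dirichlet-multinomial (Pólya) distribution obtained
by integrating the Balding–Nichols population frequencies out of the
multinomial sample: counts **n** at one population-locus have

log P = log C(n; **n**) + log Γ(θ) − log Γ(θ+n) +
Σ<sub>a</sub>[log Γ(θp<sub>a</sub>+n<sub>a</sub>) − log Γ(θp<sub>a</sub>)].

Monomorphic loci contribute exactly zero and are retained. As θ → ∞ the
distribution converges to the multinomial at **p**; small θ drives
populations toward fixation.

Regression layer: y<sub>j</sub> = logit F<sub>ST,j</sub> = −ln θ<sub>j</sub>
~ N(α₀ + Σ m<sub>g</sub>β<sub>g</sub>G<sub>jg</sub>, σ²). Factor columns
are standardized to mean 0, sd 1 before fitting and coefficients are
reported on that scale (raw-scale back-transformation is available via the
recorded means/sds). Correlated factors are handled explicitly by
factor-subset runs (`FactorMatrix.subset`), not silent pruning.

Priors: flat Dirichlet(1,…,1) on each **p**<sub>i</sub>; α₀, β<sub>g</sub>
~ N(0, τ² = 10); σ² ~ inverse-gamma(2, 1); uniform over the 2<sup>G</sup>
models. All configurable.

### Sampler

One sweep updates, in order: (1) every y<sub>j</sub> by Gaussian random
walk (coordinate-wise Metropolis; the Dirichlet-multinomial factorises over
populations given **p**); (2) every locus's **p**<sub>i</sub> by a
Dirichlet proposal centred on the current value (concentration c·p + 0.5;
the 0.5 shift keeps proposal parameters off zero; degenerate draws ≤ 1e−12
are replaced by a no-op); (3) (α₀, β<sub>m</sub>) and σ² by Gibbs
(normal/inverse-gamma conjugacy on the y scale); (4) one reversible jump:
a uniformly chosen factor is added with a coefficient drawn from a
pilot-tuned Normal proposal, or removed, with the standard
birth/death acceptance ratio (uniform model prior cancels). Zero-count
cells contribute nothing to the likelihood, so the implementation stores
only nonzero (population, locus, allele) cells and forms per-population and
per-locus sums with `bincount`.

Pilot phase: 10 runs of 1000 iterations under the full model adapt the
random-walk scales and the Dirichlet concentrations toward ~30% acceptance
(multiplicative update, factor clipped to [0.5, 2] per round); the second
half of the pilot iterations also collects β samples whose mean and
1.5 × sd parameterise the reversible-jump proposals. Pilots ending outside
a 10–60% acceptance band trigger a warning with the observed rates —
advisory, not fatal.

Schedules: the *desk* preset (default) is 10 × 1000 pilots, 10,000 burn-in,
thinning 10, 5,000 retained (≈ half a minute for 33 populations × 8 loci on
one core); the *paper* preset (5 × 10⁶ burn-in, thinning 50, 60,000
retained) reproduces the published schedule of the original software and
takes hours. Tests and the reproduction script use the desk preset; the
problem sizes they run (33 populations, 8 loci, ~20 diploids per
population, 20 replicates) are the study's own dimensions.

### Posterior summaries

Model probabilities are exact empirical visit frequencies (they sum to 1 by
construction); their Monte-Carlo standard errors come from 25-batch means
of the thinned indicator series. HPDIs are the shortest contiguous
interval containing ⌈level·n⌉ sorted samples (≥ 100 samples required).
Posterior modes are the argmax of a Silverman-bandwidth Gaussian KDE on a
512-point grid — mode values from other software depend on the analogous
convention and are comparable only approximately. Coefficient summaries
are conditional on the factor being included; a factor included in fewer
than 100 retained samples reports NaN rather than a meaningless interval.
Convergence diagnostics (acceptance rates, logit-F_ST plots) are emitted
but advisory.

## Synthetic data

The generator emulates the statistical structure the F-model assumes, with
full ground truth recorded: census occupancy flips by independent annual
Bernoulli extinction (default 0.1) and colonisation (default 0.1) events —
the target system's observed 5–20% annual turnover band — with
shifted-Poisson (≥ 1) counts for occupied sites; sites sit on a
jittered-spacing line network (roadside habitat); factors come from the
same feature extraction as real data; logit F<sub>ST</sub> is linear in the
standardized factors plus N(0, σ²) noise; genotypes are Balding–Nichols
draws (ancestral frequencies flat-Dirichlet, population frequencies
Dirichlet(θ<sub>j</sub>**p**<sub>i</sub>), individuals random unions of two
gene copies). Default dimensions mirror the study: 33 populations, 8 loci,
22 diploids per population (≈ 730 plants), 21 census years; default
α₀ = −2.2 puts F<sub>ST</sub> near 0.1, the study's global scale.

What the generator does *not* emulate: genotyping artefacts (null alleles,
allele-binning error), linkage, selection and heterosis, seed-bank
genetics, source-sink colonisation pedigrees (a forward founder-effect mode
exists as a demonstration only), and spatially autocorrelated dispersal
beyond the line-network geometry. Passing recovery tests therefore shows
the estimator is correct *under its own assumptions* — not that those
assumptions hold in any particular field system.

## Numerical choices and degenerate inputs

* Likelihood evaluation is exact via log-gamma; no approximations.
* The inclusion floor (default 4 sampled plants) excludes populations whose
  allele frequencies cannot be estimated; excluding every population is a
  hard error.
* Monomorphic loci: retained, zero log-likelihood contribution; reported as
  missing in per-locus F_ST (0/0).
* Tie-breaks: the HPDI window search takes the first minimal-width window
  of the sorted sample; model enumeration orders subsets by size then
  lexicographically (null first, full model last).
* Determinism: every stochastic component takes a seed and uses an
  independent `numpy` Generator; identical seeds give byte-identical
  serialized outputs.

## Validation strategy

Fast implementations are checked against deliberately naive references
(`metafst.validate`): Pólya-urn sequence enumeration for the likelihood
(all count vectors with n ≤ 4, K ≤ 3, plus normalization over outcomes),
exhaustive subsampling for rarefaction (all tensors with ≤ 6 copies), and,
for the sampler itself, a 2-population × 1-locus × 2-allele × 1-factor
instance whose model probabilities are computed by dense numerical
quadrature (regression coefficients integrated analytically given σ²; σ²
by Gauss–Legendre on the log scale against its prior; p and the two logit
differentiations on wide Gauss–Legendre grids — the grid is converged to
~1e−7). The generator and the fitter are additionally checked as a
calibrated pair: 95% HPDIs must cover generating coefficients in ≥ 80% of
20 replicates, and coefficient signs must be recovered in ≥ 18 of 20.

## Known limitations

* The Dirichlet-multinomial convention matches the hierarchical F-model
  literature; programs using Weir–Cockerham-style estimators will differ
  numerically, especially at small sample sizes.
* Reversible-jump mixing depends on the pilot-tuned proposals; severe
  factor collinearity can slow model-space mixing (use factor-subset runs).
* The desk preset trades Monte-Carlo error for speed; for publication-grade
  intervals use the paper preset and check batch-mean standard errors.
* Census-derived ages are right-censored by the census span (a site
  occupied throughout a 21-year census has "age 21" but may be older).
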