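# metafst

**What drives genetic differentiation in a metapopulation?** In systems of
small, patchily distributed populations linked by dispersal and subject to
extinction–recolonisation turnover, a population's differentiation from the
rest of the system reflects its demographic history: founder effects at
colonisation, drift in small demes, and erosion of both by migration as the
population ages. `metafst` is a Python library for quantifying these
effects. It is written for population geneticists and ecologists who hold
two kinds of data on the same set of populations: a long-term census
(per-site annual counts plus inter-site distances) and codominant
multi-locus genotypes (e.g. microsatellites in GenePop format).

## The model

Each population *j* receives its own differentiation parameter. At locus
*i* with ancestral allele frequencies **p**<sub>i</sub>, the allele counts
sampled from population *j* follow a Dirichlet-multinomial (Pólya)
distribution with parameters θ<sub>j</sub>**p**<sub>i</sub>, the
Balding–Nichols construction, so that

&nbsp;&nbsp;&nbsp;&nbsp;F<sub>ST,j</sub> = 1 / (1 + θ<sub>j</sub>).

A regression layer ties differentiation to demographic factors on the logit
scale:

&nbsp;&nbsp;&nbsp;&nbsp;ln(F<sub>ST,j</sub> / (1 − F<sub>ST,j</sub>)) ~
Normal(α₀ + Σ<sub>g</sub> m<sub>g</sub> β<sub>g</sub> G<sub>jg</sub>, σ²),

where G<sub>jg</sub> are standardized factors and **m** ∈ {0,1}<sup>G</sup>
is a model indicator ranging over all 2<sup>G</sup> factor subsets. A
reversible-jump MCMC samples jointly over ancestral frequencies, θ, the
regression parameters and **m**; posterior model probabilities are the
chain's visit frequencies, and per-factor importances are sums of the
probabilities of models containing each factor.

The demographic factors themselves are derived from the census:

* **age** — consecutive occupied years up to the collection year (a single
  empty year counts as extinction and resets the clock);
* **harmonic mean size** — harmonic mean of the yearly plant counts over
  occupied years;
* **connectivity** — S<sub>i</sub> = Σ<sub>j≠i</sub> w<sub>j</sub>
  exp(−α d<sub>ij</sub>) over extant source populations, with the source
  weight w<sub>j</sub> either the proportion of census years occupied
  (S<sub>t</sub>) or the long-term size (S<sub>s</sub>), and d<sub>ij</sub>
  a road-network shortest-path distance.

Classical summaries (H<sub>O</sub>, H<sub>S</sub>, H<sub>T</sub>,
G<sub>ST</sub>-style F<sub>ST</sub>, Jost's D, rarefied allelic richness)
and a synthetic-data generator with recorded ground truth round out the
package.

## Worked example

```python
from metafst import (BundleConfig, FModelConfig, make_recovery_bundle,
                     mcmc_run, tally_counts)

bundle = make_recovery_bundle(
    BundleConfig(n_populations=33, n_loci=8, diploids_per_pop=20), seed=7)
counts = tally_counts(bundle.genotypes)
post = mcmc_run(counts, bundle.factors,
                FModelConfig(seed=1, pilot_runs=5, pilot_length=500,
                             burn_in=3000, thinning=5, retained=2000))
print(post.model_probs()[["label", "probability"]])
print(post.coefficient_summary().round(3))
```

prints (the bundle was generated with α₀ = −2.2, β = (−0.5, +0.3),
σ² = 0.1 on standardized age and harmonic size):

```
                         label  probability
                      constant        0.000
      constant + harmonic_size        0.000
                constant + age        0.307
constant + age + harmonic_size        0.693

               inclusion   mean   mode  hpdi_low  hpdi_high
constant           1.000 -2.131 -2.143    -2.344     -1.914
age                1.000 -0.644 -0.640    -0.889     -0.427
harmonic_size      0.693  0.317  0.347     0.120      0.536
```

The chain concentrates on models containing age, the age coefficient is
negative (older populations are less differentiated — founder effects fade)
and both 95% highest-posterior-density intervals cover the generating
coefficients. More narrative walkthroughs live in `examples/`:
census-derived factors, diversity summaries, F-model fitting, and the
packaged 33-population study table.

A thin CLI mirrors the library (`metafst simulate | features | stats | fit |
correlations | reproduce`).

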