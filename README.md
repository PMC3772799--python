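# islandrad

Analyses of island radiations on time-calibrated phylogenies: contrasting
diversification tempo between clades, building molecular-clock calibrations
from island ages and COI divergence rates, and reconstructing ancestral
geographic ranges under the Dispersal-Extinction-Cladogenesis (DEC) model —
including its time-stratified variant, in which an island cannot be occupied
before it emerges.

The package is aimed at phylogeneticists working on hotspot archipelagos
(the running example is the five high Hawaiian islands: Kauai, Oahu,
Molokai, Maui, Hawaii), where chronograms, island emergence ages, and
presence/absence range tables are the standard raw materials. Every stage
can also be exercised on truth-known synthetic data generated by the
package itself, so nothing needs to be downloaded.

## What it computes

**Diversification contrast.** On an ultrametric chronogram the cophenetic
(patristic) distance between tips *i*, *j* satisfies
*d(i,j) = 2·age(MRCA(i,j))*. A clade's tempo is summarized by the
Fisher–Pearson skewness *g₁ = m₃/m₂^{3/2}* of its branch-length sample: a
clade that diversified in a recent burst has many short edges and a few
long stems, hence high *g₁*. The difference *g₁(clade A) − g₁(clade B)* is
tested against a null built by pooling both samples and re-partitioning
them at random into groups of the original sizes (a standard two-sample
permutation test; 1000 permutations by default, seeded and
bit-reproducible).

**Clock calibrations.** Island calibrations are normal priors *N(age, sd)*
on the crown age of a taxon pair that straddles an old-island/young-island
split, with the mean at the end of shield building. Rate calibrations
convert a pairwise COI divergence rate *r* %/my (mean of uncorrected
p-distances between island-split taxon pairs, outliers excluded, divided by
the island age *T*) into a per-lineage clock-rate prior with mean
*r/2/100* substitutions/site/my. Both are emitted as declarative JSON
documents; no dating engine is run.

**DEC biogeography.** Ranges are non-empty subsets of *K* islands encoded
as bitmasks. Along branches a range gains area *j* at rate *d·|R|* and
loses each area at rate *e*; at speciation a multi-area range splits by
peripheral-isolate sympatry or vicariance, all scenarios equally weighted.
The likelihood is computed by pruning with `exp(QΔt)` branch propagators
(piecewise across emergence strata in the time-stratified model), *d* and
*e* are estimated by bounded maximum likelihood, marginal ancestral ranges
are obtained from inside/outside passes, multi-island probabilities are
pooled as "widespread" (naming any single multi-island state above a
threshold), and competing models are compared with a ≥2 log-likelihood-unit
separation rule.

## Worked example

Simulate a two-clade tree in which clade A diversified in a recent burst
(speciation rate ×4.5 within 1.5 my of the present) while clade B
diversified at a constant rate, then test the skewness contrast:

```bash
islandrad contrast two_clade.nwk tips1.txt tips2.txt --seed 42 --mode one_sided
```

prints (abridged):

```
observed 1.505   sig True   q95 1.276
```

The burst clade's branch lengths are more right-skewed than the constant
clade's by 1.505 skewness units, beyond the 95% quantile (1.276) of the
permutation null, so the tempo difference is significant at α = 0.05.

Fit DEC rates to a simulated 30-tip tree whose tip ranges evolved under
*d* = 0.05, *e* = 0.01:

```bash
islandrad simulate --seed 5 --out-prefix demo
islandrad dec fit demo.nwk demo.ranges.csv dec.yaml
```

```
"d": 0.0358, "e": 1e-05, "loglik": -40.10, "converged": true
```

The dispersal rate is recovered within a factor of two of the truth (0.05);
the extinction estimate sits at the lower bound, as expected when no range
loss survives in the tip data. `islandrad dec anc … --d 0.05 --e 0.01`
then writes per-node marginal range probabilities with the widespread
summary, and `islandrad rate demo.pairs.csv --age 0.5` reruns the
divergence-rate recipe (outlier exclusion mask included) and emits the
clock prior.

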