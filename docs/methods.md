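# Methods

## Chronograms

All stages consume a rooted, ultrametric tree whose branch lengths are in
millions of years (my). Node ages are computed as the maximum path length
to a descendant tip, so they remain defined for slightly non-ultrametric
input; ultrametricity is checked as the relative spread of root-to-tip path
lengths against a tolerance (default 1e-6), and violation is an error in
strict mode or a warning otherwise. Newick labels after a closing
parenthesis are read as internal node names, never as support values, to
avoid silently misparsing annotated trees. Polytomies are accepted at the
I/O layer but rejected by the DEC stage, which requires a bifurcating tree.

Patristic distances are taken from the tree's path-length matrix; on an
ultrametric tree they must equal twice the MRCA age, and the test suite
checks this identity entrywise at 1e-9 on simulated trees.

## Skewness contrast between clades

A clade's branch-length sample contains every edge strictly inside its
crown subtree; the stem edge predates crown diversification and is excluded
by default (an `include_stem` flag adds it). The statistic is the
moment-based Fisher–Pearson skewness g1 = m3 / m2^(3/2); the small-sample
adjusted G1 is selectable, and the permutation inference is valid under
either because the same statistic is applied to observed and permuted data.

The two-sample null pools both samples and repeatedly re-partitions the
pooled values into groups of the original sizes — the only scheme under
which the group labels are exchangeable when the two clades share a
branch-length distribution. Pooled values are placed in a stable sorted
order before shuffling so the null sample is bit-identical for a given seed
regardless of input order. The decision uses order-statistic quantiles
rounded outward (`lower`/`higher` interpolation), keeping the rejection
rate at or below the nominal level under the null; with 1000 permutations
the measured type-I rate at alpha = 0.05 sits near 0.05 (checked against
the exact binomial 99% band over 500 replicates in the acceptance suite).
Both the central 1 - alpha interval (two-sided mode, default) and the
1 - alpha quantile (one-sided mode) are always reported, because the two
readings of "tested against the 95% quantile of the null" differ and both
are useful in practice.

## Divergence rates and calibration priors

Uncorrected p-distance drops columns with a gap or ambiguity in either
sequence by default (pairwise deletion), the conventional reading of
"uncorrected pairwise divergence". The rate recipe averages retained
pairwise divergences and divides by the calibrating island age T; the
outlier rule is unspecified in common usage, so the default is the Tukey
IQR fence (1.5 x IQR) with a z-score (> 2 SD) alternative, and the
exclusion mask is always part of the result so the step is auditable.

Pairwise divergence accumulates on two lineages, so the per-lineage clock
rate is half the pairwise rate; the conversion from r %/my to a clock-rate
prior mean is r / 2 / 100 substitutions/site/my (5.2 %/my -> 0.026,
2.3 %/my -> 0.0115). Island calibrations are normal priors on a node age
with the mean at the island's end of shield building. Priors are emitted
as declarative JSON (target, family, mean, SD, units) rather than injected
into any dating program: Bayesian dating itself is out of scope.

## DEC model

State space: all subsets of the ordered area list, encoded as bitmasks
(bit i = presence on area i), the empty range included internally as an
absorbing state. The anagenetic generator gains area j from range R at
rate d x (number of occupied source areas with a nonzero dispersal
multiplier into j; multipliers default to all ones, i.e. equal transition
rates) and loses each occupied area at rate e. Cladogenesis at a node with
range R: identical inheritance if |R| = 1; otherwise, for each a in R, the
ordered daughter pairs (a, R), (R, a) (subset sympatry) and (a, R\a),
(R\a, a) (vicariance), deduplicated and equally weighted; relative weights
per scenario class are configurable. The root is summed over occupiable
non-null ranges with equal weights, and no conditioning on survival is
applied, matching the conventions of the classic DEC implementations.

Branch propagators are matrix exponentials of the generator
(`scipy.linalg.expm`, Pade with scaling-and-squaring); the test suite
checks them against a scaled Taylor-series evaluation at 1e-10 on the
32-state (five-area) system. Pruning uses per-node rescaling to avoid
underflow. The likelihood is verified against an exhaustive enumeration
over all internal-node state assignments (with explicit scenario loops and
series exponentials) on trees with up to 5 tips and 3 areas, at 1e-8.

**Time stratification.** Strata are delimited by per-island emergence ages
supplied in configuration; an island is available at all ages up to and
including its emergence age. The youngest islands' ages follow the
standard end-of-shield-building chronology (Hawaii 0.5, Maui 1.3,
Molokai 1.9 my); Kauai and Oahu ages are required inputs with deliberately
no default (test fixtures use 5.1 and 3.0 my). Within a stratum, rates
into ranges containing unavailable islands are zero; at stratum boundaries
a hard projection removes any mass on such ranges, so a lineage can never
occupy an island before it emerges — the acceptance suite asserts exactly
zero marginal probability on such ranges at every node older than the
emergence. If the root age predates every configured island the
configuration is rejected with a diagnostic rather than silently patched,
since no range can exist there. Because stratification only removes
histories, the stratified likelihood can never exceed the unconstrained
likelihood at the same rates; this nested-model inequality is checked on
simulations.

**Estimation and reconstruction.** (d, e) are maximized in log10 space
with L-BFGS-B inside bounds (default 1e-5..10 events/my) from three
deterministic starting points; per-start optima are reported so
multiple-start agreement is visible. Marginal ancestral ranges use the
standard inside/outside decomposition: the inside pass gives the
likelihood of the data below a node given its range immediately before its
split, the outside pass propagates root weights through sibling messages
and branch operators, and their product normalized per node is the
marginal. The "widespread" summary lists single-island probabilities,
pools all multi-island states, and names any single multi-island state
whose probability reaches a threshold (default 0.15, e.g. "Maui/Hawaii").
Model choice follows the rule that the best model must exceed all others
by at least 2 log-likelihood units, otherwise "not separated".

## Synthetic data

**Trees.** Birth-death simulation runs forward in time. Conditioning is on
crown age (recursive lineage simulation, both crown children must survive),
on tip count (iterative Gillespie cut at a uniform time after the lineage
count first reaches the target), or on both (crown-age simulation with
rejection until the tip count matches). Extinct subtrees are pruned.
Burst mode multiplies the speciation rate within a shift window of the
present (defaults: shift 1.5 my, multiplier 8), reproducing the
long-stems-then-recent-burst shape of a clade whose diversification is
concentrated in the era of the youngest islands; under pure birth the mean
tip count of a crown-age tree matches 2·exp(lambda·t), which the tests
check.

**Ranges.** Forward DEC simulation draws cladogenetic scenarios from the
model's scenario distribution and anagenetic events by Gillespie sampling
with stratum-aware rates (availability only grows toward the present, and
the memoryless property allows redrawing waiting times at boundaries).
Branches that collapse to the null range are redrawn and counted; the
count is reported so the induced conditioning is visible. Single-branch
end-state frequencies are checked against rows of exp(Qt).

**Divergence pairs.** Clean pairs are rate/100 x T plus Gaussian noise;
a configured fraction is replaced by 5-10x outliers mimicking comparisons
that predate the calibrating island. The planted outlier index set is
returned for closed-loop tests of the exclusion rule.

## Study conditions used in the acceptance checks

Problem sizes were chosen to make each check statistically meaningful on a
single CPU in a few minutes. Type-I calibration uses two iid exponential
samples of 30 branch lengths, 500 test replicates, 1000 permutations.
The burst-contrast condition grafts a burst clade (lambda = 0.3816 /my,
multiplier 4.5, shift 1.5 my) and a constant clade (lambda = 0.78 /my)
at a 6.5 my root, both conditioned on crown age 5 my and 100 tips; these
rates put the conditioned tip count at the unconditional mean, and the
resulting population branch-length skewness difference is about 1.5
(pooled over many replicates), the scale of interest for a recent-burst
versus steady-tempo contrast. The mean observed difference across
replicates is about 1.6, the direction is positive in ~98% and the
one-sided test rejects in ~85% of replicates. Dispersal-rate recovery
simulates 20 datasets on 50-tip trees (Yule lambda = 0.3) over five areas
at d = 0.05, e = 0.01 and refits by ML; d is recovered within a factor of
two in essentially all replicates. Extinction e is weakly identified from
extant ranges alone and routinely collapses to the lower bound; only d
recovery is asserted.

## Limitations

The simulators emulate tempo and range-evolution patterns, not real data:
no rate heterogeneity across lineages, no sequence-level evolution, no
sampling error in the chronogram, and tip-count conditioning takes the
first passage to the target count. Passing tests therefore demonstrate
internal correctness and statistical behaviour under the model, not
robustness to empirical violations. The DEC implementation deliberately
omits founder-event (jump) cladogenesis and distance-scaled dispersal, and
the state space is capped at 8 areas. Branch-length skewness is a coarse
tempo summary; it detects a recent burst but does not estimate shift times
or rates.
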