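# Methods

## The statistic

Long-term balancing selection (e.g. heterozygote advantage) maintains
two allelic classes at a locus far longer than neutral drift would.
Neutral mutations arising on a haplotype linked to one of the balanced
alleles can drift up only to the frequency of their class; given enough
time they fix *within* the class, so polymorphism accumulates at folded
frequencies nearly identical to that of the balanced allele.
Recombination eventually decouples flanking variants, but their
frequencies remain near the class frequency until drift disperses them.

`betasel` scores each candidate core SNP by contrasting two estimators
of the population-scaled mutation rate θ computed from the SNPs inside
a window centred on the core (core site excluded):

    β = θ̂_β − θ̂_w,
    θ̂_β = Σ_{i=1}^{n−1} i·d_i·S_i / Σ_{i=1}^{n−1} d_i,
    θ̂_w = Σ_i S_i / a_{n−1},   a_k = Σ_{j≤k} 1/j,

where S_i is the number of window SNPs whose derived allele is seen i
times among n chromosomes, and i·S_i is the standard unbiased per-class
θ estimator.  The weights are folded-frequency similarities to the core
SNP:

    g(f) = min(f, n−f),  m = max(g(f0), n/2 − g(f0)),
    d_i = ((m − |g(f0) − g(f_i)|)/m)^p.

d_i = 1 at identical folded frequency and 0 at the maximum possible
folded difference m.  Under neutrality θ̂_β and θ̂_w estimate the same
quantity and β ≈ 0; allelic-class build-up inflates the classes with
d_i ≈ 1 and drives β > 0.

Two readings of the θ̂_β denominator are possible; we sum d_i over all
n−1 frequency classes whether or not they are occupied, which is the
only reading under which θ̂_β is a weighted average of the per-class
estimators (and therefore unbiased for θ under neutrality given the
window SNP count).

### Folded version

When ancestral states are unavailable the fully folded variant replaces
the per-class estimator with a folded-class analogue.  For folded class
j = 1..⌊n/2⌋ the unbiased estimator is

    θ̂*_j = S*_j · (1 + δ_{j,n−j}) / (1/j + 1/(n−j)),

(E[S*_j] = θ(1/j + 1/(n−j)) for j < n/2 and θ/j for the self-symmetric
class j = n/2, which the Kronecker-δ factor absorbs), and θ̂_β,folded is
the d_j-weighted average over folded classes.  θ̂_w depends only on the
total segregating-site count and is folding-invariant.  The folded β is
invariant under derived/ancestral relabelling of any subset of sites
(property-tested).

### Parameters

- `p` (default 2): sharpness of the similarity weighting.  Power is
  fairly insensitive to p over a broad range; smaller p is preferable
  when per-site sample sizes vary.  Exposed everywhere as a parameter.
- `window_bp` (default 1000): total window span.  The informative
  signal is confined to the "ancestral region" around the balanced
  site in which no recombination between allelic classes is expected —
  about 1 kb for human-like parameters — and 1 kb windows performed
  well across selection timings in simulation; the optimum shifts with
  the recombination rate, hence a parameter rather than a constant.
- `min_folded_freq` (default 0.15): cores below 15% folded frequency
  are not scored in scans.  Balanced polymorphisms with very unequal
  equilibrium frequencies are rarely maintained against drift, so such
  cores contribute false positives.
- `percentile` (default 0.01) and `sharing_fraction` (default 0.5):
  a site is called in a population if its β is in the top 1% of that
  population's scores, and called *shared* if flagged in at least
  ⌈sharing_fraction × #populations⌉ populations — old balanced
  polymorphism should predate population splits and recur across
  populations.

### Numerical choices

- Window membership is the half-open interval
  [center − w/2, center + w/2); half-open avoids double counting at
  edges.  Shared coordinate-line convention for masks: a site at
  position x is inside interval [a, b) iff a ≤ x < b.
- Empty windows yield a missing (NaN) score, never 0, so SNP deserts do
  not dilute downstream percentile calling.
- Top-percentile calling flags exactly ⌈percentile × N⌉ sites; ties are
  broken by ascending position for determinism.
- Odd n: folded classes run to ⌊n/2⌋ and m uses n/2 as a real number.
- With variable per-site sample sizes (e.g. per-site missingness),
  folded frequencies are compared on the proportion scale; the d ratio
  is scale-free, so this reduces exactly to the count-scale statistic
  when sample sizes are uniform.  The weight denominator uses the core
  SNP's sample size.  Only the unfolded statistic supports this path.
- The exact Hardy–Weinberg filter enumerates the conditional
  distribution of heterozygote counts in log space (gammaln /
  logsumexp); the two-sided P sums configurations no more probable than
  the observed one with a 1+1e-12 relative guard against ties lost to
  rounding.

## Simulations

### Forward model

A diploid Wright–Fisher population of size Ne is burnt in for
`burn_in` generations from an empty state (long enough past 4·Ne for
mutation–drift equilibrium at the defaults), then split into two
populations — the focal ("human") one and an outgroup ("chimpanzee")
branch — evolved independently for `split_gens` generations.  Balanced
runs introduce a single overdominant mutation at the centre of the
region `t_sel` generations before sampling, with genotype fitnesses
1 : 1+hs : 1+s (ancestral homozygote : heterozygote : derived
homozygote).  Selection is implemented as fitness-weighted sampling of
parents, which reproduces the deterministic recursion whose interior
equilibrium is q* = h/(2h−1); negative h is paired with negative s.
Runs are conditioned on the balanced polymorphism surviving to
sampling: on loss *or fixation* the run restarts from the introduction
generation (fixation also destroys the polymorphism being conditioned
on; at the default parameters it is rare).  At the end, `n_sample`
chromosomes are drawn from the focal population and one from the
outgroup; substitutions are variants whose outgroup allele does not
occur in the focal sample.

Mutation is infinite-sites on continuous positions (rounded to 1-based
integer bp on output; the rare rounding collision keeps the first
site), recombination a single crossover per meiosis at rate r·L.
Rescaling by an integer Q divides Ne and all generation counts by Q and
multiplies mu, r and s by Q, preserving the population-scaled
parameters θ, ρ and 2Ne·s (verified by a cross-scale test).

The engine packs haplotypes into uint64 bitmasks (one bit per
segregating mutation) with an inline xorshift128+ RNG inside a numba
kernel, making a rescaled (Q = 10) balanced replicate of a 10-kb region
run in about a second.  The outgroup branch can be disabled
(`sample_outgroup=False`) when no statistic under study uses
substitutions; the branch is independent of the focal sample, so this
changes nothing else.

### Coalescent null

`run_neutral_coalescent` (msprime, haploid samples, population size
2·Ne, infinite-sites mutations) is the fast exchangeable null for the
forward simulator's neutral arm: identical θ = 4·Ne·mu and
ρ = 4·Ne·r per bp, sample size and output format.  A cross-validation
test checks that forward-neutral and coalescent segregating-site counts
agree within Monte-Carlo error.

### Frequency matching and power

For each balanced parameter set, neutral core SNPs are drawn from the
null replicates among variants whose sampled derived frequency lies
within 10% (relative, i.e. target·(1 ± 0.10); an absolute-band mode is
provided since either reading is defensible) of the balanced
equilibrium frequency, one core per replicate in the power harness.
Power is the fraction of balanced replicates whose score exceeds the
(1 − FPR) quantile of the neutral scores; the full empirical ROC is
always computed.  Default report FPRs are 0.01 and 0.05 (explicit
operating points rather than a figure-derived one).

### What the generator does and does not emulate

The generator reproduces an equilibrium panmictic population with
human-like Ne, mutation and recombination rates, a single balanced
variant, and sampling noise.  It does not model non-equilibrium
demography (bottlenecks, expansions, subdivision, admixture),
frequency-dependent selection, variable mutation/recombination maps,
sequencing error, or ancestral-state miscalls — a piecewise
population-size hook exists in `SimConfig` but is untested.  Passing
tests therefore demonstrate correctness of the statistic and its
behaviour under the idealized model, not robustness to every real-data
complication.

### Problem sizes used by the test suite

The calibration check uses 1,500 coalescent replicates (n = 100, 10-kb
regions, all matched cores pooled).  The power and build-up checks use
300 balanced forward replicates (h = 1.5, s = 0.01, selection from the
split, Q = 10) against 400 neutral coalescent replicates, one matched
core each — enough replication for the qualitative orderings under
test while keeping the default suite a desk-scale run.  Unit-level
Monte-Carlo checks use smaller batches with 3-standard-error bands.

A note on the neutral mean of β: conditioning the core on an
intermediate frequency selects genealogically deeper-than-average
windows, so the mean β over frequency-matched neutral cores is slightly
positive (of order the per-window θ̂_w ≈ 1 at the defaults) rather than
exactly zero; it is an order of magnitude below the balanced-arm mean.

## Known limitations

- The scan assumes one population per input table and one contig per
  count file; multi-contig VCFs are keyed by contig.
- Sites lacking an ancestral-allele call are dropped in unfolded mode
  (REF-polarization would systematically miscall); a flag retains them
  for folded-only analyses.
- The variable-sample-size path approximates the weight denominator
  with the core's sample size.
- The composite-likelihood statistics (T1/T2), HKA, and
  substitution-augmented variants of β are out of scope; Tajima's D is
  included as the comparator.
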