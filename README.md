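# betasel

Detecting **long-term balancing selection** from allele-frequency
correlation.

Balancing selection (heterozygote advantage, frequency- or
environment-dependent selection) maintains two alleles at a locus over
long evolutionary times.  Neutral mutations arising in linkage with one
of the balanced alleles can rise no higher than the frequency of their
allelic class, and given enough time they fix *within* the class — so
polymorphism piles up at folded frequencies nearly identical to the
balanced allele's.  `betasel` detects these clusters with the summary
statistic

```
β = θ̂_β − θ̂_w
```

computed in a window around each candidate core SNP (core excluded),
where θ̂_w is Watterson's estimator and

```
θ̂_β = Σᵢ i·dᵢ·Sᵢ / Σᵢ dᵢ ,      dᵢ = ((m − |g(f₀) − g(fᵢ)|)/m)ᵖ ,
g(f) = min(f, n−f) ,             m = max(g(f₀), n/2 − g(f₀)) ,
```

a similarity-weighted average of the unbiased per-frequency-class
estimators i·Sᵢ (Sᵢ = number of window SNPs seen i times among n
chromosomes).  Under neutrality β ≈ 0; allelic-class build-up drives it
positive.  A fully folded version needs no ancestral states.  The
statistic needs no outgroup sequence and runs genome-wide in seconds,
making it suited to the many species with population data but no
high-quality outgroup.

The package is aimed at population geneticists running selection scans:
it covers the statistic itself, the sliding-window scan with the
standard quality filters (accessibility/repeat masks, folded-frequency
floor, top-percentile and cross-population sharing calls, exact
Hardy–Weinberg screening), and forward/coalescent simulators for
calibrating significance thresholds and measuring power.

## Worked example

Score a 3-SNP contig (columns: position, derived count, sample size):

```bash
$ printf '100 50 100\n400 50 100\n600 25 100\n' > toy.counts
$ betasel scan --input toy.counts --window 1000 --p 2 --out toy.scores.tsv
wrote 3 scores to toy.scores.tsv
$ cat toy.scores.tsv
position  folded_freq  theta_beta  theta_w       beta
100       0.5          1.49970006  0.1931479782  1.306552082
400       0.5          1.687162567 0.3862959564  1.300866611
600       0.25         0           0.3862959564  -0.3862959564
```

The cores at 100 and 400 sit at folded frequency 0.5 with neighbours at
the same frequency, so the similarity-weighted estimator θ̂_β far
exceeds θ̂_w and β > 0 — the build-up signature.  The core at 600
(folded 0.25) sees only SNPs at its maximum folded distance (m = 25),
so every weight dᵢ on an occupied class is 0, θ̂_β = 0, and
β = −θ̂_w.  Each run also writes a `.manifest.json` recording the
resolved parameters, seed, versions and input checksums.

The same pipeline in Python:

```python
from betasel import ScanConfig, SiteCount, scan_population
sites = [SiteCount(100, 50, 100), SiteCount(400, 50, 100), SiteCount(600, 25, 100)]
scores = scan_population(sites, ScanConfig(window_bp=1000, p=2.0))
```

Simulation, e.g. ten balanced replicates at equilibrium frequency 0.75
(h = 1.5) with tenfold rescaling, and a power table:

```bash
betasel simulate --mode balanced --h 1.5 --s 0.01 --tsel 250000 \
    --rescale 10 --reps 10 --seed 7 --out sims/balanced
betasel simulate --mode coalescent --reps 10 --seed 8 --out sims/neutral
betasel power --balanced bal_scores.tsv --neutral neu_scores.tsv --out power
```

## Layout

- `betasel.core_stats` — fold/similarity primitives, θ̂_w, θ̂_β, β
  (unfolded, folded, variable-n), Tajima's D, exact HWE test
- `betasel.io` — count tables, VCF → per-population counts (AA-tag
  polarization), BED masks, score TSVs
- `betasel.scan` — windows, per-population scans, top-percentile and
  shared-signal calling, neutral-quantile thresholds
- `betasel.simulate` — bit-packed Wright–Fisher forward engine with
  overdominance (numba), msprime coalescent null, frequency matching,
  ROC/power analysis
- `betasel.cli` — `betasel scan | simulate | power`

See `docs/methods.md` for the model, parameter meanings, numerical
conventions and limitations.
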