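"""Site-frequency-spectrum statistics for detecting balancing selection.

Long-term balancing selection lets linked neutral variants drift to
fixation *within* an allelic class, so polymorphism accumulates at folded
frequencies nearly identical to the balanced allele's.  The β statistic
captures this by contrasting two estimators of the population mutation
rate θ computed from the SNPs surrounding a focal ("core") SNP:

    β = θ̂_β − θ̂_w

θ̂_w is Watterson's estimator.  θ̂_β is a weighted average of the per-
frequency-class estimators θ̂_i = i·S_i (S_i = number of derived variants
seen i times among n chromosomes), where class i is weighted by its
folded-frequency similarity d_i to the core SNP.  Under neutrality β is
close to zero; an excess of variants at the core SNP's frequency drives
it positive.

The similarity measure is computed on the folded spectrum,

    g(f)  = min(f, n − f)
    m     = max(g(f0), n/2 − g(f0))
    d_i   = ((m − |g(f0) − g(f_i)|) / m) ** p

so d_i = 1 when a variant matches the core folded frequency and d_i = 0
at the maximum possible folded difference m.  The exponent p (default 2)
controls how sharply mismatching frequencies are down-weighted.

The module also provides a fully folded variant of β (no ancestral
states needed), Tajima's D as a comparator statistic, and an exact
Hardy–Weinberg test used to screen candidate sites for technical
artifacts such as collapsed paralogs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "WindowSpectrum",
    "BetaScore",
    "HWEResult",
    "fold",
    "max_fold_diff",
    "similarity",
    "similarity_weights",
    "folded_similarity_weights",
    "harmonic_number",
    "theta_watterson",
    "theta_beta",
    "beta_unfolded",
    "fold_spectrum",
    "theta_beta_folded",
    "beta_folded",
    "beta_variable_n",
    "tajimas_d",
    "hwe_exact_test",
]


# ---------------------------------------------------------------------------
# folded-frequency similarity


def fold(count: float, n: float) -> float:
    """Folded (minor) allele count: ``min(count, n - count)``.

    Works on the count scale or, with ``n=1``, on the proportion scale.
    """
    if not 0 <= count <= n:
        raise ValueError(f"allele count {count} outside [0, {n}]")
    return min(count, n - count)


def max_fold_diff(core_folded: float, n: float) -> float:
    """Maximum possible folded-frequency difference from a core SNP.

    ``m = max(g(f0), n/2 - g(f0))`` on the count scale; n/2 is kept as a
    real number for odd n.
    """
    if not 0 <= core_folded <= n / 2:
        raise ValueError(f"folded count {core_folded} outside [0, {n / 2}]")
    return max(core_folded, n / 2 - core_folded)


def similarity(core_count: int, site_count: int, n: int, p: float = 2.0) -> float:
    """Frequency similarity d between a core SNP and a second SNP.

    Both counts are unfolded derived counts among ``n`` chromosomes and
    must be polymorphic (1..n-1).  Returns a value in [0, 1]: 1 when the
    folded frequencies coincide, 0 at the maximum folded difference.
    """
    if p <= 0:
        raise ValueError("p must be positive")
    for c in (core_count, site_count):
        if not 1 <= c <= n - 1:
            raise ValueError(f"count {c} not polymorphic for n={n}")
    g0 = fold(core_count, n)
    gi = fold(site_count, n)
    m = max_fold_diff(g0, n)
    return ((m - abs(g0 - gi)) / m) ** p


def similarity_weights(core_count: int, n: int, p: float = 2.0) -> np.ndarray:
    """d_i for every unfolded frequency class i = 1..n-1 (vectorized)."""
    if p <= 0:
        raise ValueError("p must be positive")
    if not 1 <= core_count <= n - 1:
        raise ValueError(f"core count {core_count} not polymorphic for n={n}")
    i = np.arange(1, n)
    g = np.minimum(i, n - i).astype(float)
    g0 = fold(core_count, n)
    m = max_fold_diff(g0, n)
    return ((m - np.abs(g0 - g)) / m) ** p


def folded_similarity_weights(core_folded: int, n: int, p: float = 2.0) -> np.ndarray:
    """d_j for folded frequency classes j = 1..floor(n/2)."""
    if p <= 0:
        raise ValueError("p must be positive")
    if not 1 <= core_folded <= n / 2:
        raise ValueError(f"core folded count {core_folded} outside [1, {n / 2}]")
    j = np.arange(1, n // 2 + 1, dtype=float)
    m = max_fold_diff(core_folded, n)
    return ((m - np.abs(core_folded - j)) / m) ** p


# ---------------------------------------------------------------------------
# window spectra


@dataclass(frozen=True)
class WindowSpectrum:
    """Unfolded site-frequency spectrum of the SNPs around one core SNP.

    Attributes
    ----------
    n : int
        Number of sampled chromosomes.
    counts : numpy.ndarray
        Length ``n - 1``; ``counts[i - 1]`` is S_i, the number of window
        SNPs whose derived allele appears i times.  The core site itself
        is excluded.
    core_count : int or None
        Unfolded derived count of the core SNP (1..n-1).
    """

    n: int
    counts: np.ndarray
    core_count: int | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if self.n < 2:
            raise ValueError("need at least 2 chromosomes")
        if counts.shape != (self.n - 1,):
            raise ValueError(
                f"spectrum must have {self.n - 1} classes, got {counts.shape}"
            )
        if (counts < 0).any():
            raise ValueError("negative class counts")
        if self.core_count is not None and not 1 <= self.core_count <= self.n - 1:
            raise ValueError("core count must be polymorphic (1..n-1)")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_derived_counts(
        cls, derived_counts: Iterable[int], n: int, core_count: int | None = None
    ) -> "WindowSpectrum":
        """Build a spectrum from the derived counts of the window SNPs."""
        arr = np.fromiter(derived_counts, dtype=np.int64)
        if arr.size and ((arr < 1) | (arr > n - 1)).any():
            raise ValueError("window derived counts must be in 1..n-1")
        counts = np.bincount(arr, minlength=n)[1:n] if arr.size else np.zeros(
            n - 1, dtype=np.int64
        )
        return cls(n=n, counts=counts, core_count=core_count)

    @property
    def n_snps(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class BetaScore:
    """Per-core-SNP β record.

    ``beta = theta_beta - theta_w`` exactly; all three are NaN for an
    empty window (a SNP desert carries no information and reporting 0
    would bias downstream percentile calling).
    """

    position: int
    folded_freq: float
    theta_beta: float
    theta_w: float
    beta: float
    n_window_snps: int

    @property
    def is_missing(self) -> bool:
        return math.isnan(self.beta)


def harmonic_number(k: int) -> float:
    """a_k = sum_{i=1}^{k} 1/i."""
    return float(np.sum(1.0 / np.arange(1, k + 1))) if k >= 1 else 0.0


def theta_watterson(spec: WindowSpectrum) -> float:
    """Watterson's θ estimator: total segregating sites over a_{n-1}."""
    s = spec.counts.sum()
    if s == 0:
        return 0.0
    return float(s) / harmonic_number(spec.n - 1)


def theta_beta(spec: WindowSpectrum, p: float = 2.0) -> float:
    """Similarity-weighted average of the per-class estimators i·S_i.

    The denominator sums d_i over *all* classes 1..n-1, occupied or not,
    so that θ̂_β is a weighted average of the per-class estimators θ̂_i.
    """
    if spec.core_count is None:
        raise ValueError("spectrum has no core count")
    if spec.counts.sum() == 0:
        return 0.0
    d = similarity_weights(spec.core_count, spec.n, p)
    i = np.arange(1, spec.n)
    return float((i * d * spec.counts).sum() / d.sum())


def beta_unfolded(
    spec: WindowSpectrum, p: float = 2.0, position: int = -1
) -> BetaScore:
    """β = θ̂_β − θ̂_w for one core SNP from its window spectrum."""
    if spec.core_count is None:
        raise ValueError("spectrum has no core count")
    nsnps = spec.n_snps
    ff = fold(spec.core_count, spec.n) / spec.n
    if nsnps == 0:
        return BetaScore(position, ff, math.nan, math.nan, math.nan, 0)
    tb = theta_beta(spec, p)
    tw = theta_watterson(spec)
    return BetaScore(position, ff, tb, tw, tb - tw, nsnps)


# ---------------------------------------------------------------------------
# folded β (no ancestral states required)


def fold_spectrum(spec: WindowSpectrum) -> np.ndarray:
    """Collapse an unfolded spectrum to folded classes 1..floor(n/2).

    S*_j = S_j + S_{n-j} for j < n/2; S*_{n/2} = S_{n/2} for even n.
    """
    n = spec.n
    nf = n // 2
    out = np.zeros(nf, dtype=np.int64)
    for j in range(1, nf + 1):
        if j == n - j:
            out[j - 1] = spec.counts[j - 1]
        else:
            out[j - 1] = spec.counts[j - 1] + spec.counts[n - j - 1]
    return out


def theta_beta_folded(
    n: int, folded_counts: np.ndarray, core_folded: int, p: float = 2.0
) -> float:
    """Folded analogue of θ̂_β.

    Each folded class j gets the unbiased per-class estimator

        θ̂*_j = S*_j · (1 + δ_{j, n-j}) / (1/j + 1/(n-j))

    (the Kronecker δ corrects the double-counted symmetric class at
    j = n/2), and the estimators are averaged with weights d_j.
    """
    folded_counts = np.asarray(folded_counts, dtype=np.int64)
    nf = n // 2
    if folded_counts.shape != (nf,):
        raise ValueError(f"folded spectrum must have {nf} classes")
    if folded_counts.sum() == 0:
        return 0.0
    j = np.arange(1, nf + 1, dtype=float)
    delta = (j == n - j).astype(float)
    theta_star = folded_counts * (1.0 + delta) / (1.0 / j + 1.0 / (n - j))
    d = folded_similarity_weights(core_folded, n, p)
    return float((d * theta_star).sum() / d.sum())


def beta_folded(
    n: int,
    folded_counts: np.ndarray,
    core_folded: int,
    p: float = 2.0,
    position: int = -1,
) -> BetaScore:
    """Fully folded β: needs only minor-allele counts.

    θ̂_w is folding-invariant (it depends only on the total number of
    segregating sites), so only the weighted estimator changes.
    """
    folded_counts = np.asarray(folded_counts, dtype=np.int64)
    nsnps = int(folded_counts.sum())
    ff = core_folded / n
    if nsnps == 0:
        return BetaScore(position, ff, math.nan, math.nan, math.nan, 0)
    tb = theta_beta_folded(n, folded_counts, core_folded, p)
    tw = nsnps / harmonic_number(n - 1)
    return BetaScore(position, ff, tb, tw, tb - tw, nsnps)


# ---------------------------------------------------------------------------
# variable per-site sample sizes


def beta_variable_n(
    core_count: int,
    core_n: int,
    site_counts: Sequence[int],
    site_ns: Sequence[int],
    p: float = 2.0,
    position: int = -1,
) -> BetaScore:
    """Unfolded β when window SNPs have differing sample sizes.

    Folded frequencies are compared on the proportion scale (g(f)/n), so
    the similarity of two sites is well defined even when their sample
    sizes differ; the ratio in d is scale-free, hence for uniform n this
    reduces exactly to :func:`beta_unfolded`.  Each site contributes its
    own derived count as the per-site θ estimate, and the weight
    denominator sums d over the frequency classes of the core SNP's
    sample size.
    """
    site_counts = np.asarray(site_counts, dtype=float)
    site_ns = np.asarray(site_ns, dtype=float)
    if site_counts.shape != site_ns.shape:
        raise ValueError("site_counts and site_ns must have equal length")
    g0 = fold(core_count, core_n) / core_n
    ff = g0
    if site_counts.size == 0:
        return BetaScore(position, ff, math.nan, math.nan, math.nan, 0)
    m = max(g0, 0.5 - g0)
    phi = np.minimum(site_counts, site_ns - site_counts) / site_ns
    d_sites = ((m - np.abs(g0 - phi)) / m) ** p
    denom = similarity_weights(core_count, core_n, p).sum()
    tb = float((site_counts * d_sites).sum() / denom)
    tw = site_counts.size / harmonic_number(core_n - 1)
    return BetaScore(position, ff, tb, tw, tb - tw, int(site_counts.size))


# ---------------------------------------------------------------------------
# Tajima's D (comparator)


def tajimas_d(spec: WindowSpectrum) -> float:
    """Tajima's D from an unfolded window spectrum.

    Returns NaN when the window holds no segregating sites.  Uses the
    standard variance normalization (a1, a2, b1, b2, c1, c2, e1, e2
    constants from the original derivation).
    """
    n = spec.n
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    s = int(spec.counts.sum())
    if s == 0:
        return math.nan
    i = np.arange(1, n)
    pi = float((spec.counts * 2.0 * i * (n - i)).sum()) / (n * (n - 1))
    a1 = harmonic_number(n - 1)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    if var <= 0:
        return math.nan
    return (pi - s / a1) / math.sqrt(var)


# ---------------------------------------------------------------------------
# exact Hardy–Weinberg test


@dataclass(frozen=True)
class HWEResult:
    """Exact-test P values for one biallelic genotype triple."""

    p_het_excess: float
    p_two_sided: float


def hwe_exact_test(obs_hom_ref: int, obs_het: int, obs_hom_alt: int) -> HWEResult:
    """Exact conditional Hardy–Weinberg test.

    Enumerates every heterozygote count compatible with the observed
    allele counts (het counts share the parity of the minor-allele
    count).  The conditional probability of h heterozygotes given n
    diploids and n_a copies of the minor allele is

        P(h) ∝ n! / (h! · ((n_a - h)/2)! · ((2n - n_a - h)/2)!) · 2^h.

    Returns the one-sided P for heterozygote *excess* (P[het >= obs])
    and the standard two-sided P (sum of configurations no more probable
    than the observed one).
    """
    for c in (obs_hom_ref, obs_het, obs_hom_alt):
        if c < 0:
            raise ValueError("negative genotype count")
    n = obs_hom_ref + obs_het + obs_hom_alt
    if n < 1:
        raise ValueError("no genotypes observed")
    n_a = min(2 * obs_hom_ref + obs_het, 2 * obs_hom_alt + obs_het)
    hets = np.arange(n_a % 2, n_a + 1, 2)
    # log unnormalized probabilities, normalized by logsumexp for stability
    from scipy.special import gammaln, logsumexp

    logp = (
        hets * math.log(2.0)
        - gammaln(hets + 1)
        - gammaln((n_a - hets) / 2 + 1)
        - gammaln((2 * n - n_a - hets) / 2 + 1)
    )
    logz = logsumexp(logp)
    prob = np.exp(logp - logz)
    obs_idx = int(np.searchsorted(hets, obs_het))
    if obs_idx >= len(hets) or hets[obs_idx] != obs_het:
        raise ValueError(
            f"het count {obs_het} incompatible with allele counts (parity)"
        )
    p_excess = float(prob[obs_idx:].sum())
    p_two = float(prob[prob <= prob[obs_idx] * (1 + 1e-12)].sum())
    return HWEResult(min(p_excess, 1.0), min(p_two, 1.0))
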