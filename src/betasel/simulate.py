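"""Forward and coalescent simulation of balancing selection, and power analysis.

The forward arm reproduces the classic two-species protocol: a single
panmictic diploid population is burnt in to mutation–drift equilibrium,
splits into a "human" and an outgroup ("chimpanzee") population, and
the human population optionally receives one overdominant mutation at
the region's center (genotype fitnesses 1 : 1+hs : 1+s) a set number of
generations before sampling.  Runs are conditioned on the balanced
polymorphism surviving: a replicate in which it is lost (or fixed) is
restarted from the introduction generation.  At the end, n_sample human
chromosomes and one outgroup chromosome are drawn; substitutions are
the variants whose outgroup allele does not appear in the human sample.

All rates can be rescaled by an integer Q (population size and
generation counts divided by Q; mutation, recombination and selection
multiplied by Q), the standard trick for speeding up forward
simulation while preserving the population-scaled parameters.

The neutral coalescent arm (msprime) is the fast, exchangeable null for
the forward simulator's neutral side: same θ and ρ, same sample size,
same output format.  Neutral core SNPs are frequency-matched to the
balanced equilibrium frequency before scoring so the two arms are
compared at like-for-like core frequencies.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import msprime
import numpy as np
from scipy.optimize import brentq

from . import _kernel, core_stats
from .io import SiteCount
from .scan import build_window

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SimResult",
    "MatchedCore",
    "PowerResult",
    "PowerExperiment",
    "equilibrium_frequency",
    "equilibrium_frequency_numeric",
    "h_for_equilibrium",
    "run_forward",
    "run_neutral_coalescent",
    "match_neutral_cores",
    "power_analysis",
    "power_experiment",
]


# ---------------------------------------------------------------------------
# deterministic overdominance equilibrium


def equilibrium_frequency(h: float, s: float | None = None) -> float:
    """Stable interior equilibrium frequency of the derived allele.

    With genotype fitnesses 1, 1+hs, 1+s the deterministic change in
    derived-allele frequency vanishes at q* = h / (2h − 1), independent
    of s.  An interior stable equilibrium exists only for h < 0 or
    h > 1 (heterozygote advantage once the sign of s is matched); if
    ``s`` is supplied, the protected-polymorphism conditions hs > 0 and
    hs > s are checked as well.
    """
    if abs(2.0 * h - 1.0) < 1e-300:
        raise ValueError("h = 1/2 admits no interior equilibrium")
    q = h / (2.0 * h - 1.0)
    if not 0.0 < q < 1.0:
        raise ValueError(f"h={h} gives equilibrium {q:.4g} outside (0, 1)")
    if s is not None:
        hs = h * s
        if not (hs > 0 and hs > s):
            raise ValueError(
                f"h={h}, s={s}: heterozygote is not the fittest genotype"
            )
    return q


def equilibrium_frequency_numeric(h: float, s: float) -> float:
    """Interior equilibrium found by root-finding on Δq (cross-check path).

    Solves Δq(q) = q' − q = 0 on (0, 1) for the one-generation
    deterministic recursion under fitnesses 1, 1+hs, 1+s.
    """

    def delta_q(q: float) -> float:
        w11 = 1.0 + s
        w01 = 1.0 + h * s
        wbar = q * q * w11 + 2 * q * (1 - q) * w01 + (1 - q) ** 2
        return (q * q * w11 + q * (1 - q) * w01) / wbar - q

    eps = 1e-9
    if delta_q(eps) * delta_q(1 - eps) > 0:
        raise ValueError(f"no interior equilibrium for h={h}, s={s}")
    return float(brentq(delta_q, eps, 1 - eps, xtol=1e-14))


def h_for_equilibrium(q: float) -> float:
    """Inverse of :func:`equilibrium_frequency`: h = q / (2q − 1)."""
    if not 0 < q < 1 or abs(q - 0.5) < 1e-12:
        raise ValueError("equilibrium frequency must be in (0,1), != 1/2")
    return q / (2.0 * q - 1.0)


# ---------------------------------------------------------------------------
# configuration and results


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters (unscaled; rescale_Q applied internally).

    Defaults follow a human-like equilibrium model: Ne = 10,000
    diploids, mu = r = 2.5e-8 per bp per generation, 10-kb regions,
    100,000 generations of burn-in, a species split 250,000 generations
    before sampling, and 100 sampled chromosomes plus one outgroup
    chromosome.  ``t_sel`` is the number of generations before sampling
    at which the balanced variant is introduced (at most
    ``split_gens``).  ``size_schedule`` is an untested hook for
    piecewise population-size histories.
    """

    Ne: int = 10_000
    mu: float = 2.5e-8
    r: float = 2.5e-8
    L: int = 10_000
    burn_in: int = 100_000
    split_gens: int = 250_000
    t_sel: int = 250_000
    h: float = 1.5
    s: float = 0.01
    n_sample: int = 100
    rescale_Q: int = 1
    seed: int = 1
    restart_limit: int = 10_000
    sample_outgroup: bool = True
    capacity_words: int = 16
    size_schedule: tuple | None = None

    def __post_init__(self) -> None:
        if self.rescale_Q < 1:
            raise ValueError("rescale_Q must be a positive integer")
        if self.t_sel > self.split_gens:
            raise ValueError("t_sel cannot predate the split")
        if self.Ne // self.rescale_Q < 2:
            raise ValueError("rescaled population too small")
        if self.n_sample < 2:
            raise ValueError("need at least 2 sampled chromosomes")


@dataclass
class SimResult:
    """Sampled output of one simulation replicate.

    positions are 1-based integer bp (continuous mutation positions
    rounded on output); counts are derived-allele counts among
    ``n_sample`` chromosomes, polymorphic in the sample (1..n-1).
    substitutions are positions where the outgroup chromosome's allele
    is absent from the human sample.  For balanced runs, balanced_pos /
    balanced_count give the core variant's sampled state and restarts
    the number of times the conditioning forced a restart.
    """

    positions: np.ndarray
    counts: np.ndarray
    n_sample: int
    substitutions: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64)
    )
    balanced_pos: int | None = None
    balanced_count: int | None = None
    restarts: int = 0

    @property
    def balanced_freq(self) -> float | None:
        if self.balanced_count is None:
            return None
        return self.balanced_count / self.n_sample

    @property
    def n_sites(self) -> int:
        return int(len(self.positions))

    def to_sites(self) -> list[SiteCount]:
        return [
            SiteCount(int(p), int(c), self.n_sample)
            for p, c in zip(self.positions, self.counts)
        ]


# ---------------------------------------------------------------------------
# forward simulation


def _fresh_state(
    n_hap: int, words: int, cap: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    pop = np.zeros((n_hap, words), np.uint64)
    positions = np.zeros(cap, np.float64)
    inuse = np.zeros(cap, np.bool_)
    free_stack = np.arange(cap - 1, -1, -1, dtype=np.int64).copy()
    return pop, positions, inuse, free_stack, cap


def _rng_words(ss: np.random.SeedSequence) -> np.ndarray:
    state = ss.generate_state(2, np.uint64)
    if state[0] == 0 and state[1] == 0:
        state[0] = np.uint64(0x9E3779B97F4A7C15)
    return state


def _sample_population(
    pop: np.ndarray,
    positions: np.ndarray,
    inuse: np.ndarray,
    rows: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """(float positions, derived counts among rows) for every active slot."""
    slots = np.flatnonzero(inuse)
    if slots.size == 0:
        return np.empty(0), np.empty(0, dtype=np.int64)
    counts = _kernel.unpack_columns(pop, rows, slots)
    return positions[slots], counts


def run_forward(config: SimConfig, balanced: bool = False) -> SimResult:
    """One Wright–Fisher forward replicate.

    Burn-in, split into human + outgroup populations, optional
    introduction of a single overdominant variant at the region center
    ``t_sel`` generations before sampling (restarting from the
    introduction generation if it is lost or fixed), sampling, and
    substitution classification.  Fully deterministic given
    ``config.seed``.
    """
    Q = config.rescale_Q
    N = config.Ne // Q
    two_n = 2 * N
    mu = config.mu * Q
    r = config.r * Q
    s_eff = config.s * Q
    L = float(config.L)
    burn = config.burn_in // Q
    split_g = config.split_gens // Q
    t_sel = config.t_sel // Q
    mu_total = two_n * mu * L
    rL = r * L
    check_every = 16
    if balanced:
        equilibrium_frequency(config.h, config.s)  # validates the scheme
        if abs(s_eff) >= 0.5:
            raise ValueError("rescaled selection coefficient too large")

    ss = np.random.SeedSequence(config.seed)
    ss_kernel, ss_sample = ss.spawn(2)
    state = _rng_words(ss_kernel)
    sampler = np.random.default_rng(ss_sample)

    W = config.capacity_words
    cap = 64 * W
    popA, positions, inuse, free_stack, n_free = _fresh_state(two_n, W, cap)
    popB = np.zeros_like(popA)
    fixed_buf = np.zeros(65536, np.float64)
    n_fixed = 0

    def _run(pop_cur, pop_buf, pos, use, free, nf, gens, sel, h, s, nfix):
        st, nf, buf, nfix = _kernel.evolve(
            pop_cur, pop_buf, pos, use, free, nf, gens, mu_total, rL, L, N,
            sel, h, s, check_every, state, fixed_buf, nfix,
        )
        if st == _kernel.FULL:
            raise RuntimeError(
                "mutation slot capacity exhausted; increase capacity_words"
            )
        cur = pop_cur if buf == 0 else pop_buf
        nxt = pop_buf if buf == 0 else pop_cur
        return st, cur, nxt, nf, nfix

    # burn-in to mutation-drift equilibrium (fixations predate the split:
    # shared by both descendant populations, so not substitutions)
    st, cur, nxt, n_free, _ = _run(
        popA, popB, positions, inuse, free_stack, n_free, burn, -1, 0.0, 0.0, 0
    )
    n_fixed = 0

    # split: duplicate state for the outgroup branch
    if config.sample_outgroup:
        chimp_pop = cur.copy()
        chimp_buf = np.zeros_like(chimp_pop)
        chimp_pos = positions.copy()
        chimp_use = inuse.copy()
        chimp_free = free_stack.copy()
        chimp_nfree = n_free

    restarts = 0
    sel_slot = -1
    balanced_position: float | None = None
    if balanced:
        # neutral interlude between split and introduction
        pre = split_g - t_sel
        if pre > 0:
            st, cur, nxt, n_free, n_fixed = _run(
                cur, nxt, positions, inuse, free_stack, n_free, pre, -1, 0.0,
                0.0, n_fixed,
            )
        if n_free == 0:
            raise RuntimeError("no free slot for the balanced variant")
        n_free -= 1
        sel_slot = int(free_stack[n_free])
        positions[sel_slot] = L / 2.0
        inuse[sel_slot] = True
        balanced_position = L / 2.0
        intro_hap = int(sampler.integers(two_n))
        cur[intro_hap, sel_slot >> 6] |= np.uint64(1) << np.uint64(sel_slot & 63)
        # snapshot the introduction generation for restart-on-loss
        snap_pop = cur.copy()
        snap_pos = positions.copy()
        snap_use = inuse.copy()
        snap_free = free_stack.copy()
        snap_nfree = n_free
        snap_nfixed = n_fixed
        while True:
            st, cur, nxt, n_free, n_fixed = _run(
                cur, nxt, positions, inuse, free_stack, n_free, t_sel,
                sel_slot, config.h, s_eff, n_fixed,
            )
            if st == _kernel.OK:
                break
            restarts += 1
            if restarts > config.restart_limit:
                raise RuntimeError(
                    f"balanced variant lost {restarts} times "
                    f"(h={config.h}, s={config.s}, Q={Q}); restart limit hit"
                )
            np.copyto(cur, snap_pop)
            np.copyto(positions, snap_pos)
            np.copyto(inuse, snap_use)
            np.copyto(free_stack, snap_free)
            n_free = snap_nfree
            n_fixed = snap_nfixed
    else:
        st, cur, nxt, n_free, n_fixed = _run(
            cur, nxt, positions, inuse, free_stack, n_free, split_g, -1, 0.0,
            0.0, n_fixed,
        )
    human_fixed = fixed_buf[:n_fixed].copy()

    # outgroup branch: neutral evolution from the split state
    if config.sample_outgroup:
        n_fixed_c = 0
        st, ccur, cnxt, chimp_nfree, n_fixed_c = _run(
            chimp_pop, chimp_buf, chimp_pos, chimp_use, chimp_free,
            chimp_nfree, split_g, -1, 0.0, 0.0, 0,
        )
        chimp_fixed = fixed_buf[:n_fixed_c].copy()

    # sampling
    rows = np.sort(sampler.choice(two_n, size=config.n_sample, replace=False))
    pos_f, counts = _sample_population(cur, positions, inuse, rows)

    subs: list[float] = []
    if config.sample_outgroup:
        chimp_row = int(sampler.integers(two_n))
        c_slots = np.flatnonzero(chimp_use)
        c_derived = set()
        if c_slots.size:
            bits = _kernel.row_bits(ccur, chimp_row, c_slots)
            c_derived = {chimp_pos[sl] for sl, b in zip(c_slots, bits) if b}
        c_derived.update(chimp_fixed.tolist())
        human_states: dict[float, tuple[bool, bool]] = {}
        n = config.n_sample
        for p, c in zip(pos_f, counts):
            human_states[p] = (c > 0, c < n)  # (derived present, ancestral present)
        for p in human_fixed:
            human_states[p] = (True, False)
        all_pos = set(human_states) | c_derived
        for p in all_pos:
            der, anc = human_states.get(p, (False, True))
            chimp_has_derived = p in c_derived
            if chimp_has_derived:
                if not der:
                    subs.append(p)
            else:
                if not anc:
                    subs.append(p)

    # polymorphic-in-sample sites only, 1-based integer positions
    n = config.n_sample
    keep = (counts > 0) & (counts < n)
    pos_f, counts = pos_f[keep], counts[keep]
    order = np.argsort(pos_f)
    pos_i = np.rint(pos_f[order]).astype(np.int64) + 1
    counts = counts[order]
    balanced_count: int | None = None
    balanced_ipos: int | None = None
    if balanced and balanced_position is not None:
        balanced_ipos = int(round(balanced_position)) + 1
        hit = np.flatnonzero(np.isclose(pos_f[order], balanced_position))
        balanced_count = int(counts[hit[0]]) if hit.size else 0
    # de-duplicate integer-rounded collisions, preferring the balanced site
    if pos_i.size:
        uniq: dict[int, int] = {}
        for p, c in zip(pos_i, counts):
            if p not in uniq:
                uniq[p] = c
        if balanced_count and balanced_ipos is not None:
            uniq[balanced_ipos] = balanced_count
        pos_i = np.fromiter(sorted(uniq), dtype=np.int64, count=len(uniq))
        counts = np.array([uniq[p] for p in pos_i], dtype=np.int64)

    return SimResult(
        positions=pos_i,
        counts=counts,
        n_sample=config.n_sample,
        substitutions=np.sort(np.rint(np.array(subs)).astype(np.int64) + 1),
        balanced_pos=balanced_ipos if balanced else None,
        balanced_count=balanced_count if balanced else None,
        restarts=restarts,
    )


# ---------------------------------------------------------------------------
# neutral coalescent null


def run_neutral_coalescent(
    config: SimConfig, replicates: int, seed: int | None = None
) -> list[SimResult]:
    """Standard neutral coalescent replicates matched to the forward arm.

    Same θ = 4·Ne·mu and ρ = 4·Ne·r per bp, region length and sample
    size as the forward simulator's neutral side (rescaling is a
    forward-time device and does not apply here).  Infinite-sites
    mutations on a continuous genome, rounded to 1-based integer bp on
    output, exactly like the forward arm.
    """
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    msp_seeds = 1 + ss.generate_state(2 * replicates, np.uint32).astype(np.int64) % (
        2**31 - 2
    )
    out: list[SimResult] = []
    for k in range(replicates):
        ts = msprime.sim_ancestry(
            samples=config.n_sample,
            ploidy=1,
            population_size=2 * config.Ne,
            sequence_length=config.L,
            recombination_rate=config.r,
            discrete_genome=False,
            random_seed=int(msp_seeds[2 * k]),
        )
        mts = msprime.sim_mutations(
            ts,
            rate=config.mu,
            discrete_genome=False,
            random_seed=int(msp_seeds[2 * k + 1]),
        )
        pos: list[int] = []
        cnt: list[int] = []
        last = -1
        for var in mts.variants():
            c = int(var.genotypes.sum())
            if not 0 < c < config.n_sample:
                continue
            p = int(round(var.site.position)) + 1
            if p == last:
                continue  # integer-rounding collision; keep the first
            pos.append(p)
            cnt.append(c)
            last = p
        out.append(
            SimResult(
                positions=np.array(pos, dtype=np.int64),
                counts=np.array(cnt, dtype=np.int64),
                n_sample=config.n_sample,
            )
        )
    return out


# ---------------------------------------------------------------------------
# frequency matching and power


@dataclass(frozen=True)
class MatchedCore:
    """A neutral variant standing in for a balanced core SNP."""

    replicate: int
    position: int
    derived_count: int


def match_neutral_cores(
    neutral_results: Sequence[SimResult],
    target_freq: float,
    tolerance: float = 0.10,
    mode: str = "relative",
    max_per_replicate: int | None = 1,
    seed: int | None = None,
) -> list[MatchedCore]:
    """Neutral variants whose sampled frequency is near a target frequency.

    ``mode='relative'`` accepts derived frequencies within
    target·(1 ± tolerance); ``'absolute'`` within target ± tolerance.
    At most ``max_per_replicate`` cores are drawn per replicate (None
    for all); replicates with no qualifying variant are skipped and
    counted in the log.
    """
    if mode == "relative":
        lo, hi = target_freq * (1 - tolerance), target_freq * (1 + tolerance)
    elif mode == "absolute":
        lo, hi = target_freq - tolerance, target_freq + tolerance
    else:
        raise ValueError(f"unknown matching mode {mode!r}")
    rng = np.random.default_rng(seed)
    out: list[MatchedCore] = []
    skipped = 0
    for k, res in enumerate(neutral_results):
        freqs = res.counts / res.n_sample
        idx = np.flatnonzero((freqs >= lo) & (freqs <= hi))
        if idx.size == 0:
            skipped += 1
            continue
        if max_per_replicate is not None and idx.size > max_per_replicate:
            idx = rng.choice(idx, size=max_per_replicate, replace=False)
        for i in np.sort(idx):
            out.append(
                MatchedCore(k, int(res.positions[i]), int(res.counts[i]))
            )
    if skipped:
        logger.info(
            "%d of %d neutral replicates had no variant in [%.3f, %.3f]",
            skipped,
            len(neutral_results),
            lo,
            hi,
        )
    return out


@dataclass
class PowerResult:
    """Empirical ROC and power of one statistic at fixed false-positive rates."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    power: dict[float, float]
    thresholds: dict[float, float]


def power_analysis(
    balanced_scores: Sequence[float],
    neutral_scores: Sequence[float],
    fprs: Sequence[float] = (0.01, 0.05),
) -> PowerResult:
    """Power to separate balanced from neutral replicates by one statistic.

    The ROC sweeps a threshold over the pooled scores (higher score =
    more selection-like); power at a target FPR is the fraction of
    balanced replicates exceeding the corresponding neutral quantile.
    """
    bal = np.asarray(balanced_scores, dtype=float)
    neu = np.asarray(neutral_scores, dtype=float)
    bal = bal[~np.isnan(bal)]
    neu = neu[~np.isnan(neu)]
    if bal.size == 0 or neu.size == 0:
        raise ValueError("need scores in both arms")
    if np.ptp(bal) == 0 and np.ptp(neu) == 0 and bal[0] == neu[0]:
        warnings.warn("constant scores in both arms; ROC is a coin flip")
    thr = np.unique(np.concatenate([bal, neu]))[::-1]
    tpr = (bal[None, :] >= thr[:, None]).mean(axis=1)
    fpr = (neu[None, :] >= thr[:, None]).mean(axis=1)
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    power: dict[float, float] = {}
    cuts: dict[float, float] = {}
    for a in fprs:
        cut = float(np.quantile(neu, 1.0 - a))
        power[a] = float((bal > cut).mean())
        cuts[a] = cut
    return PowerResult(fpr=fpr, tpr=tpr, auc=auc, power=power, thresholds=cuts)


# ---------------------------------------------------------------------------
# end-to-end power experiment (balanced forward arm vs neutral coalescent arm)


@dataclass
class PowerExperiment:
    """Per-replicate scores of both arms, ready for power_analysis.

    buildup_* hold the per-replicate fraction of window SNPs whose
    folded frequency lies within 0.05 of the core SNP's folded
    frequency — the allelic-class build-up signal itself.
    """

    beta_balanced: np.ndarray
    beta_neutral: np.ndarray
    tajd_balanced: np.ndarray
    tajd_neutral: np.ndarray
    buildup_balanced: np.ndarray
    buildup_neutral: np.ndarray
    balanced_freqs: np.ndarray
    restarts: np.ndarray


def _score_core(
    res: SimResult, core_pos: int, core_count: int, window_bp: int, p: float
) -> tuple[float, float, float]:
    """(β, Tajima's D, build-up fraction) for one core SNP."""
    sites = res.to_sites()
    core = SiteCount(core_pos, core_count, res.n_sample)
    spec = build_window(core, sites, window_bp)
    beta = core_stats.beta_unfolded(spec, p, position=core_pos).beta
    tajd = core_stats.tajimas_d(spec)
    if spec.n_snps == 0:
        return beta, tajd, math.nan
    n = res.n_sample
    i = np.arange(1, n)
    folded = np.minimum(i, n - i) / n
    core_folded = min(core_count, n - core_count) / n
    close = np.abs(folded - core_folded) <= 0.05
    frac = float(spec.counts[close].sum() / spec.n_snps)
    return beta, tajd, frac


def power_experiment(
    config: SimConfig,
    n_balanced: int,
    n_neutral: int,
    seed: int | None = None,
    window_bp: int = 1000,
    p: float = 2.0,
    match_tolerance: float = 0.10,
) -> PowerExperiment:
    """Run both arms and score every replicate at its core SNP.

    Balanced arm: forward replicates conditioned on maintenance, scored
    at the balanced variant (replicates where the sample happens to
    miss the balanced polymorphism are skipped).  The outgroup branch
    is not simulated here: neither β nor Tajima's D uses substitutions
    and the branch is independent of the human sample.  Neutral arm:
    coalescent replicates, one frequency-matched core each.
    """
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(3 + n_balanced, np.uint32) % (2**31 - 1)
    target = equilibrium_frequency(config.h, config.s)

    bb, tb, fb, freqs, rst = [], [], [], [], []
    for k in range(n_balanced):
        cfg = replace(
            config, seed=int(child[3 + k]), sample_outgroup=False
        )
        res = run_forward(cfg, balanced=True)
        rst.append(res.restarts)
        if not res.balanced_count:
            logger.info("replicate %d: balanced variant absent from sample", k)
            continue
        freqs.append(res.balanced_freq)
        beta, tajd, frac = _score_core(
            res, res.balanced_pos, res.balanced_count, window_bp, p
        )
        bb.append(beta)
        tb.append(tajd)
        fb.append(frac)

    neutral = run_neutral_coalescent(config, n_neutral, seed=int(child[0]))
    cores = match_neutral_cores(
        neutral,
        target,
        tolerance=match_tolerance,
        max_per_replicate=1,
        seed=int(child[1]),
    )
    bn, tn, fn = [], [], []
    for mc in cores:
        beta, tajd, frac = _score_core(
            neutral[mc.replicate], mc.position, mc.derived_count, window_bp, p
        )
        bn.append(beta)
        tn.append(tajd)
        fn.append(frac)

    return PowerExperiment(
        beta_balanced=np.array(bb),
        beta_neutral=np.array(bn),
        tajd_balanced=np.array(tb),
        tajd_neutral=np.array(tn),
        buildup_balanced=np.array(fb),
        buildup_neutral=np.array(fn),
        balanced_freqs=np.array(freqs),
        restarts=np.array(rst, dtype=np.int64),
    )
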