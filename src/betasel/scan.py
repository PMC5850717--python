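"""Sliding-window β scan and shared-signal calling.

Every polymorphic site in turn serves as the core SNP; the surrounding
SNPs within a fixed window (default 1 kb, half-open
[center − w/2, center + w/2), core excluded) form the spectrum from
which β is computed.  Core SNPs below a minimum folded frequency
(default 15%) are skipped: balanced polymorphisms with a rarer minor
allele are not expected to survive drift, and such cores mostly add
false positives.  Per-population score vectors are then thresholded at
a top percentile, and signals flagged in enough populations are called
as shared (old) balancing selection candidates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import core_stats
from .core_stats import BetaScore, WindowSpectrum
from .io import MaskSet, SiteCount

logger = logging.getLogger(__name__)

__all__ = [
    "ScanConfig",
    "build_window",
    "scan_population",
    "call_top_sites",
    "neutral_threshold",
]


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of a β scan.

    window_bp is the total window span in base pairs; p the similarity
    exponent; min_folded_freq the per-core folded-frequency floor (as a
    proportion); percentile the top fraction flagged per population;
    sharing_fraction the fraction of populations a flagged site must
    recur in to be called shared.  fold_mode selects the unfolded
    (ancestral-state-aware) or fully folded statistic.  window_mask
    drops a core SNP whose whole window overlaps a masked base; when
    False masking is left to site-level filtering.
    """

    window_bp: int = 1000
    p: float = 2.0
    min_folded_freq: float = 0.15
    percentile: float = 0.01
    fold_mode: str = "unfolded"
    sharing_fraction: float = 0.5
    window_mask: bool = True

    def __post_init__(self) -> None:
        if self.window_bp < 2:
            raise ValueError("window_bp must be >= 2")
        if not 0 < self.percentile < 1:
            raise ValueError("percentile must be in (0, 1)")
        if not 0 <= self.min_folded_freq <= 0.5:
            raise ValueError("min_folded_freq must be in [0, 0.5]")
        if self.fold_mode not in ("folded", "unfolded"):
            raise ValueError(f"unknown fold_mode {self.fold_mode!r}")
        if not 0 < self.sharing_fraction <= 1:
            raise ValueError("sharing_fraction must be in (0, 1]")
        if self.p <= 0:
            raise ValueError("p must be positive")


def build_window(
    core: SiteCount, sites: Sequence[SiteCount], window_bp: int
) -> WindowSpectrum:
    """Spectrum of the SNPs within window_bp of a core SNP, core excluded.

    Membership is the half-open interval
    [core.position − window_bp/2, core.position + window_bp/2).  Sites
    must be sorted by position and share the core's sample size.
    """
    half = window_bp / 2.0
    lo = core.position - half
    hi = core.position + half
    positions = np.array([s.position for s in sites])
    i0, i1 = np.searchsorted(positions, [lo, hi], side="left")
    counts = []
    for s in sites[i0:i1]:
        if s.position == core.position:
            continue
        if s.sample_size != core.sample_size:
            raise ValueError(
                "mixed sample sizes in window; use the variable-n path"
            )
        counts.append(s.derived_count)
    return WindowSpectrum.from_derived_counts(
        counts, core.sample_size, core_count=core.derived_count
    )


def _window_members(
    positions: np.ndarray, center: int, window_bp: int
) -> tuple[int, int]:
    half = window_bp / 2.0
    i0 = int(np.searchsorted(positions, center - half, side="left"))
    i1 = int(np.searchsorted(positions, center + half, side="left"))
    return i0, i1


def scan_population(
    sites: Sequence[SiteCount],
    config: ScanConfig,
    masks: MaskSet | None = None,
    contig: str = "",
) -> list[BetaScore]:
    """β for every eligible core SNP of one population/contig.

    Cores failing the folded-frequency floor are skipped.  With a mask
    and ``config.window_mask``, cores whose window overlaps a masked
    base are skipped (the windowed SNP count would be unreliable there);
    site-level mask filtering should be applied to ``sites`` beforehand
    via :func:`betasel.io.apply_mask` if desired.  Output is
    deterministic given the input.
    """
    out: list[BetaScore] = []
    if not sites:
        return out
    positions = np.array([s.position for s in sites])
    uniform_n = len({s.sample_size for s in sites}) == 1
    half = config.window_bp / 2.0
    for k, core in enumerate(sites):
        if core.folded_freq < config.min_folded_freq:
            continue
        if (
            masks is not None
            and config.window_mask
            and masks.overlaps_window(
                contig, core.position - half, core.position + half
            )
        ):
            continue
        i0, i1 = _window_members(positions, core.position, config.window_bp)
        neighbors = [s for s in sites[i0:i1] if s.position != core.position]
        if uniform_n:
            spec = WindowSpectrum.from_derived_counts(
                (s.derived_count for s in neighbors),
                core.sample_size,
                core_count=core.derived_count,
            )
            if config.fold_mode == "folded":
                score = core_stats.beta_folded(
                    core.sample_size,
                    core_stats.fold_spectrum(spec),
                    core.folded_count,
                    config.p,
                    position=core.position,
                )
            else:
                score = core_stats.beta_unfolded(
                    spec, config.p, position=core.position
                )
        else:
            if config.fold_mode == "folded":
                raise NotImplementedError(
                    "folded mode requires a uniform sample size"
                )
            score = core_stats.beta_variable_n(
                core.derived_count,
                core.sample_size,
                [s.derived_count for s in neighbors],
                [s.sample_size for s in neighbors],
                config.p,
                position=core.position,
            )
        out.append(score)
    return out


def call_top_sites(
    scores_by_pop: Mapping[str, Sequence[BetaScore]], config: ScanConfig
) -> tuple[dict[str, set[int]], set[int]]:
    """Flag top-percentile scores per population and call shared signals.

    Within each population the ceil(percentile × N) highest non-missing
    β scores are flagged (ties broken deterministically by position).
    The shared set contains positions flagged in at least
    ceil(sharing_fraction × #populations) populations.
    """
    if not scores_by_pop:
        raise ValueError("need at least one population")
    flags: dict[str, set[int]] = {}
    for pop, scores in scores_by_pop.items():
        valid = [sc for sc in scores if not math.isnan(sc.beta)]
        n = len(valid)
        if n == 0:
            flags[pop] = set()
            continue
        k = math.ceil(config.percentile * n)
        if n < 1.0 / config.percentile:
            logger.warning(
                "population %s has %d scores (< 1/percentile); using top %d",
                pop,
                n,
                k,
            )
        ranked = sorted(valid, key=lambda sc: (-sc.beta, sc.position))
        flags[pop] = {sc.position for sc in ranked[:k]}
    n_pops = len(scores_by_pop)
    need = math.ceil(config.sharing_fraction * n_pops)
    tally: dict[int, int] = {}
    for posset in flags.values():
        for pos in posset:
            tally[pos] = tally.get(pos, 0) + 1
    shared = {pos for pos, c in tally.items() if c >= need}
    return flags, shared


def neutral_threshold(neutral_scores: Sequence[float], quantile: float) -> float:
    """Empirical quantile of a neutral β distribution (type-7 interpolation).

    Used to turn simulated neutral score distributions into genome-scan
    significance cutoffs, e.g. ``quantile=0.9995`` for a top-0.05-percentile
    threshold.
    """
    arr = np.asarray(neutral_scores, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no neutral scores supplied")
    if not 0 <= quantile <= 1:
        raise ValueError("quantile must be in [0, 1]")
    return float(np.quantile(arr, quantile, method="linear"))
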