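"""Input/output: allele-count tables, VCF-derived counts, BED masks, score tables.

The native input is a whitespace-delimited table with one polymorphic
site per line, ``position derived_count sample_size``; positions are
1-based and must increase strictly within a file (one file per contig).
Counts can also be derived directly from a multi-sample VCF, polarizing
by the AA (ancestral allele) INFO tag.  Accessibility / repeat masks are
read from BED.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_stats import BetaScore

logger = logging.getLogger(__name__)

__all__ = [
    "SiteCount",
    "MaskSet",
    "CountTableError",
    "read_count_table",
    "write_count_table",
    "vcf_to_counts",
    "read_bed",
    "apply_mask",
    "write_scores",
    "read_scores",
]


class CountTableError(ValueError):
    """Malformed or mis-ordered allele-count table."""


@dataclass(frozen=True)
class SiteCount:
    """One polymorphic site.

    position is a 1-based genomic coordinate; derived_count is the
    number of derived-allele copies among sample_size sampled
    chromosomes.  Sites retained for analysis satisfy
    1 <= derived_count <= sample_size - 1.
    """

    position: int
    derived_count: int
    sample_size: int

    @property
    def folded_count(self) -> int:
        return min(self.derived_count, self.sample_size - self.derived_count)

    @property
    def folded_freq(self) -> float:
        return self.folded_count / self.sample_size

    def is_polymorphic(self) -> bool:
        return 1 <= self.derived_count <= self.sample_size - 1


def read_count_table(
    path: str | Path, drop_monomorphic: bool = True
) -> list[SiteCount]:
    """Read a 3-column allele-count table.

    An optional header line (first line beginning with a non-digit) is
    skipped.  Monomorphic lines (count 0 or n) are dropped with a
    warning by default, or rejected when ``drop_monomorphic`` is False.
    Positions must be strictly increasing.
    """
    sites: list[SiteCount] = []
    last_pos = -1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if lineno == 1 and not line[0].isdigit():
                continue  # header
            fields = line.split()
            if len(fields) != 3:
                raise CountTableError(
                    f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                )
            try:
                pos, cnt, n = (int(x) for x in fields)
            except ValueError as exc:
                raise CountTableError(f"{path}:{lineno}: {exc}") from None
            if not 0 <= cnt <= n:
                raise CountTableError(
                    f"{path}:{lineno}: derived count {cnt} outside [0, {n}]"
                )
            if pos <= last_pos:
                raise CountTableError(
                    f"{path}:{lineno}: position {pos} not strictly increasing"
                )
            last_pos = pos
            site = SiteCount(pos, cnt, n)
            if not site.is_polymorphic():
                if drop_monomorphic:
                    logger.warning(
                        "%s:%d: dropping monomorphic site at %d", path, lineno, pos
                    )
                    continue
                raise CountTableError(
                    f"{path}:{lineno}: monomorphic site at position {pos}"
                )
            sites.append(site)
    return sites


def write_count_table(sites: Iterable[SiteCount], path: str | Path) -> None:
    """Write sites as a 3-column table with a header line."""
    with open(path, "w") as fh:
        fh.write("position\tderived_count\tsample_size\n")
        for s in sites:
            fh.write(f"{s.position}\t{s.derived_count}\t{s.sample_size}\n")


# ---------------------------------------------------------------------------
# VCF


def vcf_to_counts(
    vcf_path: str | Path,
    samples: Sequence[str],
    keep_unpolarized: bool = False,
) -> dict[str, list[SiteCount]]:
    """Derive per-site allele counts for a set of samples from a VCF.

    Only biallelic SNP records are used (multiallelic records are
    skipped with a warning).  The ancestral allele is taken from the AA
    INFO tag; the derived count is the number of non-ancestral alleles
    among the genotypes of ``samples``.  Missing genotype calls reduce
    that site's sample size.  Sites whose AA is absent or matches
    neither allele are dropped unless ``keep_unpolarized`` is set (for
    folded-only analyses), in which case the ALT allele is counted.

    Returns a mapping contig -> sites in ascending position order.
    """
    import pysam

    out: dict[str, list[SiteCount]] = {}
    with pysam.VariantFile(str(vcf_path)) as vf:
        header_samples = set(vf.header.samples)
        missing = [s for s in samples if s not in header_samples]
        if missing:
            raise KeyError(f"samples not in VCF header: {missing}")
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                logger.warning(
                    "%s:%d: skipping non-biallelic record", rec.chrom, rec.pos
                )
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                logger.warning("%s:%d: skipping non-SNP record", rec.chrom, rec.pos)
                continue
            aa = rec.info.get("AA")
            if isinstance(aa, (tuple, list)):
                aa = aa[0] if aa else None
            aa = aa.strip().upper() if isinstance(aa, str) else None
            if aa == ref.upper():
                derived_idx = 1
            elif aa == alt.upper():
                derived_idx = 0
            elif keep_unpolarized:
                derived_idx = 1  # arbitrary orientation; folded use only
            else:
                logger.warning(
                    "%s:%d: no usable ancestral allele; site dropped",
                    rec.chrom,
                    rec.pos,
                )
                continue
            derived = 0
            n = 0
            for s in samples:
                for allele in rec.samples[s].allele_indices:
                    if allele is None:
                        continue
                    n += 1
                    if allele == derived_idx:
                        derived += 1
            if n == 0 or derived == 0 or derived == n:
                continue
            out.setdefault(rec.chrom, []).append(SiteCount(rec.pos, derived, n))
    return out


# ---------------------------------------------------------------------------
# masks


@dataclass(frozen=True)
class MaskSet:
    """Normalized genomic intervals with keep/drop polarity.

    Intervals follow BED convention: half-open [start, end).  Positions
    are compared directly against the interval bounds, matching the
    half-open rule (a site at ``end`` is outside).  After normalization
    the per-contig intervals are sorted and non-overlapping.
    """

    intervals: Mapping[str, np.ndarray]  # contig -> (k, 2) int array
    polarity: str = "drop-inside"

    def __post_init__(self) -> None:
        if self.polarity not in ("drop-inside", "keep-inside"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @classmethod
    def from_intervals(
        cls,
        intervals: Iterable[tuple[str, int, int]],
        polarity: str = "drop-inside",
    ) -> "MaskSet":
        """Build from (contig, start, end) triples, merging overlaps."""
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end in intervals:
            if start >= end:
                raise ValueError(f"empty interval {contig}:{start}-{end}")
            by_contig.setdefault(contig, []).append((int(start), int(end)))
        merged: dict[str, np.ndarray] = {}
        for contig, ivals in by_contig.items():
            ivals.sort()
            out: list[list[int]] = []
            for s, e in ivals:
                if out and s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            merged[contig] = np.array(out, dtype=np.int64)
        return cls(intervals=merged, polarity=polarity)

    def contains(self, contig: str, positions: np.ndarray) -> np.ndarray:
        """Boolean mask: which positions fall inside an interval."""
        ivals = self.intervals.get(contig)
        positions = np.asarray(positions)
        if ivals is None or len(ivals) == 0:
            return np.zeros(positions.shape, dtype=bool)
        idx = np.searchsorted(ivals[:, 0], positions, side="right") - 1
        inside = idx >= 0
        inside[inside] &= positions[inside] < ivals[idx[inside], 1]
        return inside

    def overlaps_window(self, contig: str, start: float, end: float) -> bool:
        """Does any interval overlap the half-open window [start, end)?"""
        ivals = self.intervals.get(contig)
        if ivals is None or len(ivals) == 0:
            return False
        i = np.searchsorted(ivals[:, 1], start, side="right")
        return i < len(ivals) and ivals[i, 0] < end


def read_bed(path: str | Path, polarity: str = "drop-inside") -> MaskSet:
    """Read a BED3+ file into a normalized MaskSet."""
    triples: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                triples.append((fields[0], int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return MaskSet.from_intervals(triples, polarity=polarity)


def apply_mask(
    sites: Sequence[SiteCount], masks: MaskSet, contig: str = ""
) -> list[SiteCount]:
    """Filter sites by a mask (site-level).

    drop-inside removes sites whose position falls in an interval;
    keep-inside retains only those.  Window-level masking (dropping a
    core SNP whose whole window touches a masked base) lives in the scan
    layer.
    """
    if not sites:
        return []
    positions = np.array([s.position for s in sites])
    inside = masks.contains(contig, positions)
    keep = inside if masks.polarity == "keep-inside" else ~inside
    return [s for s, k in zip(sites, keep) if k]


# ---------------------------------------------------------------------------
# score tables


def write_scores(scores: Iterable[BetaScore], path: str | Path) -> None:
    """Write β scores as TSV: position, folded_freq, theta_beta, theta_w, beta."""
    with open(path, "w") as fh:
        fh.write("position\tfolded_freq\ttheta_beta\ttheta_w\tbeta\n")
        for sc in scores:
            fh.write(
                f"{sc.position}\t{sc.folded_freq:.6g}\t{sc.theta_beta:.10g}\t"
                f"{sc.theta_w:.10g}\t{sc.beta:.10g}\n"
            )


def read_scores(path: str | Path) -> list[BetaScore]:
    """Read a TSV written by :func:`write_scores`."""
    out: list[BetaScore] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {name: i for i, name in enumerate(header)}
        for raw in fh:
            f = raw.split()
            if not f:
                continue
            tb = float(f[cols["theta_beta"]])
            tw = float(f[cols["theta_w"]])
            beta = float(f[cols["beta"]])
            nw = 0 if math.isnan(beta) else -1
            out.append(
                BetaScore(
                    int(f[cols["position"]]),
                    float(f[cols["folded_freq"]]),
                    tb,
                    tw,
                    beta,
                    nw,
                )
            )
    return out
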