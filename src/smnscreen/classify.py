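"""Paralog attribution of reads via PSV bases, and per-site pileups.

SMN1 and SMN2 are distinguished by the base a read carries at a handful of
paralog-specific variant (PSV) positions, not by where it maps: an aligner
co-maps reads from both genes onto SMN1 with MAPQ ~0.  Accordingly this
module never filters on MAPQ.  A read is assigned by majority vote over its
usable PSV observations (base quality >= the configured floor, base != N);
ties — including reads showing only third-allele bases — are AMBIGUOUS, so
ambiguous reads can never contribute SMN1 evidence.

Base extraction assumes ungapped alignments; records whose CIGAR carries
indels, splices or clips are skipped with a logged warning rather than
risking an off-register base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .locus import CallingThresholds, PsvSite, SmnLocusConfig
from .samio import AlignedRead

__all__ = [
    "PsvObservation",
    "ReadClass",
    "SiteCounts",
    "PsvPileup",
    "extract_psv_observations",
    "classify_read",
    "classify_reads",
    "build_pileup",
]

logger = logging.getLogger(__name__)

_UNGAPPED_OPS = frozenset("M=X0123456789")


class ReadClass(Enum):
    SMN1 = "SMN1"
    SMN2 = "SMN2"
    AMBIGUOUS = "AMBIGUOUS"
    UNINFORMATIVE = "UNINFORMATIVE"


@dataclass(frozen=True)
class PsvObservation:
    """One read's base call at one PSV site."""

    site: PsvSite
    base: str
    qual: int


@dataclass(frozen=True)
class SiteCounts:
    """Quality-passing pileup counts at one PSV site."""

    smn1: int = 0
    smn2: int = 0
    other: int = 0

    @property
    def total(self) -> int:
        return self.smn1 + self.smn2 + self.other


@dataclass(frozen=True)
class PsvPileup:
    """Per-site counts of SMN1-supporting / SMN2-supporting / other bases."""

    counts: tuple[SiteCounts, ...]
    sites: tuple[PsvSite, ...]

    def total_depths(self) -> tuple[int, ...]:
        return tuple(c.total for c in self.counts)


def _is_ungapped(cigar: str) -> bool:
    return not cigar or all(ch in _UNGAPPED_OPS for ch in cigar)


def extract_psv_observations(
    read: AlignedRead, cfg: SmnLocusConfig
) -> list[PsvObservation]:
    """Observations at every configured PSV position the read's span covers.

    Offset arithmetic is ungapped (position minus leftmost mapped position);
    gapped records are skipped entirely.  Unmapped reads yield nothing.
    """
    if not read.is_mapped:
        return []
    if not _is_ungapped(read.cigar):
        logger.warning(
            "read %s has gapped CIGAR %s over the SMN region; skipping PSV "
            "extraction for it",
            read.read_id,
            read.cigar,
        )
        return []
    obs: list[PsvObservation] = []
    for site in cfg.psv_sites:
        if read.chrom != site.chrom:
            continue
        off = site.pos - read.pos
        if 0 <= off < len(read.seq):
            obs.append(
                PsvObservation(site=site, base=read.seq[off], qual=read.quals[off])
            )
    return obs


def classify_read(
    observations: Sequence[PsvObservation], thresholds: CallingThresholds
) -> ReadClass:
    """Majority vote over usable PSV observations.

    Observations below the base-quality floor or with base N are dropped.
    No usable observation -> UNINFORMATIVE; more SMN1-matching bases -> SMN1;
    more SMN2-matching -> SMN2; tie (including only third-allele bases) ->
    AMBIGUOUS.
    """
    n1 = n2 = usable = 0
    for o in observations:
        if o.qual < thresholds.min_base_quality or o.base == "N":
            continue
        usable += 1
        if o.base == o.site.smn1_base:
            n1 += 1
        elif o.base == o.site.smn2_base:
            n2 += 1
    if usable == 0:
        return ReadClass.UNINFORMATIVE
    if n1 > n2:
        return ReadClass.SMN1
    if n2 > n1:
        return ReadClass.SMN2
    return ReadClass.AMBIGUOUS


def classify_reads(
    reads: Iterable[AlignedRead], cfg: SmnLocusConfig
) -> dict[ReadClass, int]:
    """Per-class counts over all mapped reads (a partition of them)."""
    counts = {c: 0 for c in ReadClass}
    for read in reads:
        if not read.is_mapped:
            continue
        counts[classify_read(extract_psv_observations(read, cfg), cfg.thresholds)] += 1
    return counts


def build_pileup(reads: Iterable[AlignedRead], cfg: SmnLocusConfig) -> PsvPileup:
    """Aggregate quality-passing PSV base counts over all mapped reads.

    Each read contributes at most one observation per site.  MAPQ-0 reads are
    included by design: at a segmental duplication every informative read is
    a multi-mapper.
    """
    minq = cfg.thresholds.min_base_quality
    sites = cfg.psv_sites
    n1 = [0] * len(sites)
    n2 = [0] * len(sites)
    other = [0] * len(sites)
    for read in reads:
        for obs in extract_psv_observations(read, cfg):
            if obs.qual < minq or obs.base == "N":
                continue
            i = sites.index(obs.site)
            if obs.base == obs.site.smn1_base:
                n1[i] += 1
            elif obs.base == obs.site.smn2_base:
                n2[i] += 1
            else:
                other[i] += 1
    return PsvPileup(
        counts=tuple(
            SiteCounts(smn1=a, smn2=b, other=c) for a, b, c in zip(n1, n2, other)
        ),
        sites=tuple(sites),
    )
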