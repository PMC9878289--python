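"""Sample QC, coverage-score computation, and the qualitative screen call.

The screen decides one thing per sample: is SMN1 exon 7 absent on both
alleles?  The evidence is the *coverage score* — SMN1-supporting read depth
at the PSV sites, normalised to copy-equivalents by half the mean control-gene
depth (control genes are diploid, so half their depth is the per-copy depth
scale).  A QC-passing sample scoring below the deletion cutoff is POSITIVE;
everything else, including carriers at ~1 copy-equivalent, is NEGATIVE by
design.  Samples failing QC are FAIL and never receive a POSITIVE/NEGATIVE
call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .classify import PsvPileup, build_pileup
from .locus import CallingThresholds, SmnLocusConfig
from .samio import AlignedRead

__all__ = [
    "SampleMetrics",
    "CoverageScore",
    "QcResult",
    "ScreenCall",
    "ScreenResult",
    "compute_metrics",
    "qc_sample",
    "coverage_score",
    "call_sample",
    "screen_sample",
]

#: Per-base depth must reach this fraction of the sample mean to count as
#: uniformly covered.
UNIFORMITY_FRACTION = 0.2


@dataclass(frozen=True)
class SampleMetrics:
    """Depth and uniformity QC metrics for one sample.

    ``uniformity`` is the fraction of targeted control-gene bases with depth
    at least ``UNIFORMITY_FRACTION`` x the mean control depth.
    ``psv_total_depth`` is the mean, over PSV sites, of total quality-passing
    base counts.
    """

    mean_control_depth: float
    per_gene_depth: tuple[float, ...]
    uniformity: float
    total_reads: int
    psv_total_depth: float


@dataclass(frozen=True)
class CoverageScore:
    """Normalised SMN1 exon 7 copy estimate (dimensionless copy-equivalents)."""

    score: float
    per_site_scores: tuple[float, ...]


class QcResult(NamedTuple):
    passed: bool
    fail_reason: str


class ScreenCall:
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    FAIL = "FAIL"


@dataclass(frozen=True)
class ScreenResult:
    """Qualitative per-sample outcome with its supporting evidence."""

    sample_id: str
    call: str
    score: CoverageScore | None
    metrics: SampleMetrics
    fail_reason: str = ""


def compute_metrics(
    reads: Iterable[AlignedRead],
    pileup: PsvPileup,
    cfg: SmnLocusConfig,
) -> SampleMetrics:
    """Depth, uniformity and PSV-depth metrics from a sample's reads.

    Per-interval depth is (aligned bases falling inside the interval) divided
    by interval length; the sample's control depth is the mean over control
    intervals.  Uniformity pools all control-interval bases.
    """
    controls = cfg.control_genes
    depth_arrays = [np.zeros(c.length + 1, dtype=np.int64) for c in controls]
    total_reads = 0
    for read in reads:
        if not read.is_mapped:
            continue
        total_reads += 1
        for arr, c in zip(depth_arrays, controls):
            if read.chrom != c.chrom:
                continue
            lo = max(read.pos, c.start)
            hi = min(read.end, c.end)
            if lo > hi:
                continue
            arr[lo - c.start] += 1
            arr[hi - c.start + 1] -= 1

    per_base = [np.cumsum(arr[:-1]) for arr in depth_arrays]
    per_gene_depth = tuple(float(pb.mean()) if pb.size else 0.0 for pb in per_base)
    mean_control_depth = float(np.mean(per_gene_depth)) if per_gene_depth else 0.0

    if mean_control_depth > 0:
        pooled = np.concatenate(per_base)
        uniformity = float(
            (pooled >= UNIFORMITY_FRACTION * mean_control_depth).mean()
        )
    else:
        uniformity = 0.0

    depths = pileup.total_depths()
    psv_total_depth = float(np.mean(depths)) if depths else 0.0
    return SampleMetrics(
        mean_control_depth=mean_control_depth,
        per_gene_depth=per_gene_depth,
        uniformity=uniformity,
        total_reads=total_reads,
        psv_total_depth=psv_total_depth,
    )


def qc_sample(metrics: SampleMetrics, thresholds: CallingThresholds) -> QcResult:
    """Apply the sample-failure rules; thresholds fail *strictly below*.

    A sample at exactly the minimum control depth passes.  The reason names
    the first failing rule (control depth, then PSV depth, then uniformity).
    """
    if metrics.mean_control_depth < thresholds.min_control_depth:
        return QcResult(
            False,
            f"control depth {metrics.mean_control_depth:.2f} < "
            f"{thresholds.min_control_depth:g}X",
        )
    if metrics.psv_total_depth < thresholds.min_psv_total_depth:
        return QcResult(
            False,
            f"PSV depth {metrics.psv_total_depth:.2f} < "
            f"{thresholds.min_psv_total_depth:g}",
        )
    if metrics.uniformity < thresholds.min_uniformity:
        return QcResult(
            False,
            f"uniformity {metrics.uniformity:.3f} < {thresholds.min_uniformity:g}",
        )
    return QcResult(True, "")


def coverage_score(pileup: PsvPileup, metrics: SampleMetrics) -> CoverageScore:
    """SMN1 copy-equivalents: per-site SMN1 depth over half the control depth.

    Control genes are diploid, so ``mean_control_depth / 2`` is the depth one
    gene copy contributes; dividing the SMN1-supporting PSV depth by it puts
    the score on a copy-number scale (0 = homozygous deletion, ~1 = carrier,
    ~2 = two copies).  The final score is the mean over PSV sites.
    """
    if metrics.mean_control_depth <= 0:
        raise ValueError(
            "coverage score undefined: mean control depth is zero "
            "(sample should have failed QC)"
        )
    per_copy = metrics.mean_control_depth / 2.0
    per_site = tuple(c.smn1 / per_copy for c in pileup.counts)
    return CoverageScore(
        score=float(np.mean(per_site)) if per_site else 0.0,
        per_site_scores=per_site,
    )


def call_sample(
    sample_id: str,
    score: CoverageScore | None,
    qc: QcResult,
    thresholds: CallingThresholds,
    metrics: SampleMetrics,
) -> ScreenResult:
    """Emit the qualitative screen outcome; QC failure takes precedence.

    POSITIVE iff the score is strictly below the deletion cutoff.  Carriers
    (~1 copy-equivalent) are NEGATIVE: the screen detects only the homozygous
    deletion.
    """
    if not qc.passed:
        return ScreenResult(
            sample_id=sample_id,
            call=ScreenCall.FAIL,
            score=None,
            metrics=metrics,
            fail_reason=qc.fail_reason,
        )
    if score is None:
        raise ValueError("QC passed but no score supplied")
    call = (
        ScreenCall.POSITIVE
        if score.score < thresholds.deletion_score_cutoff
        else ScreenCall.NEGATIVE
    )
    return ScreenResult(
        sample_id=sample_id, call=call, score=score, metrics=metrics, fail_reason=""
    )


def screen_sample(
    sample_id: str,
    reads: Sequence[AlignedRead],
    cfg: SmnLocusConfig,
    library_failed: bool = False,
) -> ScreenResult:
    """Full per-sample pipeline: pileup -> metrics -> QC -> score -> call.

    ``library_failed`` marks an upstream wet-lab failure (insufficient
    pre-capture library); it forces FAIL without touching the reads.
    """
    pileup = build_pileup(reads, cfg)
    metrics = compute_metrics(reads, pileup, cfg)
    if library_failed:
        return ScreenResult(
            sample_id=sample_id,
            call=ScreenCall.FAIL,
            score=None,
            metrics=metrics,
            fail_reason="insufficient pre-capture library",
        )
    qc = qc_sample(metrics, cfg.thresholds)
    if not qc.passed:
        return call_sample(sample_id, None, qc, cfg.thresholds, metrics)
    score = coverage_score(pileup, metrics)
    return call_sample(sample_id, score, qc, cfg.thresholds, metrics)
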