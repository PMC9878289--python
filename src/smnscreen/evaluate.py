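"""Batch screening, truth comparison and report writing.

``run_batch`` turns a list of per-sample SAM files into one ScreenResult
each; a corrupt or unreadable file yields a FAIL row rather than aborting the
batch.  ``evaluate`` compares calls with a truth table using the standard
screening-assay definitions: sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP).  FAIL samples are excluded from the 2x2 cells and reported via a
separate failure rate, and an undefined ratio (no positives in truth) is
``None`` — reported as not applicable, never as 0.  Confidence intervals are
deliberately not computed: the screen output is qualitative.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import __version__
from .calling import ScreenCall, ScreenResult, screen_sample
from .locus import SmnLocusConfig
from .samio import read_sam

__all__ = [
    "ConfusionTable",
    "CohortSummary",
    "run_batch",
    "evaluate",
    "load_truth",
    "write_reports",
]


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 screening counts plus the QC-failure tally."""

    tp: int
    fp: int
    tn: int
    fn: int
    fail_count: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn + self.fail_count

    @property
    def sensitivity(self) -> float | None:
        """TP / (TP + FN); None when no positive samples exist in truth."""
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    @property
    def specificity(self) -> float | None:
        """TN / (TN + FP); None when no negative samples exist in truth."""
        denom = self.tn + self.fp
        return self.tn / denom if denom else None

    @property
    def failure_rate(self) -> float | None:
        return self.fail_count / self.total if self.total else None


@dataclass(frozen=True)
class CohortSummary:
    """All per-sample screen results of one batch, in input order."""

    results: tuple[ScreenResult, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "sample_id": r.sample_id,
                    "call": r.call,
                    "score": r.score.score if r.score is not None else float("nan"),
                    "mean_control_depth": r.metrics.mean_control_depth,
                    "uniformity": r.metrics.uniformity,
                    "psv_total_depth": r.metrics.psv_total_depth,
                    "fail_reason": r.fail_reason,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "sample_id",
                "call",
                "score",
                "mean_control_depth",
                "uniformity",
                "psv_total_depth",
                "fail_reason",
            ],
        )


def run_batch(
    sam_paths: Sequence[str | Path],
    cfg: SmnLocusConfig,
    sample_ids: Sequence[str] | None = None,
) -> CohortSummary:
    """Screen every SAM file; sample ids default to file stems.

    An unreadable or malformed input becomes a FAIL result with reason
    "unreadable input" and the batch continues — one bad sample must not sink
    a screening run.  Samples are independent, so processing order cannot
    affect any per-sample result.
    """
    if sample_ids is None:
        sample_ids = [Path(p).stem for p in sam_paths]
    if len(sample_ids) != len(sam_paths):
        raise ValueError("sample_ids and sam_paths length mismatch")

    results: list[ScreenResult] = []
    for sid, path in zip(sample_ids, sam_paths):
        try:
            reads = read_sam(path)
        except Exception:
            from .calling import SampleMetrics

            results.append(
                ScreenResult(
                    sample_id=sid,
                    call=ScreenCall.FAIL,
                    score=None,
                    metrics=SampleMetrics(0.0, (), 0.0, 0, 0.0),
                    fail_reason="unreadable input",
                )
            )
            continue
        results.append(screen_sample(sid, reads, cfg))
    return CohortSummary(results=tuple(results))


def load_truth(path: str | Path) -> dict[str, str]:
    """Read a truth TSV (sample_id, ..., expected_call) into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["sample_id"], df["expected_call"]))


def evaluate(
    summary: CohortSummary, truth: Mapping[str, str] | str | Path
) -> ConfusionTable:
    """Confusion table of screen calls against expected calls.

    ``truth`` maps sample_id -> POSITIVE/NEGATIVE (or is a path to a truth
    TSV).  FAIL samples are counted separately and excluded from the 2x2
    cells.  A summary sample missing from truth is an error naming it.
    """
    if not isinstance(truth, Mapping):
        truth = load_truth(truth)
    tp = fp = tn = fn = fail = 0
    for r in summary.results:
        if r.sample_id not in truth:
            raise KeyError(f"sample {r.sample_id} missing from truth table")
        if r.call == ScreenCall.FAIL:
            fail += 1
            continue
        expected = truth[r.sample_id]
        if r.call == ScreenCall.POSITIVE:
            if expected == ScreenCall.POSITIVE:
                tp += 1
            else:
                fp += 1
        else:
            if expected == ScreenCall.POSITIVE:
                fn += 1
            else:
                tn += 1
    return ConfusionTable(tp=tp, fp=fp, tn=tn, fn=fn, fail_count=fail)


def _result_json(r: ScreenResult, cfg: SmnLocusConfig) -> dict:
    return {
        "sample_id": r.sample_id,
        "call": r.call,
        "score": r.score.score if r.score is not None else None,
        "per_site_scores": list(r.score.per_site_scores) if r.score else None,
        "fail_reason": r.fail_reason,
        "metrics": {
            "mean_control_depth": r.metrics.mean_control_depth,
            "per_gene_depth": list(r.metrics.per_gene_depth),
            "uniformity": r.metrics.uniformity,
            "total_reads": r.metrics.total_reads,
            "psv_total_depth": r.metrics.psv_total_depth,
        },
        "thresholds": dataclasses.asdict(cfg.thresholds),
        "software_version": __version__,
        # Sole non-deterministic field, kept in a dedicated key so reruns can
        # be compared byte-for-byte after masking it.
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }


def write_reports(
    summary: CohortSummary,
    out_dir: str | Path,
    cfg: SmnLocusConfig,
    plot: bool = True,
) -> dict[str, Path]:
    """Write the batch TSV, one JSON per sample, and a score scatter plot.

    The scatter is the visual the screen is read from: one score per sample
    with a dotted line at the deletion cutoff; QC-passing samples below the
    line are screen positive.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    batch_path = out_dir / "batch_summary.tsv"
    summary.to_frame().to_csv(batch_path, sep="\t", index=False, float_format="%.6g")
    paths["batch"] = batch_path

    sample_dir = out_dir / "samples"
    sample_dir.mkdir(exist_ok=True)
    for r in summary.results:
        p = sample_dir / f"{r.sample_id}.json"
        p.write_text(json.dumps(_result_json(r, cfg), indent=2) + "\n")
    paths["samples"] = sample_dir

    if plot and summary.results:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = summary.to_frame()
        called = df[df["call"] != ScreenCall.FAIL]
        fig, ax = plt.subplots(figsize=(8, 4))
        colors = called["call"].map({"POSITIVE": "red", "NEGATIVE": "black"})
        ax.scatter(range(len(called)), called["score"], s=8, c=colors)
        ax.axhline(
            cfg.thresholds.deletion_score_cutoff,
            linestyle=":",
            color="grey",
            label=f"cutoff = {cfg.thresholds.deletion_score_cutoff:g}",
        )
        ax.set_xlabel("sample")
        ax.set_ylabel("coverage score (SMN1 copy-equivalents)")
        ax.legend(loc="upper right")
        fig.tight_layout()
        plot_path = out_dir / "score_scatter.png"
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
        paths["plot"] = plot_path

    return paths
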