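"""QC rules, coverage-score arithmetic and the qualitative screen call."""

import dataclasses

import numpy as np
import pytest

from smnscreen import (
    AlignedRead,
    CallingThresholds,
    CoverageScore,
    GenomicInterval,
    PsvPileup,
    SampleMetrics,
    ScreenCall,
    SimulationParams,
    SmnLocusConfig,
    build_pileup,
    call_sample,
    compute_metrics,
    coverage_score,
    qc_sample,
    screen_sample,
)
from smnscreen.classify import SiteCounts


@pytest.fixture(scope="module")
def kilo_cfg(cfg):
    """Default config with a single 1,000 bp control interval."""
    return dataclasses.replace(
        cfg, control_genes=(GenomicInterval("chr2", 1001, 2000, "CTRL"),)
    )


def _control_reads(n, length=150, chrom="chr2", start=1001):
    quals = bytes([30]) * length
    return [
        AlignedRead(
            read_id=f"c{i}",
            chrom=chrom,
            pos=start + (i * 7) % (1000 - length),
            seq="A" * length,
            quals=quals,
            mapq=60,
        )
        for i in range(n)
    ]


def test_interval_depth_is_aligned_bases_over_length(kilo_cfg):
    reads = _control_reads(100)
    metrics = compute_metrics(reads, build_pileup(reads, kilo_cfg), kilo_cfg)
    assert metrics.per_gene_depth == (pytest.approx(15.0),)  # 100*150/1000
    assert metrics.mean_control_depth == pytest.approx(15.0)
    assert metrics.total_reads == 100


def test_zero_reads_give_zero_depth_and_zero_uniformity(cfg):
    metrics = compute_metrics([], build_pileup([], cfg), cfg)
    assert metrics.mean_control_depth == 0.0
    assert metrics.uniformity == 0.0
    assert metrics.psv_total_depth == 0.0


def test_simulated_control_depth_matches_diploid_poisson_oracle(cfg, make_sample):
    """Diploid controls at haploid depth 50 -> mean control depth ~100."""
    depths = []
    for seed in range(15):
        reads, _ = make_sample(2, 0, seed=seed)
        m = compute_metrics(reads, build_pileup(reads, cfg), cfg)
        depths.append(m.mean_control_depth)
        assert m.uniformity > 0.99
    assert abs(np.mean(depths) - 100.0) < 3 * np.sqrt(100.0 / 15)


def _metrics(control=100.0, uniformity=0.99, psv=100.0):
    return SampleMetrics(
        mean_control_depth=control,
        per_gene_depth=(control,),
        uniformity=uniformity,
        total_reads=1000,
        psv_total_depth=psv,
    )


def test_qc_thresholds_fail_strictly_below(cfg):
    t = cfg.thresholds
    assert qc_sample(_metrics(control=20.0, uniformity=0.96), t).passed
    failed = qc_sample(_metrics(control=19.9), t)
    assert not failed.passed and "control depth" in failed.fail_reason
    failed = qc_sample(_metrics(uniformity=0.90), t)
    assert not failed.passed and "uniformity" in failed.fail_reason
    failed = qc_sample(_metrics(psv=5.0), t)
    assert not failed.passed and "PSV depth" in failed.fail_reason
    assert qc_sample(_metrics(uniformity=0.95, psv=20.0), t).passed  # boundaries


def test_qc_reason_names_first_failing_rule(cfg):
    failed = qc_sample(_metrics(control=5.0, uniformity=0.1, psv=0.0), cfg.thresholds)
    assert failed.fail_reason.startswith("control depth")


def _pileup(cfg, smn1):
    return PsvPileup(
        counts=tuple(SiteCounts(smn1=smn1, smn2=0) for _ in cfg.psv_sites),
        sites=cfg.psv_sites,
    )


def test_score_is_smn1_depth_over_half_control_depth(cfg):
    score = coverage_score(_pileup(cfg, 50), _metrics(control=100.0))
    assert score.score == pytest.approx(1.0)
    assert score.per_site_scores == (pytest.approx(1.0),) * 3
    assert coverage_score(_pileup(cfg, 0), _metrics()).score == 0.0


def test_score_undefined_at_zero_control_depth(cfg):
    with pytest.raises(ValueError, match="control depth"):
        coverage_score(_pileup(cfg, 10), _metrics(control=0.0))


def test_call_rules_and_qc_precedence(cfg):
    from smnscreen import QcResult

    t = cfg.thresholds
    m = _metrics()
    pos = call_sample("a", CoverageScore(0.02, (0.02,)), QcResult(True, ""), t, m)
    assert pos.call == ScreenCall.POSITIVE
    neg = call_sample("b", CoverageScore(0.98, (0.98,)), QcResult(True, ""), t, m)
    assert neg.call == ScreenCall.NEGATIVE  # carrier-like score stays negative
    fail = call_sample("c", None, QcResult(False, "control depth 0.00 < 20X"), t, m)
    assert fail.call == ScreenCall.FAIL and fail.score is None
    assert fail.fail_reason


def test_simulated_carrier_screens_negative(cfg, make_sample):
    reads, truth = make_sample(1, 2, seed=41)
    result = screen_sample("carrier", reads, cfg)
    assert truth.expected_call == "NEGATIVE"
    assert result.call == ScreenCall.NEGATIVE
    assert 0.6 < result.score.score < 1.4


def test_library_failure_flag_forces_fail(cfg, make_sample):
    reads, _ = make_sample(2, 2, seed=1)
    result = screen_sample("lib", reads, cfg, library_failed=True)
    assert result.call == ScreenCall.FAIL
    assert "pre-capture library" in result.fail_reason


def test_low_depth_sample_fails_qc_not_positive(cfg):
    """A sample with almost no reads must FAIL, never be called a deletion."""
    p = SimulationParams(haploid_depth=1.0)
    from smnscreen import SampleGenotype, simulate_sample

    reads, _ = simulate_sample(SampleGenotype("ld", 0, 2), p, cfg, seed=9)
    result = screen_sample("ld", reads, cfg)
    assert result.call == ScreenCall.FAIL
    assert result.score is None


def test_expected_score_monotone_in_smn1_copies(cfg, make_sample):
    """Mean score is nondecreasing over smn1 in {0,1,2,3} (smn2 fixed)."""
    means = []
    for smn1 in range(4):
        vals = [
            screen_sample("m", make_sample(smn1, 2, seed=100 * smn1 + k)[0], cfg)
            .score.score
            for k in range(12)
        ]
        means.append(np.mean(vals))
    assert all(b > a for a, b in zip(means, means[1:]))
    for smn1, m in enumerate(means):
        assert abs(m - smn1) < 0.25
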