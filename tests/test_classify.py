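"""Read->paralog attribution: extraction, majority vote, pileup, oracles."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from smnscreen import (
    AlignedRead,
    PsvObservation,
    ReadClass,
    SimulationParams,
    build_pileup,
    classify_read,
    classify_reads,
    extract_psv_observations,
)
from smnscreen.simulate import region_templates

Q30 = bytes([30]) * 150


def make_read(pos, seq=None, chrom="chr5", quals=None, flags=0, cigar=""):
    seq = seq if seq is not None else "A" * 150
    return AlignedRead(
        read_id="r",
        chrom=chrom,
        pos=pos,
        seq=seq,
        quals=quals if quals is not None else bytes([30]) * len(seq),
        flags=flags,
        cigar=cigar,
    )


def test_extraction_covers_exactly_the_spanned_sites(cfg):
    read = make_read(70247700)  # spans 70247700..70247849
    obs = extract_psv_observations(read, cfg)
    assert [o.site.pos for o in obs] == [70247724, 70247773]


def test_control_region_read_has_no_observations(cfg):
    read = make_read(75724500, chrom="chr1")
    assert extract_psv_observations(read, cfg) == []


def test_n_base_passes_through_and_is_then_ignored(cfg):
    seq = list("A" * 150)
    seq[70247724 - 70247700] = "N"
    read = make_read(70247700, "".join(seq))
    obs = extract_psv_observations(read, cfg)
    assert obs[0].base == "N"
    # N never counts as evidence; the other site's 'A' is a third allele
    assert classify_read(obs[:1], cfg.thresholds) is ReadClass.UNINFORMATIVE


def test_unmapped_or_gapped_reads_yield_nothing(cfg):
    assert extract_psv_observations(make_read(70247700, flags=0x4), cfg) == []
    gapped = make_read(70247700, cigar="75M1D75M")
    assert extract_psv_observations(gapped, cfg) == []


def test_majority_vote_rules(cfg):
    s1, s2, s3 = cfg.psv_sites
    t = cfg.thresholds
    one_smn1 = [PsvObservation(s1, s1.smn1_base, 30)]
    assert classify_read(one_smn1, t) is ReadClass.SMN1
    tie = [PsvObservation(s1, s1.smn1_base, 30), PsvObservation(s2, s2.smn2_base, 30)]
    assert classify_read(tie, t) is ReadClass.AMBIGUOUS
    two_v_one = tie + [PsvObservation(s3, s3.smn1_base, 30)]
    assert classify_read(two_v_one, t) is ReadClass.SMN1
    assert classify_read([], t) is ReadClass.UNINFORMATIVE
    low_q = [PsvObservation(s1, s1.smn1_base, 10)]
    assert classify_read(low_q, t) is ReadClass.UNINFORMATIVE
    third_allele = [
        PsvObservation(s, b, 30)
        for s in (s1,)
        for b in "ACGT"
        if b not in (s.smn1_base, s.smn2_base)
    ][:1]
    assert classify_read(third_allele, t) is ReadClass.AMBIGUOUS


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.data())
def test_vote_symmetry_under_paralog_base_swap(cfg, data):
    """Swapping the SMN1/SMN2 base at every site swaps SMN1<->SMN2 calls."""
    sites = cfg.psv_sites
    obs = [
        PsvObservation(
            s,
            data.draw(st.sampled_from("ACGTN"), label=f"base@{s.pos}"),
            data.draw(st.integers(0, 40), label=f"qual@{s.pos}"),
        )
        for s in sites
        if data.draw(st.booleans(), label=f"use@{s.pos}")
    ]
    swapped_sites = {
        s: dataclasses.replace(s, smn1_base=s.smn2_base, smn2_base=s.smn1_base)
        for s in sites
    }
    swapped = [dataclasses.replace(o, site=swapped_sites[o.site]) for o in obs]
    flip = {
        ReadClass.SMN1: ReadClass.SMN2,
        ReadClass.SMN2: ReadClass.SMN1,
        ReadClass.AMBIGUOUS: ReadClass.AMBIGUOUS,
        ReadClass.UNINFORMATIVE: ReadClass.UNINFORMATIVE,
    }
    assert classify_read(swapped, cfg.thresholds) == flip[
        classify_read(obs, cfg.thresholds)
    ]


def test_classification_partitions_all_mapped_reads(cfg, make_sample):
    reads, _ = make_sample(1, 2, seed=21)
    counts = classify_reads(reads, cfg)
    assert sum(counts.values()) == sum(r.is_mapped for r in reads)
    assert counts[ReadClass.SMN1] > 0 and counts[ReadClass.SMN2] > 0


def _hamming_oracle(read, templates, cfg):
    """Assign a read to the template at smaller Hamming distance, or None on tie."""
    dists = {}
    for name in ("smn1", "smn2"):
        tpl, tpl_start = templates[name]
        off = read.pos - tpl_start
        seg = tpl[off : off + len(read.seq)]
        seq_codes = np.frombuffer(read.seq.encode(), dtype=np.uint8)
        lut = np.full(256, 255, np.uint8)
        for i, b in enumerate(b"ACGT"):
            lut[b] = i
        dists[name] = int((lut[seq_codes] != seg).sum())
    if dists["smn1"] == dists["smn2"]:
        return None
    return ReadClass.SMN1 if dists["smn1"] < dists["smn2"] else ReadClass.SMN2


def test_vote_agrees_with_hamming_distance_oracle_and_origin(cfg, make_sample):
    """On error-free reads the vote recovers the template of origin, and
    matches full-sequence Hamming matching whenever the distances differ."""
    reads, _ = make_sample(1, 1, seed=2, p=SimulationParams(error_rate=0.0))
    templates = region_templates(cfg)
    checked = 0
    for r in reads:
        if r.chrom != "chr5":
            continue
        obs = extract_psv_observations(r, cfg)
        if not obs:
            continue
        got = classify_read(obs, cfg.thresholds)
        origin = ReadClass.SMN1 if ":smn1:" in r.read_id else ReadClass.SMN2
        assert got == origin
        oracle = _hamming_oracle(r, templates, cfg)
        assert oracle is not None and got == oracle
        checked += 1
    assert checked > 50


def test_pileup_has_zero_smn1_support_for_homozygous_deletion(cfg, make_sample):
    reads, _ = make_sample(0, 2, seed=13, p=SimulationParams(error_rate=0.0))
    pileup = build_pileup(reads, cfg)
    assert all(c.smn1 == 0 for c in pileup.counts)
    assert all(c.smn2 > 0 for c in pileup.counts)


def test_pileup_of_no_reads_is_all_zero(cfg):
    pileup = build_pileup([], cfg)
    assert all(c.total == 0 for c in pileup.counts)


def test_pileup_fraction_matches_binomial_copy_ratio(cfg, make_sample):
    reads, _ = make_sample(2, 2, seed=17, p=SimulationParams(error_rate=0.0))
    pileup = build_pileup(reads, cfg)
    for c in pileup.counts:
        lo, hi = stats.binom.interval(0.99, c.smn1 + c.smn2, 0.5)
        assert lo <= c.smn1 <= hi


def test_low_quality_bases_are_excluded_from_pileup(cfg, make_sample):
    p = SimulationParams(error_rate=0.0, low_qual_fraction=1.0, low_qual_phred=10)
    reads, _ = make_sample(2, 2, seed=3, p=p)
    pileup = build_pileup(reads, cfg)
    assert all(c.total == 0 for c in pileup.counts)
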