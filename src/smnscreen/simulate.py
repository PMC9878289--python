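"""Aligned-read simulator for SMN1/SMN2 genotypes with known truth.

The simulator emulates the post-alignment view of a hybridisation-capture
panel: 2x150 bp read pairs at Poisson depth over (i) an SMN exon 7 capture
region and (ii) a set of diploid control-gene intervals.  SMN1 and SMN2
template sequences are identical except at the configured PSV positions, and
all SMN-derived reads are reported at SMN1-anchored coordinates with MAPQ 0 —
exactly the situation that forces a caller to use PSV bases, not mapping,
to attribute reads to a paralog.

There is no FASTQ stage and no aligner: reads are born "aligned" because the
screening algorithm's input boundary is a SAM/BAM file.  Each gene copy
contributes ``haploid_depth`` fold-coverage; control intervals are always
diploid (2 x haploid_depth).  Fragment lengths are drawn from a truncated
normal around twice the read length (~300 bp, matching a typical capture
library insert), and sequencing errors are uniform base substitutions applied
silently at Q30 — quality-based filtering is exercised instead through an
explicit low-quality injection option.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .locus import GenomicInterval, SmnLocusConfig
from .samio import (
    FLAG_PAIRED,
    FLAG_READ1,
    FLAG_READ2,
    FLAG_REVERSE,
    AlignedRead,
    write_sam,
)

__all__ = [
    "SampleGenotype",
    "SimulationParams",
    "TruthRecord",
    "SimulationError",
    "simulate_sample",
    "simulate_cohort",
    "CohortFiles",
    "region_templates",
    "config_contigs",
]

_BASE_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)
_ASCII_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ASCII_TO_CODE[_b] = _i

#: Sequence context beyond the target interval from which clipped fragment
#: starts may draw; must exceed the maximum fragment length.
TEMPLATE_FLANK = 1000

_DEFAULT_QUAL = 30


class SimulationError(ValueError):
    """Raised for impossible simulation requests."""


@dataclass(frozen=True)
class SampleGenotype:
    """SMN1/SMN2 exon 7 copy numbers of one sample.

    ``smn1_copies == 0`` is the homozygous SMN1 exon 7 deletion (the screened
    condition); 1 copy is a carrier; 2+ is unaffected.
    """

    sample_id: str
    smn1_copies: int
    smn2_copies: int

    def __post_init__(self) -> None:
        if self.smn1_copies < 0 or self.smn2_copies < 0:
            raise ValueError(f"{self.sample_id}: copy numbers must be >= 0")


@dataclass(frozen=True)
class SimulationParams:
    """Sequencing model parameters.

    haploid_depth : mean fold-coverage contributed by a single gene copy.
    read_length : bases per read (2 x read_length bases per pair).
    paired : emit proper FR read pairs when true, single reads otherwise.
    error_rate : per-base probability of a uniform substitution error.
    low_qual_fraction : fraction of bases whose quality is dropped to
        ``low_qual_phred`` (below the default Q20 evidence gate); lets tests
        exercise quality filtering since substitution errors keep Q30.
    """

    haploid_depth: float = 50.0
    read_length: int = 150
    paired: bool = True
    error_rate: float = 0.001
    low_qual_fraction: float = 0.0
    low_qual_phred: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.haploid_depth <= 0:
            raise ValueError("haploid_depth must be > 0")
        if self.read_length < 50:
            raise ValueError("read_length must be >= 50")
        if not (0.0 <= self.error_rate <= 0.1):
            raise ValueError("error_rate must be in [0, 0.1]")
        if not (0.0 <= self.low_qual_fraction <= 1.0):
            raise ValueError("low_qual_fraction must be in [0, 1]")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated sample."""

    sample_id: str
    smn1_copies: int
    smn2_copies: int

    @property
    def expected_call(self) -> str:
        return "POSITIVE" if self.smn1_copies == 0 else "NEGATIVE"


def _interval_seed(interval: GenomicInterval) -> int:
    # Stable across processes (unlike hash()) so templates are reproducible.
    key = f"{interval.chrom}:{interval.start}-{interval.end}".encode()
    return zlib.crc32(key)


def region_templates(
    cfg: SmnLocusConfig,
) -> dict[str, tuple[np.ndarray, int]]:
    """Deterministic template sequences, one per simulated interval.

    Returns a mapping from template name to ``(codes, tpl_start)`` where
    ``codes`` is a uint8 array of base codes (0..3 = ACGT) spanning the
    interval plus :data:`TEMPLATE_FLANK` on each side, and ``tpl_start`` is
    the 1-based genomic position of its first element.  ``smn1`` and ``smn2``
    differ only at the PSV positions.
    """
    out: dict[str, tuple[np.ndarray, int]] = {}

    def synth(interval: GenomicInterval) -> tuple[np.ndarray, int]:
        rng = np.random.default_rng(_interval_seed(interval))
        n = interval.length + 2 * TEMPLATE_FLANK
        return rng.integers(0, 4, size=n, dtype=np.uint8), interval.start - TEMPLATE_FLANK

    base, tpl_start = synth(cfg.smn_region)
    smn1 = base.copy()
    smn2 = base.copy()
    for site in cfg.psv_sites:
        off = site.pos - tpl_start
        smn1[off] = _ASCII_TO_CODE[ord(site.smn1_base)]
        smn2[off] = _ASCII_TO_CODE[ord(site.smn2_base)]
    out["smn1"] = (smn1, tpl_start)
    out["smn2"] = (smn2, tpl_start)
    for i, ctrl in enumerate(cfg.control_genes):
        out[f"control:{ctrl.label or i}"] = synth(ctrl)
    return out


def config_contigs(cfg: SmnLocusConfig) -> dict[str, int]:
    """Contig name -> length mapping for SAM headers, derived from the config."""
    lengths: dict[str, int] = {}
    for iv in (cfg.smn_region, cfg.exon7, *cfg.control_genes):
        lengths[iv.chrom] = max(lengths.get(iv.chrom, 0), iv.end + 2 * TEMPLATE_FLANK)
    return lengths


def _simulate_interval(
    rng: np.random.Generator,
    template: np.ndarray,
    tpl_start: int,
    interval: GenomicInterval,
    depth: float,
    params: SimulationParams,
    mapq: int,
    name_prefix: str,
) -> list[AlignedRead]:
    """Emit reads at the requested mean fold-coverage over one interval.

    Fragment starts are uniform over an extended window so every position of
    the interval sees the same expected coverage (no edge attenuation); the
    fragment count is Poisson with mean chosen so that interior coverage
    equals ``depth``.
    """
    rl = params.read_length
    L = interval.length
    if params.paired:
        frag_mean = 2 * rl
        frag_sd = max(1.0, 0.1 * frag_mean)
        bases_per_frag = 2 * rl
    else:
        frag_mean = rl
        frag_sd = 0.0
        bases_per_frag = rl

    n_frags = rng.poisson(depth * (L + frag_mean - 1) / bases_per_frag)
    if n_frags == 0:
        return []

    if params.paired and frag_sd > 0:
        flens = np.clip(
            np.rint(rng.normal(frag_mean, frag_sd, size=n_frags)),
            frag_mean - 3 * frag_sd,
            frag_mean + 3 * frag_sd,
        ).astype(np.int64)
        flens = np.maximum(flens, rl)  # mates may overlap but never invert
    else:
        flens = np.full(n_frags, frag_mean, dtype=np.int64)

    # start uniform over [interval.start - flen + 1, interval.end]
    span = L + flens - 1
    starts = interval.start - flens + 1 + np.floor(rng.random(n_frags) * span).astype(
        np.int64
    )

    if params.paired:
        read_starts = np.concatenate([starts, starts + flens - rl])
        frag_idx = np.concatenate([np.arange(n_frags), np.arange(n_frags)])
        is_read2 = np.concatenate(
            [np.zeros(n_frags, bool), np.ones(n_frags, bool)]
        )
    else:
        read_starts = starts
        frag_idx = np.arange(n_frags)
        is_read2 = np.zeros(n_frags, bool)

    n_reads = read_starts.size
    offsets = read_starts[:, None] - tpl_start + np.arange(rl)[None, :]
    mat = template[offsets]  # (n_reads, rl) base codes

    if params.error_rate > 0:
        err = rng.random(mat.shape) < params.error_rate
        if err.any():
            shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
            mat[err] = (mat[err] + shift) % 4

    ascii_mat = _BASE_ASCII[mat]
    seqs = ascii_mat.reshape(n_reads, rl).view(f"S{rl}").ravel()

    const_quals = bytes([_DEFAULT_QUAL]) * rl
    qual_rows: np.ndarray | None = None
    if params.low_qual_fraction > 0:
        qmat = np.full((n_reads, rl), _DEFAULT_QUAL, dtype=np.uint8)
        low = rng.random(qmat.shape) < params.low_qual_fraction
        qmat[low] = params.low_qual_phred
        qual_rows = qmat

    reads: list[AlignedRead] = []
    for j in range(n_reads):
        i = int(frag_idx[j])
        fs = int(starts[i])
        flen = int(flens[i])
        pos = int(read_starts[j])
        if params.paired:
            if is_read2[j]:
                flags = FLAG_PAIRED | 0x2 | FLAG_REVERSE | FLAG_READ2
                mate_pos, tlen = fs, -flen
            else:
                flags = FLAG_PAIRED | 0x2 | 0x20 | FLAG_READ1
                mate_pos, tlen = fs + flen - rl, flen
        else:
            flags, mate_pos, tlen = 0, 0, 0
        reads.append(
            AlignedRead(
                read_id=f"{name_prefix}:{i:06d}",
                chrom=interval.chrom,
                pos=pos,
                seq=seqs[j].decode("ascii"),
                quals=bytes(qual_rows[j]) if qual_rows is not None else const_quals,
                mapq=mapq,
                flags=flags,
                cigar=f"{rl}M",
                mate_pos=mate_pos,
                tlen=tlen,
            )
        )
    return reads


def simulate_sample(
    genotype: SampleGenotype,
    params: SimulationParams,
    cfg: SmnLocusConfig,
    seed: int | None = None,
) -> tuple[list[AlignedRead], TruthRecord]:
    """Simulate one sample's aligned reads plus its truth record.

    SMN-region reads come from ``smn1_copies`` SMN1 template copies and
    ``smn2_copies`` SMN2 template copies, all reported at SMN1 coordinates
    with MAPQ 0 (paralog co-mapping).  Each control interval receives diploid
    coverage (2 x haploid_depth) at MAPQ 60.  Deterministic given ``seed``
    (falling back to ``params.seed``).
    """
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    templates = region_templates(cfg)

    total_copies = genotype.smn1_copies + genotype.smn2_copies
    if total_copies == 0 and not cfg.control_genes:
        raise SimulationError("nothing to simulate: zero template copies and no controls")

    reads: list[AlignedRead] = []
    for paralog, copies in (
        ("smn1", genotype.smn1_copies),
        ("smn2", genotype.smn2_copies),
    ):
        if copies == 0:
            continue
        tpl, tpl_start = templates[paralog]
        reads.extend(
            _simulate_interval(
                rng,
                tpl,
                tpl_start,
                cfg.smn_region,
                copies * params.haploid_depth,
                params,
                mapq=0,
                name_prefix=f"{genotype.sample_id}:{paralog}",
            )
        )
    for i, ctrl in enumerate(cfg.control_genes):
        key = f"control:{ctrl.label or i}"
        tpl, tpl_start = templates[key]
        reads.extend(
            _simulate_interval(
                rng,
                tpl,
                tpl_start,
                ctrl,
                2 * params.haploid_depth,
                params,
                mapq=60,
                name_prefix=f"{genotype.sample_id}:{key}",
            )
        )

    truth = TruthRecord(
        sample_id=genotype.sample_id,
        smn1_copies=genotype.smn1_copies,
        smn2_copies=genotype.smn2_copies,
    )
    return reads, truth


@dataclass(frozen=True)
class CohortFiles:
    """Filesystem layout of a simulated cohort."""

    sam_paths: tuple[Path, ...]
    truth_path: Path
    manifest_path: Path
    truth: pd.DataFrame


def simulate_cohort(
    genotypes: Sequence[SampleGenotype],
    params: SimulationParams,
    cfg: SmnLocusConfig,
    out_dir: str | Path,
    base_seed: int = 0,
) -> CohortFiles:
    """Simulate a cohort to disk: one SAM per sample plus a truth table.

    Per-sample seed is ``base_seed + sample index``, so individual samples
    can be regenerated without re-running the cohort.
    """
    ids = [g.sample_id for g in genotypes]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise SimulationError(f"duplicate sample_id(s): {', '.join(dupes)}")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    contigs = config_contigs(cfg)

    sam_paths: list[Path] = []
    rows = []
    for idx, g in enumerate(genotypes):
        reads, truth = simulate_sample(g, params, cfg, seed=base_seed + idx)
        sam_path = out_dir / f"{g.sample_id}.sam"
        write_sam(reads, sam_path, contigs=contigs)
        sam_paths.append(sam_path)
        rows.append(
            {
                "sample_id": g.sample_id,
                "smn1_copies": g.smn1_copies,
                "smn2_copies": g.smn2_copies,
                "expected_call": truth.expected_call,
                "sam_path": str(sam_path),
                "seed": base_seed + idx,
            }
        )

    truth_df = pd.DataFrame(
        rows, columns=["sample_id", "smn1_copies", "smn2_copies", "expected_call",
                       "sam_path", "seed"]
    )
    truth_path = out_dir / "truth.tsv"
    manifest_path = out_dir / "manifest.tsv"
    truth_df[["sample_id", "smn1_copies", "smn2_copies", "expected_call"]].to_csv(
        truth_path, sep="\t", index=False
    )
    truth_df[["sample_id", "sam_path", "seed"]].to_csv(
        manifest_path, sep="\t", index=False
    )
    return CohortFiles(
        sam_paths=tuple(sam_paths),
        truth_path=truth_path,
        manifest_path=manifest_path,
        truth=truth_df,
    )
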