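"""Aligned-read container and SAM round-trip helpers (pysam-backed).

Reads are kept in a deliberately small frozen dataclass: the caller only needs
position, sequence, base qualities and SAM flags.  Mapping quality is carried
but never used to filter SMN-region reads — paralog co-mapping makes MAPQ 0
the expected value there.
"""

from __future__ import annotations

import array
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pysam

__all__ = ["AlignedRead", "SamFormatError", "write_sam", "read_sam"]

FLAG_PAIRED = 0x1
FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80


class SamFormatError(ValueError):
    """Raised when an input SAM file cannot be parsed."""


@dataclass(frozen=True, slots=True)
class AlignedRead:
    """One mapped read in reference (SMN1-anchored or control) coordinates.

    ``pos`` is the 1-based leftmost mapped position.  ``quals`` holds raw
    Phred values as bytes (index to get an int).  ``mate_pos``/``tlen`` carry
    pair bookkeeping for SAM round-trips only.
    """

    read_id: str
    chrom: str
    pos: int
    seq: str
    quals: bytes
    mapq: int = 0
    flags: int = 0
    cigar: str = ""
    mate_pos: int = 0
    tlen: int = 0

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError(
                f"read {self.read_id}: seq length {len(self.seq)} != "
                f"quals length {len(self.quals)}"
            )
        if self.pos < 1:
            raise ValueError(f"read {self.read_id}: pos must be >= 1")

    @property
    def is_mapped(self) -> bool:
        return not self.flags & FLAG_UNMAPPED

    @property
    def end(self) -> int:
        """1-based inclusive rightmost reference position (ungapped)."""
        return self.pos + len(self.seq) - 1


def _contigs_from_reads(reads: Sequence[AlignedRead]) -> dict[str, int]:
    lengths: dict[str, int] = {}
    for r in reads:
        lengths[r.chrom] = max(lengths.get(r.chrom, 0), r.end + 100_000)
    return lengths


def write_sam(
    reads: Sequence[AlignedRead],
    path: str | Path,
    contigs: dict[str, int] | None = None,
) -> None:
    """Write reads as a SAM file with a header declaring every contig.

    ``contigs`` maps contig name to length; when omitted, lengths are derived
    from the reads themselves (rightmost position plus slack), which keeps the
    header deterministic for a fixed read set.
    """
    if contigs is None:
        contigs = _contigs_from_reads(reads)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": length} for name, length in contigs.items()],
        }
    )
    tid = {name: i for i, name in enumerate(contigs)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = r.read_id
            a.flag = r.flags
            a.reference_id = tid[r.chrom]
            a.reference_start = r.pos - 1
            a.mapping_quality = r.mapq
            a.cigarstring = r.cigar or f"{len(r.seq)}M"
            a.query_sequence = r.seq
            a.query_qualities = array.array("B", r.quals)
            if r.flags & FLAG_PAIRED:
                a.next_reference_id = tid[r.chrom]
                a.next_reference_start = r.mate_pos - 1
                a.template_length = r.tlen
            else:
                a.next_reference_id = -1
                a.next_reference_start = -1
            out.write(a)


def read_sam(path: str | Path) -> list[AlignedRead]:
    """Parse a SAM file into mapped :class:`AlignedRead` records.

    Unmapped records are dropped (they carry no positional evidence).  Raises
    :class:`SamFormatError` on malformed input, naming the offending file.
    """
    path = Path(path)
    reads: list[AlignedRead] = []
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped or rec.reference_name is None:
                    continue
                quals = rec.query_qualities
                reads.append(
                    AlignedRead(
                        read_id=rec.query_name or "",
                        chrom=rec.reference_name,
                        pos=rec.reference_start + 1,
                        seq=rec.query_sequence or "",
                        quals=bytes(quals) if quals is not None else b"",
                        mapq=rec.mapping_quality,
                        flags=rec.flag,
                        cigar=rec.cigarstring or "",
                        mate_pos=(rec.next_reference_start + 1)
                        if rec.next_reference_start is not None
                        and rec.next_reference_start >= 0
                        else 0,
                        tlen=rec.template_length,
                    )
                )
    except (ValueError, OSError) as exc:
        raise SamFormatError(f"cannot parse SAM file {path}: {exc}") from exc
    return reads
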