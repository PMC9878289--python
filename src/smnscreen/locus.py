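"""Genomic model of the SMA screening assay.

The assay inspects three paralog-specific variant (PSV) positions inside the
SMN1 exon 7 target region.  SMN1 and SMN2 are near-identical paralogs on chr5;
short reads from either gene co-map onto SMN1 coordinates, so the only reliable
paralog evidence is the base a read carries at a PSV, never its mapping
position or mapping quality.  This module defines the locus configuration —
PSV sites, the exon 7 target interval, the enclosing SMN capture region, the
diploid control-gene intervals used for depth normalisation, and the calling
thresholds — and validates it.

Configurations are plain YAML so a laboratory can redefine sites or thresholds
without touching code.  A packaged default models the three discriminating
positions at chr5:70247724, 70247773 and 70247921 (hg38, SMN1 coordinates).
Only the middle site's base pair (C in SMN1, T in SMN2 — the classic exon 7
c.840C>T paralog difference) is well established; the outer two carry
placeholder base pairs and are expected to be edited for a real assay.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

VALID_BASES = frozenset("ACGT")

__all__ = [
    "GenomicInterval",
    "PsvSite",
    "CallingThresholds",
    "SmnLocusConfig",
    "ConfigError",
    "load_locus_config",
    "save_locus_config",
    "validate_config",
    "default_config",
]


class ConfigError(ValueError):
    """Raised when a locus configuration cannot be loaded or is inconsistent."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, fully closed genomic interval (SAM/VCF POS convention)."""

    chrom: str
    start: int
    end: int
    label: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def encloses(self, other: "GenomicInterval") -> bool:
        return (
            other.chrom == self.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            other.chrom == self.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass(frozen=True)
class PsvSite:
    """One paralog-discriminating position, with its SMN1 and SMN2 base.

    Positions are hg38 SMN1 coordinates; SMN2-derived reads are assumed to be
    co-mapped onto SMN1, so a single coordinate addresses both paralogs.
    """

    chrom: str
    pos: int
    smn1_base: str
    smn2_base: str


@dataclass(frozen=True)
class CallingThresholds:
    """Tunable QC and calling thresholds.

    min_control_depth : mean fold-coverage over control genes below which a
        sample fails QC (strictly below; exactly 20.0X passes).
    min_uniformity : minimum fraction of control-gene bases with depth at
        least 0.2 x the sample's mean control depth.
    min_base_quality : Phred floor for a base to count as PSV evidence.
    deletion_score_cutoff : coverage score (SMN1 copy-equivalents) below which
        a QC-passing sample is called screen positive.  Midpoint between the
        0-copy and 1-copy score clusters.
    min_psv_total_depth : minimum mean read depth across PSV sites; guards
        against calling a deletion from sheer coverage dropout.
    """

    min_control_depth: float = 20.0
    min_uniformity: float = 0.95
    min_base_quality: int = 20
    deletion_score_cutoff: float = 0.5
    min_psv_total_depth: float = 20.0


@dataclass(frozen=True)
class SmnLocusConfig:
    psv_sites: tuple[PsvSite, ...]
    exon7: GenomicInterval
    smn_region: GenomicInterval
    control_genes: tuple[GenomicInterval, ...]
    thresholds: CallingThresholds = field(default_factory=CallingThresholds)


def validate_config(cfg: SmnLocusConfig) -> list[str]:
    """Return a list of invariant violations; empty iff the config is valid.

    Violations are data (strings naming the field and rule), not exceptions,
    so callers can report all problems at once.
    """
    problems: list[str] = []

    if len(cfg.psv_sites) < 1:
        problems.append("psv_sites: at least one PSV site required")

    seen_pos: set[tuple[str, int]] = set()
    for site in cfg.psv_sites:
        tag = f"psv_sites[{site.chrom}:{site.pos}]"
        if site.smn1_base not in VALID_BASES:
            problems.append(f"{tag}: smn1_base {site.smn1_base!r} not in A/C/G/T")
        if site.smn2_base not in VALID_BASES:
            problems.append(f"{tag}: smn2_base {site.smn2_base!r} not in A/C/G/T")
        if site.smn1_base == site.smn2_base:
            problems.append(f"{tag}: smn1_base == smn2_base ({site.smn1_base})")
        key = (site.chrom, site.pos)
        if key in seen_pos:
            problems.append(f"{tag}: duplicate PSV position")
        seen_pos.add(key)
        if not cfg.exon7.contains(site.chrom, site.pos):
            problems.append(f"{tag}: PSV position outside exon7 interval")

    for name, iv in [("exon7", cfg.exon7), ("smn_region", cfg.smn_region)] + [
        (f"control_genes[{i}]", c) for i, c in enumerate(cfg.control_genes)
    ]:
        if iv.start < 1:
            problems.append(f"{name}: start must be >= 1")
        if iv.end < iv.start:
            problems.append(f"{name}: end < start")

    if not cfg.smn_region.encloses(cfg.exon7):
        problems.append("exon7: exon7 outside smn_region")

    if len(cfg.control_genes) < 1:
        problems.append("control_genes: at least one control interval required")
    for i, c in enumerate(cfg.control_genes):
        if c.overlaps(cfg.smn_region):
            problems.append(f"control_genes[{i}]: overlaps smn_region")

    t = cfg.thresholds
    if t.min_control_depth < 0:
        problems.append("thresholds.min_control_depth: must be nonnegative")
    if not (0.0 <= t.min_uniformity <= 1.0):
        problems.append("thresholds.min_uniformity: must be in [0, 1]")
    if t.min_base_quality < 0:
        problems.append("thresholds.min_base_quality: must be nonnegative")
    if not (0.0 < t.deletion_score_cutoff <= 1.0):
        problems.append("thresholds.deletion_score_cutoff: must be in (0, 1]")
    if t.min_psv_total_depth < 0:
        problems.append("thresholds.min_psv_total_depth: must be nonnegative")

    return problems


def _interval_from_mapping(d: dict, default_label: str = "") -> GenomicInterval:
    return GenomicInterval(
        chrom=str(d["chrom"]),
        start=int(d["start"]),
        end=int(d["end"]),
        label=str(d.get("label", default_label)),
    )


def _config_from_mapping(doc: dict) -> SmnLocusConfig:
    try:
        sites = tuple(
            PsvSite(
                chrom=str(s["chrom"]),
                pos=int(s["pos"]),
                smn1_base=str(s["smn1_base"]).upper(),
                smn2_base=str(s["smn2_base"]).upper(),
            )
            for s in doc.get("psv_sites", [])
        )
        exon7 = _interval_from_mapping(doc["exon7"], "exon7")
        smn_region = _interval_from_mapping(doc["smn_region"], "smn_region")
        controls = tuple(
            _interval_from_mapping(c, f"control_{i}")
            for i, c in enumerate(doc.get("control_genes", []))
        )
        thresholds = CallingThresholds(**doc.get("thresholds", {}))
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed locus config: {exc!r}") from exc
    return SmnLocusConfig(
        psv_sites=sites,
        exon7=exon7,
        smn_region=smn_region,
        control_genes=controls,
        thresholds=thresholds,
    )


def load_locus_config(path: str | Path | None = None) -> SmnLocusConfig:
    """Load and validate a locus configuration from YAML.

    With ``path=None`` the packaged default configuration is loaded.  Raises
    :class:`ConfigError` on parse failure or any invariant violation.
    """
    if path is None:
        text = (
            resources.files("smnscreen").joinpath("data/default_locus.yaml").read_text()
        )
    else:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        text = path.read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"config is not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    cfg = _config_from_mapping(doc)
    problems = validate_config(cfg)
    if problems:
        raise ConfigError("invalid locus config: " + "; ".join(problems))
    return cfg


def default_config() -> SmnLocusConfig:
    """The packaged default assay model (three PSV sites, three control genes)."""
    return load_locus_config(None)


def _config_to_mapping(cfg: SmnLocusConfig) -> dict:
    def iv(i: GenomicInterval) -> dict:
        return {"chrom": i.chrom, "start": i.start, "end": i.end, "label": i.label}

    return {
        "psv_sites": [dataclasses.asdict(s) for s in cfg.psv_sites],
        "exon7": iv(cfg.exon7),
        "smn_region": iv(cfg.smn_region),
        "control_genes": [iv(c) for c in cfg.control_genes],
        "thresholds": dataclasses.asdict(cfg.thresholds),
    }


def save_locus_config(cfg: SmnLocusConfig, path: str | Path) -> None:
    """Serialise a config to YAML; ``load_locus_config`` round-trips it."""
    Path(path).write_text(yaml.safe_dump(_config_to_mapping(cfg), sort_keys=False))
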