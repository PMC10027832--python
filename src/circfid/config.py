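"""Pipeline thresholds and shared enumerations.

Every filter constant used by the error-calling pipeline lives here, in one
validated place.  The defaults encode the published circle-sequencing filter:
repeat units of at least 30 nt with at least 90% identity between copies, a
base must be part of at least 3 repeat copies that all make the same call,
the summed Phred quality of the calls must exceed 100, the base must lie
strictly more than 2 nt away from both ends of the consensus, and the genomic
site must be covered by at least 200 consensus reads of which fewer than 1%
support a non-reference call.

The inequality senses are deliberate and asymmetric (``>100``, ``>2``,
``>=200``, ``<1%``); tests rely on the exact boundary behaviour.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Union


class ConfigError(ValueError):
    """Raised when a configuration file cannot be parsed or validated."""


class PolymeraseClass(str, Enum):
    """The RNA polymerase that produced a transcript.

    RNAPI transcribes the large ribosomal RNAs, RNAPII the messenger RNAs,
    RNAPIII the 5S rRNA and tRNAs, and mtRNAP the mitochondrial transcripts.
    Sites outside annotated transcripts, or under features of conflicting
    classes, are ``UNASSIGNED``.
    """

    RNAPI = "RNAPI"
    RNAPII = "RNAPII"
    RNAPIII = "RNAPIII"
    MTRNAP = "mtRNAP"
    UNASSIGNED = "unassigned"

    @classmethod
    def from_label(cls, label: str) -> "PolymeraseClass":
        for member in cls:
            if member.value == label:
                return member
        raise ConfigError(f"unknown polymerase class label: {label!r}")


PAIR_MODES = ("merge", "independent", "r1_only")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable thresholds of the error-identification pipeline.

    Attributes
    ----------
    min_repeat_len : int
        Minimum repeat-unit (RNA fragment) size in nt.
    min_repeat_identity : float
        Minimum fraction of agreeing positions between successive repeat
        copies for a read to be accepted.
    min_repeats : int
        A base call must be part of at least this many repeat copies.
    min_quality_sum : int
        The summed Phred scores of the contributing calls must be strictly
        greater than this value.
    edge_margin : int
        A base must be strictly more than this many nt away from both ends
        of the (rotated) consensus.
    min_site_depth : int
        A genomic site must be covered by at least this many consensus reads.
    max_alt_fraction : float
        The fraction of covering reads supporting a non-reference call must
        be strictly below this value, otherwise the site is treated as a
        polymorphism / RNA-editing site and excluded.
    phred_offset : int
        ASCII offset of FASTQ quality strings.
    pair_mode : str
        How paired-end input is consumed: ``merge`` expects pre-merged
        single reads, ``independent`` processes both mates separately,
        ``r1_only`` ignores R2.
    mapq_floor : int
        Minimum mapping quality for alignments ingested from external SAM;
        below it the consensus is treated as unmapped.
    """

    min_repeat_len: int = 30
    min_repeat_identity: float = 0.90
    min_repeats: int = 3
    min_quality_sum: int = 100
    edge_margin: int = 2
    min_site_depth: int = 200
    max_alt_fraction: float = 0.01
    phred_offset: int = 33
    pair_mode: str = "merge"
    mapq_floor: int = 20

    def __post_init__(self) -> None:
        if self.min_repeat_len < 1:
            raise ConfigError("min_repeat_len must be >= 1")
        if self.min_repeats < 1:
            raise ConfigError("min_repeats must be >= 1")
        if self.min_quality_sum < 0:
            raise ConfigError("min_quality_sum must be >= 0")
        if self.edge_margin < 0:
            raise ConfigError("edge_margin must be >= 0")
        if not (0.0 < self.min_repeat_identity <= 1.0):
            raise ConfigError("min_repeat_identity must be in (0, 1]")
        if not (0.0 <= self.max_alt_fraction < 1.0):
            raise ConfigError("max_alt_fraction must be in [0, 1)")
        if self.min_site_depth < 1:
            raise ConfigError("min_site_depth must be >= 1")
        if self.pair_mode not in PAIR_MODES:
            raise ConfigError(
                f"pair_mode must be one of {PAIR_MODES}, got {self.pair_mode!r}"
            )
        if self.phred_offset not in (33, 64):
            raise ConfigError("phred_offset must be 33 or 64")
        if self.mapq_floor < 0:
            raise ConfigError("mapq_floor must be >= 0")


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}


def _cast(key: str, raw: str):
    target = _FIELD_TYPES[key]
    raw = raw.strip()
    try:
        if target in ("int", int):
            return int(raw)
        if target in ("float", float):
            return float(raw)
        return raw
    except ValueError as exc:
        raise ConfigError(f"cannot parse value for {key!r}: {raw!r}") from exc


def load_config(path: Union[str, Path]) -> PipelineConfig:
    """Load a plain-text ``key=value`` configuration file.

    Blank lines and lines starting with ``#`` are ignored.  Absent keys take
    their defaults; unknown keys and invariant violations raise
    :class:`ConfigError`.
    """
    path = Path(path)
    overrides = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "=" not in stripped:
            raise ConfigError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, _, raw = stripped.partition("=")
        key = key.strip()
        if key not in _FIELD_TYPES:
            raise ConfigError(f"{path}:{lineno}: unknown configuration key {key!r}")
        overrides[key] = _cast(key, raw)
    return PipelineConfig(**overrides)


def serialize_config(cfg: PipelineConfig) -> str:
    """Render a config as ``key=value`` text; round-trips with load_config."""
    lines = [
        f"{f.name}={getattr(cfg, f.name)}" for f in dataclasses.fields(PipelineConfig)
    ]
    return "\n".join(lines) + "\n"


def save_config(cfg: PipelineConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(serialize_config(cfg))
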