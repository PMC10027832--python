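"""Shared fixtures: small deterministic references and read constructors."""

from __future__ import annotations

import numpy as np
import pytest

from circfid.config import PipelineConfig, PolymeraseClass
from circfid.consensus import ReadRecord
from circfid.locate import BuiltinAligner
from circfid.seqs import decode
from circfid.simulate import TranscriptFeature


def make_read(
    fragment: str,
    copies: int = 3,
    rotation: int = 0,
    read_length: int | None = None,
    qual: int = 34,
    read_id: str = "r1",
) -> ReadRecord:
    """Rolling-circle read: ``copies`` tandem copies starting at ``rotation``."""
    tiled = (fragment * (copies + 1))[rotation : rotation + copies * len(fragment)]
    if read_length is not None:
        tiled = tiled[:read_length]
    return ReadRecord(read_id, tiled, np.full(len(tiled), qual, dtype=np.int16))


def random_seq(rng: np.random.Generator, length: int) -> str:
    return decode(rng.integers(0, 4, size=length).astype(np.uint8))


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(7)


@pytest.fixture
def toy_genome(rng) -> dict[str, str]:
    return {"chr1": random_seq(rng, 3000)}


@pytest.fixture
def toy_aligner(toy_genome) -> BuiltinAligner:
    return BuiltinAligner(toy_genome)


@pytest.fixture
def toy_features(toy_genome) -> list[TranscriptFeature]:
    return [
        TranscriptFeature("t0", "chr1", 100, 1400, "+", PolymeraseClass.RNAPII),
        TranscriptFeature("t1", "chr1", 1500, 2800, "-", PolymeraseClass.RNAPI),
    ]
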