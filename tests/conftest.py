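from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper module

from maturems import ScannerConfig


@pytest.fixture
def config() -> ScannerConfig:
    return ScannerConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130301)


def random_dna(rng: np.random.Generator, length: int, with_n: bool = False) -> str:
    alphabet = "ACGTN" if with_n else "ACGT"
    probs = (0.24, 0.24, 0.24, 0.24, 0.04) if with_n else None
    return "".join(rng.choice(list(alphabet), size=length, p=probs))
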