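"""Shared fixtures: scoring scheme and synthetic stand-in sequences.

The stand-ins mirror the structural properties of published reference
proteins (cysteine counts, GY-chain length, tandem repeat counts, a 5/6
identity repeat pair) but are synthetic constructions — no third-party
sequence data is stored in the repository.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from krtap import ScoringScheme, SequenceRecord
from krtap.synthetic import make_ancestors

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme.blosum62()


@pytest.fixture(scope="session")
def mt_like() -> SequenceRecord:
    """Synthetic metallothionein-like protein: 61 residues, exactly 20 Cys."""
    return make_ancestors(0)[0]


@pytest.fixture(scope="session")
def occludin_like() -> SequenceRecord:
    """Synthetic occludin-fragment-like protein: 70 residues, GYG-rich."""
    return make_ancestors(0)[1]


@pytest.fixture(scope="session")
def small_uhs_like() -> SequenceRecord:
    """Synthetic stand-in for a small ultra-high-sulphur KRTAP:
    105 residues of which 37 are cysteine (deterministic construction)."""
    rng = np.random.default_rng(170105)
    cys_positions = set(rng.choice(105, size=37, replace=False).tolist())
    fill = iter(rng.choice(list("AGSTPRVQ"), size=105 - 37))
    residues = "".join(
        "C" if i in cys_positions else str(next(fill)) for i in range(105)
    )
    return SequenceRecord(id="UHS105_synthetic", residues=residues,
                          annotation="synthetic small UHS KRTAP-like protein")


@pytest.fixture(scope="session")
def gy_chain_like() -> SequenceRecord:
    """Synthetic stand-in for a GY-repeat protein: 155 residues of which a
    contiguous 123 form a glycine-tyrosine chain."""
    rng = np.random.default_rng(155123)
    flank = lambda n: "".join(rng.choice(list("ASTPRVQC"), size=n))  # noqa: E731
    residues = flank(16) + "GY" * 61 + "G" + flank(16)
    assert len(residues) == 155
    return SequenceRecord(id="GYCHAIN_synthetic", residues=residues,
                          annotation="synthetic GY-repeat KRTAP-like protein")


@pytest.fixture(scope="session")
def gy_partner_like() -> SequenceRecord:
    """Synthetic GY-repeat partner in which every third Y is F, so the
    optimal gapless local alignment with a pure GY chain has 5/6 identity."""
    return SequenceRecord(id="GYF_synthetic", residues="GYGYGF" * 10,
                          annotation="synthetic GY/F-repeat partner")


@pytest.fixture(scope="session")
def tandem36_like() -> SequenceRecord:
    """Synthetic stand-in with 36 tandem copies of the CC-prefixed 5-mer
    CCTDY (the maximal-repeat-count archetype)."""
    return SequenceRecord(id="TANDEM36_synthetic", residues="CCTDY" * 36,
                          annotation="synthetic tandem-repeat KRTAP-like protein")
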