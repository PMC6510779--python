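"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import pytest

from sigma54_scope.genome import AnnotatedGenome, Feature
from sigma54_scope.simulate import GenomeSimConfig, generate_genome


def make_genome(contig: str, features: list[Feature] | None = None, **kw) -> AnnotatedGenome:
    """One-contig toy genome; contig id is 'ctg'."""
    return AnnotatedGenome(contigs={"ctg": contig}, features=features or [], **kw)


@pytest.fixture(scope="session")
def sim_genome():
    """Default synthetic genome (seed 42) with its truth table."""
    return generate_genome(GenomeSimConfig(seed=42))


@pytest.fixture(scope="session")
def sim_config():
    return GenomeSimConfig(seed=42)
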