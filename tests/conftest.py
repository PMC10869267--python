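"""Shared fixtures: toy hand-checked genomes and seeded simulations."""

from __future__ import annotations

import pytest

from hybridome.allelic import CrossOrientation
from hybridome.simulate import SimulationConfig, simulate_reference, simulate_strain_variants
from hybridome.variants import Variant, VariantKind, VariantSet

TOY_REF = {"chrT": "AACGTT"}


@pytest.fixture
def toy_ref():
    return dict(TOY_REF)


@pytest.fixture
def snp_variant():
    return Variant("chrT", 3, "C", "G", VariantKind.SNP)


@pytest.fixture
def ins_variant():
    return Variant("chrT", 2, "A", "ATT", VariantKind.INS)


@pytest.fixture
def del_variant():
    return Variant("chrT", 2, "ACG", "A", VariantKind.DEL)


@pytest.fixture
def bj_cross():
    """B6 mother x JF1 father (the 'BJ' orientation)."""
    return CrossOrientation("B6", "JF1")


@pytest.fixture(scope="session")
def sim_genome():
    """One 20-kb simulated contig with strain variants at default rates."""
    cfg = SimulationConfig(seed=7, contigs={"chrS": 20_000})
    ref = simulate_reference(cfg)
    variants = simulate_strain_variants(ref, cfg)
    return cfg, ref, variants


def make_variant_set(*records):
    return VariantSet.from_records(records)
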