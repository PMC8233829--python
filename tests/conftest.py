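import numpy as np
import pytest

from trackmc.chemistry import ReactionTable
from trackmc.cross_sections import build_tables
from trackmc.dna_damage import DNAReactionParams
from trackmc.dna_geometry import DNAGeometryParams, generate_nucleus_geometry


@pytest.fixture(scope="session")
def xs_table():
    """Full cross-section table on the 10 eV .. 1 TeV grid (built once)."""
    return build_tables()


@pytest.fixture(scope="session")
def chem_table():
    return ReactionTable.from_file()


@pytest.fixture(scope="session")
def dna_params(chem_table):
    return DNAReactionParams.from_file(chem_table)


@pytest.fixture(scope="session")
def small_geometry():
    """3x3x3-voxel nucleus block with dense histones, deterministic seed."""
    return generate_nucleus_geometry(
        DNAGeometryParams(n_voxels=(3, 3, 3), histone_every_bp=50), seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
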