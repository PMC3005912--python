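from pathlib import Path

import pytest

from isortho import (
    IsoformRecord,
    OrthologueGroup,
    SynthSpec,
    align_group,
    generate_group,
    similarity_matrix,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture(scope="session")
def fig1_synth():
    """The canonical worked example: three equal-length exons, patterns
    110 and 111 mirrored across two species, no noise."""
    return generate_group(SynthSpec(seed=1))


@pytest.fixture(scope="session")
def fig1_msa(fig1_synth):
    return align_group(fig1_synth.group)


@pytest.fixture(scope="session")
def fig1_sim(fig1_msa):
    return similarity_matrix(fig1_msa)


def make_group(members, group_id="G", species=("hs", "mm")):
    """Build an OrthologueGroup from (id, species_index, sequence) triples."""
    return OrthologueGroup(
        group_id=group_id,
        species_a=species[0],
        species_b=species[1],
        isoforms=[
            IsoformRecord(
                isoform_id=iso_id,
                gene_id=f"gene_{species[sp]}",
                species=species[sp],
                sequence=seq,
            )
            for iso_id, sp, seq in members
        ],
    )
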