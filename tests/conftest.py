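import numpy as np
import pytest

from mhguide import (DeletionVariant, FlankConfig, GenomeSequence, PlantSpec,
                     make_genome, plant_variant)


@pytest.fixture(scope="session")
def base_genome() -> GenomeSequence:
    return make_genome(8000, seed=11)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def planted_set(base_genome):
    """A genome with a mixed bag of planted deletion loci and their truths.

    Covers both flank configurations, abutted and distant µHs, planted PAMs,
    an off-target duplication and a nested repeat.
    """
    rng = np.random.default_rng(20231)
    specs = [
        PlantSpec(3, 0, FlankConfig.OUTER_RIGHT, pam=True),
        PlantSpec(4, 2, FlankConfig.OUTER_RIGHT, pam=True),
        PlantSpec(5, 6, FlankConfig.OUTER_LEFT, pam=True),
        PlantSpec(3, 0, FlankConfig.OUTER_LEFT, pam=True),
        PlantSpec(6, 4, FlankConfig.OUTER_RIGHT, pam=True, offtarget_copies=1),
        PlantSpec(4, 10, FlankConfig.OUTER_RIGHT, pam=True, nested=(3, 2)),
        PlantSpec(3, 1, FlankConfig.OUTER_RIGHT),        # no planted PAM
        PlantSpec(8, 0, FlankConfig.OUTER_RIGHT, pam=True),
    ]
    genome = base_genome
    out = []
    for i, spec in enumerate(specs):
        genome, var, truth = plant_variant(genome, spec, rng, start=600 + 700 * i)
        out.append((var, truth))
    return genome, out
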