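import numpy as np
import pytest

from multiguide.model import Interval, RegionSet
from multiguide.synthesis import make_genome, plant_sites, random_guide


@pytest.fixture(scope="session")
def small_synthetic():
    """A two-chromosome random genome with gene and TE annotation."""
    return make_genome({"chrA": 50_000, "chrB": 30_000}, 0.45, seed=11)


@pytest.fixture(scope="session")
def whole_genome_regions(small_synthetic):
    asm = small_synthetic.assembly
    return RegionSet(
        [Interval(c, 0, L) for c, L in asm.lengths.items()], "allowed"
    )


@pytest.fixture(scope="session")
def planted_fixture(small_synthetic, whole_genome_regions):
    """Genome carrying 4 perfect sites plus near-miss and invisible decoys."""
    rng = np.random.default_rng(3)
    guide = random_guide(rng)
    planted, truth = plant_sites(
        small_synthetic.assembly,
        guide,
        k=4,
        regions=whole_genome_regions,
        spacing=2_000,
        decoy_spec=[(0, 2), (0, 3), (1, 0)],
        seed=23,
    )
    return planted, truth
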