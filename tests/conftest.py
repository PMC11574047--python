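import numpy as np
import pytest

from damidpipe.genome_model import GeneAnnotation, GenomeModel
from damidpipe.synthetic_data import SimulationConfig, SyntheticStudy, simulate_study

# Toy chromosome with GATC sites exactly every 100 bp starting at 0:
# fragments [0,100), ..., [900,1000).  Non-site positions are random over
# {A,C,T} (no G), so no spurious motif can occur and every site's anchor
# sequence is unique.
_rng = np.random.default_rng(1234)
_units = []
for _ in range(10):
    filler = "".join(np.array(list("ACT"))[_rng.integers(0, 3, 96)])
    _units.append("GATC" + filler)
TOY_CHROM = "".join(_units)


@pytest.fixture(scope="session")
def toy_sequences():
    return {"chrT": TOY_CHROM}


@pytest.fixture(scope="session")
def toy_model(toy_sequences):
    return GenomeModel.from_sequences(toy_sequences)


@pytest.fixture(scope="session")
def toy_genes():
    # two genes splitting the toy chromosome; extension 0 keeps the split exact
    return GeneAnnotation(
        ["geneA", "geneB"],
        ["chrT", "chrT"],
        np.array([0, 500]),
        np.array([500, 1000]),
        ["+", "-"],
    )


def small_config(seed=1, **overrides):
    """Desk-scale simulation: 3 x 500 kb chromosomes, sparse genes."""
    defaults = dict(
        seed=seed,
        n_chromosomes=3,
        chrom_length=500_000,
        n_genes=300,
        n_expressed_genes=60,
        n_up=12,
        n_down=12,
        reads_per_replicate=400_000,
        rapid_reads_per_replicate=300_000,
        nb_dispersion=0.02,
        fraction_diff_bins=0.05,
        diff_effect_log2=2.0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def study() -> SyntheticStudy:
    return simulate_study(small_config(seed=1))
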