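import numpy as np
import pytest

from sedsift.simulate import (
    DamageModel,
    FragmentModel,
    ReferenceSeq,
    SimConfig,
    TaxonSpec,
    simulate_metagenome,
)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def make_taxon(
    taxon_id: str,
    genus: str,
    abundance: float,
    length: int = 5000,
    seed: int = 0,
    role: str = "mitochondrion",
) -> TaxonSpec:
    rng = np.random.default_rng(seed)
    return TaxonSpec(
        taxon_id=taxon_id,
        name=f"{genus} {taxon_id}",
        genus=genus,
        abundance=abundance,
        references=[ReferenceSeq(f"{taxon_id}_ref", role, random_sequence(rng, length))],
    )


@pytest.fixture(scope="session")
def two_taxon_mixture():
    return [
        make_taxon("speciesA", "Alpha", 0.7, seed=11),
        make_taxon("speciesB", "Beta", 0.3, seed=22),
    ]


@pytest.fixture(scope="session")
def damaged_simulation(two_taxon_mixture):
    """2,000 reads with the default damage model and no sequencing error."""
    cfg = SimConfig(seed=7, n_reads=2000, error_rate=0.0)
    return simulate_metagenome(
        two_taxon_mixture, FragmentModel(), DamageModel(), cfg
    )
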