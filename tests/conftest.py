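import pytest
from hypothesis import settings

from photothermal.synth import DesignSpec, generate_phenotypes

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from photothermal.types import (
    Elf3Allele,
    GenotypeSpec,
    Group,
    PpdH1Allele,
    ResponseParams,
)


@pytest.fixture
def genotype_spec():
    return GenotypeSpec("test_geno", Group.HEB, Elf3Allele.HV, PpdH1Allele.HV)


@pytest.fixture
def simulate_single(genotype_spec):
    """Factory: plant records for one genotype under the 5-photoperiod ladder."""

    def _make(params: ResponseParams, seed: int = 0, replicates: int = 10,
              repetitions: int = 1,
              photoperiods=(16.0, 18.0, 20.0, 22.0, 24.0)):
        design = DesignSpec(
            genotypes=[(genotype_spec, params)],
            photoperiods_h=photoperiods,
            replicates=replicates,
            repetitions=repetitions,
            seed=seed,
        )
        return generate_phenotypes(design)

    return _make
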