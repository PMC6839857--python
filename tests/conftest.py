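import pytest

import ystrpop as y
from ystrpop.haplotypes import Haplotype, Panel, Sample


def build_panel(loci, rows):
    """Panel from (sample_id, population, {locus: allele-tuple}) triples."""
    samples = [
        Sample(sid, pop, Haplotype({k: tuple(v) for k, v in alleles.items()}))
        for sid, pop, alleles in rows
    ]
    return Panel(loci=list(loci), samples=samples)


@pytest.fixture(scope="session")
def default_loci():
    return y.default_panel()


@pytest.fixture(scope="session")
def study_spectrum():
    """The haplotype spectrum forced by the study's printed counts:
    400 samples carrying 396 distinct haplotypes, 392 of them unique."""
    loci = y.default_panel()
    keys = y.distinct_haplotype_keys(396, loci)
    counts = {k: (2 if i >= 392 else 1) for i, k in enumerate(keys)}
    return y.FrequencySpectrum("haplotype", counts)


@pytest.fixture(scope="session")
def study_panel(study_spectrum, default_loci):
    return y.sample_from_spectra(
        {"Bouyei": study_spectrum}, default_loci, mode="exact", seed=2024
    )
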