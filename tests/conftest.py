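import pytest

from estmarker import SimulationConfig, gen_read_observations, gen_unigenes


@pytest.fixture(scope="session")
def clean_dataset():
    """A small no-noise, well-covered two-genotype dataset with truth.

    Zero base-error rate and depth far above the allele-qualification
    threshold, so every planted variant is recoverable and no spurious
    call can arise.
    """
    config = SimulationConfig(
        n_unigenes=30, seed=101, coverage_mean=20, base_error_rate=0.0
    )
    unigenes, truth = gen_unigenes(config)
    observations = gen_read_observations(unigenes, truth, config)
    return config, unigenes, truth, observations


@pytest.fixture()
def unigene_map(clean_dataset):
    _, unigenes, _, _ = clean_dataset
    return {u.id: u for u in unigenes}
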