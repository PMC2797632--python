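import pytest

from maxgrowth.predictor import fit_predictor
from maxgrowth.synthetic import SyntheticSpec, generate_genome, generate_training_table


@pytest.fixture(scope="session")
def biased_partition():
    """A small genome under moderate translational selection."""
    return generate_genome(
        SyntheticSpec(n_genes=80, n_heg=16, gene_len=600, gc=0.45, s_strength=2.0, seed=11)
    )


@pytest.fixture(scope="session")
def neutral_partition():
    """The matched genome without selection on synonymous choice."""
    return generate_genome(
        SyntheticSpec(n_genes=80, n_heg=16, gene_len=600, gc=0.45, s_strength=0.0, seed=11)
    )


@pytest.fixture(scope="session")
def training_table():
    return generate_training_table(80, noise_sd=0.15, seed=5)


@pytest.fixture(scope="session")
def refit_model(training_table):
    """A model with a fitted composite, usable for F composition."""
    return fit_predictor(training_table, lambda_mode="log")
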