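import pytest

from bilemic import synthetic
from bilemic.datasets import load_logp_table, load_thermo_table
from bilemic.itc import fit_demicellization


@pytest.fixture(scope="session")
def clean_series():
    """Noise-free reference titration (n=10, cmc=0.45 mM, dH_demic=-5, dH_dil=-0.2)."""
    return synthetic.gen_itc_experiment(synthetic.default_truth(noise_sd=0.0))


@pytest.fixture(scope="session")
def clean_fit(clean_series):
    return fit_demicellization(clean_series)


@pytest.fixture(scope="session")
def thermo_df():
    return load_thermo_table()


@pytest.fixture(scope="session")
def logp_df():
    return load_logp_table()
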