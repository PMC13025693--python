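import pytest
from hypothesis import HealthCheck, settings

from mitochar import presets
from mitochar.synthetic_data import gen_mitogenome

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def jd_record():
    """Published J. diaphana annotation table (no sequence)."""
    return presets.load_paper_record("jdiaphana")


@pytest.fixture(scope="session")
def ap_record():
    """Published A. pelagicus annotation table (no sequence)."""
    return presets.load_paper_record("apelagicus")


@pytest.fixture(scope="session")
def jd_synth():
    """Synthetic J. diaphana-like genome with its generation log."""
    return gen_mitogenome(presets.paper_genome_spec("jdiaphana"), seed=11)


@pytest.fixture(scope="session")
def ap_synth():
    return gen_mitogenome(presets.paper_genome_spec("apelagicus"), seed=11)
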