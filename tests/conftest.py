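import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def network():
    from golgisim.network import compile_network

    return compile_network()


@pytest.fixture(scope="session")
def reference_config():
    """Synthetic WT-like reference; tuned once per session."""
    from golgisim.synth import make_reference_config

    return make_reference_config()


@pytest.fixture(scope="session")
def reference_exact(reference_config):
    from golgisim.engine import exact_profile

    return exact_profile(reference_config)


def small_config(rates=None, n_cisternae=1, residence_times=(1.0,), entry_mix=None,
                 n_glycans=1000, seed=0):
    """Convenience builder with all-zero default rates."""
    from golgisim.engine import GolgiConfig
    from golgisim.rules import ENZYMES

    full = {e: (0.0,) * n_cisternae for e in ENZYMES}
    if rates:
        full.update(rates)
    return GolgiConfig(
        n_cisternae=n_cisternae,
        residence_times=residence_times,
        rates=full,
        entry_mix=entry_mix or {"Man9GlcNAc2": 1.0},
        n_glycans=n_glycans,
        seed=seed,
    )
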