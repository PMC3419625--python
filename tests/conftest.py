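import numpy as np
import pytest

try:
    from hypothesis import settings, HealthCheck

    settings.register_profile(
        "ci",
        deadline=None,
        derandomize=True,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass

import genereconcile as gr


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated version pair with a few events of every class."""
    cfg = gr.SimulationConfig(
        seed=42,
        n_chromosomes=2,
        genes_per_chromosome=60,
        split_in_B=3,
        merge_in_B=3,
        tandem_expand_in_B=3,
        chimera_in_B=3,
        chimera_in_B_triples=1,
        chimera_in_A=3,
        chimera_in_A_triples=0,
        invert_blocks=1,
        invert_block_sizes=[6],
        relocate=2,
        unplace_in_A=4,
    )
    return gr.simulate_pair(cfg)


@pytest.fixture(scope="session")
def small_result(small_sim):
    return gr.reconcile_pair(
        small_sim.genes_a,
        small_sim.genes_b,
        small_sim.seqs_a,
        small_sim.seqs_b,
        evidence=small_sim.proteins,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
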