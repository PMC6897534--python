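import numpy as np
import pandas as pd
import pytest

from combokill.simulate import CloneUniverse, TracingDesign, simulate_clone_tracing


@pytest.fixture(scope="session")
def tracing_run():
    """One moderate clone-tracing simulation shared across tests.

    Two active drugs at 1e-2 resistance frequency, no cross-resistance,
    triplicates, sequencing depth 1e6 — large enough for stable enrichment
    scores, small enough to simulate in well under a second.
    """
    universe = CloneUniverse(
        n_clones=100_000,
        resistance_freqs={"C": 1e-2, "O": 1e-2},
        true_xi=0.0,
        seed=11,
    )
    design = TracingDesign(drugs=("C", "O"), depth=1_000_000,
                           pretreatment_depth=5_000_000)
    table, sheet, truth = simulate_clone_tracing(universe, design, seed=11)
    return universe, design, table, sheet, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
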