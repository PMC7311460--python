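import numpy as np
import pytest

import atacbench as ab


@pytest.fixture(scope="session")
def groups6():
    return np.array(["A", "A", "A", "B", "B", "B"])


@pytest.fixture(scope="session")
def small_matrix():
    """Reduced-size simulated matrix (same composition as the full design)."""
    design = ab.SimulationDesign(n_peaks=3000, replicates_per_condition=3, seed=42)
    return ab.simulate_counts(design)


@pytest.fixture(scope="session")
def batch_fixture():
    """Simulated matrix with an injected batch crossing both conditions."""
    design = ab.SimulationDesign(n_peaks=4000, replicates_per_condition=6, seed=5)
    clean = ab.simulate_counts(design)
    batch = np.array([0, 0, 0, 1, 1, 1, 0, 0, 0, 1, 1, 1])
    noisy = ab.batch_inject(clean, batch, batch_effect_size=1.5, seed=9)
    return clean, noisy, batch
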