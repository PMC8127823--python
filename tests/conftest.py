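import numpy as np
import pandas as pd
import pytest

from ohnofate import ExpressionMatrix, SimConfig, SpeciesTree, simulate_expression


@pytest.fixture(scope="session")
def stree():
    return SpeciesTree.default()


@pytest.fixture(scope="session")
def small_zero_noise_bundle():
    """60 triplets, zero noise: every fate exactly identifiable."""
    return simulate_expression(SimConfig(n_triplets=60, noise_sd=0.0, seed=3))


@pytest.fixture()
def toy_matrix():
    values = pd.DataFrame(
        [[0.0, 2.0, 5.0], [1.0, 1.0, 1.0], [0.5, 1.2, 0.0], [0.0, 0.0, 0.0]],
        index=["g1", "g2", "g3", "g4"],
        columns=["t1", "t2", "t3"],
    )
    return ExpressionMatrix(values=values, species="salmon")


def profile_with_r(target_r: float, n: int = 13) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic pair (x, base) with Pearson r(x, base) == target_r exactly."""
    t = np.arange(n, dtype=float)
    u = (t - t.mean()) / np.linalg.norm(t - t.mean())
    w = np.sin(t)  # anything not collinear with u
    w = w - w.mean()
    w = w - (w @ u) * u
    w /= np.linalg.norm(w)
    x = target_r * u + np.sqrt(1 - target_r**2) * w
    return x, t
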