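import numpy as np
import pytest

from aqstruct import synthetic_data as sd


@pytest.fixture(scope="session")
def taxonic_indicators():
    """Taxonic indicator dataset at the study's scale (n=1139, p=0.15, d=2)."""
    spec = sd.PopulationSpec(
        structure="taxonic", n=1139, class_weights=(0.85, 0.15), seed=1
    )
    return sd.generate_continuous_indicators(spec)


@pytest.fixture(scope="session")
def six_class_items():
    """Six-class item mixture from the packaged profiles, n=5000."""
    spec = sd.six_class_spec(5000, seed=4)
    return sd.generate_six_class_items(spec)


@pytest.fixture(scope="session")
def three_factor_items():
    """Binary items from 3 orthogonal probit factors (6 items each), n=5000."""
    rng = np.random.default_rng(7)
    n, loads = 5000, 0.8
    z = rng.standard_normal((n, 3))
    cols = {}
    true_loadings = np.zeros((18, 3))
    for f in range(3):
        for j in range(6):
            idx = f * 6 + j
            lam = loads - 0.05 * j  # mild heterogeneity within a block
            true_loadings[idx, f] = lam
            tau = -0.4 + 0.15 * j
            liab = lam * z[:, f] + np.sqrt(1 - lam**2) * rng.standard_normal(n)
            cols[f"item_{idx + 1}"] = (liab > tau).astype(np.int8)
    import pandas as pd

    return pd.DataFrame(cols), true_loadings
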