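import numpy as np
import pandas as pd
import pytest

import raex


def make_beta_matrix(beta: pd.DataFrame, total: pd.DataFrame, material: str, threshold=750.0):
    """Assemble a BetaMatrix directly from beta/total frames."""
    return raex.BetaMatrix(
        beta=beta.where(total > 0),
        total=total,
        pass_filter=(total > threshold).fillna(False),
        intensity_threshold=threshold,
        material=material,
    )


@pytest.fixture(scope="session")
def small_sim_panel():
    """A modest simulated panel shared across tests (read-only)."""
    cfg = raex.SimConfig(n_genes=300, seed=42)
    return raex.simulate_panel(cfg)


@pytest.fixture(scope="session")
def noise_free_panel():
    """Zero-measurement-noise panel: classification should be exact."""
    cfg = raex.SimConfig(
        n_genes=400,
        seed=7,
        beta_noise_sd=0.0,
        gdna_het_bias_sd=0.0,
        low_intensity_fraction=0.0,
        expressed_fraction=1.0,
    )
    return raex.simulate_panel(cfg)
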