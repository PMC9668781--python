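import numpy as np
import pandas as pd
import pytest

from biofortqg.simulate import generate_dataset, small_config


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small single-trait augmented-design dataset with its truth."""
    cfg = small_config(n_genotypes=40, n_checks=3, n_trials=3, n_blocks=3,
                       traits=("TCC",))
    return generate_dataset(cfg, seed=7)


@pytest.fixture(scope="session")
def multitrait_dataset():
    """All 11 traits on a compact design, with ordinal discretisation."""
    cfg = small_config(
        n_genotypes=30, n_checks=3, n_trials=3, n_blocks=3,
        traits=("TCC", "DMC.Grav", "DMC.OD", "FRY", "ShY", "HI", "DRY",
                "NRP", "StC", "PulpColor", "HCN"),
    )
    return generate_dataset(cfg, seed=5)


@pytest.fixture()
def blup_like_table():
    """Deterministic genotype x trait table shaped like BLUP output."""
    rng = np.random.default_rng(11)
    traits = ["TCC", "FRY", "HCN"]
    data = rng.normal([4.0, 16.0, 6.8], [2.0, 4.0, 1.2], size=(25, 3))
    return pd.DataFrame(data, columns=traits,
                        index=[f"G{i:03d}" for i in range(25)])
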