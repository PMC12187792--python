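import numpy as np
import pandas as pd
import pytest

from phytoaccum.synthetic_data import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default stated world: 35 sites, 46 elements, seed 1."""
    return generate_dataset(SynthConfig(n_sites=35, seed=1))


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Noise-free closed-loop world: every index analytically predictable."""
    cfg = SynthConfig(
        n_sites=10,
        seed=1,
        subsoil_gsd=1.0,
        frond_gsd=1.0,
        replicate_gsd=1.0,
        ree_rho=0.0,
    )
    return cfg, generate_dataset(cfg)


@pytest.fixture()
def wide_csv(tmp_path):
    """Wide CSV: 2 sites x 3 elements."""
    path = tmp_path / "frond_wide.csv"
    pd.DataFrame(
        {"site_id": [1, 2], "Ce": [19.1, 21.0], "Zn": [26.4, 30.0], "Cu": [9.0, 8.5]}
    ).to_csv(path, index=False)
    return path


@pytest.fixture()
def long_csv_with_reps(tmp_path):
    """Long CSV with 3 replicates for one site/element plus a second element."""
    path = tmp_path / "frond_long.csv"
    rows = [
        {"site_id": 1, "element": "Ce", "replicate": r, "value_mg_kg": v}
        for r, v in zip((1, 2, 3), (18.0, 19.1, 20.4))
    ] + [{"site_id": 1, "element": "Zn", "replicate": 1, "value_mg_kg": 26.4}]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
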