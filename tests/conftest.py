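import numpy as np
import pandas as pd
import pytest

from nutriscreen import SyntheticConfig, fit_table, normalize_rma, simulate_campaign


def small_config(seed: int = 11, **overrides) -> SyntheticConfig:
    """A fast-but-complete campaign: short reads, few wells, full structure."""
    defaults = dict(
        seed=seed,
        n_cell_lines=8,
        n_substrates=12,
        n_genes=20,
        duration_h=30.0,
        interval_h=0.5,
        n_survival_samples=40,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def campaign():
    """One shared small campaign plus its fitted params and RMA table."""
    cfg = small_config()
    data = simulate_campaign(cfg)
    params = fit_table(data["traces"])
    rma = normalize_rma(params, data["platemap"])
    return {"config": cfg, "data": data, "params": params, "rma": rma}


@pytest.fixture()
def toy_platemap_params():
    """Three negative controls {0.1, 0.2, 0.3} and one test well A=0.5."""
    platemap = pd.DataFrame(
        {
            "plate_id": "P1",
            "well": ["A01", "A02", "A03", "A04"],
            "cell_line": "CL01",
            "substrate": ["uridine", "blank", "blank", "blank"],
            "role": ["test"] + ["negative_control"] * 3,
            "replicate": [1, 1, 2, 3],
        }
    )
    params = pd.DataFrame(
        {
            "plate_id": "P1",
            "well": ["A01", "A02", "A03", "A04"],
            "lambda_h": 0.0,
            "mu": 0.0,
            "A": [0.5, 0.1, 0.2, 0.3],
            "auc": 0.0,
        }
    )
    return platemap, params


def assert_frames_equal_bytes(path_a, path_b):
    with open(path_a, "rb") as fa, open(path_b, "rb") as fb:
        assert fa.read() == fb.read(), f"{path_a} differs from {path_b}"


def rng_mid(rng: np.random.Generator, n_carbons: int) -> np.ndarray:
    f = rng.dirichlet(np.ones(n_carbons + 1))
    return f / f.sum()
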