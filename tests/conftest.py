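import numpy as np
import pandas as pd
import pytest

from bonequant import QuantMatrix, SimulationConfig, simulate_bone_proteome


def make_design(n_donors: int = 3, groups=("arm_a", "arm_b")) -> pd.DataFrame:
    rows = []
    for d in range(n_donors):
        for gi, g in enumerate(groups):
            rows.append(
                {
                    "run_id": f"donor{d + 1:03d}_{'AB'[gi]}",
                    "donor_id": f"donor{d + 1:03d}",
                    "replicate_set": "AB"[gi],
                    "group": g,
                    "acquisition": "DIA",
                }
            )
    return pd.DataFrame(rows)


def make_matrix(values, level="protein", scale="raw", features=None, samples=None,
                feature_meta=None) -> QuantMatrix:
    arr = np.asarray(values, dtype=float)
    features = features or [f"F{i + 1}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j + 1}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=features, columns=samples)
    meta = None
    if feature_meta is not None:
        meta = pd.DataFrame(feature_meta, index=features)
    return QuantMatrix(values=df, level=level, scale=scale, feature_meta=meta)


@pytest.fixture(scope="session")
def small_truth():
    """A 5-protein, 4-donor synthetic dataset with moderate missingness."""
    cfg = SimulationConfig(
        n_donors=4, n_proteins=5, collagen_fraction=0.2,
        target_missingness=0.15, seed=42,
    )
    return simulate_bone_proteome(cfg)


@pytest.fixture(scope="session")
def complete_truth():
    """Noise-free-missingness dataset: every cell observed."""
    cfg = SimulationConfig(
        n_donors=5, n_proteins=10, mcar_rate=0.0, mnar_slope=0.0, seed=7,
    )
    return simulate_bone_proteome(cfg)


@pytest.fixture(scope="session")
def correlated_log2():
    """Complete log2 protein matrix with strong inter-feature correlation."""
    from bonequant import log2_transform

    cfg = SimulationConfig(
        n_donors=10, n_proteins=40, mcar_rate=0.0, mnar_slope=0.0, seed=11,
    )
    truth = simulate_bone_proteome(cfg)
    return log2_transform(truth.latent_matrix("protein"))
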