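import numpy as np
import pandas as pd
import pytest

from metanetdiff import synth
from metanetdiff.data import FeatureMatrix, bio_design
from metanetdiff import qc


def make_matrix(values: np.ndarray, sample_ids=None, scale="log",
                mz=None) -> FeatureMatrix:
    """Wrap a plain array (features x samples) in a FeatureMatrix."""
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    ids = pd.Index([f"F{i:04d}" for i in range(p)], name="feature_id")
    cols = sample_ids if sample_ids is not None else [f"s{j}" for j in range(n)]
    feats = pd.DataFrame({
        "mz": np.linspace(100.0, 900.0, p) if mz is None else mz,
        "rt": np.linspace(10.0, 600.0, p),
        "column_id": ["AE"] * p,
    }, index=ids)
    return FeatureMatrix(values=pd.DataFrame(values, index=ids, columns=cols),
                         features=feats, scale=scale)


def simple_design(n_samples: int, diets=None, ages=None, tech=1,
                  batches=1) -> pd.DataFrame:
    """A flat design table for hand-built matrices (one tissue)."""
    rows = []
    for j in range(n_samples):
        bio = f"s{j}"
        for t in range(1, tech + 1):
            rows.append({
                "sample_id": bio if tech == 1 else f"{bio}_t{t}",
                "bio_id": bio,
                "diet": diets[j] if diets is not None else "AL",
                "age": ages[j] if ages is not None else 10,
                "tissue": "thorax",
                "batch": j % batches + 1,
                "bio_rep": j + 1,
                "tech_rep": t,
            })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def study():
    """One small simulated study shared across tests (read-only)."""
    cfg = synth.SynthConfig(n_features=600, seed=42)
    design = synth.make_design(cfg)
    matrix, truth = synth.simulate_features(design, cfg)
    return cfg, design, matrix, truth


@pytest.fixture(scope="session")
def clean_study(study):
    """The shared study taken through the QC chain (read-only)."""
    cfg, design, matrix, truth = study
    logged = qc.log_transform(matrix)
    kept, _ = qc.snr_filter(logged, design)
    collapsed = qc.collapse_tech_reps(kept, design)
    filtered = qc.missingness_filter(collapsed)
    clean = qc.center_features(qc.impute(filtered, seed=0))
    return cfg, bio_design(design), clean, truth
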