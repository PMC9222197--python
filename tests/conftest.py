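import numpy as np
import pandas as pd
import pytest

from orgshift import spatial_data as sp
from orgshift import synthetic_data as sd

#: Per-class marker counts of the curated 548-marker reference set.
MARKER_COUNTS = {
    "cytosol": 58,
    "ER": 96,
    "proteasome": 29,
    "Golgi": 16,
    "lysosome": 17,
    "mitochondrion": 101,
    "nucleus": 107,
    "nucleus-chromatin": 32,
    "ribosome": 47,
    "peroxisome": 15,
    "plasma membrane": 30,
}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def marker_fixture_path(tmp_path):
    """Marker TSV with the reference per-class counts (548 markers total)."""
    rows = []
    i = 0
    for cls, count in MARKER_COUNTS.items():
        for _ in range(count):
            rows.append((f"M{i:04d}", cls))
            i += 1
    path = tmp_path / "markers.tsv"
    pd.DataFrame(rows, columns=["protein_id", "compartment"]).to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def tiny_experiment():
    """Two proteins, one replicate, ten fractions."""
    table = pd.DataFrame(
        [np.arange(1.0, 11.0), np.ones(10)],
        index=pd.Index(["A", "B"], name="protein_id"),
        columns=[f"fraction_{i}" for i in range(1, 11)],
    )
    return sp.FractionationExperiment("ctrl", [table], ["1"])


@pytest.fixture(scope="session")
def small_dataset():
    """Small paired dataset with movers shared across tests (session-cached)."""
    cfg = sd.GeneratorConfig(
        n_unknown=60, n_movers=8, markers_per_class=(6,) * 11, seed=11
    )
    control, treated, truth = sd.simulate_dataset(cfg)
    cm = sp.concatenate_replicates(sp.normalize_experiment(control))
    tm = sp.concatenate_replicates(sp.normalize_experiment(treated))
    return cfg, cm, tm, truth


def profile_matrix(values: np.ndarray, ids, n_fractions=10, label="x") -> sp.SpatialProfileMatrix:
    values = np.asarray(values, dtype=float)
    n_rep = values.shape[1] // n_fractions
    return sp.SpatialProfileMatrix(
        protein_ids=list(ids),
        matrix=values,
        replicate_boundaries=[(r * n_fractions, (r + 1) * n_fractions) for r in range(n_rep)],
        n_fractions=n_fractions,
        condition_label=label,
    )
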