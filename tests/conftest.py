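import numpy as np
import pandas as pd
import pytest

import resilax as rx
from resilax.workflow import analyze_study


@pytest.fixture(scope="session")
def default_study():
    """The default simulated study (full-size generator, seed 42)."""
    return rx.simulate_study(seed=42)


@pytest.fixture(scope="session")
def default_results(default_study):
    """Full pipeline output on the default study."""
    return analyze_study(default_study.dataset, default_study.survival, seed=42)


@pytest.fixture(scope="session")
def small_study():
    """A reduced study for fast I/O and CLI tests."""
    cfg = rx.SimConfig(n_genes=300, n_genotypes=12, seed=7)
    return rx.simulate_study(cfg)


def make_dataset(values, genotypes=None, treatments=None, t_dev=None,
                 t_heat=None, t_rec=None, split=None):
    """Hand-build a small ExpressionDataset with sensible metadata defaults."""
    values = pd.DataFrame(values)
    n = values.shape[1]
    values.index = [f"g{i}" for i in range(values.shape[0])]
    values.columns = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame({
        "sample_id": values.columns,
        "genotype": genotypes or ["N2"] * n,
        "treatment": treatments or ["control"] * n,
        "t_dev": t_dev if t_dev is not None else np.arange(44.0, 44.0 + n),
        "t_heat": t_heat if t_heat is not None else [0.0] * n,
        "t_rec": t_rec if t_rec is not None else [0.0] * n,
        "split": split or ["train"] * n,
    }).set_index("sample_id")
    return rx.ExpressionDataset(values, meta)


def make_axis(loadings, name="custom", sd=None, mean=None):
    """Axis over unit-scale standardizer coordinates, for hand examples."""
    loadings = np.asarray(loadings, dtype=float)
    loadings = loadings / np.linalg.norm(loadings)
    gene_ids = pd.Index([f"g{i}" for i in range(len(loadings))])
    st = rx.Standardizer(
        gene_ids,
        np.zeros(len(loadings)) if mean is None else np.asarray(mean, float),
        np.ones(len(loadings)) if sd is None else np.asarray(sd, float),
        source_tag="hand",
    )
    return rx.Axis(name=name, loadings=loadings, gene_ids=gene_ids, standardizer=st)
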