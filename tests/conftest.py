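import numpy as np
import pandas as pd
import pytest

from surfglm.design import build_design, parse_formula
from surfglm.fsio import VertexMapStack
from surfglm.synthetic import SimulationConfig, make_icosphere, simulate_arrays, simulate_dataset


@pytest.fixture(scope="session")
def ico2():
    """162-vertex icosphere at hemisphere scale."""
    return make_icosphere(2, 100.0)


@pytest.fixture(scope="session")
def ico0():
    """Plain icosahedron (12 vertices, regular degree 5)."""
    return make_icosphere(0, 1.0)


@pytest.fixture(scope="session")
def age_sex_spec():
    return parse_formula("qdecr_thickness ~ age + sex")


@pytest.fixture()
def pheno30():
    rng = np.random.default_rng(42)
    return pd.DataFrame(
        {
            "id": [f"s{i:03d}" for i in range(30)],
            "age": rng.uniform(47, 80, 30),
            "sex": rng.choice(["F", "M"], 30),
            "bmi": rng.normal(25, 3, 30),
        }
    )


@pytest.fixture(scope="session")
def null_dataset(age_sex_spec):
    """A zero-effect synthetic dataset with its design, held in memory."""
    cfg = SimulationConfig(n_subjects=40, seed=11)
    mesh, maps, pheno = simulate_arrays(cfg)
    stack = VertexMapStack(maps, list(pheno["id"]))
    design = build_design(age_sex_spec, pheno)
    return cfg, mesh, stack, pheno, design


@pytest.fixture()
def subjects_dir(tmp_path):
    """A small on-disk synthetic subjects directory (planted age effect)."""
    cfg = SimulationConfig(n_subjects=25, seed=5, beta_age=-0.02)
    mesh, pheno = simulate_dataset(cfg, tmp_path)
    return cfg, tmp_path, mesh, pheno
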