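import numpy as np
import pandas as pd
import pytest

from ddg_errorband import SyntheticConfig, build_predictor_table, generate_dataset
from ddg_errorband.synthetic import format_dssp, write_fxout


@pytest.fixture(scope="session")
def dataset():
    """A moderate correctly-specified dataset shared across tests."""
    return generate_dataset(SyntheticConfig(n_per_system=60), seed=11)


@pytest.fixture(scope="session")
def table5(dataset):
    """Full-pool design table for the shared dataset."""
    return build_predictor_table(dataset.df, "model5")


@pytest.fixture()
def fxout_path(tmp_path):
    rng = np.random.default_rng(3)
    from ddg_errorband.data_model import CANONICAL_TERMS

    rows = []
    for i in range(3):
        terms = {t: round(float(rng.normal(0, 0.5)), 5) for t in CANONICAL_TERMS}
        terms["vdw_clash"] = 0.50
        rows.append((f"Dif_mut_{i}.pdb", terms))
    path = tmp_path / "dif.fxout"
    write_fxout(path, rows)
    return path, rows


@pytest.fixture()
def dssp_path(tmp_path):
    residues = [
        ("A", 1, "M", "H", 120),
        ("A", 2, "K", "H", 95),
        ("A", 3, "V", "E", 10),
        ("A", 4, "L", "E", 4),
        ("A", 5, "A", "", 30),
        ("A", 6, "Y", "T", 88),
        ("A", 7, "T", "S", 61),
        ("A", 8, "R", "G", 140),
        ("A", 9, "E", "B", 77),
        ("A", 10, "G", "", 52),
    ]
    path = tmp_path / "toy.dssp"
    path.write_text(format_dssp(residues))
    return path, residues
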