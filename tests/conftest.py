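import numpy as np
import pandas as pd
import pytest

from oglyc_lpm.encoding import DesignMatrix
from oglyc_lpm.study_io import SiteRecord, StudyTable


def make_record(accession="P00001", site_position=50, window=None,
                protein_length=200, flags=None, **kwargs):
    window = window or "ACDEFGHLSMNPQRSTV"       # 17-mer, center S
    return SiteRecord(
        accession=accession, site_position=site_position,
        site_residue=window[len(window) // 2], window=window,
        protein_length=protein_length, flags=flags or {}, **kwargs)


@pytest.fixture
def toy_design():
    """50 x 5 Gaussian design with a known linear response."""
    rng = np.random.default_rng(42)
    X = pd.DataFrame(rng.normal(size=(50, 5)),
                     columns=[f"x{i}" for i in range(5)])
    beta = np.array([1.0, -0.5, 0.25, 0.0, 2.0])
    y = 0.3 + X.to_numpy() @ beta + 0.1 * rng.normal(size=50)
    return DesignMatrix(X, y, [(i,) for i in range(50)])


@pytest.fixture
def binary_design():
    """Logistic-generated binary response on 6 predictors (n=300)."""
    rng = np.random.default_rng(7)
    X = pd.DataFrame(rng.normal(size=(300, 6)),
                     columns=[f"x{i}" for i in range(6)])
    eta = 1.2 * X["x0"] - 0.8 * X["x1"]
    y = (rng.random(300) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return DesignMatrix(X, y, [(i,) for i in range(300)])


@pytest.fixture
def small_table():
    recs = [
        make_record("P1", 20, flags={"Ogly_21": True}),
        make_record("P2", 30, flags={"Ogly_21": True}),
        make_record("P3", 40, flags={"glyco_status": True}, sugar_count=2),
        make_record("P4", 50, flags={"glyco_status": True}, sugar_count=3),
    ]
    return StudyTable(recs)
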