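"""Bundled reference tables.

Published positional amino-acid marginal distributions for the three PTM
classes, and the published LPM coefficient tables (structural WLS,
sequence-only WLS, structural OLS with heteroscedasticity-consistent |t|).
The coefficient tables let the predictor run in "fixture mode" — scoring
new windows with the published model — without refitting anything.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_DATA = resources.files("oglyc_lpm") / "data"

MARGINAL_FILES = {
    "oglcnac": "marginals_oglcnac.csv",
    "ogalnac": "marginals_ogalnac.csv",
    "phospho": "marginals_phospho.csv",
}

MODEL_FILES = {
    "structural_wls": "lpm_structural_wls.csv",
    "sequence_wls": "lpm_sequence_wls.csv",
    "structural_ols_white": "lpm_structural_ols_white.csv",
}


def load_marginals(ptm: str) -> pd.DataFrame:
    """Residue x offset table of percentages for one PTM class.

    Index: the 20 residue letters; columns: signed window offsets
    (ints; ±8 for the glycosylation classes, ±7 for phosphorylation).
    """
    if ptm not in MARGINAL_FILES:
        raise KeyError(f"unknown PTM class {ptm!r}; one of {sorted(MARGINAL_FILES)}")
    with (_DATA / MARGINAL_FILES[ptm]).open() as fh:
        df = pd.read_csv(fh, index_col="residue")
    df.columns = df.columns.astype(int)
    return df


#: published variable labels -> design-matrix column names
VARIABLE_ALIASES = {"Phi angle": "phi", "Psi angle": "psi"}


def load_model(name: str) -> pd.DataFrame:
    """Published coefficient table: variable, beta and an |t|-type column.

    Variable labels are normalized to the design-matrix column naming
    (e.g. "Phi angle" -> "phi").
    """
    if name not in MODEL_FILES:
        raise KeyError(f"unknown model {name!r}; one of {sorted(MODEL_FILES)}")
    with (_DATA / MODEL_FILES[name]).open() as fh:
        df = pd.read_csv(fh)
    df["variable"] = df["variable"].replace(VARIABLE_ALIASES)
    return df


def model_coefficients(name: str) -> dict[str, float]:
    df = load_model(name)
    return dict(zip(df["variable"], df["beta"]))
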