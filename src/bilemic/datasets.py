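"""Packaged reference tables.

``thermo_table.csv``: per-temperature demicellization state functions of
three hydrophobic C3 derivatives of sodium cholate (NaAdC, NaAdCH2C,
NatButPhC) in carbonate buffer, transcribed from the published
characterization of these surfactants: cmc (mM and 1e6 * mole fraction),
aggregation number and dG/dH/dS of demicellization per temperature.

``logp_predictors.csv``: log P values of six natural unconjugated bile
salts from five structure-based predictors and the molecular-lipophilicity-
potential ("virtual") method, next to the experimental octan-1-ol/water
values, for predictor benchmarking.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_thermo_table", "load_logp_table", "PREDICTOR_COLUMNS"]

PREDICTOR_COLUMNS = ["iLOGP", "XLOGP3", "WLOGP", "MLOGP", "SILICOS_IT", "virtual"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("bilemic.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_thermo_table() -> pd.DataFrame:
    """Reference demicellization thermodynamics, one row per (surfactant, T)."""
    return _read("thermo_table.csv")


def load_logp_table() -> pd.DataFrame:
    """Reference log P predictor benchmark, one row per bile salt."""
    return _read("logp_predictors.csv")
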