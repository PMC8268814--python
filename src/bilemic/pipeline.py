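"""End-to-end analysis: reference tables + seeded synthetic round trips.

``run_full_analysis`` regenerates everything derivable from the packaged
reference tables (entropies, mole fractions, heat capacities, mean
aggregation numbers, predictor residuals, the cmc-based log P estimate) and
exercises the full synthetic pipeline (simulate -> fit) with known ground
truth, returning one nested, JSON-serializable report.  Identical
configurations give byte-identical reports: all stochastic stages consume
the explicit seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import counterion, lipophilicity, tensiometry, thermo
from .config import AnalysisConfig
from .datasets import PREDICTOR_COLUMNS, load_logp_table, load_thermo_table
from .itc import fit_demicellization
from .synthetic import (
    default_schedule,
    default_truth,
    gen_corrin_harkins_series,
    gen_itc_experiment,
    gen_surface_tension_curve,
)

__all__ = ["run_full_analysis", "write_report"]


def _thermo_section(config: AnalysisConfig) -> dict:
    df = (
        pd.read_csv(config.thermo_table)
        if config.thermo_table
        else load_thermo_table()
    )
    section: dict = {}
    for name, grp in df.groupby("surfactant", sort=False):
        rows = []
        records = []
        for row in grp.itertuples():
            dS = thermo.delta_s_demic(row.dG_kJ_mol, row.dH_kJ_mol, row.T_K)
            x = thermo.mole_fraction_from_cmc(row.cmc_mM, config.water_molarity_mm)
            rows.append(
                {
                    "T_K": row.T_K,
                    "cmc_mM": row.cmc_mM,
                    "x_cmc_e6": 1e6 * x,
                    "x_cmc_e6_printed": row.x_cmc_e6,
                    "n": row.n,
                    "dG_kJ_mol": row.dG_kJ_mol,
                    "dH_kJ_mol": row.dH_kJ_mol,
                    "dS_J_mol_K": dS,
                    "dS_J_mol_K_printed": row.dS_J_mol_K,
                }
            )
            records.append(
                thermo.ThermoRecord(
                    temperature=row.T_K,
                    cmc=row.cmc_mM,
                    x_cmc=x,
                    n=row.n,
                    dG_demic=row.dG_kJ_mol,
                    dH_demic=row.dH_kJ_mol,
                    dS_demic=dS,
                    label=name,
                )
            )
        summary = thermo.summarize(records)
        section[name] = {
            "rows": rows,
            "mean_n": summary.mean_n,
            "sd_n": summary.sd_n,
            "dCp_J_mol_K": summary.dCp_demic,
            "dCp_stderr": summary.dCp_stderr,
            "max_dS_residual": max(
                abs(r["dS_J_mol_K"] - r["dS_J_mol_K_printed"]) for r in rows
            ),
        }
    return section


def _lipophilicity_section(config: AnalysisConfig) -> dict:
    df = (
        pd.read_csv(config.logp_table) if config.logp_table else load_logp_table()
    )
    residuals = {}
    for col in PREDICTOR_COLUMNS:
        records = [
            lipophilicity.LogPRecord(
                compound=row.compound,
                predictor=col,
                predicted=float(getattr(row, col)),
                experimental=float(row.experimental),
            )
            for row in df.itertuples()
        ]
        msr = lipophilicity.mean_squared_residual(records)
        residuals[col] = {
            "mean_squared_residual": msr,
            "reliability": lipophilicity.classify_reliability(msr),
        }
    # cmc-based log P estimate for the adamantyl cholate derivative at 25 degC.
    tdf = (
        pd.read_csv(config.thermo_table)
        if config.thermo_table
        else load_thermo_table()
    )
    adc = tdf[(tdf.surfactant == "NaAdC") & (tdf.T_K == 298.15)].iloc[0]
    logp_adc = lipophilicity.predict_logp_from_cmc(float(adc.cmc_mM))
    return {
        "predictor_residuals": residuals,
        "adc_logp_from_cmc": {
            "cmc_mM": float(adc.cmc_mM),
            "predicted_logp": logp_adc,
        },
        "reference_fit": {
            "slope": lipophilicity.REFERENCE_FIT.slope,
            "intercept": lipophilicity.REFERENCE_FIT.intercept,
            "r_squared": lipophilicity.REFERENCE_FIT.r_squared,
        },
    }


def _synthetic_section(config: AnalysisConfig) -> dict:
    seed = int(config.seed)
    truth = default_truth(seed=seed)
    series = gen_itc_experiment(truth, default_schedule())
    fit = fit_demicellization(
        series,
        drop_first=config.drop_first_injection,
        refine=config.refine_itc_fit,
        convention=config.cmc_convention,
    )
    itc_part = {
        "truth": {
            "n": truth.params.n,
            "cmc_mM": truth.cmc,
            "dH_demic": truth.dH_demic,
            "dH_dil": truth.dH_dil,
        },
        "fit": {
            "n": fit.n,
            "cmc_mM": fit.cmc,
            "dH_demic": fit.dH_demic,
            "dH_dil": fit.dH_dil,
            "r_squared": fit.r_squared,
        },
    }
    ch_points = gen_corrin_harkins_series(
        A=-1.0, beta=0.63, noise_sd=0.02, seed=seed + 1
    )
    ch = counterion.corrin_harkins_fit(ch_points)
    curve = gen_surface_tension_curve(noise_sd=0.3, seed=seed + 2)
    bp = tensiometry.detect_cmc_breakpoint(curve, alpha=config.breakpoint_alpha)
    return {
        "itc_round_trip": itc_part,
        "corrin_harkins": {"truth_beta": 0.63, "fitted_beta": ch.beta, "A": ch.A},
        "tensiometry": {"truth_cmc_mM": 0.4, "fitted_cmc_mM": bp.cmc},
    }


def run_full_analysis(config: AnalysisConfig | None = None) -> dict:
    """Run every stage; returns the report as a nested dict (see module doc)."""
    config = config or AnalysisConfig()
    report = {
        "config": config.to_dict(),
        "thermodynamics": _thermo_section(config),
        "lipophilicity": _lipophilicity_section(config),
        "synthetic_recovery": _synthetic_section(config),
    }
    if config.output_path:
        write_report(report, config.output_path)
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
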