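"""CSV/JSON readers and writers for the analysis stages."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .counterion import PKA2_CARBONATE, sodium_from_carbonate_buffer
from .exceptions import ValidationError
from .itc import DemicellizationFitResult, ITCInjectionSeries
from .tensiometry import SurfaceTensionCurve

__all__ = [
    "read_itc_csv",
    "write_itc_csv",
    "read_surface_tension_csv",
    "write_surface_tension_csv",
    "read_corrin_harkins_csv",
    "write_fit_result",
]

_ITC_COLUMNS = ["injection_id", "volume_uL", "heat_kJ_per_mol"]


def _read_sidecar(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def read_itc_csv(csv_path: str | Path, meta_path: str | Path) -> ITCInjectionSeries:
    """Injection table (injection_id, volume_uL, heat_kJ_per_mol) plus a
    JSON/YAML sidecar with the experiment-level conditions."""
    df = pd.read_csv(csv_path)
    missing = [c for c in _ITC_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"ITC table is missing columns {missing}")
    meta = _read_sidecar(meta_path)
    for key in ("syringe_conc_mM", "cell_volume_uL", "temperature_K"):
        if key not in meta:
            raise ValidationError(f"ITC sidecar is missing {key!r}")
    return ITCInjectionSeries(
        syringe_conc=float(meta["syringe_conc_mM"]),
        cell_volume=float(meta["cell_volume_uL"]),
        injection_volumes=df["volume_uL"].to_numpy(float),
        heats=df["heat_kJ_per_mol"].to_numpy(float),
        temperature=float(meta["temperature_K"]),
        buffer_total_conc=float(meta["buffer_total_mM"]) if "buffer_total_mM" in meta else None,
        pH=float(meta["pH"]) if "pH" in meta else None,
        label=str(meta.get("label", "")),
    )


def write_itc_csv(
    series: ITCInjectionSeries, csv_path: str | Path, meta_path: str | Path
) -> None:
    df = pd.DataFrame(
        {
            "injection_id": np.arange(1, len(series) + 1),
            "volume_uL": series.injection_volumes,
            "heat_kJ_per_mol": series.heats,
        }
    )
    df.to_csv(csv_path, index=False)
    meta = {
        "syringe_conc_mM": series.syringe_conc,
        "cell_volume_uL": series.cell_volume,
        "temperature_K": series.temperature,
        "label": series.label,
    }
    if series.buffer_total_conc is not None:
        meta["buffer_total_mM"] = series.buffer_total_conc
    if series.pH is not None:
        meta["pH"] = series.pH
    Path(meta_path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_surface_tension_csv(
    path: str | Path, temperature: float = 298.15, label: str = ""
) -> SurfaceTensionCurve:
    """Curve table with columns conc_mM, gamma_mN_per_m."""
    df = pd.read_csv(path)
    for col in ("conc_mM", "gamma_mN_per_m"):
        if col not in df.columns:
            raise ValidationError(f"surface-tension table is missing column {col!r}")
    return SurfaceTensionCurve(
        concentrations=df["conc_mM"].to_numpy(float),
        gamma=df["gamma_mN_per_m"].to_numpy(float),
        temperature=temperature,
        label=label,
    )


def write_surface_tension_csv(curve: SurfaceTensionCurve, path: str | Path) -> None:
    pd.DataFrame(
        {"conc_mM": curve.concentrations, "gamma_mN_per_m": curve.gamma}
    ).to_csv(path, index=False)


def read_corrin_harkins_csv(path: str | Path, pKa2: float = PKA2_CARBONATE):
    """Rows of (buffer_total_mM, pH, cmc_mM); returns (points, dataframe)
    where points are (cmc_mM, sodium_M) pairs with speciated sodium."""
    df = pd.read_csv(path)
    for col in ("buffer_total_mM", "pH", "cmc_mM"):
        if col not in df.columns:
            raise ValidationError(f"Corrin–Harkins table is missing column {col!r}")
    df = df.copy()
    df["sodium_M"] = [
        sodium_from_carbonate_buffer(row.buffer_total_mM, row.pH, pKa2)
        for row in df.itertuples()
    ]
    points = list(zip(df["cmc_mM"].tolist(), df["sodium_M"].tolist()))
    return points, df


def write_fit_result(result: DemicellizationFitResult, path: str | Path) -> None:
    """Flat JSON or single-row CSV, by file extension."""
    path = Path(path)
    data = result.to_dict()
    if path.suffix.lower() == ".csv":
        pd.DataFrame([data]).to_csv(path, index=False)
    else:
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
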