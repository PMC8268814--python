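"""State functions of demicellization with counterion-binding correction.

For an ionic surfactant the micellization constant must include the bound
counterions: ``K_mic = K [Na+]^(beta*n)``, and the Gibbs energy of
demicellization per mole of monomer is ``dG_demic = (R T / n) ln K_mic``.
The entropy follows from the Gibbs–Helmholtz bookkeeping
``dS = (dH - dG)/T`` and the heat capacity ``dC_P,demic`` is the slope of
``dH_demic`` versus temperature (positive when hydrophobic surface becomes
water-exposed on dissociation).

Sign convention: every quantity refers to DEMICELLIZATION (``dG_demic > 0``
and ``dS_demic < 0`` for bile-salt systems); micellization values are the
negatives and are never stored.

Units: kJ/mol for enthalpies and Gibbs energies, J/(mol K) for entropies
and heat capacities, mM for concentrations, M for sodium activity.  The
literal term ``[Na+]^(beta*n)`` is negative in ``ln`` for sub-molar sodium;
its *contribution* to dG is conventionally quoted as a magnitude, which is
what :func:`sodium_term_contribution` returns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import ValidationError
from .mass_action import WATER_MOLARITY_MM

__all__ = [
    "R_GAS",
    "ThermoRecord",
    "ThermoSummary",
    "k_mic",
    "delta_g_demic",
    "delta_s_demic",
    "heat_capacity_demic",
    "mole_fraction_from_cmc",
    "sodium_term_contribution",
    "summarize",
]

#: Gas constant, J/(mol K).
R_GAS = 8.314


@dataclass(frozen=True)
class ThermoRecord:
    """Per-temperature demicellization state functions (one table row)."""

    temperature: float      # K
    cmc: float              # mM
    x_cmc: float            # mole fraction
    n: float                # aggregation number
    dG_demic: float         # kJ/mol
    dH_demic: float         # kJ/mol
    dS_demic: float         # J/(mol K)
    label: str = ""


@dataclass(frozen=True)
class ThermoSummary:
    """Cross-temperature summary for one surfactant."""

    mean_n: float
    sd_n: float
    dCp_demic: float            # J/(mol K)
    dCp_stderr: float
    records: tuple = field(default_factory=tuple)


def k_mic(K: float, sodium: float, beta: float, n: float) -> float:
    """Counterion-corrected micellization constant ``K [Na+]^(beta*n)``.

    Computed in log space so that large ``K`` and large ``beta*n`` do not
    overflow.  ``sodium`` in M; ``beta`` in [0, 1].
    """
    if not sodium > 0:
        raise ValidationError("sodium concentration must be > 0")
    if not 0.0 <= beta <= 1.0:
        raise ValidationError(f"beta must be within [0, 1], got {beta}")
    return math.exp(math.log(K) + beta * n * math.log(sodium))


def delta_g_demic(k_mic_value: float, temperature: float, n: float) -> float:
    """Gibbs energy of demicellization per monomer, ``(R T / n) ln K_mic`` (kJ/mol)."""
    if not k_mic_value > 0:
        raise ValidationError("K_mic must be > 0")
    if n < 2:
        raise ValidationError("aggregation number must be >= 2")
    return R_GAS * temperature / n * math.log(k_mic_value) / 1000.0


def delta_s_demic(dG: float, dH: float, temperature: float) -> float:
    """Demicellization entropy ``(dH - dG)/T`` in J/(mol K) from kJ/mol inputs."""
    if not temperature > 0:
        raise ValidationError("temperature must be > 0 K")
    return 1000.0 * (dH - dG) / temperature


def heat_capacity_demic(records) -> tuple[float, float]:
    """Heat capacity of demicellization from the temperature dependence of dH.

    ``records`` is an iterable of ``(temperature_K, dH_kJ_mol)`` pairs (or
    :class:`ThermoRecord`).  Returns the OLS slope converted to J/(mol K)
    together with its standard error.
    """
    pairs = [
        (r.temperature, r.dH_demic) if isinstance(r, ThermoRecord) else tuple(r)
        for r in records
    ]
    if len(pairs) < 3:
        raise ValidationError("need at least 3 (T, dH) points for dC_P")
    T = np.array([p[0] for p in pairs], dtype=float)
    H = np.array([p[1] for p in pairs], dtype=float)
    if np.unique(T).size < 2:
        raise ValidationError("temperatures must not all coincide")
    fit = stats.linregress(T, H)
    return 1000.0 * float(fit.slope), 1000.0 * float(fit.stderr)


def mole_fraction_from_cmc(
    cmc: float, water_molarity_mm: float = WATER_MOLARITY_MM
) -> float:
    """cmc (mM) expressed as a mole fraction, ``cmc / 55500`` by default."""
    if cmc < 0:
        raise ValidationError("cmc must be >= 0")
    return cmc / water_molarity_mm


def sodium_term_contribution(
    beta: float, n: float, sodium: float, temperature: float
) -> float:
    """Magnitude of the ``[Na+]^(beta*n)`` term in dG_demic, kJ/mol.

    ``|(R T / n) ln [Na+]^(beta*n)| = R T beta |ln [Na+]|`` — independent of
    ``n``, which cancels.
    """
    if not sodium > 0:
        raise ValidationError("sodium concentration must be > 0")
    if not 0.0 <= beta <= 1.0:
        raise ValidationError(f"beta must be within [0, 1], got {beta}")
    return R_GAS * temperature * beta * abs(math.log(sodium)) / 1000.0


def summarize(records) -> ThermoSummary:
    """Mean aggregation number (± sample sd) and dC_P over per-temperature records."""
    records = tuple(records)
    if len(records) < 2:
        raise ValidationError("need at least 2 records to summarize")
    ns = np.array([r.n for r in records], dtype=float)
    mean_n = float(np.mean(ns))
    sd_n = float(np.std(ns, ddof=1))
    try:
        dcp, se = heat_capacity_demic(records)
    except ValidationError:
        dcp, se = float("nan"), float("nan")
    return ThermoSummary(
        mean_n=mean_n, sd_n=sd_n, dCp_demic=dcp, dCp_stderr=se, records=records
    )


def build_record(
    temperature: float,
    cmc: float,
    n: float,
    dH_demic: float,
    K: float,
    sodium: float,
    beta: float,
    label: str = "",
    water_molarity_mm: float = WATER_MOLARITY_MM,
) -> ThermoRecord:
    """Assemble a full per-temperature record from fitted quantities.

    Computes ``K_mic``, then ``dG_demic`` and ``dS_demic``, so the
    Gibbs–Helmholtz relation holds exactly by construction.
    """
    km = k_mic(K, sodium, beta, n)
    dG = delta_g_demic(km, temperature, n)
    dS = delta_s_demic(dG, dH_demic, temperature)
    return ThermoRecord(
        temperature=temperature,
        cmc=cmc,
        x_cmc=mole_fraction_from_cmc(cmc, water_molarity_mm),
        n=n,
        dG_demic=dG,
        dH_demic=dH_demic,
        dS_demic=dS,
        label=label,
    )
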