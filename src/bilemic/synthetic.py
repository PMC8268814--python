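"""Seeded generators for every input the analysis pipeline consumes.

The original instrument data (enthalpograms, tensiometry curves,
Corrin–Harkins series) are not deposited anywhere, so these generators
replace the instruments: they run the exact forward models of the fitting
modules plus realistic noise, and carry their ground truth, which makes
every fitter testable by round trip.

Defaults mirror the experimental protocol: 2 µL injections of a 4 mM
micellar solution into a 200 µL cell (38 injections walks the cell from
zero through roughly three times the reference cmc of 0.45 mM), carbonate
buffer 50.60 mM at pH 10.35 ([Na+] = 0.0765 M), heat noise 1% of
|dH_demic|.  Noise on heats is Gaussian; noise on cmc-type (positive)
quantities is lognormal.

Every generator is a deterministic function of (seed, settings).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .itc import ITCInjectionSeries, model_heats
from .mass_action import MassActionParams, params_from_cmc
from .tensiometry import SurfaceTensionCurve

__all__ = [
    "SyntheticGroundTruth",
    "InjectionSchedule",
    "default_schedule",
    "default_truth",
    "gen_itc_experiment",
    "gen_surface_tension_curve",
    "gen_corrin_harkins_series",
    "gen_logp_cmc_dataset",
    "DEFAULT_SODIUM_SERIES",
]

#: [Na+] (M) of the three study buffers (50.6/150/700 mM total at pH 10.35).
DEFAULT_SODIUM_SERIES = (0.0765, 0.227, 1.058)


@dataclass(frozen=True)
class InjectionSchedule:
    """Injection protocol of a titration (volumes µL, concentration mM)."""

    syringe_conc: float = 4.0
    cell_volume: float = 200.0
    injection_volumes: tuple = field(
        default_factory=lambda: (2.0,) * 38
    )


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Ground truth of one simulated demicellization experiment."""

    params: MassActionParams
    dH_demic: float        # kJ/mol
    dH_dil: float          # kJ/mol
    beta: float
    sodium: float          # M
    cmc: float             # mM
    noise_sd: float        # kJ/mol, absolute
    seed: int


def default_schedule(
    n_injections: int = 38,
    injection_volume: float = 2.0,
    cell_volume: float = 200.0,
    syringe_conc: float = 4.0,
) -> InjectionSchedule:
    return InjectionSchedule(
        syringe_conc=syringe_conc,
        cell_volume=cell_volume,
        injection_volumes=(injection_volume,) * n_injections,
    )


def default_truth(
    n: float = 10.0,
    cmc: float = 0.45,
    dH_demic: float = -5.0,
    dH_dil: float = -0.2,
    beta: float = 0.63,
    sodium: float = 0.0765,
    noise_sd: float | None = None,
    seed: int = 0,
) -> SyntheticGroundTruth:
    """Reference study conditions; ``noise_sd=None`` means 1% of |dH_demic|."""
    if noise_sd is None:
        noise_sd = 0.01 * abs(dH_demic)
    return SyntheticGroundTruth(
        params=params_from_cmc(n, cmc),
        dH_demic=dH_demic,
        dH_dil=dH_dil,
        beta=beta,
        sodium=sodium,
        cmc=cmc,
        noise_sd=noise_sd,
        seed=seed,
    )


def gen_itc_experiment(
    truth: SyntheticGroundTruth,
    schedule: InjectionSchedule | None = None,
    temperature: float = 298.15,
    label: str = "synthetic",
) -> ITCInjectionSeries:
    """Simulate one enthalpogram from the mass-action forward model.

    Per-injection heat = dH_dil + dH_demic * (net monomer created per mole
    injected, with full dilution/displacement bookkeeping) + Gaussian noise.
    Warns if the schedule never carries the cell across the cmc.
    """
    if schedule is None:
        schedule = default_schedule()
    vols = np.asarray(schedule.injection_volumes, dtype=float)
    heats = model_heats(
        truth.params, truth.dH_demic, truth.dH_dil,
        vols, schedule.cell_volume, schedule.syringe_conc,
    )
    final_conc = schedule.syringe_conc * (
        1.0 - float(np.prod(1.0 - vols / schedule.cell_volume))
    )
    if final_conc < truth.cmc:
        warnings.warn(
            f"titration ends at {final_conc:.3g} mM, below the cmc "
            f"{truth.cmc:.3g} mM: no transition will be observed",
            stacklevel=2,
        )
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        heats = heats + rng.normal(0.0, truth.noise_sd, size=heats.size)
    return ITCInjectionSeries(
        syringe_conc=schedule.syringe_conc,
        cell_volume=schedule.cell_volume,
        injection_volumes=vols,
        heats=heats,
        temperature=temperature,
        label=label,
    )


def gen_surface_tension_curve(
    cmc: float = 0.4,
    pre_slope: float = -8.0,
    plateau: float = 53.4,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_points: int = 20,
    span: tuple[float, float] = (0.125, 8.0),
    post_slope: float = 0.0,
    temperature: float = 298.15,
) -> SurfaceTensionCurve:
    """Two-segment tensiometry curve, continuous at the break.

    ``gamma = plateau + pre_slope*(ln c - ln cmc)`` below the cmc and
    ``plateau + post_slope*(ln c - ln cmc)`` above (flat by default).
    ``span`` multiplies the cmc to give the concentration range; the cmc
    itself is always included as a sample so a noiseless curve breaks at an
    observed point.  Gaussian noise of ``noise_sd`` mN/m on gamma.
    """
    if not cmc > 0:
        raise ValidationError("cmc must be > 0")
    c = np.geomspace(span[0] * cmc, span[1] * cmc, n_points)
    c = np.unique(np.append(c, cmc))
    t = np.log(c / cmc)
    gamma = plateau + np.where(t <= 0, pre_slope * t, post_slope * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        gamma = gamma + rng.normal(0.0, noise_sd, size=gamma.size)
    return SurfaceTensionCurve(
        concentrations=c, gamma=gamma, temperature=temperature, label="synthetic"
    )


def gen_corrin_harkins_series(
    A: float,
    beta: float,
    sodium_values=DEFAULT_SODIUM_SERIES,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """(cmc mM, sodium M) pairs from log10 cmc = A - beta log10 [Na+],
    with multiplicative lognormal noise of log-sd ``noise_sd`` on cmc."""
    if not 0.0 <= beta <= 1.0:
        raise ValidationError(f"beta must be within [0, 1], got {beta}")
    sodium = np.asarray(sodium_values, dtype=float)
    cmc = 10.0 ** (A - beta * np.log10(sodium))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        cmc = cmc * np.exp(rng.normal(0.0, noise_sd, size=cmc.size))
    return list(zip(cmc.tolist(), sodium.tolist()))


def gen_logp_cmc_dataset(
    slope: float = -1.0,
    intercept: float = 2.79,
    n: int = 12,
    noise_sd: float = 0.15,
    seed: int = 0,
    cmc_range: tuple[float, float] = (0.1, 15.0),
):
    """(logP, cmc mM) pairs on a calibration line, cmc log-uniform over the
    span of the published compound set, Gaussian noise on log P."""
    if n < 3:
        raise ValidationError("need n >= 3 points")
    rng = np.random.default_rng(seed)
    cmc = np.exp(rng.uniform(np.log(cmc_range[0]), np.log(cmc_range[1]), size=n))
    logp = intercept + slope * np.log10(cmc)
    if noise_sd > 0:
        logp = logp + rng.normal(0.0, noise_sd, size=n)
    return list(zip(logp.tolist(), cmc.tolist()))
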