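"""Mass-action description of surfactant self-aggregation.

The monomer/micelle equilibrium ``n S <=> M_n`` with equilibrium constant
``K = [M_n]/[S]^n`` implies the mass balance

.. math::

    S_{tot} = [S] + n K [S]^n,

which links the free-monomer concentration ``[S]`` to the total surfactant
concentration ``S_tot``.  Working concentrations are millimolar throughout,
so ``K`` carries units of mM^(1-n).  The aggregation number ``n`` is a real
number: fits routinely return non-integer values such as 10.5.

This module is the exact forward model shared by the synthetic-data
generators and the titration fitters: the monomer concentration, its
analytic derivative

.. math::

    \\frac{d[S]}{dS_{tot}} = \\frac{1}{1 + n^2 K [S]^{n-1}},

and the mapping between ``(n, K)`` and the critical micelle concentration
(cmc).

cmc convention
--------------
The model itself never singles out one concentration as "the" cmc; an
operational criterion is required.  The default here is the *inflection
criterion*: the cmc is the total concentration at which the second
derivative ``d^2[S]/dS_tot^2`` is extremal, i.e. where the monomer-vs-total
curve bends most sharply.  This matches the calorimetric definition of the
cmc as the midpoint (steepest point) of the per-injection heat sigmoid.
For the mass-action model the criterion has a closed form: the inflection
sits at the free-monomer concentration ``s*`` satisfying

.. math::

    n^2 K (s^*)^{n-1} = \\frac{n-2}{2n-1},
    \\qquad cmc = s^* \\left(1 + \\frac{n-2}{n(2n-1)}\\right),

which is used directly (and makes ``params_from_cmc`` an exact inverse of
``cmc_from_params``).  The criterion degenerates (flattens) as ``n -> 2``,
which is reported as an error rather than silently clamped.  A mole-fraction
convention, ``K = x_cmc^{-n}``, is available via ``convention="mole_fraction"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .exceptions import ConvergenceError, ValidationError

__all__ = [
    "MassActionParams",
    "EquilibriumState",
    "monomer_concentration",
    "monomer_derivative",
    "equilibrium_state",
    "cmc_from_params",
    "params_from_cmc",
    "WATER_MOLARITY_MM",
]

#: Molar concentration of pure water, in mM, used for mole-fraction conversions.
WATER_MOLARITY_MM = 55_500.0

# Relative tolerance demanded of the mass-balance residual after the solve.
_BALANCE_RTOL = 1e-10


@dataclass(frozen=True)
class MassActionParams:
    """Parameters of the aggregation equilibrium ``n S <=> M_n``.

    Attributes
    ----------
    n : float
        Aggregation number (monomers per micelle), real-valued, >= 2.
    K : float
        Micellization equilibrium constant ``[M_n]/[S]^n`` in mM^(1-n).
    """

    n: float
    K: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.n) and self.n >= 2.0):
            raise ValidationError(f"aggregation number must be finite and >= 2, got {self.n}")
        if not (np.isfinite(self.K) and self.K > 0.0):
            raise ValidationError(f"equilibrium constant must be finite and > 0, got {self.K}")


@dataclass(frozen=True)
class EquilibriumState:
    """Solved equilibrium composition at one total concentration (mM)."""

    s_total: float
    s_monomer: float
    micellar_fraction: float
    ds_dstot: float


def _monomer_scalar(s_total: float, n: float, K: float) -> float:
    if s_total < 0:
        raise ValidationError(f"total concentration must be >= 0, got {s_total}")
    if s_total == 0.0:
        return 0.0
    log_nk = math.log(n) + math.log(K)
    log_stot = math.log(s_total)
    # Both s <= s_total and n K s^n <= s_total bound the root from above, so the
    # smaller of the two is a valid bracket end and keeps s^n from overflowing.
    log_hi_balance = (log_stot - log_nk) / n
    log_hi = min(log_stot, log_hi_balance)
    s_hi = math.exp(log_hi)

    def f(s: float) -> float:
        if s <= 0.0:
            return -s_total
        return s - s_total + math.exp(log_nk + n * math.log(s))

    try:
        root = brentq(f, 0.0, s_hi * (1.0 + 1e-12), xtol=1e-300, rtol=4 * np.finfo(float).eps)
    except (ValueError, OverflowError) as exc:  # pragma: no cover - pathological params
        raise ConvergenceError(
            f"monomer solve failed for n={n}, K={K}, s_total={s_total}: {exc}"
        ) from exc
    residual = abs(f(root))
    if not residual <= _BALANCE_RTOL * s_total:
        raise ConvergenceError(
            f"mass-balance residual {residual:.3e} exceeds {_BALANCE_RTOL:.0e} * s_total "
            f"for n={n}, K={K}, s_total={s_total}"
        )
    return root


def monomer_concentration(s_total, params: MassActionParams):
    """Free-monomer concentration ``[S]`` (mM) at total concentration ``s_total``.

    Solves the mass balance ``s + n K s^n = s_total`` by bracketed Brent
    iteration; the returned root satisfies the balance to a relative residual
    of 1e-10.  Accepts scalars or arrays.
    """
    arr = np.asarray(s_total, dtype=float)
    if arr.ndim == 0:
        return _monomer_scalar(float(arr), params.n, params.K)
    out = np.empty(arr.shape, dtype=float)
    for idx, val in np.ndenumerate(arr):
        out[idx] = _monomer_scalar(float(val), params.n, params.K)
    return out


def monomer_derivative(s_monomer, params: MassActionParams):
    """Analytic ``d[S]/dS_tot = 1/(1 + n^2 K s^(n-1))`` evaluated at ``s_monomer``.

    Always in (0, 1]; computed through the logistic function of
    ``-(ln(n^2 K) + (n-1) ln s)`` so that extreme ``n``/``K`` never overflow.
    """
    s = np.asarray(s_monomer, dtype=float)
    if np.any(s < 0):
        raise ValidationError("monomer concentration must be >= 0")
    n, K = params.n, params.K
    log_n2k = 2.0 * math.log(n) + math.log(K)
    with np.errstate(divide="ignore"):
        logw = log_n2k + (n - 1.0) * np.log(s)
    # s == 0 gives logw = -inf, i.e. derivative exactly 1 (monomers only).
    result = expit(-logw)
    return float(result) if result.ndim == 0 else result


def equilibrium_state(s_total: float, params: MassActionParams) -> EquilibriumState:
    """Solve the equilibrium and bundle monomer, micellar fraction and derivative."""
    s = monomer_concentration(s_total, params)
    frac = 0.0 if s_total == 0 else 1.0 - s / s_total
    return EquilibriumState(
        s_total=float(s_total),
        s_monomer=float(s),
        micellar_fraction=float(frac),
        ds_dstot=float(monomer_derivative(s, params)),
    )


def _inflection_w(n: float) -> float:
    # Value of n^2 K s^(n-1) at the inflection of [S] vs S_tot.
    return (n - 2.0) / (2.0 * n - 1.0)


def cmc_from_params(
    params: MassActionParams,
    convention: str = "inflection",
    water_molarity_mm: float = WATER_MOLARITY_MM,
) -> float:
    """Critical micelle concentration (mM) implied by ``(n, K)``.

    ``convention="inflection"`` (default) places the cmc at the extremum of
    ``d^2[S]/dS_tot^2``; ``convention="mole_fraction"`` inverts the
    mole-fraction convention ``K = x_cmc^(-n)``.
    """
    n, K = params.n, params.K
    if convention == "mole_fraction":
        return water_molarity_mm * math.exp(-math.log(K) / n)
    if convention != "inflection":
        raise ValidationError(f"unknown cmc convention {convention!r}")
    if n <= 2.0:
        raise ValidationError(
            "the inflection cmc criterion is flat for n <= 2; no unique cmc exists"
        )
    w = _inflection_w(n)
    log_s_star = (math.log(w) - 2.0 * math.log(n) - math.log(K)) / (n - 1.0)
    return math.exp(log_s_star) * (1.0 + w / n)


def params_from_cmc(
    n: float,
    cmc: float,
    convention: str = "inflection",
    water_molarity_mm: float = WATER_MOLARITY_MM,
) -> MassActionParams:
    """Equilibrium constant from aggregation number and cmc (exact inverse of
    :func:`cmc_from_params` under the same convention)."""
    if not (np.isfinite(cmc) and cmc > 0):
        raise ValidationError(f"cmc must be finite and > 0, got {cmc}")
    if convention == "mole_fraction":
        if n < 2.0:
            raise ValidationError(f"aggregation number must be >= 2, got {n}")
        K = math.exp(-n * math.log(cmc / water_molarity_mm))
        return MassActionParams(n=n, K=K)
    if convention != "inflection":
        raise ValidationError(f"unknown cmc convention {convention!r}")
    if n <= 2.0:
        raise ValidationError(
            "the inflection cmc criterion is flat for n <= 2; K is not identifiable from cmc"
        )
    w = _inflection_w(n)
    s_star = cmc / (1.0 + w / n)
    K = math.exp(math.log(w) - 2.0 * math.log(n) - (n - 1.0) * math.log(s_star))
    return MassActionParams(n=n, K=K)
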