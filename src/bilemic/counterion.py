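"""Corrin–Harkins counterion-binding analysis and buffer sodium speciation.

The cmc of an ionic surfactant falls with counterion concentration as

    log10(cmc) = A - beta * log10([Na+]),

where ``beta`` is the degree of counterion binding (fraction of counterions
condensed on the micelle surface).  ``beta`` is the negative slope of the
double-log plot; base-10 logs throughout.

The experiments use carbonate/bicarbonate buffers at pH 10.35, so the
sodium released per mole of buffer depends on the carbonate fraction:
bicarbonate contributes one Na+, carbonate two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import ValidationError

__all__ = [
    "CorrinHarkinsFit",
    "CorrinHarkinsRegression",
    "corrin_harkins_fit",
    "sodium_from_carbonate_buffer",
    "PKA2_CARBONATE",
]

#: Thermodynamic second dissociation constant of carbonic acid at 25 degC.
PKA2_CARBONATE = 10.33


@dataclass(frozen=True)
class CorrinHarkinsFit:
    """Fitted Corrin–Harkins line: intercept A (log10 mM), binding degree beta."""

    A: float
    beta: float
    r_squared: float
    physical: bool = True  # False flags beta outside [0, 1]; never clamped


class CorrinHarkinsRegression(BaseEstimator, RegressorMixin):
    """OLS of log10(cmc / mM) on log10([Na+] / M).

    ``fit(X, y)``: ``X`` is sodium in M (shape ``(m,)`` or ``(m, 1)``), ``y``
    is cmc in mM.  Fitted attributes: ``A_``, ``beta_``, ``r_squared_``,
    ``physical_``.  ``predict(X)`` returns cmc in mM.
    """

    def fit(self, X, y):
        sodium = np.asarray(X, dtype=float)
        if sodium.ndim == 2 and sodium.shape[1] == 1:
            sodium = sodium[:, 0]
        cmc = np.asarray(y, dtype=float)
        if sodium.shape != cmc.shape or sodium.ndim != 1:
            raise ValidationError("X and y must be matching 1-D arrays")
        if np.any(sodium <= 0) or np.any(cmc <= 0):
            raise ValidationError("sodium and cmc values must be > 0")
        if np.unique(sodium).size < 2:
            raise ValidationError("need at least 2 distinct sodium concentrations")
        lx = np.log10(sodium)
        ly = np.log10(cmc)
        fit = stats.linregress(lx, ly)
        self.A_ = float(fit.intercept)
        self.beta_ = float(-fit.slope)
        self.r_squared_ = float(fit.rvalue**2)
        self.physical_ = bool(0.0 <= self.beta_ <= 1.0)
        return self

    def predict(self, X):
        sodium = np.asarray(X, dtype=float)
        if sodium.ndim == 2 and sodium.shape[1] == 1:
            sodium = sodium[:, 0]
        return 10.0 ** (self.A_ - self.beta_ * np.log10(sodium))


def corrin_harkins_fit(points) -> CorrinHarkinsFit:
    """Fit the Corrin–Harkins line to ``(cmc_mM, sodium_M)`` pairs."""
    pts = list(points)
    cmc = np.array([p[0] for p in pts], dtype=float)
    sodium = np.array([p[1] for p in pts], dtype=float)
    est = CorrinHarkinsRegression().fit(sodium, cmc)
    return CorrinHarkinsFit(
        A=est.A_, beta=est.beta_, r_squared=est.r_squared_, physical=est.physical_
    )


def sodium_from_carbonate_buffer(
    total: float, pH: float, pKa2: float = PKA2_CARBONATE
) -> float:
    """Total sodium (M) delivered by a carbonate/bicarbonate buffer.

    ``total`` is the summed buffer concentration in mM.  With carbonate
    fraction ``f = 1/(1 + 10^(pKa2 - pH))`` (Henderson–Hasselbalch), each
    mole of buffer carries ``1 + f`` sodium ions.  Ionic-strength
    corrections are deliberately omitted.
    """
    if not total > 0:
        raise ValidationError("buffer concentration must be > 0")
    f = 1.0 / (1.0 + 10.0 ** (pKa2 - pH))
    return total * (1.0 + f) / 1000.0
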