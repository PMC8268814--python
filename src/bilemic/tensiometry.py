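"""cmc extraction from surface-tension curves by segmented-line fitting.

Below the cmc the surface tension of a surfactant solution falls roughly
linearly in ``ln c`` as the air/water interface populates; above the cmc
added surfactant goes into micelles and the curve flattens.  The cmc is the
breakpoint of a continuous two-segment linear model in ``(ln c, gamma)``:

    gamma(t) = g0 + b_pre * (t - tau)   for t <= tau
    gamma(t) = g0 + b_post * (t - tau)  for t >  tau,      t = ln(c / mM)

fitted by least squares over the breakpoint ``tau`` (grid over the interior
sample range, then bounded local refinement; ties broken toward the lower
concentration).  A two-segment fit that is not significantly better than a
single straight line (partial F-test) is rejected as "no breakpoint".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import NoBreakpointError, ValidationError

__all__ = [
    "SurfaceTensionCurve",
    "BreakpointFit",
    "SegmentedBreakpointRegression",
    "detect_cmc_breakpoint",
]


@dataclass
class SurfaceTensionCurve:
    """A gamma-vs-concentration curve (concentrations mM, gamma mN/m)."""

    concentrations: np.ndarray
    gamma: np.ndarray
    temperature: float = 298.15
    label: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.concentrations.shape != self.gamma.shape or self.concentrations.ndim != 1:
            raise ValidationError("concentrations and gamma must be matching 1-D arrays")
        if self.concentrations.size < 6:
            raise ValidationError("need at least 6 points on a surface-tension curve")
        if np.any(self.concentrations <= 0):
            raise ValidationError("concentrations must be strictly positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValidationError("concentrations must be strictly increasing")


class BreakpointFit(NamedTuple):
    cmc: float
    pre_slope: float
    post_slope: float
    rss: float
    p_value: float


def _segmented_rss(t: np.ndarray, g: np.ndarray, tau: float):
    """Least-squares fit of the continuous hinge model at fixed breakpoint."""
    design = np.column_stack(
        [np.ones_like(t), np.minimum(t - tau, 0.0), np.maximum(t - tau, 0.0)]
    )
    beta, _, _, _ = np.linalg.lstsq(design, g, rcond=None)
    resid = g - design @ beta
    return float(resid @ resid), beta


class SegmentedBreakpointRegression(BaseEstimator, RegressorMixin):
    """Continuous two-segment regression of gamma on ln(concentration).

    Parameters
    ----------
    min_side : int
        Minimum points required on each side of the breakpoint (default 3).
    alpha : float
        Significance level of the partial F-test against a single line.
    n_refine_grid : int
        Breakpoint candidates inserted between consecutive samples.

    Fitted attributes: ``cmc_`` (mM), ``breakpoint_`` (ln mM),
    ``pre_slope_``, ``post_slope_`` (mN/m per ln-unit), ``rss_``,
    ``p_value_``, ``slope_order_ok_``.
    """

    def __init__(self, min_side: int = 3, alpha: float = 0.05, n_refine_grid: int = 8):
        self.min_side = min_side
        self.alpha = alpha
        self.n_refine_grid = n_refine_grid

    def fit(self, X, y):
        c = np.asarray(X, dtype=float)
        if c.ndim == 2 and c.shape[1] == 1:
            c = c[:, 0]
        g = np.asarray(y, dtype=float)
        if c.shape != g.shape or c.ndim != 1:
            raise ValidationError("X and y must be matching 1-D arrays")
        if np.any(c <= 0):
            raise ValidationError("concentrations must be strictly positive")
        order = np.argsort(c)
        t = np.log(c[order])
        g = g[order]
        m = t.size
        if m < 2 * self.min_side:
            raise ValidationError(
                f"need at least {2 * self.min_side} points, got {m}"
            )

        # Single-line reference fit.
        line = stats.linregress(t, g)
        rss1 = float(np.sum((g - line.intercept - line.slope * t) ** 2))
        scale = float(np.ptp(g)) ** 2 + 1.0
        tol0 = 1e-16 * scale * m
        if rss1 <= tol0:
            raise NoBreakpointError(
                "surface-tension data lie on a single straight line; no cmc breakpoint"
            )

        # Candidate breakpoints: interior sample abscissae plus a uniform
        # in-fill of each admissible interval (left/right sides keep >= min_side).
        lo_idx, hi_idx = self.min_side - 1, m - self.min_side
        cands = [t[k] for k in range(lo_idx, hi_idx + 1)]
        for k in range(lo_idx, hi_idx):
            cands.extend(
                np.linspace(t[k], t[k + 1], self.n_refine_grid + 2)[1:-1]
            )
        cands = np.sort(np.asarray(cands))

        best_tau, best_rss, best_beta = None, np.inf, None
        for tau in cands:  # ascending: strict '<' breaks ties toward lower cmc
            rss, beta = _segmented_rss(t, g, tau)
            if rss < best_rss * (1.0 - 1e-12):
                best_tau, best_rss, best_beta = float(tau), rss, beta

        # Local refinement between the neighbouring samples of the best candidate.
        k = int(np.searchsorted(t, best_tau, side="right")) - 1
        k = min(max(k, lo_idx), hi_idx - 1) if hi_idx > lo_idx else lo_idx
        lo = t[max(k, lo_idx)]
        hi = t[min(k + 1, hi_idx)]
        if hi > lo:
            res = minimize_scalar(
                lambda tau: _segmented_rss(t, g, tau)[0],
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-12},
            )
            if res.fun < best_rss * (1.0 - 1e-12) or (
                res.fun <= best_rss and res.x < best_tau
            ):
                best_tau = float(res.x)
                best_rss, best_beta = _segmented_rss(t, g, best_tau)

        rss2 = best_rss
        # Partial F-test: 2 extra parameters (second slope and breakpoint).
        if rss2 <= tol0:
            p_value = 0.0
        else:
            df2 = m - 4
            if df2 <= 0:
                raise ValidationError("too few points for the breakpoint F-test")
            F = ((rss1 - rss2) / 2.0) / (rss2 / df2)
            p_value = float(stats.f.sf(max(F, 0.0), 2, df2))
            if p_value > self.alpha:
                raise NoBreakpointError(
                    f"two-segment fit not significantly better than a single line "
                    f"(F-test p = {p_value:.3g})"
                )

        self.breakpoint_ = best_tau
        self.cmc_ = float(np.exp(best_tau))
        self.intercept_ = float(best_beta[0])
        self.pre_slope_ = float(best_beta[1])
        self.post_slope_ = float(best_beta[2])
        self.rss_ = rss2
        self.p_value_ = p_value
        self.slope_order_ok_ = abs(self.post_slope_) < abs(self.pre_slope_)
        if not self.slope_order_ok_:
            warnings.warn(
                "post-cmc slope magnitude is not smaller than the pre-cmc slope; "
                "breakpoint orientation is atypical for a micellization curve",
                stacklevel=2,
            )
        return self

    def predict(self, X):
        c = np.asarray(X, dtype=float)
        if c.ndim == 2 and c.shape[1] == 1:
            c = c[:, 0]
        t = np.log(c)
        return (
            self.intercept_
            + self.pre_slope_ * np.minimum(t - self.breakpoint_, 0.0)
            + self.post_slope_ * np.maximum(t - self.breakpoint_, 0.0)
        )


def detect_cmc_breakpoint(curve: SurfaceTensionCurve, alpha: float = 0.05) -> BreakpointFit:
    """Breakpoint cmc (mM) and segment slopes for one surface-tension curve."""
    est = SegmentedBreakpointRegression(alpha=alpha).fit(
        curve.concentrations, curve.gamma
    )
    return BreakpointFit(
        cmc=est.cmc_,
        pre_slope=est.pre_slope_,
        post_slope=est.post_slope_,
        rss=est.rss_,
        p_value=est.p_value_,
    )
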