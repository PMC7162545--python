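"""Empirical dosage-scaling description of the Dorsal (Dl) nuclear gradient.

The Dl gradient along the dorsoventral (DV) axis of the early *Drosophila*
embryo is well described by a Gaussian peak centred at the ventral midline
plus a shallow linear tail and a basal offset:

    c(x) = alpha * [exp(-x^2 / (2 sigma^2)) + m*|x| + b]

where ``x`` is the relative DV coordinate (0 = ventral midline, 1 = dorsal
midline), ``alpha`` is proportional to maternal *dl* dosage, ``sigma`` is the
gradient width, ``m`` the (negative) tail slope and ``b`` the basal level.
In a pure dosage-scaling world, halving or doubling the *dl* dose simply
multiplies ``alpha`` by 0.5 or 2.

Gene-expression borders are modelled as concentration thresholds: a border
sits where ``c(x)`` crosses a threshold ``theta``.  The dosage sensitivity of
a border at ``x_g`` is the logarithmic derivative

    phi = (d ln x_g / d ln alpha) at fixed theta
        = -c(x_g) / (x_g * c'(x_g)),

obtained from the implicit-function theorem on ``c(x_g) = theta / alpha``
(``alpha`` cancels, so phi is dosage-independent).  Small phi means robust
borders; the dosage-scaling model turns out to be highly sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "EmpiricalGradientParams",
    "BoundaryPrediction",
    "SensitivityResult",
    "eval_gradient",
    "boundary_position",
    "sensitivity_coefficient",
    "min_sensitivity",
    "predict_domains",
]

_ROOT_TOL = 1e-9


class GradientParameterError(ValueError):
    """Raised for parameter values outside the model's domain."""


class SensitivitySingularityError(ZeroDivisionError):
    """Raised when the gradient slope vanishes at the evaluation point."""


@dataclass(frozen=True)
class EmpiricalGradientParams:
    """Parameters of the Gaussian-plus-tail gradient.

    alpha : dosage-proportional amplitude (1 = wildtype, 0.5 = 1x, 2 = 4x)
    sigma : gradient width in relative DV coordinate
    m     : tail slope (typically negative)
    b     : basal level at large |x|
    """

    alpha: float = 1.0
    sigma: float = 0.15
    m: float = -0.1
    b: float = 0.4

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise GradientParameterError(f"sigma must be > 0, got {self.sigma}")
        if self.alpha <= 0:
            raise GradientParameterError(f"alpha must be > 0, got {self.alpha}")
        if self.b < 0:
            raise GradientParameterError(f"b must be >= 0, got {self.b}")
        if 1 + self.m + self.b <= 0:
            raise GradientParameterError(
                "1 + m + b must be > 0 for a positive gradient on [0, 1]"
            )

    def with_alpha(self, alpha: float) -> "EmpiricalGradientParams":
        return replace(self, alpha=alpha)


@dataclass(frozen=True)
class BoundaryPrediction:
    """A threshold crossing of the gradient.

    x_g is NaN when the threshold is never reached (``expressed`` False).
    ``multiple`` flags non-monotone gradients with several crossings.
    """

    x_g: float
    theta: float
    expressed: bool
    multiple: bool = False


@dataclass(frozen=True)
class SensitivityResult:
    phi: float
    x_g: float


def eval_gradient(params: EmpiricalGradientParams, x) -> np.ndarray | float:
    """Evaluate c(x) = alpha * [exp(-x^2/2sigma^2) + m|x| + b].

    ``x`` may be a scalar or array in [-1, 1]; the gradient is symmetric
    about the ventral midline at x = 0.
    """
    xa = np.abs(np.asarray(x, dtype=float))
    val = params.alpha * (
        np.exp(-(xa**2) / (2.0 * params.sigma**2)) + params.m * xa + params.b
    )
    return float(val) if np.isscalar(x) or np.ndim(x) == 0 else val


def _gradient_slope(params: EmpiricalGradientParams, x: float) -> float:
    """dc/dx for x in (0, 1]."""
    g = np.exp(-(x**2) / (2.0 * params.sigma**2))
    return params.alpha * (-(x / params.sigma**2) * g + params.m)


def boundary_position(
    params: EmpiricalGradientParams, theta: float
) -> BoundaryPrediction:
    """Locate the border where c(x) = theta on [0, 1].

    For m <= 0 the gradient is strictly decreasing on (0, 1] so the crossing
    is unique.  Returns ``expressed=False`` (x_g = NaN) when theta exceeds
    the ventral maximum, and caps x_g at 1 when the gradient never falls
    below theta.  Non-monotone cases (m > 0) report the ventral-most
    crossing with ``multiple=True`` when several exist.
    """
    if theta <= 0:
        raise GradientParameterError(f"theta must be > 0, got {theta}")
    c0 = eval_gradient(params, 0.0)
    c1 = eval_gradient(params, 1.0)
    if theta > c0:
        return BoundaryPrediction(np.nan, theta, expressed=False)
    if params.m <= 0:
        if theta < c1:
            return BoundaryPrediction(1.0, theta, expressed=True)
        x = brentq(
            lambda t: eval_gradient(params, t) - theta, 0.0, 1.0, xtol=_ROOT_TOL
        )
        return BoundaryPrediction(float(x), theta, expressed=True)
    # m > 0: scan for sign changes, report the ventral-most.
    grid = np.linspace(0.0, 1.0, 2001)
    vals = eval_gradient(params, grid) - theta
    signs = np.sign(vals)
    idx = np.nonzero(signs[:-1] * signs[1:] < 0)[0]
    if idx.size == 0:
        x = 1.0 if vals[-1] >= 0 else np.nan
        return BoundaryPrediction(x, theta, expressed=not np.isnan(x))
    x = brentq(
        lambda t: eval_gradient(params, t) - theta,
        grid[idx[0]],
        grid[idx[0] + 1],
        xtol=_ROOT_TOL,
    )
    return BoundaryPrediction(float(x), theta, expressed=True, multiple=idx.size > 1)


def sensitivity_coefficient(
    params: EmpiricalGradientParams, x_g: float
) -> SensitivityResult:
    """Analytic dosage sensitivity phi = -c(x_g) / (x_g * c'(x_g)).

    Derived by implicit differentiation of c(x_g) = theta/alpha at fixed
    theta; independent of alpha.
    """
    if not 0 < x_g < 1:
        raise GradientParameterError(f"x_g must lie in (0, 1), got {x_g}")
    slope = _gradient_slope(params, x_g)
    if slope == 0:
        raise SensitivitySingularityError(f"c'(x) = 0 at x = {x_g}")
    phi = -eval_gradient(params, x_g) / (x_g * slope)
    return SensitivityResult(phi=float(phi), x_g=float(x_g))


def min_sensitivity(
    params: EmpiricalGradientParams, x_lo: float = 0.05, x_hi: float = 0.9
) -> SensitivityResult:
    """Minimum of phi over border positions in (x_lo, x_hi).

    Dense grid (step <= 1e-3) followed by bounded local refinement.
    """
    if not (0 < x_lo < x_hi < 1):
        raise GradientParameterError("require 0 < x_lo < x_hi < 1")
    n = max(int(np.ceil((x_hi - x_lo) / 1e-3)) + 1, 101)
    grid = np.linspace(x_lo, x_hi, n)
    g = np.exp(-(grid**2) / (2.0 * params.sigma**2))
    c = g + params.m * grid + params.b
    dc = -(grid / params.sigma**2) * g + params.m
    phi = -c / (grid * dc)
    i = int(np.argmin(phi))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, n - 1)]
    res = minimize_scalar(
        lambda t: sensitivity_coefficient(params, t).phi,
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return SensitivityResult(phi=float(res.fun), x_g=float(res.x))


def local_sensitivity_minima(
    params: EmpiricalGradientParams, x_lo: float = 0.05, x_hi: float = 0.9
) -> list[SensitivityResult]:
    """Interior local minima of phi on (x_lo, x_hi), ventral-most first.

    For low basal levels the sensitivity landscape also declines toward the
    dorsal midline, where the gradient itself vanishes and a "border" ceases
    to be meaningful; the biologically relevant minimum is the interior one
    on the Gaussian shoulder, which this function isolates (whereas
    :func:`min_sensitivity` reports the global range minimum).
    """
    if not (0 < x_lo < x_hi < 1):
        raise GradientParameterError("require 0 < x_lo < x_hi < 1")
    n = max(int(np.ceil((x_hi - x_lo) / 1e-3)) + 1, 101)
    grid = np.linspace(x_lo, x_hi, n)
    g = np.exp(-(grid**2) / (2.0 * params.sigma**2))
    c = g + params.m * grid + params.b
    dc = -(grid / params.sigma**2) * g + params.m
    phi = -c / (grid * dc)
    interior = np.nonzero((phi[1:-1] < phi[:-2]) & (phi[1:-1] < phi[2:]))[0] + 1
    out = []
    for i in interior:
        res = minimize_scalar(
            lambda t: sensitivity_coefficient(params, t).phi,
            bounds=(grid[i - 1], grid[i + 1]),
            method="bounded",
            options={"xatol": 1e-8},
        )
        out.append(SensitivityResult(phi=float(res.fun), x_g=float(res.x)))
    return out


def calibrate_threshold(
    params: EmpiricalGradientParams, x_border: float
) -> float:
    """Threshold theta such that the border sits at ``x_border``."""
    return float(eval_gradient(params, x_border))


def predict_domains(
    wt_params: EmpiricalGradientParams,
    wt_borders: Mapping[str, float],
    alphas: Sequence[float] = (0.5, 1.0, 2.0),
    repressed: Mapping[str, bool] | None = None,
) -> pd.DataFrame:
    """Predict border shifts under dosage change for threshold-calibrated genes.

    Thresholds are calibrated so each wildtype border reproduces exactly at
    alpha = 1, then the border is re-solved at each dosage multiplier.  For a
    gene marked ``repressed`` (e.g. *dpp*, expressed below threshold), the
    domain is dorsal of the crossing and "lost" means the whole axis is above
    threshold.

    Returns a tidy frame with columns gene, alpha, theta, x_border, expressed,
    saturated (border pinned at the dorsal midline), multiple.
    """
    repressed = repressed or {}
    rows = []
    for gene, x_wt in wt_borders.items():
        if not 0 < x_wt < 1:
            raise GradientParameterError(
                f"wildtype border for {gene!r} must lie in (0, 1), got {x_wt}"
            )
        theta = calibrate_threshold(wt_params, x_wt)
        for alpha in alphas:
            pred = boundary_position(wt_params.with_alpha(alpha), theta)
            if repressed.get(gene, False):
                # domain is [x_border, 1]; lost if gradient > theta everywhere
                expressed = not (pred.expressed and pred.x_g >= 1.0)
                x_border = 0.0 if not pred.expressed else pred.x_g
                saturated = not pred.expressed  # whole axis below threshold
            else:
                expressed = pred.expressed
                x_border = pred.x_g
                saturated = pred.expressed and pred.x_g >= 1.0
            rows.append(
                {
                    "gene": gene,
                    "alpha": alpha,
                    "theta": theta,
                    "x_border": x_border,
                    "expressed": expressed,
                    "saturated": saturated,
                    "multiple": pred.multiple,
                }
            )
    return pd.DataFrame(rows)
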