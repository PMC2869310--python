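"""Trade-off model of gene-expression fitness.

Fitness of a genotype is the benefit of expressing a gene minus a
Monod-type cost of mobilising limited cellular resources::

    C(X) = k * X / (1 - X / M)
    w(x) = B(x) - C(X0 * x),   with  x = X / X0

``X0`` is the expression level that maximises fitness.  The benefit
function is calibrated so that the optimal genotype has relative fitness
one and sits at a stationary point: ``w(1) = 1`` and ``w'(1) = 0``.

Because the cost is convex and diverges as expression approaches the
capacity ``M``, the calibrated fitness function is concave at the optimum
and its curvature grows in magnitude with ``X0``.  Three selection
coefficients follow from the calibrated model:

* :func:`sel_coeff_halving` -- cost of halving expression, the proxy for
  losing one copy of a duplicated gene (Taylor and exact variants);
* :func:`sel_coeff_pseudogene` -- cost of expressing a non-functional
  peptide at unchanged level (a lower bound);
* :func:`missense_fitness_loss` -- cost of an allele that erodes a
  fraction ``alpha`` of the benefit.

All three increase with ``X0`` at fixed cost parameters, which is the
model's central qualitative prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "CostParams",
    "BenefitFunction",
    "GeneModel",
    "SelectionCoefficients",
    "cost",
    "cost_derivative",
    "cost_second_derivative",
    "calibrate_benefit",
    "fitness",
    "curvature_at_optimum",
    "taylor_fitness",
    "sel_coeff_halving",
    "sel_coeff_pseudogene",
    "missense_fitness_loss",
    "selection_coefficients",
    "halving_selection",
    "pseudogene_selection",
    "fitness_curvature",
]


def _as_float(a):
    """Return a python float for 0-d results, the array otherwise."""
    a = np.asarray(a)
    return float(a) if a.ndim == 0 else a


@dataclass(frozen=True)
class CostParams:
    """Parameters of the expression cost ``C(X) = k*X / (1 - X/M)``.

    Parameters
    ----------
    k : float
        Scaling factor converting resource usage into a fitness cost.
    M : float
        Maximal expression capacity given the available cellular
        resources; the cost diverges as ``X -> M``.
    """

    k: float
    M: float

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"cost scaling k must be > 0, got {self.k}")
        if not self.M > 0:
            raise ValueError(f"expression capacity M must be > 0, got {self.M}")


def cost(X, params: CostParams):
    """Expression cost ``C(X) = k*X / (1 - X/M)``.

    Strictly increasing and convex on ``[0, M)``; raises for ``X >= M``
    (saturation of cellular resources) or negative ``X``.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("expression level X must be non-negative")
    if np.any(X >= params.M):
        raise ValueError(
            f"expression level at or above capacity M={params.M}: "
            "cellular resources saturated"
        )
    return _as_float(params.k * X / (1.0 - X / params.M))


def cost_derivative(X, params: CostParams):
    """First derivative ``C'(X) = k / (1 - X/M)^2``."""
    X = np.asarray(X, dtype=float)
    if np.any(X < 0) or np.any(X >= params.M):
        raise ValueError("X outside [0, M)")
    return _as_float(params.k / (1.0 - X / params.M) ** 2)


def cost_second_derivative(X, params: CostParams):
    """Second derivative ``C''(X) = 2k / (M * (1 - X/M)^3)``."""
    X = np.asarray(X, dtype=float)
    if np.any(X < 0) or np.any(X >= params.M):
        raise ValueError("X outside [0, M)")
    return _as_float(2.0 * params.k / (params.M * (1.0 - X / params.M) ** 3))


@dataclass(frozen=True)
class BenefitFunction:
    """Benefit of expression as a function of relative level ``x``.

    The default family is affine, ``B(x) = intercept + slope * x``, in
    which case ``curvature`` (``B''(1)``) is zero.  Any twice
    differentiable user benefit can be plugged in via ``fn`` provided its
    slope ``B'(1)`` and curvature ``B''(1)`` are supplied explicitly.
    """

    intercept: float
    slope: float
    curvature: float = 0.0
    family: str = "affine"
    fn: Optional[Callable] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("benefit must be increasing at x = 1 (slope > 0)")

    def __call__(self, x):
        if self.fn is not None:
            return self.fn(x)
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def calibrate_benefit(X0: float, params: CostParams, family: str = "affine") -> BenefitFunction:
    """Calibrate a benefit function for a gene with optimum ``X0``.

    The two calibration conditions are normalization, ``B(1) - C(X0) = 1``,
    and optimality, ``B'(1) = X0 * C'(X0)``.  For the affine family this
    fixes the slope ``b = X0*C'(X0)`` and intercept ``a = 1 + C(X0) - b``.
    """
    if not 0 < X0 < params.M:
        raise ValueError(f"X0 must lie in (0, M={params.M}), got {X0}")
    if family != "affine":
        raise ValueError(
            "only the affine family can be auto-calibrated; construct a "
            "BenefitFunction with fn/slope/curvature for custom benefits"
        )
    b = X0 * cost_derivative(X0, params)
    a = 1.0 + cost(X0, params) - b
    return BenefitFunction(intercept=a, slope=b, curvature=0.0, family="affine")


@dataclass(frozen=True)
class GeneModel:
    """One gene's model: optimum ``X0``, cost parameters and benefit."""

    X0: float
    cost: CostParams
    benefit: BenefitFunction

    def __post_init__(self) -> None:
        if not 0 < self.X0 < self.cost.M:
            raise ValueError(f"X0 must lie in (0, M={self.cost.M}), got {self.X0}")

    @classmethod
    def calibrated(cls, X0: float, k: float = 0.01, M: float = 100.0) -> "GeneModel":
        """Build a gene with an affine benefit calibrated at ``X0``."""
        params = CostParams(k=k, M=M)
        return cls(X0=X0, cost=params, benefit=calibrate_benefit(X0, params))


def fitness(x, gene: GeneModel):
    """Relative fitness ``w(x) = B(x) - C(X0 * x)``.

    ``w(1) = 1`` for a calibrated gene.  Defined for
    ``0 <= x < M/X0``; beyond that the cost diverges.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("relative expression x must be non-negative")
    return _as_float(gene.benefit(x) - cost(gene.X0 * x, gene.cost))


def curvature_at_optimum(gene: GeneModel) -> float:
    """Second derivative of fitness at the optimum:
    ``w''(1) = B''(1) - X0^2 * C''(X0)``.  Negative for any calibrated
    gene (the optimum is a maximum), with magnitude increasing in X0.
    """
    return float(
        gene.benefit.curvature
        - gene.X0**2 * cost_second_derivative(gene.X0, gene.cost)
    )


def taylor_fitness(x, gene: GeneModel):
    """Second-order expansion of fitness around the optimum:
    ``1 + w''(1)/2 * (x - 1)^2``."""
    x = np.asarray(x, dtype=float)
    return _as_float(1.0 + 0.5 * curvature_at_optimum(gene) * (x - 1.0) ** 2)


def sel_coeff_halving(gene: GeneModel, method: str = "taylor") -> float:
    """Selection coefficient against halving expression (loss of one of
    two copies of the gene).

    ``method="taylor"`` evaluates the quadratic expansion at x = 1/2,
    giving ``s = -w''(1)/8``; ``method="exact"`` returns ``1 - w(1/2)``.
    The Taylor form is the more accurate the smaller ``X0/M`` is.
    """
    if method == "taylor":
        return -curvature_at_optimum(gene) / 8.0
    if method == "exact":
        return float(1.0 - fitness(0.5, gene))
    raise ValueError(f"unknown method {method!r}; use 'taylor' or 'exact'")


def sel_coeff_pseudogene(gene: GeneModel) -> float:
    """Selection coefficient against expressing a non-functional peptide.

    A disabling mutation keeps the full expression cost while the benefit
    drops to its zero-function baseline; to first order the coefficient is
    ``B(1) - B(0) ~= B'(1) = X0 * C'(X0)``.  This is a *lower bound*: a
    dominant-negative peptide can cost more.
    """
    return float(gene.X0 * cost_derivative(gene.X0, gene.cost))


def missense_fitness_loss(alpha: float, gene: GeneModel) -> float:
    """Fitness loss of a missense allele eroding a fraction ``alpha`` of
    the benefit at unchanged expression: ``loss = alpha * B(1)`` with
    ``B(1) = 1 + C(X0)`` for a calibrated gene.  Increasing in ``X0``
    because highly expressed genes paid more for their benefit.
    """
    if not 0 <= alpha <= 1:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return float(alpha * (1.0 + cost(gene.X0, gene.cost)))


@dataclass(frozen=True)
class SelectionCoefficients:
    """Bundle of the derived coefficients for one gene."""

    s_halving_taylor: float
    s_halving_exact: float
    s_pseudogene: float
    missense_loss: Optional[float] = None
    pseudogene_is_lower_bound: bool = True


def selection_coefficients(gene: GeneModel, alpha: Optional[float] = None) -> SelectionCoefficients:
    """All selection coefficients for a calibrated gene at once."""
    return SelectionCoefficients(
        s_halving_taylor=sel_coeff_halving(gene, "taylor"),
        s_halving_exact=sel_coeff_halving(gene, "exact"),
        s_pseudogene=sel_coeff_pseudogene(gene),
        missense_loss=None if alpha is None else missense_fitness_loss(alpha, gene),
    )


# ---------------------------------------------------------------------------
# Vectorised forms over arrays of X0 (shared k, M), used by the simulator
# and the synthetic-data generator where building one GeneModel per gene
# would dominate the runtime.

def fitness_curvature(X0, k: float, M: float):
    """Vectorised ``w''(1)`` for affine-benefit genes."""
    params = CostParams(k=k, M=M)
    X0 = np.asarray(X0, dtype=float)
    return _as_float(-(X0**2) * cost_second_derivative(X0, params))


def halving_selection(X0, k: float, M: float, method: str = "exact"):
    """Vectorised selection coefficient against halving expression."""
    params = CostParams(k=k, M=M)
    X0 = np.asarray(X0, dtype=float)
    if np.any(X0 <= 0) or np.any(X0 >= M):
        raise ValueError("X0 must lie in (0, M)")
    if method == "taylor":
        return _as_float(-fitness_curvature(X0, k, M) / 8.0)
    if method == "exact":
        b = X0 * cost_derivative(X0, params)
        return _as_float(b / 2.0 - cost(X0, params) + cost(X0 / 2.0, params))
    raise ValueError(f"unknown method {method!r}; use 'taylor' or 'exact'")


def pseudogene_selection(X0, k: float, M: float):
    """Vectorised pseudogenization coefficient ``X0 * C'(X0)``."""
    params = CostParams(k=k, M=M)
    X0 = np.asarray(X0, dtype=float)
    return _as_float(X0 * cost_derivative(X0, params))
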