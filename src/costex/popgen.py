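"""Stochastic post-WGD gene loss driven by selection coefficients.

Each ohnologon starts with two copies.  Loss of the first copy fixes in
the population as a Poisson process whose rate is the neutral
loss-fixation rate ``lambda0`` scaled by the probability of fixation of a
deleterious allele relative to a neutral one (genic-selection diffusion
result).  Once one copy is lost the survivor carries the full dosage
constraint and is not lost again, so

    P(both copies survive to T) = exp(-2 * lambda0 * r(s) * T)

with ``r(s) = 4*Ne*s / (exp(4*Ne*s) - 1)`` and ``r(0) = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import GeneModel, sel_coeff_halving

__all__ = [
    "PopGenParams",
    "fixation_rate_ratio",
    "expected_retention",
    "draw_retention",
    "simulate_retention",
    "calibrate_loss_intensity",
]


@dataclass(frozen=True)
class PopGenParams:
    """Population-genetic parameters of the loss process.

    Ne
        Effective population size.
    lambda0
        Neutral per-copy loss-fixation rate (events per copy per time
        unit).
    T
        Time elapsed since the WGD, in the same time units.
    """

    Ne: float
    lambda0: float
    T: float

    def __post_init__(self) -> None:
        for name in ("Ne", "lambda0", "T"):
            if not getattr(self, name) >= 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.Ne > 0:
            raise ValueError("Ne must be strictly positive")


def fixation_rate_ratio(s, Ne: float):
    """Fixation probability of a deleterious loss allele relative to a
    neutral one: ``r(s) = 4*Ne*s / (exp(4*Ne*s) - 1)``, with ``r(0) = 1``.

    Strictly decreasing in ``s``; values in ``(0, 1]``.
    """
    s_in = np.asarray(s, dtype=float)
    if np.any(s_in < 0):
        raise ValueError("s must be >= 0 (advantageous loss is out of scope)")
    x = np.atleast_1d(4.0 * Ne * s_in)
    r = np.empty_like(x)
    small = x < 1e-8
    # series for x -> 0; the exact form is 0/0 at x = 0
    r[small] = 1.0 - x[small] / 2.0
    xl = x[~small]
    # x*exp(-x)/(1-exp(-x)) avoids overflow for large x
    r[~small] = xl * np.exp(-xl) / (-np.expm1(-xl))
    if s_in.ndim == 0:
        return float(r[0])
    return r


def expected_retention(s, params: PopGenParams, lambda_scale=1.0):
    """Probability that both copies of an ohnologon survive to time T.

    ``lambda_scale`` optionally multiplies the neutral rate per gene
    (e.g. functional-category loss-rate modifiers); scalar or array
    broadcastable against ``s``.
    """
    r = fixation_rate_ratio(s, params.Ne)
    p = np.exp(-2.0 * params.lambda0 * np.asarray(lambda_scale, dtype=float) * params.T * r)
    p = np.asarray(p)
    return float(p) if p.ndim == 0 else p


def draw_retention(s, params: PopGenParams, rng: np.random.Generator, lambda_scale=1.0):
    """Bernoulli retention outcomes at the closed-form probabilities.

    Returns ``(p_retained, retained)`` arrays of the same shape as ``s``.
    """
    s = np.atleast_1d(np.asarray(s, dtype=float))
    p = np.atleast_1d(expected_retention(s, params, lambda_scale))
    p = np.broadcast_to(p, s.shape)
    retained = rng.random(s.shape) < p
    return p, retained


def simulate_retention(
    genes: Sequence[GeneModel],
    params: PopGenParams,
    coeff_method: str = "exact",
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Draw one retention outcome per gene model.

    Returns a frame with columns ``ohnologon_id``, ``X0``, ``s``,
    ``p_retained`` and ``retained``; reproducible for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if len(genes) == 0:
        return pd.DataFrame(
            columns=["ohnologon_id", "X0", "s", "p_retained", "retained"]
        )
    s = np.array([sel_coeff_halving(g, coeff_method) for g in genes])
    p, retained = draw_retention(s, params, rng)
    return pd.DataFrame(
        {
            "ohnologon_id": [f"o{i:06d}" for i in range(len(genes))],
            "X0": [g.X0 for g in genes],
            "s": s,
            "p_retained": p,
            "retained": retained,
        }
    )


def calibrate_loss_intensity(
    s,
    Ne: float,
    target_retention: float = 0.5,
    lambda_scale=1.0,
) -> float:
    """Solve for the loss intensity ``lambda0*T`` at which the mean
    closed-form retention over the supplied coefficients equals
    ``target_retention``.

    The mean retention is strictly decreasing in the intensity, so a
    scalar root-find suffices.  Returns the product ``lambda0*T``.
    """
    if not 0 < target_retention < 1:
        raise ValueError("target_retention must lie in (0, 1)")
    s = np.asarray(s, dtype=float)
    r = fixation_rate_ratio(s, Ne) * np.asarray(lambda_scale, dtype=float)

    def mean_retention(log_lt: float) -> float:
        return float(np.mean(np.exp(-2.0 * np.exp(log_lt) * r))) - target_retention

    lo, hi = -30.0, 30.0
    if mean_retention(lo) < 0 or mean_retention(hi) > 0:
        raise ValueError("target retention unattainable for these coefficients")
    return float(np.exp(brentq(mean_retention, lo, hi, xtol=1e-12)))
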