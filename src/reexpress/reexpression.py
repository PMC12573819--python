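"""Re-expression of log-exposure regression coefficients, with CI propagation.

When a study regresses an outcome on :math:`\\log_b`-transformed exposure, its
slope :math:`\\hat\\beta_{\\log}` is in outcome units per unit of
:math:`\\log_b` exposure.  Pooling it with studies that used untransformed
exposure requires *re-expression*: multiplying by a factor that converts the
slope to outcome units per exposure unit.  The factor depends on where on the
exposure axis the linearisation is anchored, so several conventions coexist.
This module provides three standard geometries as configurable defaults
(write :math:`s = \\sigma_{\\log}\\,\\ln b`, :math:`g` = exposure median):

``RB``
    local derivative of :math:`\\beta\\,\\log_b x` at the geometric center:
    :math:`1/(g \\ln b)`.
``Dz``
    population least-squares slope of :math:`\\beta\\,\\log_b X` regressed on
    :math:`X` for lognormal :math:`X`:
    :math:`s^2 e^{-s^2/2} / (\\ln b \\cdot g \\cdot (e^{s^2}-1))`.
``Alt``
    derivative evaluated at the arithmetic mean :math:`g\\,e^{s^2/2}`:
    :math:`1/(\\ln b \\cdot g \\cdot e^{s^2/2})`.

All three reduce to the RB factor as :math:`\\sigma_{\\log} \\to 0`.  Custom
factors can be registered via :data:`FACTORS`.

Because a re-expressed coefficient is an estimate — a random variable, not a
constant — every re-expression here carries a 95% confidence interval, either
by multiplicative scaling of the normal-theory CI of the logged coefficient or
by parametric Monte Carlo propagation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from scipy import stats

from .study_data import Interval

__all__ = [
    "ReportedLoggedEstimate",
    "ReexpressedEstimate",
    "ci_from_se",
    "reexpression_factor",
    "reexpress",
    "FACTORS",
]

Method = Literal["RB", "Dz", "Alt"]


@dataclass(frozen=True)
class ReportedLoggedEstimate:
    """A regression coefficient reported per unit of log_b exposure.

    Parameters
    ----------
    beta_log
        Slope in outcome units per unit of :math:`\\log_b` exposure.
    se_log
        Standard error of ``beta_log`` (same units), nonnegative.
    log_base
        The logarithm base ``b`` used by the study (> 1); 10 is common in
        environmental epidemiology.
    geo_median
        Median (geometric center) of the exposure distribution, in exposure
        units.
    sigma_log
        SD of the :math:`\\log_b`-transformed exposure (dimensionless in
        log-base units).
    sigma_log_se
        Optional standard error of ``sigma_log``, used only by parametric-MC
        propagation; default 0 treats the exposure spread as known.
    """

    beta_log: float
    se_log: float
    log_base: float
    geo_median: float
    sigma_log: float
    sigma_log_se: float = 0.0

    def __post_init__(self) -> None:
        if not self.log_base > 1:
            raise ValueError(f"log_base must exceed 1, got {self.log_base}")
        if not self.geo_median > 0:
            raise ValueError(f"geo_median must be positive, got {self.geo_median}")
        if not self.sigma_log > 0:
            raise ValueError(f"sigma_log must be positive, got {self.sigma_log}")
        if self.se_log < 0 or self.sigma_log_se < 0:
            raise ValueError("standard errors must be nonnegative")

    def sigma_natural(self) -> float:
        """SD of the natural-log exposure, s = sigma_log * ln(b)."""
        return self.sigma_log * math.log(self.log_base)


@dataclass(frozen=True)
class ReexpressedEstimate:
    """A coefficient converted to the untransformed-exposure scale."""

    method: str
    beta: float
    ci: Interval
    factor: float
    n_rejected_draws: int = 0


def ci_from_se(estimate: float, se: float, level: float = 0.95) -> Interval:
    """Two-sided normal-theory confidence interval ``estimate ± z * se``.

    The standard normal quantile is used (not t), since reported estimates
    arrive without degrees of freedom.
    """
    if se < 0:
        raise ValueError(f"standard error must be nonnegative, got {se}")
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    z = stats.norm.ppf(1 - (1 - level) / 2)
    return Interval(estimate - z * se, estimate + z * se)


def _factor_rb(ctx: ReportedLoggedEstimate) -> float:
    return 1.0 / (ctx.geo_median * math.log(ctx.log_base))


def _factor_dz(ctx: ReportedLoggedEstimate) -> float:
    s2 = ctx.sigma_natural() ** 2
    return (s2 * math.exp(-s2 / 2)) / (
        math.log(ctx.log_base) * ctx.geo_median * math.expm1(s2)
    )


def _factor_alt(ctx: ReportedLoggedEstimate) -> float:
    s2 = ctx.sigma_natural() ** 2
    return 1.0 / (math.log(ctx.log_base) * ctx.geo_median * math.exp(s2 / 2))


#: Registry of re-expression factors; users may register their own
#: ``name -> f(ReportedLoggedEstimate) -> float``.
FACTORS: dict[str, Callable[[ReportedLoggedEstimate], float]] = {
    "RB": _factor_rb,
    "Dz": _factor_dz,
    "Alt": _factor_alt,
}


def reexpression_factor(method: str, context: ReportedLoggedEstimate) -> float:
    """Multiplier converting ``beta_log`` to the untransformed-exposure scale."""
    try:
        f = FACTORS[method]
    except KeyError:
        raise KeyError(
            f"unknown re-expression method {method!r}; "
            f"registered: {sorted(FACTORS)}"
        ) from None
    return f(context)


def reexpress(
    estimate: ReportedLoggedEstimate,
    method: str,
    propagation: Literal["multiplicative", "parametric-mc"] = "multiplicative",
    n_draws: int = 10_000,
    seed: int = 1,
    level: float = 0.95,
) -> ReexpressedEstimate:
    """Convert a logged-exposure coefficient to the untransformed scale with a CI.

    ``multiplicative`` scales the normal-theory CI of ``beta_log`` by the
    factor (exact when the factor is treated as known; the interval is
    reordered so lower <= upper).  ``parametric-mc`` draws
    ``(beta_log*, sigma_log*)`` independently from normal sampling
    distributions centered at the reported values, recomputes
    ``factor * beta_log*`` per draw, and takes empirical
    ``(alpha/2, 1-alpha/2)`` quantiles — this admits the asymmetric intervals
    seen in published re-expressed columns.  Draws with ``sigma_log* <= 0``
    are rejected and redrawn; the count is recorded on the result.
    """
    factor = reexpression_factor(method, estimate)
    beta = factor * estimate.beta_log
    if factor == 0.0:
        warnings.warn(
            f"re-expression factor for {method!r} is exactly 0; "
            "returning the degenerate interval (0, 0)",
            stacklevel=2,
        )
        return ReexpressedEstimate(method, 0.0, Interval(0.0, 0.0), 0.0)

    if propagation == "multiplicative":
        ci = ci_from_se(estimate.beta_log, estimate.se_log, level).scaled(factor)
        return ReexpressedEstimate(method, beta, ci, factor)

    if propagation != "parametric-mc":
        raise ValueError(f"unknown propagation mode {propagation!r}")
    if n_draws < 100:
        raise ValueError(f"parametric-mc requires n_draws >= 100, got {n_draws}")

    rng = np.random.default_rng(seed)
    beta_draws = rng.normal(estimate.beta_log, estimate.se_log, size=n_draws)
    if estimate.sigma_log_se > 0:
        sigma_draws = rng.normal(estimate.sigma_log, estimate.sigma_log_se, n_draws)
        n_rejected = 0
        bad = sigma_draws <= 0
        while bad.any():
            n_rejected += int(bad.sum())
            sigma_draws[bad] = rng.normal(
                estimate.sigma_log, estimate.sigma_log_se, int(bad.sum())
            )
            bad = sigma_draws <= 0
    else:
        sigma_draws = np.full(n_draws, estimate.sigma_log)
        n_rejected = 0

    factor_fn = FACTORS[method]
    if estimate.sigma_log_se == 0:
        # factor does not vary across draws
        reexpressed = factor * beta_draws
    else:
        reexpressed = np.empty(n_draws)
        for i in range(n_draws):
            ctx = ReportedLoggedEstimate(
                beta_log=beta_draws[i],
                se_log=estimate.se_log,
                log_base=estimate.log_base,
                geo_median=estimate.geo_median,
                sigma_log=float(sigma_draws[i]),
            )
            reexpressed[i] = factor_fn(ctx) * beta_draws[i]
    alpha = 1 - level
    lo, hi = np.percentile(reexpressed, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return ReexpressedEstimate(method, beta, Interval(float(lo), float(hi)), factor,
                               n_rejected_draws=n_rejected)
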