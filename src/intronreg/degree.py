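"""Exponential and hypo-exponential models of regulatory in-degree.

The number of TFs bound per regulatory region (the region's in-degree) is
modeled with a continuous exponential density f(x) = lambda * exp(-lambda*x),
whose maximum-likelihood rate is lambda = n / sum(x) (1/lambda is the mean
number of interactions).  When a gene's promoter and first-intron
in-degrees are summed, the sum of independent exponentials with distinct
rates follows a hypo-exponential distribution; for two rates

    f(x) = l1*l2/(l2 - l1) * (exp(-l1*x) - exp(-l2*x)),

and in general the density is a signed mixture of the component
exponentials with weights prod_{j != i} l_j / (l_j - l_i).  Equal rates are
dispatched to the Erlang (gamma) closed form, where the distinct-rate
formula is numerically unstable.

Counts are integers but are modeled with the continuous densities
throughout; when comparing model likelihoods, zero counts are evaluated at
half a count (0.5) so the hypo-exponential density, which vanishes at 0,
stays finite — the comparison applies the same evaluation points to both
models.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

_EQUAL_RATE_RTOL = 1e-9


@dataclass
class DegreeFit:
    """Fitted rate(s): one rate = exponential, several = hypo-exponential."""

    rates: list[float]
    n: int
    log_likelihood: float

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.rates):
            raise ValueError("all rates must be positive")

    @property
    def mean(self) -> float:
        return sum(1.0 / r for r in self.rates)


def exponential_rate_from_totals(n_regions: int, total_interactions: float) -> float:
    """MLE rate from a screen's printed totals: lambda = n / sum(x)."""
    if n_regions <= 0 or total_interactions <= 0:
        raise ValueError("need positive region count and interaction total")
    return n_regions / total_interactions


def fit_exponential(values: Sequence[float]) -> DegreeFit:
    """Exponential MLE: lambda = n / sum(x); zeros are retained."""
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        raise ValueError("empty sample")
    if np.any(x < 0):
        raise ValueError("in-degrees must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero sample: exponential rate undefined")
    lam = len(x) / total
    loglik = len(x) * math.log(lam) - lam * total
    return DegreeFit(rates=[lam], n=len(x), log_likelihood=float(loglik))


def _split_rates(rates: Sequence[float]) -> str:
    """Dispatch: 'distinct', 'erlang' (all equal), or error for mixtures."""
    r = np.asarray(rates, dtype=float)
    if len(r) == 0 or np.any(r <= 0):
        raise ValueError("rates must be a non-empty positive list")
    if len(r) == 1:
        return "single"
    close = np.isclose(r[:, None], r[None, :], rtol=_EQUAL_RATE_RTOL)
    np.fill_diagonal(close, False)
    if not close.any():
        return "distinct"
    if close.all() or np.allclose(r, r[0], rtol=_EQUAL_RATE_RTOL):
        return "erlang"
    raise ValueError(
        "rates with a mix of equal and distinct values are not supported; "
        "perturb or merge the near-equal rates"
    )


def _mixture_weights(rates: np.ndarray) -> np.ndarray:
    """w_i = prod_{j != i} l_j / (l_j - l_i) for distinct rates."""
    k = len(rates)
    w = np.empty(k)
    for i in range(k):
        others = np.delete(rates, i)
        w[i] = np.prod(others / (others - rates[i]))
    return w


def hypoexp_density(x, rates: Sequence[float]) -> np.ndarray | float:
    """Hypo-exponential density of the sum of independent exponentials.

    A single rate reduces exactly to the exponential density; equal rates
    use the Erlang closed form.  Negative x has density 0.
    """
    kind = _split_rates(rates)
    xa = np.asarray(x, dtype=float)
    r = np.asarray(rates, dtype=float)
    if kind == "single":
        out = stats.expon.pdf(xa, scale=1.0 / r[0])
    elif kind == "erlang":
        out = stats.gamma.pdf(xa, a=len(r), scale=1.0 / r[0])
    else:
        w = _mixture_weights(r)
        flat = np.atleast_1d(xa)
        vals = (w[:, None] * r[:, None] * np.exp(-np.outer(r, np.clip(flat, 0, None)))
                ).sum(axis=0)
        vals = np.where(flat < 0, 0.0, np.maximum(vals, 0.0))  # round-off guard
        out = vals if xa.shape else vals[0]
    if np.isscalar(x) or xa.shape == ():
        return float(out)
    return out


def hypoexp_cdf(x, rates: Sequence[float]) -> np.ndarray | float:
    """CDF companion of :func:`hypoexp_density` (same dispatch)."""
    kind = _split_rates(rates)
    xa = np.asarray(x, dtype=float)
    r = np.asarray(rates, dtype=float)
    if kind == "single":
        out = stats.expon.cdf(xa, scale=1.0 / r[0])
    elif kind == "erlang":
        out = stats.gamma.cdf(xa, a=len(r), scale=1.0 / r[0])
    else:
        w = _mixture_weights(r)
        xc = np.clip(np.atleast_1d(xa), 0, None)
        out = 1.0 - (w[:, None] * np.exp(-r[:, None] * xc[None, :])).sum(axis=0)
        out = np.clip(out, 0.0, 1.0)
        out = np.where(np.atleast_1d(xa) < 0, 0.0, out)
        if xa.shape == ():
            out = out[0]
    if np.isscalar(x) or xa.shape == ():
        return float(out)
    return out


def hypoexp_mean(rates: Sequence[float]) -> float:
    return sum(1.0 / r for r in rates)


def _floored(x: np.ndarray) -> np.ndarray:
    """Zeros evaluated at half a count; positive values untouched."""
    return np.where(x <= 0, 0.5, x)


@dataclass
class ModelComparison:
    lambda_promoter: float
    lambda_intron: float
    lambda_combined: float  # single exponential fitted to the sums
    loglik_hypoexp: float
    loglik_exponential: float
    ks_hypoexp: float
    ks_exponential: float
    n: int
    failure: str | None = None

    @property
    def hypoexp_preferred(self) -> bool:
        return self.loglik_hypoexp > self.loglik_exponential

    def to_dict(self) -> dict:
        return {
            "lambda_promoter": self.lambda_promoter,
            "lambda_intron": self.lambda_intron,
            "lambda_combined": self.lambda_combined,
            "loglik_hypoexp": self.loglik_hypoexp,
            "loglik_exponential": self.loglik_exponential,
            "ks_hypoexp": self.ks_hypoexp,
            "ks_exponential": self.ks_exponential,
            "n": self.n,
            "hypoexp_preferred": self.hypoexp_preferred,
            "failure": self.failure,
        }


def compare_degree_models(
    promoter_sample: Sequence[float],
    intron_sample: Sequence[float],
    combined_sample: Sequence[float] | None = None,
) -> ModelComparison:
    """Does the per-gene (promoter + first intron) in-degree follow the
    hypo-exponential predicted from the per-region exponential fits, or a
    single exponential fitted directly to the sums?

    Fits lambda_P and lambda_I by MLE on the region samples, evaluates the
    combined sample's log-likelihood under (a) the parameter-free
    hypo-exponential prediction Hypo(lambda_P, lambda_I) and (b) a directly
    fitted exponential, and reports a Kolmogorov-Smirnov distance for each.
    ``combined_sample`` defaults to the per-gene sums of the two aligned
    region samples.
    """
    prom = np.asarray(promoter_sample, dtype=float)
    intr = np.asarray(intron_sample, dtype=float)
    if combined_sample is None:
        if len(prom) != len(intr):
            raise ValueError("region samples must align per gene to form sums")
        combined = prom + intr
    else:
        combined = np.asarray(combined_sample, dtype=float)
    try:
        fit_p = fit_exponential(prom)
        fit_i = fit_exponential(intr)
        fit_c = fit_exponential(combined)
    except ValueError as exc:
        logger.warning("degenerate in-degree sample: %s", exc)
        return ModelComparison(
            lambda_promoter=math.nan, lambda_intron=math.nan,
            lambda_combined=math.nan, loglik_hypoexp=math.nan,
            loglik_exponential=math.nan, ks_hypoexp=math.nan,
            ks_exponential=math.nan, n=len(combined), failure=str(exc),
        )
    lam_p, lam_i, lam_c = fit_p.rates[0], fit_i.rates[0], fit_c.rates[0]
    rates = [lam_p, lam_i]
    x_eval = _floored(combined)
    ll_hypo = float(np.log(np.asarray(hypoexp_density(x_eval, rates))).sum())
    ll_exp = float(
        np.log(stats.expon.pdf(x_eval, scale=1.0 / lam_c)).sum()
    )
    ks_hypo = float(stats.kstest(combined, lambda t: hypoexp_cdf(t, rates)).statistic)
    ks_exp = float(stats.kstest(combined, "expon", args=(0, 1.0 / lam_c)).statistic)
    return ModelComparison(
        lambda_promoter=lam_p, lambda_intron=lam_i, lambda_combined=lam_c,
        loglik_hypoexp=ll_hypo, loglik_exponential=ll_exp,
        ks_hypoexp=ks_hypo, ks_exponential=ks_exp, n=len(combined),
    )
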