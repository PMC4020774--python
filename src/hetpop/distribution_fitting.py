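"""Candidate distributions, maximum-likelihood fitting and histogram SSE.

Three two-parameter families (Weibull, gamma, lognormal) plus a Gaussian
comparison baseline. Parameters are estimated by MLE on the raw, unbinned
values; the sum of squared errors against a density-normalized histogram is
used only for model selection and bin-number optimization, so the fitted
parameters never depend on the bin count.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from hetpop.synthetic_populations import ReceptorSample

logger = logging.getLogger(__name__)

FIT_FAMILIES = ("weibull", "gamma", "lognormal", "gaussian")
#: families competing for best fit; the Gaussian is a baseline only
SELECTABLE_FAMILIES = ("weibull", "gamma", "lognormal")


class FitError(RuntimeError):
    """Raised when a sample cannot be fitted to a requested family."""


class SupportError(FitError):
    """Raised when sample values violate the family's support (x > 0)."""


@dataclass
class DistributionFit:
    """A fitted two-parameter distribution.

    ``params`` is (shape a, scale b) for weibull/gamma and (mu, sigma) for
    lognormal (of log-counts) and gaussian (of counts).
    """

    family: str
    params: tuple[float, float]
    loglik: float
    sse: float | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        if self.family not in FIT_FAMILIES:
            raise FitError(f"unknown family {self.family!r}")
        a, b = self.params
        if self.family in ("weibull", "gamma") and (a <= 0 or b <= 0):
            raise FitError("shape and scale must be > 0")
        if self.family in ("lognormal", "gaussian") and b <= 0:
            raise FitError("sigma must be > 0")
        if not np.isfinite(self.loglik):
            raise FitError("log-likelihood must be finite")

    def frozen(self):
        """The corresponding scipy frozen distribution."""
        return _frozen(self.family, self.params)

    def to_json(self, **extra) -> str:
        rec = {
            "family": self.family,
            "params": list(self.params),
            "loglik": self.loglik,
            "sse": self.sse,
            "converged": self.converged,
        }
        rec.update(extra)
        return json.dumps(rec)


@dataclass
class Histogram:
    """Equal-width histogram: ``k+1`` edges, ``k`` centers and counts."""

    edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.edges.ndim != 1 or self.edges.size < 3:
            raise ValueError("need at least 2 bins (3 edges)")
        if self.counts.size != self.edges.size - 1:
            raise ValueError("counts must have one entry per bin")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly ascending")
        widths = np.diff(self.edges)
        if np.any(np.abs(widths - widths[0]) > 1e-9 * widths[0]):
            raise ValueError("bins must be equal width")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def k(self) -> int:
        return int(self.counts.size)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def densities(self) -> np.ndarray:
        """Bin heights normalized to integrate to 1: n_i / (N * w)."""
        return self.counts / (self.total * self.width)


def _frozen(family: str, params: tuple[float, float]):
    a, b = params
    if family == "weibull":
        return stats.weibull_min(c=a, scale=b)
    if family == "gamma":
        return stats.gamma(a=a, scale=b)
    if family == "lognormal":
        return stats.lognorm(s=b, scale=np.exp(a))
    if family == "gaussian":
        return stats.norm(loc=a, scale=b)
    raise FitError(f"unknown family {family!r}")


def eval_pdf(family: str, params: tuple[float, float], x) -> np.ndarray | float:
    """Probability density of ``family`` at ``x`` (receptors/cell).

    Outside the support (x <= 0 for weibull/gamma/lognormal) the density
    is 0, not an error.
    """
    scalar = np.isscalar(x)
    x = np.asarray(x, dtype=float)
    dist = _frozen(family, params)
    with np.errstate(divide="ignore", invalid="ignore"):
        pdf = dist.pdf(x)
    pdf = np.where(np.isfinite(pdf), pdf, 0.0)
    if family != "gaussian":
        pdf = np.where(x > 0, pdf, 0.0)
    return float(pdf) if scalar else pdf


def _check_support(values: np.ndarray, family: str) -> None:
    if family == "gaussian":
        return
    n_bad = int((values <= 0).sum())
    if n_bad:
        raise SupportError(
            f"{family} requires strictly positive values; "
            f"{n_bad} nonpositive value(s) present"
        )


def fit_mle(sample: "ReceptorSample | np.ndarray", family: str) -> DistributionFit:
    """Maximum-likelihood fit of ``family`` to raw (unbinned) values.

    Lognormal and gaussian have closed-form MLEs; weibull and gamma use
    scipy's numerical MLE with the location pinned at 0, retried from
    moment-based starting points on failure.
    """
    values = np.asarray(getattr(sample, "values", sample), dtype=float)
    if values.size < 10:
        raise FitError(f"need at least 10 values to fit, got {values.size}")
    _check_support(values, family)
    if np.ptp(values) == 0:
        raise FitError("degenerate sample: all values are equal")

    converged = True
    if family == "lognormal":
        logs = np.log(values)
        mu, sigma = float(logs.mean()), float(logs.std(ddof=0))
        params = (mu, sigma)
    elif family == "gaussian":
        params = (float(values.mean()), float(values.std(ddof=0)))
    else:
        dist = stats.weibull_min if family == "weibull" else stats.gamma
        # deterministic restart ladder: scipy default, moment-matched, unit shape
        mean, var = float(values.mean()), float(values.var())
        if family == "gamma":
            a_mom = mean**2 / var if var > 0 else 1.0
            starts = [None, (a_mom, mean / a_mom), (1.0, mean)]
        else:
            starts = [None, (1.5, mean), (1.0, mean)]
        params = None
        for start in starts:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    if start is None:
                        a, _, b = dist.fit(values, floc=0)
                    else:
                        a, _, b = dist.fit(values, start[0], floc=0, scale=start[1])
                if a > 0 and b > 0 and np.isfinite(a) and np.isfinite(b):
                    params = (float(a), float(b))
                    break
            except Exception:  # noqa: BLE001 - retried from the next start
                continue
        if params is None:
            raise FitError(f"MLE for {family} failed from all starting points")

    loglik = float(np.sum(np.log(np.maximum(eval_pdf(family, params, values), 1e-300))))
    return DistributionFit(family, params, loglik, converged=converged)


def compute_sse(hist: Histogram, fit: DistributionFit) -> float:
    """Sum of squared errors between histogram and fitted pdf at bin centers.

    SSE = sum_i (d_i - f(c_i))^2 with d_i = n_i / (N * w), so observed and
    expected are both densities and the SSE is comparable across bin counts.
    """
    if hist.total == 0:
        raise ValueError("empty histogram")
    resid = hist.densities() - eval_pdf(fit.family, fit.params, hist.centers)
    return float(np.sum(resid**2))


def select_best_family(
    sample: "ReceptorSample | np.ndarray",
    k: int,
    families: tuple[str, ...] = SELECTABLE_FAMILIES,
) -> tuple[str, dict[str, DistributionFit]]:
    """Pick the family with the lowest SSE on a ``k``-bin histogram.

    The Gaussian baseline never competes. Families whose support the data
    violate or whose optimizer fails are skipped with a warning; if all are
    skipped a FitError is raised. Returns ``(family, fits)`` with each
    candidate's fit (its ``sse`` attribute filled in).
    """
    from hetpop.low_bin_search import build_histogram  # local: avoid cycle

    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    hist = build_histogram(sample, k)
    fits: dict[str, DistributionFit] = {}
    for family in families:
        try:
            fit = fit_mle(sample, family)
        except FitError as exc:
            logger.warning("skipping %s: %s", family, exc)
            continue
        fit.sse = compute_sse(hist, fit)
        fits[family] = fit
    if not fits:
        raise FitError("no candidate family could be fitted")
    best = min(fits, key=lambda f: fits[f].sse)
    return best, fits
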