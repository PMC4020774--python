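"""Representative parameters and Gaussian mixture decomposition.

The four representative parameters (geometric mean, arithmetic mean, mode,
median) are computed on raw outlier-cleaned values, never on binned data.
Multimodal tumor populations are decomposed with a 1-D Gaussian mixture
fitted by EM (10 seeded k-means initializations, monotone log-likelihood),
components ordered by descending weight ("Density 1" = highest weight), and
summarized by density-weighted sums of per-component statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hetpop.synthetic_populations import ReceptorSample

_LOG_2PI = float(np.log(2.0 * np.pi))


class MixtureError(RuntimeError):
    """Raised when EM fails to converge or components collapse."""


@dataclass(frozen=True)
class RepresentativeStats:
    """Single-value condensations of a receptor population (receptors/cell)."""

    geometric_mean: float
    arithmetic_mean: float
    mode: float
    median: float

    def as_dict(self) -> dict[str, float]:
        return {
            "geometric_mean": self.geometric_mean,
            "arithmetic_mean": self.arithmetic_mean,
            "mode": self.mode,
            "median": self.median,
        }


@dataclass
class MixtureFit:
    """Tri-modal Gaussian mixture, components sorted by descending weight."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    converged: bool
    assignments: np.ndarray  # hard labels by maximum posterior responsibility
    n_iter: int

    @property
    def m(self) -> int:
        return int(self.weights.size)

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


@dataclass
class MixtureSummary:
    """Per-component representative stats plus density-weighted mixture values."""

    component_stats: list[RepresentativeStats]
    weights: np.ndarray
    mixture: RepresentativeStats

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "components": [s.as_dict() for s in self.component_stats],
            "mixture": self.mixture.as_dict(),
        }


def _values(sample) -> np.ndarray:
    return np.asarray(getattr(sample, "values", sample), dtype=float)


def _mode(values: np.ndarray) -> float:
    # receptor counts resolve to whole receptors: round, then most frequent,
    # ties broken toward the smaller value (np.unique returns sorted keys)
    rounded = np.round(values)
    uniq, counts = np.unique(rounded, return_counts=True)
    return float(uniq[np.argmax(counts)])


def representative_stats(sample) -> RepresentativeStats:
    """Geometric mean, arithmetic mean, mode and median of raw values."""
    values = _values(sample)
    if values.size < 1:
        raise ValueError("empty sample")
    n_bad = int((values <= 0).sum())
    if n_bad:
        raise ValueError(
            f"{n_bad} nonpositive value(s); geometric mean requires values > 0"
        )
    return RepresentativeStats(
        geometric_mean=float(np.exp(np.mean(np.log(values)))),
        arithmetic_mean=float(values.mean()),
        mode=_mode(values),
        median=float(np.median(values)),
    )


def _kmeans_1d(values: np.ndarray, m: int, rng: np.random.Generator, n_iter: int = 50):
    """Lloyd's algorithm on 1-D data from random distinct starting centers."""
    centers = np.sort(rng.choice(values, size=m, replace=False))
    for _ in range(n_iter):
        labels = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
        new = np.array(
            [values[labels == j].mean() if np.any(labels == j) else centers[j] for j in range(m)]
        )
        if np.allclose(new, centers):
            break
        centers = new
    return centers, labels


def _em_once(
    values: np.ndarray,
    m: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    sd_floor: float,
):
    centers, labels = _kmeans_1d(values, m, rng)
    weights = np.array([max((labels == j).mean(), 1.0 / values.size) for j in range(m)])
    weights /= weights.sum()
    means = centers.astype(float)
    sds = np.array(
        [values[labels == j].std() if (labels == j).sum() > 1 else values.std() for j in range(m)]
    )
    sds = np.maximum(sds, sd_floor)

    prev_ll = -np.inf
    for it in range(1, max_iter + 1):
        # E step in log space for numerical stability
        log_comp = (
            np.log(weights)[None, :]
            - np.log(sds)[None, :]
            - 0.5 * _LOG_2PI
            - 0.5 * ((values[:, None] - means[None, :]) / sds[None, :]) ** 2
        )
        log_norm = np.logaddexp.reduce(log_comp, axis=1)
        ll = float(log_norm.sum())
        if ll < prev_ll - 1e-8 * abs(prev_ll):
            raise MixtureError(f"EM log-likelihood decreased at iteration {it}")
        resp = np.exp(log_comp - log_norm[:, None])

        # M step
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):
            raise MixtureError("component starved of responsibility")
        weights = nk / values.size
        means = (resp * values[:, None]).sum(axis=0) / nk
        var = (resp * (values[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, 0.0))
        if np.any(sds < sd_floor):
            raise MixtureError("component collapse: sd below floor")

        if prev_ll > -np.inf and abs(ll - prev_ll) < tol * abs(prev_ll):
            return weights, means, sds, ll, True, it
        prev_ll = ll
    return weights, means, sds, prev_ll, False, max_iter


def fit_mixture(
    sample,
    m: int = 3,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> MixtureFit:
    """Fit an m-component 1-D Gaussian mixture by EM.

    Best of ``n_init`` seeded k-means initializations by log-likelihood;
    restarts that collapse (component sd below 1e-6 of the data SD) are
    discarded. Components are sorted by descending weight and cells hard-
    assigned by maximum posterior responsibility.
    """
    values = _values(sample)
    if values.size < 10 * m:
        raise ValueError(f"need n >= {10 * m} for an m={m} mixture")
    sd_floor = 1e-6 * float(values.std())
    rng = np.random.default_rng(seed)

    best = None
    failures: list[str] = []
    for _ in range(n_init):
        try:
            result = _em_once(values, m, rng, max_iter, tol, sd_floor)
        except MixtureError as exc:
            failures.append(str(exc))
            continue
        if best is None or result[3] > best[3]:
            best = result
    if best is None:
        raise MixtureError(
            f"all {n_init} EM restarts failed: " + "; ".join(sorted(set(failures)))
        )

    weights, means, sds, ll, converged, n_iter = best
    order = np.argsort(-weights)
    weights, means, sds = weights[order], means[order], sds[order]

    log_comp = (
        np.log(weights)[None, :]
        - np.log(sds)[None, :]
        - 0.5 * _LOG_2PI
        - 0.5 * ((values[:, None] - means[None, :]) / sds[None, :]) ** 2
    )
    assignments = np.argmax(log_comp, axis=1)
    return MixtureFit(
        weights=weights,
        means=means,
        sds=sds,
        loglik=ll,
        converged=converged,
        assignments=assignments,
        n_iter=n_iter,
    )


def mixture_weighted_stat(weights, component_stats) -> float:
    """Density-weighted sum of per-component statistics: sum_m w_m * stat_m."""
    weights = np.asarray(weights, dtype=float)
    component_stats = np.asarray(component_stats, dtype=float)
    if weights.shape != component_stats.shape:
        raise ValueError(
            f"length mismatch: {weights.size} weights vs {component_stats.size} stats"
        )
    return float(weights @ component_stats)


def mixture_summary(sample, fit: MixtureFit) -> MixtureSummary:
    """Per-component stats (on hard-assigned cells) and weighted mixture values.

    Component statistics come from the cells assigned to each component, not
    from the fitted Gaussian parameters: a Gaussian's support includes
    nonpositive values where the geometric mean is undefined.
    """
    values = _values(sample)
    comp_stats = []
    for j in range(fit.m):
        members = values[fit.assignments == j]
        if members.size == 0:
            raise MixtureError(f"component {j} has no assigned cells")
        comp_stats.append(representative_stats(members))
    mixture = RepresentativeStats(
        **{
            name: mixture_weighted_stat(
                fit.weights, [getattr(s, name) for s in comp_stats]
            )
            for name in ("geometric_mean", "arithmetic_mean", "mode", "median")
        }
    )
    return MixtureSummary(component_stats=comp_stats, weights=fit.weights, mixture=mixture)
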