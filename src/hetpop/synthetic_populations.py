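"""Synthetic receptor-count populations.

Generators for heavy-tailed single-population samples (lognormal, gamma,
Weibull) with an optional planted right-tail contamination cluster, and for
tri-modal Gaussian mixtures with ground-truth component labels. Every
generator takes an explicit integer seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

FAMILIES = ("lognormal", "gamma", "weibull")


class ConfigurationError(ValueError):
    """Raised when a generator or fitter is configured inconsistently."""


@dataclass(frozen=True)
class PopulationSpec:
    """Recipe for a single heavy-tailed receptor population.

    Parameters
    ----------
    family
        One of ``lognormal``, ``gamma``, ``weibull``.
    param1, param2
        ``lognormal``: mean and SD of log-counts. ``gamma``/``weibull``:
        shape ``a`` and scale ``b`` in receptors/cell.
    n_cells
        Number of cells to draw.
    contamination_fraction
        Fraction (in [0, 0.05]) of cells drawn from a narrow outlier
        cluster in the far right tail.
    contamination_location
        Multiplier (> 1) applied to the 99th percentile of the clean
        distribution to place the outlier cluster center.
    seed
        RNG seed; same spec and seed give bit-identical samples.
    """

    family: str
    param1: float
    param2: float
    n_cells: int
    contamination_fraction: float = 0.0
    contamination_location: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.param2 <= 0:
            raise ConfigurationError("param2 (scale / sigma) must be > 0")
        if self.family in ("gamma", "weibull") and self.param1 <= 0:
            raise ConfigurationError("shape parameter must be > 0")
        if self.family == "lognormal" and self.param2 <= 0:
            raise ConfigurationError("sigma of log-counts must be > 0")
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")
        if not 0.0 <= self.contamination_fraction <= 0.05:
            raise ConfigurationError("contamination_fraction must be in [0, 0.05]")
        if self.contamination_fraction > 0 and self.contamination_location <= 1:
            raise ConfigurationError("contamination_location must be > 1")


@dataclass(frozen=True)
class MixtureSpec:
    """Recipe for a tri-modal Gaussian mixture population.

    ``weights`` must be nonnegative, sum to 1 and be strictly descending,
    matching the highest-weight-first component ordering used downstream.
    """

    weights: tuple[float, float, float]
    means: tuple[float, float, float]
    sds: tuple[float, float, float]
    n_cells: int
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (3,) or np.any(w < 0):
            raise ConfigurationError("weights must be 3 nonnegative fractions")
        if abs(float(w.sum()) - 1.0) > 1e-12:
            raise ConfigurationError(f"weights must sum to 1, got {w.sum()!r}")
        if np.any(np.diff(w) > 0):
            raise ConfigurationError("weights must be ordered descending")
        if len(self.means) != 3 or len(self.sds) != 3:
            raise ConfigurationError("means and sds must each have 3 entries")
        if any(s <= 0 for s in self.sds):
            raise ConfigurationError("all sds must be > 0")
        if any(m <= 0 for m in self.means):
            raise ConfigurationError("all means must be > 0 (receptors/cell)")
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")


@dataclass
class ReceptorSample:
    """A vector of per-cell surface receptor counts (receptors/cell).

    ``components`` optionally carries per-cell ground-truth labels
    (mixture component index, or -1/1 clean/outlier flags).
    """

    values: np.ndarray
    label: str = ""
    components: np.ndarray | None = field(default=None, repr=False)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be a 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must all be finite")

    @property
    def n(self) -> int:
        return int(self.values.size)

    def validated(self) -> "ReceptorSample":
        """Drop nonpositive values, recording how many were removed."""
        keep = self.values > 0
        dropped = int((~keep).sum())
        comp = self.components[keep] if self.components is not None else None
        return ReceptorSample(
            self.values[keep], self.label, comp, self.n_dropped + dropped
        )


def _clean_distribution(spec: PopulationSpec):
    if spec.family == "lognormal":
        return stats.lognorm(s=spec.param2, scale=math.exp(spec.param1))
    if spec.family == "gamma":
        return stats.gamma(a=spec.param1, scale=spec.param2)
    return stats.weibull_min(c=spec.param1, scale=spec.param2)


def generate_population(spec: PopulationSpec) -> ReceptorSample:
    """Draw a receptor population, optionally planting a right-tail cluster.

    Exactly ``floor(contamination_fraction * n_cells)`` cells come from a
    narrow uniform cluster on ``[0.95, 1.05] * contamination_location *
    Q99(clean)``; the remainder are clean draws. Component labels (0 clean,
    1 planted) are kept as ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    dist = _clean_distribution(spec)
    n_out = int(math.floor(spec.contamination_fraction * spec.n_cells))
    n_clean = spec.n_cells - n_out

    clean = dist.rvs(size=n_clean, random_state=rng)
    if n_out > 0:
        center = spec.contamination_location * dist.ppf(0.99)
        outliers = rng.uniform(0.95 * center, 1.05 * center, size=n_out)
        values = np.concatenate([clean, outliers])
        labels = np.concatenate(
            [np.zeros(n_clean, dtype=int), np.ones(n_out, dtype=int)]
        )
    else:
        values = clean
        labels = np.zeros(n_clean, dtype=int)

    order = rng.permutation(spec.n_cells)
    label = f"{spec.family}({spec.param1:g}, {spec.param2:g})"
    return ReceptorSample(values[order], label=label, components=labels[order])


def generate_mixture(spec: MixtureSpec) -> ReceptorSample:
    """Draw a tri-modal Gaussian mixture with per-cell component labels.

    Negative draws are rejected and redrawn (receptor counts are
    nonnegative); truncation would bias component means, rejection at the
    scales used here discards a negligible fraction.
    """
    rng = np.random.default_rng(spec.seed)
    labels = rng.choice(3, size=spec.n_cells, p=np.asarray(spec.weights))
    values = np.empty(spec.n_cells, dtype=float)
    for m in range(3):
        idx = np.flatnonzero(labels == m)
        draws = rng.normal(spec.means[m], spec.sds[m], size=idx.size)
        bad = draws <= 0
        while bad.any():
            draws[bad] = rng.normal(spec.means[m], spec.sds[m], size=int(bad.sum()))
            bad = draws <= 0
        values[idx] = draws
    return ReceptorSample(values, label="gaussian-mixture", components=labels)
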