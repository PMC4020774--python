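"""Low bin search: best family, SSE-optimal bin number, right-tail cutoff.

The search (1) selects the best-fitting two-parameter family at a reference
bin count, (2) scans bin counts ``k_min..k_max`` for the k minimizing the
SSE of the fixed raw-data MLE fit, (3) locates the leftmost sparse bin
right of the largest bin whose own and neighboring occupancies all fall
below a fraction of the largest bin's occupancy, and removes that bin plus
everything to its right. Baseline outlier/binning rules and two bootstrap
robustness protocols are included for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from hetpop.distribution_fitting import (
    DistributionFit,
    Histogram,
    compute_sse,
    fit_mle,
    select_best_family,
)
from hetpop.synthetic_populations import ReceptorSample


@dataclass(frozen=True)
class LowBinConfig:
    """Search-range and cutoff-criterion settings.

    ``eligibility_fraction`` is the occupancy criterion: a cutoff-candidate
    bin (and both neighbors) must hold fewer cells than this fraction of
    the largest bin. Only bins to the right of the largest bin are
    candidates; left-tail data are never removed.
    """

    k_min: int = 5
    k_max: int = 200
    eligibility_fraction: float = 0.01
    #: bin count at which the best family is selected, once, before the
    #: k-scan. At very coarse binning the pdf-at-center discretization error
    #: swamps genuine family differences, so a moderate fixed count is used.
    reference_k: int = 50

    def __post_init__(self) -> None:
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError("need 2 <= k_min <= k_max")
        if not 0 < self.eligibility_fraction < 1:
            raise ValueError("eligibility_fraction must be in (0, 1)")
        if self.reference_k < 2:
            raise ValueError("reference_k must be >= 2")


@dataclass
class LowBinResult:
    best_family: str
    optimal_k: int
    sse_by_k: dict[int, float]
    cutoff_bin_index: int | None
    cutoff_value: float | None
    kept_mask: np.ndarray
    removed_count: int
    fit: DistributionFit
    refit: DistributionFit

    def kept_values(self, sample: ReceptorSample) -> np.ndarray:
        return sample.values[self.kept_mask]

    def to_dict(self) -> dict:
        return {
            "best_family": self.best_family,
            "optimal_k": self.optimal_k,
            "sse_by_k": {str(k): v for k, v in self.sse_by_k.items()},
            "cutoff_bin_index": self.cutoff_bin_index,
            "cutoff_value": self.cutoff_value,
            "removed_count": self.removed_count,
            "kept_count": int(self.kept_mask.sum()),
            "fit": {"family": self.fit.family, "params": list(self.fit.params)},
            "refit": {"family": self.refit.family, "params": list(self.refit.params)},
        }


@dataclass
class BootstrapResult:
    """Per-trial cutoff values and geometric means for one protocol."""

    protocol: str
    trials: list[dict] = field(default_factory=list)

    def records_for(self, size: int) -> list[dict]:
        return [t for t in self.trials if t["size"] == size]

    def ranges(self) -> dict[int, dict[str, float]]:
        """max - min of cutoff value and geometric mean, per sample size."""
        out: dict[int, dict[str, float]] = {}
        for size in sorted({t["size"] for t in self.trials}):
            recs = self.records_for(size)
            gms = [t["geometric_mean"] for t in recs]
            cuts = [t["cutoff_value"] for t in recs if t["cutoff_value"] is not None]
            out[size] = {
                "geometric_mean": max(gms) - min(gms),
                "cutoff_value": (max(cuts) - min(cuts)) if cuts else float("nan"),
            }
        return out


def _values(sample) -> np.ndarray:
    return np.asarray(getattr(sample, "values", sample), dtype=float)


def build_histogram(sample, k: int) -> Histogram:
    """k equal-width bins spanning [min, max]; right-open except the last."""
    values = _values(sample)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if values.size < 1:
        raise ValueError("empty sample")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise ValueError("all values identical: zero range")
    # np.histogram uses right-open bins with the last bin closed
    counts, edges = np.histogram(values, bins=k, range=(lo, hi))
    return Histogram(edges=edges, counts=counts)


def optimal_bin_number(
    sample, family: str, config: LowBinConfig = LowBinConfig(), fit: DistributionFit | None = None
) -> tuple[int, dict[int, float]]:
    """argmin over k in [k_min, k_max] of the fixed-fit SSE; ties -> smaller k.

    The family's parameters are held at the raw-data MLE while k varies, so
    the scan compares binnings of the same fitted distribution.
    """
    if fit is None:
        fit = fit_mle(sample, family)
    sse_by_k: dict[int, float] = {}
    best_k, best_sse = None, math.inf
    for k in range(config.k_min, config.k_max + 1):
        sse = compute_sse(build_histogram(sample, k), fit)
        sse_by_k[k] = sse
        if sse < best_sse:  # strict: ties keep the smaller k
            best_k, best_sse = k, sse
    return best_k, sse_by_k


def find_cutoff_bin(hist: Histogram, config: LowBinConfig = LowBinConfig()) -> int | None:
    """Leftmost sparse bin strictly right of the largest bin, or None.

    Bin j qualifies when n_j, n_{j-1} and n_{j+1} are all below
    ``eligibility_fraction * n_max``. A missing right neighbor (last bin)
    counts as 0 cells; ties for the largest bin resolve to the leftmost.
    """
    counts = hist.counts
    i_max = int(np.argmax(counts))  # leftmost maximal bin
    threshold = config.eligibility_fraction * counts[i_max]
    for j in range(i_max + 1, hist.k):
        left = counts[j - 1]
        right = counts[j + 1] if j + 1 < hist.k else 0
        if counts[j] < threshold and left < threshold and right < threshold:
            return j
    return None


def low_bin_search(
    sample: ReceptorSample, config: LowBinConfig = LowBinConfig()
) -> LowBinResult:
    """Full pipeline: family selection, bin-number scan, right-tail cutoff.

    The cutoff bin and every bin to its right are removed (values at or
    above the cutoff bin's left edge); the best family is refitted on the
    kept data. Deterministic given sample and config.
    """
    values = _values(sample)
    if values.size < 100:
        raise ValueError(
            f"low_bin_search needs n >= 100 (got {values.size}); "
            "binning is meaningless on smaller samples"
        )
    family, fits = select_best_family(sample, min(config.reference_k, config.k_max))
    fit = fits[family]
    k_star, sse_by_k = optimal_bin_number(sample, family, config, fit=fit)
    hist = build_histogram(sample, k_star)
    j = find_cutoff_bin(hist, config)

    if j is None:
        kept = np.ones(values.size, dtype=bool)
        cutoff_value = None
    else:
        cutoff_value = float(hist.edges[j])
        kept = values < cutoff_value
    removed = int(values.size - kept.sum())
    refit = fit_mle(values[kept], family) if removed else fit
    return LowBinResult(
        best_family=family,
        optimal_k=k_star,
        sse_by_k=sse_by_k,
        cutoff_bin_index=j,
        cutoff_value=cutoff_value,
        kept_mask=kept,
        removed_count=removed,
        fit=fit,
        refit=refit,
    )


def three_sd_outliers(sample) -> np.ndarray:
    """Baseline rule: keep values <= mean + 3*SD (single pass)."""
    values = _values(sample)
    if values.size < 2:
        raise ValueError("need n >= 2")
    return values <= values.mean() + 3.0 * values.std(ddof=0)


def baseline_bin_rules(n: int, rule: str, palisade_exponent: float = 1.0 / 3.0) -> int:
    """Sample-size-only bin-count rules used by common software packages.

    ``matlab_sqrt`` = ceil(sqrt(n)); ``palisade`` = floor(n**exponent)
    (default cube root). Both are documented approximations of the
    commercial packages' undisclosed formulas.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rule == "matlab_sqrt":
        return int(math.ceil(math.sqrt(n)))
    if rule == "palisade":
        return int(math.floor(n**palisade_exponent))
    raise ValueError(f"unknown rule {rule!r}; expected 'matlab_sqrt' or 'palisade'")


def _geometric_mean(values: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(values))))


def _trial_record(
    size: int, trial: int, result: LowBinResult, kept: np.ndarray, dataset: np.ndarray
) -> dict:
    return {
        "size": size,
        "trial": trial,
        "cutoff_value": result.cutoff_value,
        "geometric_mean": _geometric_mean(kept),
        "dataset_geometric_mean": _geometric_mean(dataset),
        "removed_count": result.removed_count,
    }


def bootstrap_subsample(
    sample: ReceptorSample,
    sizes: list[int],
    trials: int,
    seed: int,
    config: LowBinConfig = LowBinConfig(),
) -> BootstrapResult:
    """Protocol 1: low bin search on without-replacement subsamples."""
    values = _values(sample)
    if trials < 1:
        raise ValueError("trials must be >= 1")
    for size in sizes:
        if size > values.size:
            raise ValueError(f"subsample size {size} exceeds n = {values.size}")
    rng = np.random.default_rng(seed)
    out = BootstrapResult(protocol="subsample")
    for size in sizes:
        for t in range(trials):
            sub = rng.choice(values, size=size, replace=False)
            res = low_bin_search(ReceptorSample(sub), config)
            out.trials.append(_trial_record(size, t, res, sub[res.kept_mask], sub))
    return out


def bootstrap_perturb(
    sample: ReceptorSample,
    sizes: list[int],
    trials: int,
    seed: int,
    config: LowBinConfig = LowBinConfig(),
    factor: float = 1.2,
) -> BootstrapResult:
    """Protocol 2: scale `size` randomly chosen cells by 20%, search the full set."""
    values = _values(sample)
    for size in sizes:
        if size > values.size:
            raise ValueError(f"perturbation size {size} exceeds n = {values.size}")
    rng = np.random.default_rng(seed)
    out = BootstrapResult(protocol="perturb20")
    for size in sizes:
        for t in range(trials):
            perturbed = values.copy()
            if size > 0:
                idx = rng.choice(values.size, size=size, replace=False)
                perturbed[idx] *= factor
            res = low_bin_search(ReceptorSample(perturbed), config)
            out.trials.append(_trial_record(size, t, res, perturbed[res.kept_mask], perturbed))
    return out
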