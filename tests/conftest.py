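import numpy as np
import pytest

from hetpop.synthetic_populations import (
    MixtureSpec,
    PopulationSpec,
    generate_mixture,
    generate_population,
)
from hetpop.vegf_compartment_model import (
    COMPARTMENTS,
    CompartmentModel,
    ReceptorPool,
    default_model,
)

# Table-2-scale lognormal of HUVEC VEGFR1: mu=7.83, sigma=0.57
LOGNORMAL_MU, LOGNORMAL_SIGMA = 7.83, 0.57


@pytest.fixture(scope="session")
def lognormal_sample():
    """Clean heavy-tailed sample at realistic receptor scales."""
    spec = PopulationSpec("lognormal", LOGNORMAL_MU, LOGNORMAL_SIGMA, 20_000, seed=42)
    return generate_population(spec)


@pytest.fixture(scope="session")
def contaminated_sample():
    """Lognormal bulk plus a 0.3% planted cluster at 10x Q99."""
    spec = PopulationSpec(
        "lognormal", LOGNORMAL_MU, LOGNORMAL_SIGMA, 20_000,
        contamination_fraction=0.003, contamination_location=10.0, seed=7,
    )
    return generate_population(spec)


@pytest.fixture(scope="session")
def trimodal_sample():
    spec = MixtureSpec(
        weights=(0.6, 0.3, 0.1),
        means=(1_000.0, 5_000.0, 20_000.0),
        sds=(200.0, 800.0, 3_000.0),
        n_cells=30_000,
        seed=11,
    )
    return generate_mixture(spec)


@pytest.fixture(scope="session")
def model():
    return default_model()


def make_closed_model(pool: ReceptorPool | None = None) -> CompartmentModel:
    """All transport/secretion/clearance/drug/GAG terms zeroed."""
    return CompartmentModel(
        volumes={c: 1.0 for c in COMPARTMENTS},
        secretion={c: 0.0 for c in COMPARTMENTS},
        clearance_vegf=0.0,
        clearance_drug=0.0,
        k_perm={"normal": 0.0, "diseased": 0.0},
        k_lymph={"normal": 0.0, "diseased": 0.0},
        drug_kon=0.0,
        drug_koff=0.0,
        gag_sites={"normal": 0.0, "diseased": 0.0},
        gag_kon=0.0,
        gag_koff=0.0,
        pools=[pool] if pool else [],
    )


def geometric_mean(values: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(values))))


def asymptotic_se(family: str, params, values) -> tuple[float, float]:
    """Observed-information SEs via a finite-difference Hessian of the loglik.

    Independent of the fitting path: only evaluates the pdf.
    """
    from hetpop.distribution_fitting import eval_pdf

    def nll(p):
        return -np.sum(np.log(np.maximum(eval_pdf(family, tuple(p), values), 1e-300)))

    p0 = np.asarray(params, dtype=float)
    h = 1e-4 * np.maximum(np.abs(p0), 1e-3)
    hess = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            ei, ej = np.eye(2)[i] * h[i], np.eye(2)[j] * h[j]
            hess[i, j] = (
                nll(p0 + ei + ej) - nll(p0 + ei - ej) - nll(p0 - ei + ej) + nll(p0 - ei - ej)
            ) / (4 * h[i] * h[j])
    cov = np.linalg.inv(hess)
    return tuple(np.sqrt(np.diag(cov)))
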