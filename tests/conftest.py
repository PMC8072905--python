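import numpy as np
import pytest

from ehrpk import DoseSchedule, FitConfig, Route, reference_params
from ehrpk.cohort import SAMPLING_SCHEDULES, CohortSpec, generate_cohort
from ehrpk.model import FREE_PARAMETERS


@pytest.fixture(scope="session")
def mean_params():
    """Reference mean parameter vectors per route."""
    return {route: reference_params(route) for route in Route}


@pytest.fixture(scope="session")
def schedules():
    return {route: DoseSchedule(0.5, route) for route in Route}


@pytest.fixture(scope="session")
def sample_times():
    return {route: np.asarray(SAMPLING_SCHEDULES[route][1:])
            for route in Route}


def noise_free_spec(route, **overrides):
    """Cohort spec with zero between-animal and residual variability."""
    sds = {k: 0.0 for k in FREE_PARAMETERS[Route(route)]}
    kw = dict(route=route, n_subjects=1, sigma=0.0, param_sds=sds,
              body_weight_sd_g=0.0, seed=0)
    kw.update(overrides)
    return CohortSpec(**kw)


@pytest.fixture(scope="session")
def noise_free_subjects():
    """One noise-free subject per route, simulated at the mean parameters."""
    return {route: generate_cohort(noise_free_spec(route))[0]
            for route in Route}


@pytest.fixture()
def fast_fit_cfg():
    """Small multi-start budget for tests that only need convergence."""
    return FitConfig(n_starts=2, perturb_factor=1.5, seed=11)


def perturbed_init(params, rng, factor=2.0):
    """Seeded log-uniform perturbation of every free parameter, <= x/÷ factor."""
    names = FREE_PARAMETERS[params.route]
    lo = np.log(1.0 / factor)
    hi = np.log(factor)
    vals = {n: params.get(n) * np.exp(rng.uniform(lo, hi)) for n in names}
    return params.with_values(**vals)
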