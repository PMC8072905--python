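"""Synthetic rat-cohort generator.

Emulates the design of the source study: three routes (IV bolus n=5, oral
gavage n=3, 4-h supralingual patch n=3) at 0.5 mg/kg MPA, route-specific
blood-sampling schedules, between-animal parameter variability at the
reported mean +/- SD level, a proportional residual error
C_obs = C_pred * (1 + eps) with eps ~ N(0, sigma^2), and censoring below
the assay's lower limit of quantification (LLOQ, 0.5 ng/mL).

Between-animal variability uses a lognormal distribution with moments
matched to the reported (mean, SD) -- every parameter has positive support;
a zero-truncated normal is available as an alternative. The generator is
fully reproducible from its integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import SubjectDataset
from .model import (REFERENCE_ESTIMATES, DoseSchedule, ModelParams, Route,
                    SolverConfig, default_absorption, reference_params,
                    simulate_profile)

__all__ = ["SAMPLING_SCHEDULES", "CohortSpec", "sample_subject_params",
           "generate_cohort", "default_cohort_specs"]

#: route-specific blood-sampling times (h); minute-based draws are stored
#: as fractions of an hour
SAMPLING_SCHEDULES: dict[Route, tuple[float, ...]] = {
    Route.IV: (0, 2 / 60, 5 / 60, 15 / 60, 30 / 60,
               1, 2, 3, 4, 6, 8, 10, 24, 28, 32, 48),
    Route.ORAL: (0, 5 / 60, 10 / 60, 15 / 60, 30 / 60,
                 1, 2, 3, 4, 6, 8, 10, 12, 24, 28, 32, 48),
    Route.SUPRALINGUAL: (0, 1, 2, 3, 4, 4.5, 5, 6, 7, 8, 9, 10,
                         24, 28, 32, 48),
}

#: default group sizes per route
DEFAULT_N_SUBJECTS: dict[Route, int] = {
    Route.IV: 5, Route.ORAL: 3, Route.SUPRALINGUAL: 3,
}

BODY_WEIGHT_MEAN_G = 379.8
BODY_WEIGHT_SD_G = 44.3


@dataclass
class CohortSpec:
    """Design of one synthetic dosing group.

    param_means / param_sds default to the reference estimates for the
    route; an SD of 0 makes every animal share the mean. ``sigma`` is the
    proportional residual SD applied to each simulated observation.
    """

    route: Route
    n_subjects: int | None = None
    param_means: dict[str, float] = field(default_factory=dict)
    param_sds: dict[str, float] = field(default_factory=dict)
    sigma: float = 0.15
    lloq_ng_ml: float = 0.5
    dose_mg_kg: float = 0.5
    body_weight_mean_g: float = BODY_WEIGHT_MEAN_G
    body_weight_sd_g: float = BODY_WEIGHT_SD_G
    distribution: str = "lognormal"
    n_transit: int = 5
    times: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.route = Route(self.route)
        ref = REFERENCE_ESTIMATES[self.route]
        means = {k: v[0] for k, v in ref.items()}
        sds = {k: v[1] for k, v in ref.items()}
        unknown = set(self.param_means) - set(means)
        unknown |= set(self.param_sds) - set(sds)
        if unknown:
            raise ValueError(f"unknown parameter(s) for route "
                             f"{self.route.value}: {sorted(unknown)}")
        means.update(self.param_means)
        sds.update(self.param_sds)
        self.param_means, self.param_sds = means, sds
        if self.n_subjects is None:
            self.n_subjects = DEFAULT_N_SUBJECTS[self.route]
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if any(s < 0 for s in sds.values()):
            raise ValueError("parameter SDs must be >= 0")
        if self.lloq_ng_ml <= 0:
            raise ValueError("LLOQ must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.distribution not in ("lognormal", "truncnorm"):
            raise ValueError("distribution must be lognormal|truncnorm")
        if self.times is None:
            self.times = SAMPLING_SCHEDULES[self.route]
        self.times = tuple(float(t) for t in self.times)
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("sampling times must be strictly increasing")


def _draw_positive(rng: np.random.Generator, mean: float, sd: float,
                   distribution: str) -> float:
    """One draw with the requested positive-support distribution,
    moment-matched to (mean, sd). sd == 0 degenerates to the mean."""
    if sd == 0:
        return mean
    if mean <= 0:
        raise ValueError("mean must be > 0 to draw a positive parameter")
    if distribution == "lognormal":
        s2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - 0.5 * s2
        return float(rng.lognormal(mu, np.sqrt(s2)))
    # zero-truncated normal by rejection
    for _ in range(10000):
        x = rng.normal(mean, sd)
        if x > 0:
            return float(x)
    raise ValueError("truncated-normal rejection sampling failed "
                     f"(mean={mean}, sd={sd})")


def sample_subject_params(spec: CohortSpec,
                          rng: np.random.Generator) -> ModelParams:
    """Draw one animal's parameter vector.

    Structural rate constants, clearances and volumes are sampled;
    fixed design quantities (n_transit, t_lag, patch_duration,
    released_fraction) and the residual sigma are not.
    """
    values = {name: _draw_positive(rng, spec.param_means[name],
                                   spec.param_sds[name], spec.distribution)
              for name in spec.param_means}
    base = reference_params(spec.route, sigma=max(spec.sigma, 1e-12),
                            n_transit=spec.n_transit)
    return base.with_values(**values)


def generate_cohort(spec: CohortSpec,
                    solver: SolverConfig | None = None) -> list[SubjectDataset]:
    """Simulate one dosing group.

    Per subject: draw parameters and body weight, simulate the noise-free
    profile on the sampling schedule, apply multiplicative Gaussian noise,
    flag records below the LLOQ (or negative after noise) as BLQ, and emit
    a BLQ pre-dose record at t=0. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    prefix = {Route.IV: "IV", Route.ORAL: "PO", Route.SUPRALINGUAL: "SL"}
    subjects: list[SubjectDataset] = []
    times = np.asarray(spec.times, dtype=float)
    for i in range(spec.n_subjects):
        params = sample_subject_params(spec, rng)
        bw = _draw_positive(rng, spec.body_weight_mean_g,
                            spec.body_weight_sd_g, "truncnorm") \
            if spec.body_weight_sd_g > 0 else spec.body_weight_mean_g
        schedule = DoseSchedule(nominal_dose_mg_kg=spec.dose_mg_kg,
                                route=spec.route, body_weight_g=bw)
        pred = simulate_profile(params, schedule, times, solver)
        eps = rng.normal(0.0, 1.0, size=times.size) * spec.sigma
        obs = pred * (1.0 + eps)
        blq = obs < spec.lloq_ng_ml
        pre_dose = times == 0.0
        obs = np.where(pre_dose, 0.0, obs)
        blq = blq | pre_dose
        # keep the noisy value for quantifiable records; BLQ keeps the raw
        # (possibly negative) value for transparency
        df = pd.DataFrame({"time_h": times, "conc_ng_ml": obs, "blq": blq})
        subjects.append(SubjectDataset(
            subject_id=f"{prefix[spec.route]}{i + 1:02d}",
            route=spec.route, dose_mg_kg=spec.dose_mg_kg,
            body_weight_g=round(bw, 1), records=df, true_params=params))
    return subjects


def default_cohort_specs(seed: int = 0, sigma: float = 0.15
                         ) -> dict[Route, CohortSpec]:
    """The study design as generator specs: one group per route, with
    per-route seeds derived from ``seed``."""
    return {route: CohortSpec(route=route, sigma=sigma,
                              seed=seed * 10 + k)
            for k, route in enumerate(Route)}
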