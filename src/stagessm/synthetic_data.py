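"""Synthetic study datasets for the stage-structured state-space model.

Emulates the parameter-recovery study design: 20 cohorts, four life stages,
one true covariate plus one zero-effect decoy covariate per vital-rate
process, observation biases on juveniles (psi_J = 0.5) and sub-adults
(psi_SA = 0.2), true per-cell observation CVs drawn Uniform(0.1, 1), and
noisy external CV estimates drawn Uniform((1-a) CV, (1+a) CV).

Covariate values are i.i.d. standard normal across processes and cohorts, so
a unit coefficient is a strong signal relative to unit covariate SD.  The
initial adult abundance nA0 defaults to 1000; with nA0 known the model is
scale-equivariant, so this choice only sets the scale of the indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Mapping, Optional, Tuple

import numpy as np

from .model_core import (
    STAGES,
    PROCESSES,
    CovariateSet,
    IndexDataset,
    ObservationParams,
    PopulationTrajectory,
    VitalRateParams,
    cv_to_logvar,
    draw_vital_rates,
    observe,
    propagate_states,
)

__all__ = ["StudyConfig", "StudyDataset", "generate_dataset", "generate_replicates",
           "smelt_like_fixture"]


def _default_coefs() -> Mapping[str, tuple]:
    # intercept, true-covariate effect, decoy effect
    return {"R": (1.0, 1.0, 0.0), "PL": (1.3, 1.0, 0.0),
            "J": (1.3, 1.0, 0.0), "SA": (1.3, 1.0, 0.0)}


@dataclass
class StudyConfig:
    """True generating values and design knobs of the simulation study."""

    T: int = 20
    coefs: Mapping[str, tuple] = field(default_factory=_default_coefs)
    sigmaP: Mapping[str, float] = field(
        default_factory=lambda: {"R": 0.05, "PL": 0.5, "J": 0.5, "SA": 0.5}
    )
    psi: Mapping[str, float] = field(default_factory=lambda: {"J": 0.5, "SA": 0.2})
    a: float = 0.0
    cv_range: Tuple[float, float] = (0.1, 1.0)
    nA0: float = 1000.0
    n_covariates_per_process: int = 2
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.a < 1):
            raise ValueError("a must lie in [0, 1)")
        lo, hi = self.cv_range
        if not (0 < lo <= hi):
            raise ValueError("cv_range must lie within (0, inf)")
        if self.T < 2:
            raise ValueError("need at least 2 cohorts")
        if self.n_covariates_per_process < 1:
            raise ValueError("need at least one covariate per process")

    def vital_rate_params(self) -> VitalRateParams:
        c = {p: np.asarray(self.coefs[p], dtype=float) for p in PROCESSES}
        return VitalRateParams(zeta=c["R"], beta=c["PL"], eta=c["J"], gamma=c["SA"],
                               sigmaP=dict(self.sigmaP))


@dataclass
class StudyDataset:
    """One simulated dataset plus the truth that generated it."""

    config: StudyConfig
    params: VitalRateParams
    obs_params: ObservationParams
    trajectory: PopulationTrajectory
    true_cv: np.ndarray           # (4, T) per-cell true observation CVs
    observed: IndexDataset        # carries the noisy external CV estimates
    covariates: CovariateSet      # true + decoy columns, intercept included
    replicate: int = 0
    seed: Optional[int] = None


def generate_dataset(config: StudyConfig, seed=None, replicate: int = 0) -> StudyDataset:
    """Simulate one complete dataset under the study's generating model.

    Vital rates are drawn from the covariate-driven lognormal/logit-normal
    models, states propagated deterministically, and indices observed with
    per-cell lognormal noise whose true CVs are Uniform(cv_range) draws.
    External CV estimates are Uniform((1-a) CV, (1+a) CV) around the truth.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    T = config.T
    ncov = config.n_covariates_per_process

    # design matrices: intercept + i.i.d. standard-normal covariate columns
    designs = {}
    for p in PROCESSES:
        x = rng.standard_normal((T, ncov))
        designs[p] = np.column_stack([np.ones(T), x])
    covariates = CovariateSet(**{"x" + p: designs[p] for p in PROCESSES})

    params = config.vital_rate_params()
    for p in PROCESSES:
        if params.coef(p).shape[0] != ncov + 1:
            raise ValueError(
                f"coefs[{p!r}] must have length {ncov + 1} (intercept + covariates)"
            )

    rho, phi = draw_vital_rates(params, covariates, T=T, seed=rng)
    traj = propagate_states(config.nA0, rho, phi)

    lo, hi = config.cv_range
    true_cv = rng.uniform(lo, hi, size=(4, T))
    obs_params = ObservationParams(
        psi=dict(config.psi), cv={s: true_cv[i] for i, s in enumerate(STAGES)}
    )
    observed = observe(traj, obs_params, seed=rng)

    a = config.a
    cv_ex = rng.uniform((1 - a) * true_cv, (1 + a) * true_cv)
    observed = IndexDataset(nhat=observed.nhat, cv_ex=cv_ex, mask=observed.mask)

    return StudyDataset(config=config, params=params, obs_params=obs_params,
                        trajectory=traj, true_cv=true_cv, observed=observed,
                        covariates=covariates, replicate=replicate, seed=seed)


def generate_replicates(config: StudyConfig, n_sims: int) -> List[StudyDataset]:
    """Independent replicate datasets with per-replicate seeds derived from the master.

    The same master seed always yields the same collection, and every replicate
    records its own derived seed, so results are invariant to execution order.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    ss = np.random.SeedSequence(config.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_sims)]
    return [
        generate_dataset(config, seed=child_seeds[i], replicate=i)
        for i in range(n_sims)
    ]


def smelt_like_fixture() -> StudyDataset:
    """A fixed 21-cohort dataset shaped after the estuary-fish case study.

    Exercises bias sharing — adult indices of the first six cohorts were
    collected with the sub-adult gear and share psi_SA — and one masked
    (unobserved) juvenile cell.  Fully deterministic: same output every call.
    """
    config = StudyConfig(T=21, seed=20200425)
    ds = generate_dataset(config)
    sharing = {("A", t): "SA" for t in range(1, 7)}
    obs = ObservationParams(psi=dict(ds.obs_params.psi), cv=ds.obs_params.cv,
                            bias_sharing=sharing)
    observed = observe(ds.trajectory, obs, seed=np.random.default_rng(config.seed + 1))
    nhat = observed.nhat
    mask = observed.mask.copy()
    mask[STAGES.index("J"), 9] = False  # cohort 10 juvenile survey missing
    cv_ex = ds.observed.cv_ex
    observed = IndexDataset(nhat=nhat, cv_ex=cv_ex, mask=mask)
    return replace(ds, obs_params=obs, observed=observed)
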