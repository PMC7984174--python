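"""Core domain types and stochastic kernels of the stage-structured state-space model.

The population is partitioned into four sequentially observed life stages —
post-larvae (PL), juveniles (J), sub-adults (SA) and adults (A) — followed per
birth cohort t = 1..T.  Given the adult abundance of the previous cohort, the
state process is a deterministic chain through stochastic vital rates:

    n_PL,t = rho_t * n_A,t-1          rho_t    ~ LogNormal(x_R,t' zeta, sigmaP_R^2)
    n_J,t  = phi_PL,t * n_PL,t        phi_s,t  ~ LogitNormal(x_s,t' coef, sigmaP_s^2)
    n_SA,t = phi_J,t  * n_J,t
    n_A,t  = phi_SA,t * n_SA,t

Observed indices are lognormal around the true abundances, with stage-specific
multiplicative biases psi_s and a median shift of -sigma^2/2 so that the index
is mean-unbiased for psi_s * n_s,t:

    nhat_s,t ~ LogNormal(ln(psi_s n_s,t) - sigmaO_s,t^2 / 2, sigmaO_s,t^2)

The lognormal is parameterized throughout by (log-mean, log-variance).  The
coefficient of variation of an index depends only on the log-variance,
CV = sqrt(exp(sigma^2) - 1), and is therefore invariant to psi.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

__all__ = [
    "STAGES",
    "PROCESSES",
    "VitalRateParams",
    "ObservationParams",
    "CovariateSet",
    "PopulationTrajectory",
    "IndexDataset",
    "cv_to_logvar",
    "logvar_to_cv",
    "index_moments",
    "draw_vital_rates",
    "propagate_states",
    "observe",
]

#: Life stages in the order they are reached within a cohort.
STAGES = ("PL", "J", "SA", "A")

#: Vital-rate processes: recruitment plus the three stage-transition survivals.
PROCESSES = ("R", "PL", "J", "SA")

_SURVIVALS = ("PL", "J", "SA")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def expit(x):
    """Inverse logit, numerically safe for large |x|."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class VitalRateParams:
    """Regression coefficients and process SDs of the four vital-rate processes.

    Parameters
    ----------
    zeta
        Recruitment coefficients on the log scale; first entry is the
        intercept zeta_0.
    beta, eta, gamma
        Post-larval, juvenile and sub-adult survival coefficients on the
        logit scale (intercept first).
    sigmaP
        Process SDs on the link scale, keyed by process ``R, PL, J, SA``.
    """

    zeta: np.ndarray
    beta: np.ndarray
    eta: np.ndarray
    gamma: np.ndarray
    sigmaP: Mapping[str, float]

    def __post_init__(self):
        self.zeta = np.atleast_1d(np.asarray(self.zeta, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.eta = np.atleast_1d(np.asarray(self.eta, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        self.sigmaP = {p: float(self.sigmaP[p]) for p in PROCESSES}
        for p, v in self.sigmaP.items():
            if v < 0:
                raise ValueError(f"process SD sigmaP[{p}] must be >= 0, got {v}")

    def coef(self, process: str) -> np.ndarray:
        return {"R": self.zeta, "PL": self.beta, "J": self.eta, "SA": self.gamma}[process]


@dataclass
class CovariateSet:
    """Per-process design matrices, cohort x covariate, intercept column included."""

    xR: np.ndarray
    xPL: np.ndarray
    xJ: np.ndarray
    xSA: np.ndarray

    def __post_init__(self):
        mats = {}
        T = None
        for p in PROCESSES:
            m = np.atleast_2d(np.asarray(getattr(self, "x" + p), dtype=float))
            if np.isnan(m).any():
                raise ValueError(f"design matrix for process {p} contains missing values")
            if T is None:
                T = m.shape[0]
            elif m.shape[0] != T:
                raise ValueError("design matrices must share the cohort dimension")
            mats[p] = m
        self.xR, self.xPL, self.xJ, self.xSA = (mats[p] for p in PROCESSES)

    @property
    def T(self) -> int:
        return self.xR.shape[0]

    def design(self, process: str) -> np.ndarray:
        return getattr(self, "x" + process)


@dataclass
class ObservationParams:
    """Stage-specific observation biases and the noise specification.

    ``psi`` maps stage -> multiplicative bias factor; stages absent from the
    mapping are unbiased (psi = 1).  Exactly one of the noise fields is set:

    - ``cv``:       per-(stage, cohort) coefficient-of-variation table
                    (stage -> length-T array), converted to log-variances via
                    :func:`cv_to_logvar` (external-CV scenario);
    - ``variance``: per-(stage, cohort) raw index variances (external-variance
                    scenario; conversion to log-variance involves the latent
                    state and is done by the likelihood);
    - ``sigmaO``:   per-stage log-scale SD (internally estimated scenario).

    ``bias_sharing`` optionally maps (stage, cohort) cells to *another* stage
    whose bias parameter applies there; e.g. adult indices collected with the
    sub-adult gear in early cohorts share psi_SA.
    """

    psi: Mapping[str, float] = field(default_factory=dict)
    cv: Optional[Mapping[str, np.ndarray]] = None
    variance: Optional[Mapping[str, np.ndarray]] = None
    sigmaO: Optional[Mapping[str, float]] = None
    bias_sharing: Mapping[tuple, str] = field(default_factory=dict)

    def __post_init__(self):
        self.psi = {s: float(v) for s, v in self.psi.items()}
        for s, v in self.psi.items():
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
            if v <= 0:
                raise ValueError(f"psi[{s}] must be > 0, got {v}")
        n_modes = sum(x is not None for x in (self.cv, self.variance, self.sigmaO))
        if n_modes > 1:
            raise ValueError("give at most one of cv, variance, sigmaO")
        if self.cv is not None:
            self.cv = {s: np.atleast_1d(np.asarray(v, dtype=float)) for s, v in self.cv.items()}
            for s, v in self.cv.items():
                if (v[np.isfinite(v)] <= 0).any():
                    raise ValueError(f"CVs for stage {s} must be > 0")
        if self.variance is not None:
            self.variance = {
                s: np.atleast_1d(np.asarray(v, dtype=float)) for s, v in self.variance.items()
            }
        if self.sigmaO is not None:
            self.sigmaO = {s: float(v) for s, v in self.sigmaO.items()}
            for s, v in self.sigmaO.items():
                if v <= 0:
                    raise ValueError(f"sigmaO[{s}] must be > 0, got {v}")

    def psi_for(self, stage: str, t: int) -> float:
        """Effective bias for a (stage, cohort) cell, honouring bias sharing.

        Cohorts are 1-based.
        """
        src = self.bias_sharing.get((stage, t), stage)
        return self.psi.get(src, 1.0)

    def psi_matrix(self, T: int) -> np.ndarray:
        return np.array(
            [[self.psi_for(s, t) for t in range(1, T + 1)] for s in STAGES]
        )

    def logvar_matrix(self, T: int) -> np.ndarray:
        """Resolved per-cell log-variances (stage x cohort).

        Only available for the ``cv`` and ``sigmaO`` specifications; the
        ``variance`` specification depends on the latent state.
        """
        if self.cv is not None:
            out = np.full((len(STAGES), T), np.nan)
            for i, s in enumerate(STAGES):
                if s in self.cv:
                    out[i] = cv_to_logvar(self.cv[s])
            return out
        if self.sigmaO is not None:
            out = np.full((len(STAGES), T), np.nan)
            for i, s in enumerate(STAGES):
                if s in self.sigmaO:
                    out[i] = self.sigmaO[s] ** 2
            return out
        raise ValueError("observation noise is state-dependent (variance mode) or unset")


@dataclass
class PopulationTrajectory:
    """Latent abundances and the realized vital rates that generated them.

    ``n`` is a (4, T) array over stages ``PL, J, SA, A``; ``phi`` is a (3, T)
    array over the survival transitions ``PL, J, SA``.  The update equations
    hold exactly: abundances are deterministic given ``nA0``, ``rho``, ``phi``.
    """

    nA0: float
    n: np.ndarray
    rho: np.ndarray
    phi: np.ndarray

    def __post_init__(self):
        self.nA0 = float(self.nA0)
        self.n = np.asarray(self.n, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.nA0 <= 0:
            raise ValueError("nA0 must be > 0")
        if (self.n <= 0).any():
            raise ValueError("latent abundances must be > 0")
        if ((self.phi <= 0) | (self.phi >= 1)).any():
            raise ValueError("survival probabilities must lie in (0, 1)")

    @property
    def T(self) -> int:
        return self.n.shape[1]

    def stage(self, s: str) -> np.ndarray:
        return self.n[STAGES.index(s)]


@dataclass
class IndexDataset:
    """Observed abundance indices with optional external CV estimates.

    ``nhat`` is a (4, T) array over stages PL, J, SA, A; missing cells are
    marked in ``mask`` (True = observed) and their ``nhat`` values ignored.
    """

    nhat: np.ndarray
    cv_ex: Optional[np.ndarray] = None
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.nhat = np.asarray(self.nhat, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.nhat)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if (self.nhat[self.mask] <= 0).any():
            raise ValueError("observed indices must be > 0")
        if self.cv_ex is not None:
            self.cv_ex = np.asarray(self.cv_ex, dtype=float)
            obs_cv = self.cv_ex[self.mask]
            if (obs_cv[np.isfinite(obs_cv)] <= 0).any():
                raise ValueError("external CVs must be > 0 where present")

    @property
    def T(self) -> int:
        return self.nhat.shape[1]


# ---------------------------------------------------------------------------
# Moment conversions
# ---------------------------------------------------------------------------


def cv_to_logvar(cv):
    """Log-scale variance of a lognormal index with coefficient of variation ``cv``.

    Inverts CV = sqrt(exp(sigma^2) - 1): returns ln(cv^2 + 1).
    """
    cv = np.asarray(cv, dtype=float)
    if (cv[np.isfinite(cv)] < 0).any():
        raise ValueError("cv must be >= 0")
    return np.log1p(cv**2)


def logvar_to_cv(logvar):
    """Coefficient of variation implied by a lognormal log-variance: sqrt(exp(s2) - 1)."""
    logvar = np.asarray(logvar, dtype=float)
    if (logvar[np.isfinite(logvar)] < 0).any():
        raise ValueError("logvar must be >= 0")
    return np.sqrt(np.expm1(logvar))


def index_moments(n, psi, logvar):
    """Mean and variance of a biased lognormal index.

    E[nhat] = psi * n and V[nhat] = (exp(logvar) - 1) * (psi * n)^2; the
    median shift applied inside :func:`observe` makes the index mean-unbiased
    for psi * n regardless of the noise level.
    """
    n = np.asarray(n, dtype=float)
    psi = np.asarray(psi, dtype=float)
    logvar = np.asarray(logvar, dtype=float)
    if (n <= 0).any():
        raise ValueError("n must be > 0")
    if (psi <= 0).any():
        raise ValueError("psi must be > 0")
    mean = psi * n
    var = np.expm1(logvar) * mean**2
    return mean, var


# ---------------------------------------------------------------------------
# Stochastic kernels
# ---------------------------------------------------------------------------


def draw_vital_rates(params: VitalRateParams, covariates: CovariateSet, T=None, seed=None):
    """Draw recruitment rates and survival probabilities for T cohorts.

    Recruitment is lognormal around exp(x_R' zeta); survivals are logit-normal,
    drawn on the logit scale and pushed through the logistic link.

    Returns
    -------
    rho : (T,) array of recruitment rates.
    phi : (3, T) array of survival probabilities for transitions PL, J, SA.
    """
    rng = _as_rng(seed)
    if T is None:
        T = covariates.T
    if T > covariates.T:
        raise ValueError("requested more cohorts than the covariate design provides")
    for p in PROCESSES:
        if covariates.design(p).shape[1] != params.coef(p).shape[0]:
            raise ValueError(
                f"design width {covariates.design(p).shape[1]} does not match "
                f"coefficient length {params.coef(p).shape[0]} for process {p}"
            )
    mu_R = covariates.xR[:T] @ params.zeta
    rho = np.exp(rng.normal(mu_R, params.sigmaP["R"]))
    phi = np.empty((3, T))
    for i, s in enumerate(_SURVIVALS):
        mu = covariates.design(s)[:T] @ params.coef(s)
        phi[i] = expit(rng.normal(mu, params.sigmaP[s]))
    return rho, phi


def propagate_states(nA0: float, rho: np.ndarray, phi: np.ndarray) -> PopulationTrajectory:
    """Deterministic state chain given realized vital rates.

    Per cohort: n_PL = rho * n_A(prev); n_J = phi_PL * n_PL; n_SA = phi_J * n_J;
    n_A = phi_SA * n_SA.  Adults of cohort t seed recruitment of cohort t+1.
    """
    if nA0 <= 0:
        raise ValueError("nA0 must be > 0")
    rho = np.asarray(rho, dtype=float)
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    T = rho.shape[0]
    if phi.shape != (3, T):
        raise ValueError(f"phi must have shape (3, {T})")
    n = np.empty((4, T))
    nA_prev = nA0
    for t in range(T):
        nPL = rho[t] * nA_prev
        nJ = phi[0, t] * nPL
        nSA = phi[1, t] * nJ
        nA = phi[2, t] * nSA
        n[:, t] = (nPL, nJ, nSA, nA)
        nA_prev = nA
    return PopulationTrajectory(nA0=nA0, n=n, rho=rho, phi=phi)


def observe(traj: PopulationTrajectory, obs: ObservationParams, seed=None) -> IndexDataset:
    """Draw lognormal abundance indices around a latent trajectory.

    Each cell is drawn LogNormal(ln(psi_s n_s,t) - sigma^2/2, sigma^2), so the
    index is mean-unbiased for psi_s n_s,t.  The median shift is applied here
    and only here.
    """
    rng = _as_rng(seed)
    T = traj.T
    logvar = obs.logvar_matrix(T)
    if np.isnan(logvar).any():
        bad = [
            (STAGES[i], t + 1)
            for i, t in zip(*np.nonzero(np.isnan(logvar)))
        ]
        raise ValueError(f"unresolved observation noise for cells {bad[:5]}")
    psi = obs.psi_matrix(T)
    logmean = np.log(psi * traj.n) - logvar / 2.0
    z = rng.standard_normal((4, T))
    nhat = np.exp(logmean + np.sqrt(logvar) * z)
    return IndexDataset(nhat=nhat)
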