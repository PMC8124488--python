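"""Joint log-posterior of the ICAR-Poisson areal regression.

The outcome y_i (area-level hospitalization counts) is modeled as

    y_i ~ Poisson(mu_i)
    log mu_i = log tot_i + b1 + b2*airport_i + b3*industry_i + b4*traffic_i
               + b5*construction_i + b6*seaport_i + b7*tunnel_i + s_i

with log tot_i an offset (population denominator, coefficient fixed at 1),
a flat prior on the intercept b1, Normal(0, precision 0.1) priors on
b2..b7, an intrinsic CAR (ICAR) prior on the spatial field s with unit
neighborhood weights, and a Gamma(0.01, 0.01) shape-rate prior on the
ICAR precision tau.  The ICAR prior is improper; identification comes
from the sum-to-zero constraint on s maintained throughout.

Covariates enter exactly as encoded upstream (0/1 presence flags, raw
industrial-area percentage, ordinal 1-5 scores); no standardization, so
exponentiated coefficients are rate ratios on those scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .graphs import AreaGraph

__all__ = [
    "DESIGN_COLUMNS",
    "ModelSpec",
    "ParameterState",
    "build_design",
    "linear_predictor",
    "poisson_loglik",
    "icar_logdensity",
    "log_prior",
    "log_posterior",
]

#: Fixed covariate order for beta[2..7] (1-based model indexing).
DESIGN_COLUMNS = (
    "airport",
    "industry_pct",
    "traffic_score",
    "construction",
    "seaport",
    "tunnel_score",
)

#: Zero-sum tolerance enforced on the spatial field.
SUM_ZERO_TOL = 1e-8


@dataclass(frozen=True)
class ModelSpec:
    """Prior specification.  Defaults reproduce the study's choices.

    ``beta_prior_precision`` is the Normal prior precision for the
    covariate coefficients — the "(0, 0.1)" of BUGS syntax read as mean 0,
    precision 0.1 (variance 10).  Set ``beta_prior_is_variance=True`` to
    reinterpret the same number as a variance.  The tau prior is
    shape-rate Gamma.
    """

    beta_prior_precision: float = 0.1
    tau_prior_shape: float = 0.01
    tau_prior_rate: float = 0.01
    beta_prior_is_variance: bool = False
    covariate_names: tuple[str, ...] = DESIGN_COLUMNS

    def __post_init__(self) -> None:
        if min(self.beta_prior_precision, self.tau_prior_shape, self.tau_prior_rate) <= 0:
            raise ValueError("prior hyperparameters must be positive")
        if len(self.covariate_names) != 6:
            raise ValueError("exactly six covariates are modeled")

    @property
    def beta_precision(self) -> float:
        if self.beta_prior_is_variance:
            return 1.0 / self.beta_prior_precision
        return self.beta_prior_precision


@dataclass
class ParameterState:
    """One point in parameter space: beta (length 7), zero-sum s, tau > 0."""

    beta: np.ndarray
    s: np.ndarray
    tau: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.beta.shape != (7,):
            raise ValueError("beta must have length 7")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if abs(self.s.sum()) > SUM_ZERO_TOL * max(1.0, np.abs(self.s).max()):
            raise ValueError("spatial field must sum to zero")

    def copy(self) -> "ParameterState":
        return ParameterState(self.beta.copy(), self.s.copy(), float(self.tau))


def build_design(covariates: pd.DataFrame) -> np.ndarray:
    """Design matrix (n_areas x 6) in the fixed covariate order."""
    X = covariates[list(DESIGN_COLUMNS)].to_numpy(dtype=float)
    if np.any(~np.isfinite(X)):
        raise ValueError("design matrix contains NaN/Inf")
    return X


def linear_predictor(
    state: ParameterState, X: np.ndarray, offset_log: np.ndarray
) -> np.ndarray:
    """log-mean vector: offset + intercept + covariate effects + spatial field."""
    X = np.asarray(X, dtype=float)
    offset_log = np.asarray(offset_log, dtype=float)
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(offset_log)):
        raise ValueError("NaN/Inf in design or offset")
    if X.shape != (offset_log.size, 6) or state.s.size != offset_log.size:
        raise ValueError("dimension mismatch between design, offset and field")
    return offset_log + state.beta[0] + X @ state.beta[1:] + state.s


def poisson_loglik(y: np.ndarray, mu_log: np.ndarray) -> float:
    """Poisson log-likelihood with log-means ``mu_log`` (full, with y! term)."""
    y = np.asarray(y)
    if np.any(y < 0) or not np.issubdtype(y.dtype, np.integer):
        raise ValueError("counts must be nonnegative integers")
    mu_log = np.asarray(mu_log, dtype=float)
    return float(np.sum(y * mu_log - np.exp(mu_log) - gammaln(y + 1.0)))


def icar_quadform(s: np.ndarray, graph: AreaGraph) -> float:
    """Pairwise quadratic form sum_{i~j, i<j} w_ij (s_i - s_j)^2 = s'(D-W)s."""
    q = 0.0
    for i, j, w in graph.edge_list():
        q += w * (s[i] - s[j]) ** 2
    return float(q)


def icar_logdensity(s: np.ndarray, graph: AreaGraph, tau: float) -> float:
    """Improper ICAR log-density on the sum-to-zero subspace.

    ((N - c)/2) log tau - (tau/2) sum_{i~j} w_ij (s_i - s_j)^2, with c the
    number of connected components (rank correction of the intrinsic
    model); constant terms are omitted consistently.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    s = np.asarray(s, dtype=float)
    if s.size != graph.n_areas:
        raise ValueError("field length must match the graph")
    if abs(s.sum()) > SUM_ZERO_TOL * max(1.0, np.abs(s).max()):
        raise ValueError("field must be centered (sum-to-zero contract)")
    rank = graph.n_areas - graph.n_components
    return 0.5 * rank * np.log(tau) - 0.5 * tau * icar_quadform(s, graph)


def log_prior(state: ParameterState, spec: ModelSpec) -> float:
    """Log-prior of (beta, tau); the ICAR term on s is added separately.

    Flat intercept contributes 0.  Covariate coefficients get full Normal
    log-densities; tau gets the unnormalized Gamma shape-rate kernel
    (a-1) log tau - b tau.
    """
    p = spec.beta_precision
    b = state.beta[1:]
    normal_term = 0.5 * b.size * np.log(p / (2 * np.pi)) - 0.5 * p * np.sum(b**2)
    gamma_term = (spec.tau_prior_shape - 1.0) * np.log(state.tau) - (
        spec.tau_prior_rate * state.tau
    )
    return float(normal_term + gamma_term)


def log_posterior(
    state: ParameterState,
    y: np.ndarray,
    X: np.ndarray,
    offset_log: np.ndarray,
    graph: AreaGraph,
    spec: ModelSpec,
) -> float:
    """Unnormalized log-posterior: likelihood + ICAR field prior + priors."""
    mu_log = linear_predictor(state, X, offset_log)
    return (
        poisson_loglik(y, mu_log)
        + icar_logdensity(state.s, graph, state.tau)
        + log_prior(state, spec)
    )
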