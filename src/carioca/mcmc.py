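"""Metropolis-within-Gibbs sampler for the ICAR-Poisson regression.

Run protocol mirrors the study: five chains, thinning of 10, burn-in
chosen per analysis group, convergence judged downstream by the
Brooks-Gelman-Rubin diagnostic.  Within a chain one iteration is

  1. componentwise Gaussian random-walk Metropolis on beta[1..7]
  2. blocked single-site random-walk Metropolis on the spatial field s
     (sites grouped by graph coloring: non-adjacent sites have
     conditionally independent full conditionals, so a within-color
     parallel update equals a sequential sweep), followed by re-centering
     of s with the subtracted mean absorbed into the intercept
  3. an exact conjugate Gibbs draw of the ICAR precision tau

Proposal scales adapt toward a 0.2-0.5 acceptance rate during burn-in
only and are frozen afterwards, preserving the stationary law.  Each
chain owns an independent RNG stream seeded ``base_seed + chain_index``;
runs are bit-reproducible.

Randomness draw order (relied on by replay-style tests): update_beta
draws 7 normals then 7 uniforms; update_s draws N normals then N
uniforms; update_tau draws one gamma variate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .graphs import AreaGraph
from .model import ModelSpec, ParameterState, icar_quadform, log_posterior

__all__ = [
    "McmcConfig",
    "ChainSet",
    "CONVERGENCE_BURNIN",
    "init_chains",
    "update_beta",
    "update_beta_joint",
    "update_s",
    "update_tau",
    "tau_conditional",
    "run_mcmc",
]

logger = logging.getLogger(__name__)

#: Burn-in defaults per analysis group, mapping the study's iteration
#: counts at which convergence was judged reached for each stratum.
CONVERGENCE_BURNIN = {
    "total": 15_000,
    "male": 22_000,
    "female": 11_000,
    "age_0_4": 28_000,
    "age_15_59": 5_000,
    "age_60_plus": 14_000,
}

#: Post-burn-in draws kept per chain by default in paper-protocol configs.
DEFAULT_KEPT_PER_CHAIN = 10_000


@dataclass
class McmcConfig:
    """Sampler configuration.

    ``fixed_tau`` pins the ICAR precision (skipping its Gibbs update),
    used for oracle comparisons.  ``burn_in`` counts adaptation
    iterations; kept draws number ``(n_iterations - burn_in) // thin``
    per chain.
    """

    n_iterations: int
    burn_in: int
    n_chains: int = 5
    thin: int = 10
    base_seed: int = 0
    fixed_tau: float | None = None
    init_beta_sd: float = 2.0
    tau_init_cycle: tuple[float, ...] = (0.1, 1.0, 10.0)
    initial_scale: float = 0.2
    adapt_interval: int = 50
    accept_low: float = 0.2
    accept_high: float = 0.5
    center_design: bool = True
    joint_beta_updates: bool = True

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need at least two chains (convergence diagnostics)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("require 0 <= burn_in < n_iterations")
        if self.fixed_tau is not None and self.fixed_tau <= 0:
            raise ValueError("fixed_tau must be positive")

    @property
    def n_kept(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


@dataclass
class ChainSet:
    """Thinned post-burn-in draws: array (n_chains, n_kept, n_params).

    Parameter order: ``beta[1]``, the six covariate effects by name,
    ``s[<area_id>]`` per area, ``tau``.
    """

    draws: np.ndarray
    param_names: list[str]
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.draws.ndim != 3 or self.draws.shape[2] != len(self.param_names):
            raise ValueError("draws must be (n_chains, n_kept, n_params)")
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("non-finite draws")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_kept(self) -> int:
        return self.draws.shape[1]

    def get(self, parameter: str) -> np.ndarray:
        """Draws of one parameter, shape (n_chains, n_kept)."""
        try:
            k = self.param_names.index(parameter)
        except ValueError as exc:
            raise KeyError(f"unknown parameter {parameter!r}") from exc
        return self.draws[:, :, k]

    def pooled(self, parameter: str) -> np.ndarray:
        return self.get(parameter).reshape(-1)

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: chain, iter (kept index), parameter, value."""
        n_c, n_k, n_p = self.draws.shape
        chain = np.repeat(np.arange(n_c), n_k * n_p)
        it = np.tile(np.repeat(np.arange(n_k), n_p), n_c)
        par = np.tile(np.array(self.param_names, dtype=object), n_c * n_k)
        return pd.DataFrame(
            {"chain": chain, "iter": it, "parameter": par,
             "value": self.draws.reshape(-1)}
        )

    def to_csv(self, path, provenance: dict | None = None) -> None:
        from .io import write_csv_with_provenance

        write_csv_with_provenance(self.to_dataframe(), path, provenance)

    @classmethod
    def from_csv(cls, path) -> "ChainSet":
        df = pd.read_csv(path, comment="#")
        names = list(dict.fromkeys(df["parameter"]))
        n_c = df["chain"].nunique()
        n_k = df["iter"].nunique()
        order = {p: k for k, p in enumerate(names)}
        df = df.sort_values(
            ["chain", "iter", "parameter"],
            key=lambda col: col.map(order) if col.name == "parameter" else col,
            kind="stable",
        )
        draws = df["value"].to_numpy().reshape(n_c, n_k, len(names))
        return cls(draws, names)


def _param_names(spec: ModelSpec, graph: AreaGraph) -> list[str]:
    return (
        ["beta[1]"]
        + list(spec.covariate_names)
        + [f"s[{a}]" for a in graph.area_ids]
        + ["tau"]
    )


def _init_state(rng: np.random.Generator, chain: int, config: McmcConfig,
                n_areas: int) -> ParameterState:
    beta = rng.normal(0.0, config.init_beta_sd, size=7)
    if config.fixed_tau is not None:
        tau = config.fixed_tau
    else:
        tau = config.tau_init_cycle[chain % len(config.tau_init_cycle)]
    return ParameterState(beta, np.zeros(n_areas), tau)


def init_chains(config: McmcConfig, spec: ModelSpec, graph: AreaGraph
                ) -> list[ParameterState]:
    """Overdispersed deterministic starts: beta ~ N(0, init_beta_sd^2) per
    chain stream, s = 0, tau cycled through ``tau_init_cycle``."""
    return [
        _init_state(np.random.default_rng(config.base_seed + c), c, config,
                    graph.n_areas)
        for c in range(config.n_chains)
    ]


def update_beta(
    state: ParameterState,
    y: np.ndarray,
    X: np.ndarray,
    offset_log: np.ndarray,
    spec: ModelSpec,
    rng: np.random.Generator,
    scales: np.ndarray,
) -> np.ndarray:
    """Componentwise random-walk Metropolis on beta (in place).

    Returns a boolean acceptance vector of length 7.  The spatial-field
    and tau terms cancel in every acceptance ratio, so only the Poisson
    likelihood and the Normal prior enter.
    """
    z = rng.standard_normal(7)
    u = rng.random(7)
    eta = offset_log + state.beta[0] + X @ state.beta[1:] + state.s
    exp_eta = np.exp(eta)
    accepted = np.zeros(7, dtype=bool)
    p = spec.beta_precision
    for k in range(7):
        delta = scales[k] * z[k]
        x_k = 1.0 if k == 0 else X[:, k - 1]
        d_eta = delta * x_k
        new_exp = exp_eta * np.exp(d_eta)
        d_ll = float(np.sum(y * d_eta) - np.sum(new_exp - exp_eta))
        if k == 0:
            d_prior = 0.0  # flat intercept
        else:
            b_old = state.beta[k]
            d_prior = -0.5 * p * ((b_old + delta) ** 2 - b_old**2)
        if np.log(u[k]) < d_ll + d_prior:
            state.beta[k] += delta
            eta = eta + d_eta
            exp_eta = new_exp
            accepted[k] = True
    return accepted


def update_beta_joint(
    state: ParameterState,
    y: np.ndarray,
    X: np.ndarray,
    offset_log: np.ndarray,
    spec: ModelSpec,
    rng: np.random.Generator,
    chol: np.ndarray,
) -> bool:
    """Joint Gaussian random-walk Metropolis step on all of beta (in place).

    Proposal covariance is ``chol @ chol.T`` — during burn-in an adapted
    estimate of the posterior beta covariance (classic adaptive
    Metropolis), frozen afterwards.  Complements the componentwise sweep:
    it moves along posterior ridges created by collinear covariates.
    Draws 7 normals then 1 uniform.  Returns acceptance.
    """
    z = rng.standard_normal(7)
    u = rng.random()
    delta = chol @ z
    eta = offset_log + state.beta[0] + X @ state.beta[1:] + state.s
    d_eta = delta[0] + X @ delta[1:]
    d_ll = float(np.sum(y * d_eta) - np.sum(np.exp(eta + d_eta) - np.exp(eta)))
    p = spec.beta_precision
    b_old = state.beta[1:]
    b_new = b_old + delta[1:]
    d_prior = -0.5 * p * float(np.sum(b_new**2) - np.sum(b_old**2))
    if np.log(u) < d_ll + d_prior:
        state.beta += delta
        return True
    return False


def update_s(
    state: ParameterState,
    y: np.ndarray,
    offset_log_eta_base: np.ndarray,
    color_blocks: Sequence[tuple[np.ndarray, sp.csr_matrix]],
    degrees: np.ndarray,
    rng: np.random.Generator,
    scale: float,
) -> int:
    """Blocked single-site Metropolis sweep over the spatial field (in place).

    ``offset_log_eta_base`` is the non-spatial part of the linear predictor
    (offset + intercept + covariate effects).  For each color class the
    sites are updated jointly — valid because non-adjacent sites are
    conditionally independent given the rest.  After the sweep s is
    re-centered and the subtracted mean absorbed into the intercept,
    maintaining the sum-to-zero identification without changing the
    fitted log-means.  Returns the number of accepted site moves.
    """
    n = state.s.size
    z = rng.standard_normal(n)
    u = rng.random(n)
    tau = state.tau
    n_acc = 0
    for idx, W_rows in color_blocks:
        s_old = state.s[idx]
        delta = scale * z[idx]
        s_new = s_old + delta
        eta_old = offset_log_eta_base[idx] + s_old
        # likelihood: site-local Poisson terms
        d_ll = y[idx] * delta - (np.exp(eta_old + delta) - np.exp(eta_old))
        # ICAR: -tau/2 * [deg*(s'^2 - s^2) - 2*(s' - s)*sum_j w_ij s_j]
        w_sum = W_rows @ state.s
        d_icar = -0.5 * tau * (
            degrees[idx] * (s_new**2 - s_old**2) - 2.0 * delta * w_sum
        )
        acc = np.log(u[idx]) < d_ll + d_icar
        state.s[idx] = np.where(acc, s_new, s_old)
        n_acc += int(acc.sum())
    m = state.s.mean()
    state.s -= m
    state.beta[0] += m
    return n_acc


def tau_conditional(
    s: np.ndarray, graph: AreaGraph, spec: ModelSpec
) -> tuple[float, float]:
    """Shape and rate of the conjugate full conditional of tau:
    Gamma(shape + (N - c)/2, rate + SS/2) with SS the ICAR quadratic form."""
    rank = graph.n_areas - graph.n_components
    shape = spec.tau_prior_shape + 0.5 * rank
    rate = spec.tau_prior_rate + 0.5 * icar_quadform(np.asarray(s, float), graph)
    return shape, rate


def update_tau(
    state: ParameterState,
    graph: AreaGraph,
    spec: ModelSpec,
    rng: np.random.Generator,
) -> float:
    """Exact Gibbs draw of the ICAR precision (in place); returns new tau."""
    shape, rate = tau_conditional(state.s, graph, spec)
    state.tau = float(rng.gamma(shape, 1.0 / rate))
    return state.tau


def _adapt(scale: float, rate: float, config: McmcConfig) -> float:
    if rate < config.accept_low:
        return scale * 0.7
    if rate > config.accept_high:
        return scale * 1.4
    return scale


def run_mcmc(
    y: np.ndarray,
    X: np.ndarray,
    offset_log: np.ndarray,
    graph: AreaGraph,
    spec: ModelSpec,
    config: McmcConfig,
) -> ChainSet:
    """Run the full Metropolis-within-Gibbs protocol; returns kept draws.

    Aborts with a diagnostic if the log-posterior is non-finite at any
    chain's start.  Acceptance rates (post burn-in) and frozen proposal
    scales per chain are reported in ``ChainSet.info``.
    """
    y = np.asarray(y)
    X = np.asarray(X, dtype=float)
    offset_log = np.asarray(offset_log, dtype=float)
    n = graph.n_areas
    # Internal exact reparameterization: sampling runs on the centered
    # design with intercept b1' = b1 + mean(X) @ beta[2:], which decorrelates
    # the intercept from the covariate effects (flat prior and Jacobian 1, so
    # the posterior is unchanged); draws are transformed back before storage.
    X_mean = X.mean(axis=0) if config.center_design else np.zeros(X.shape[1])
    Xc = X - X_mean
    W = sp.csr_matrix(graph.adjacency_matrix())
    degrees = graph.degrees
    color_blocks = [(idx, sp.csr_matrix(W[idx])) for idx in graph.coloring()]
    names = _param_names(spec, graph)
    kept = np.empty((config.n_chains, config.n_kept, len(names)))
    info: dict = {"acceptance": [], "scales": [], "seeds": []}

    for c in range(config.n_chains):
        seed = config.base_seed + c
        rng = np.random.default_rng(seed)
        state = _init_state(rng, c, config, n)
        lp0 = log_posterior(state, y, Xc, offset_log, graph, spec)
        if not np.isfinite(lp0):
            raise RuntimeError(
                f"chain {c}: non-finite log-posterior at initialization "
                f"(lp={lp0}); check offsets and covariates"
            )
        beta_scales = np.full(7, config.initial_scale)
        s_scale = config.initial_scale
        joint_scale = 1.0
        joint_chol = config.initial_scale / np.sqrt(7) * np.eye(7)
        # Welford accumulators for the adaptive joint-beta proposal
        w_count, w_mean, w_m2 = 0, np.zeros(7), np.zeros((7, 7))
        win_beta = np.zeros(7)
        win_s = 0
        win_joint = 0
        win_iters = 0
        post_acc_beta = np.zeros(7)
        post_acc_s = 0.0
        post_acc_joint = 0.0
        k_out = 0
        for it in range(config.n_iterations):
            a_b = update_beta(state, y, Xc, offset_log, spec, rng, beta_scales)
            a_j = False
            if config.joint_beta_updates:
                a_j = update_beta_joint(
                    state, y, Xc, offset_log, spec, rng, joint_scale * joint_chol
                )
            eta_base = offset_log + state.beta[0] + Xc @ state.beta[1:]
            a_s = update_s(state, y, eta_base, color_blocks, degrees, rng, s_scale)
            if config.fixed_tau is None:
                update_tau(state, graph, spec, rng)
            in_burn = it < config.burn_in
            if in_burn:
                w_count += 1
                d = state.beta - w_mean
                w_mean += d / w_count
                w_m2 += np.outer(d, state.beta - w_mean)
                win_beta += a_b
                win_s += a_s
                win_joint += a_j
                win_iters += 1
                if win_iters == config.adapt_interval:
                    for k in range(7):
                        beta_scales[k] = _adapt(
                            beta_scales[k], win_beta[k] / win_iters, config
                        )
                    s_scale = _adapt(s_scale, win_s / (win_iters * n), config)
                    joint_scale = _adapt(joint_scale, win_joint / win_iters, config)
                    if config.joint_beta_updates and w_count > 20 * 7:
                        cov = w_m2 / (w_count - 1)
                        cov = (2.38**2 / 7) * cov + 1e-10 * np.eye(7)
                        joint_chol = np.linalg.cholesky(cov)
                    win_beta[:] = 0.0
                    win_s = 0
                    win_joint = 0
                    win_iters = 0
            else:
                post_acc_beta += a_b
                post_acc_s += a_s
                post_acc_joint += a_j
                if (it - config.burn_in) % config.thin == config.thin - 1:
                    kept[c, k_out, 0:7] = state.beta
                    kept[c, k_out, 0] -= X_mean @ state.beta[1:]  # uncenter b1
                    kept[c, k_out, 7 : 7 + n] = state.s
                    kept[c, k_out, 7 + n] = state.tau
                    k_out += 1
        n_post = config.n_iterations - config.burn_in
        info["acceptance"].append(
            {
                "beta": (post_acc_beta / max(n_post, 1)).tolist(),
                "beta_joint": post_acc_joint / max(n_post, 1),
                "s": post_acc_s / max(n_post * n, 1),
            }
        )
        info["scales"].append(
            {"beta": beta_scales.tolist(), "s": float(s_scale),
             "beta_joint": float(joint_scale)}
        )
        info["seeds"].append(seed)
        logger.info(
            "chain %d done: mean beta acceptance %.3f, s acceptance %.3f",
            c,
            float(np.mean(post_acc_beta / max(n_post, 1))),
            post_acc_s / max(n_post * n, 1),
        )
    info["config"] = {
        "n_iterations": config.n_iterations,
        "burn_in": config.burn_in,
        "thin": config.thin,
        "n_chains": config.n_chains,
        "base_seed": config.base_seed,
        "fixed_tau": config.fixed_tau,
    }
    return ChainSet(kept[:, : config.n_kept], names, info)
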