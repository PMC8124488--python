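"""Convergence assessment and posterior summarization.

Implements the Brooks-Gelman-Rubin interval diagnostic (the red/green/blue
plot: pooled-chain central-interval width, mean within-chain width, and
their ratio, which converges to 1 at stationarity), the scalar potential
scale reduction factor, and the exponentiated posterior summary table
(rate-ratio scale: exp of the posterior mean of each coefficient, SD of
the exponentiated draws, and the exponentiated 2.5/97.5 percentiles; an
interval excluding 1 flags a credible association).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcmc import ChainSet
from .model import ModelSpec

__all__ = [
    "BgrSeries",
    "bgr",
    "psrf",
    "summarize",
    "flag_credible",
    "PSRF_WARN_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: PSRF above which summarize() warns that chains look unconverged.
PSRF_WARN_THRESHOLD = 1.1


@dataclass
class BgrSeries:
    """BGR diagnostic trajectory over increasing prefixes of kept draws.

    ``pooled_width`` is the "green" line (central-interval width of the
    pooled chains), ``mean_within_width`` the "blue" line (mean width
    within individual chains), ``ratio`` the "red" line (green/blue; 1
    by convention when both widths are 0).
    """

    checkpoints: np.ndarray
    pooled_width: np.ndarray
    mean_within_width: np.ndarray
    ratio: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "checkpoint": self.checkpoints,
                "pooled_width": self.pooled_width,
                "mean_within_width": self.mean_within_width,
                "ratio": self.ratio,
            }
        )

    def plot(self, ax=None, title: str | None = None):
        """Red/green/blue BGR plot (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.checkpoints, self.ratio, color="red", label="ratio")
        ax.plot(self.checkpoints, self.pooled_width, color="green",
                label="pooled width")
        ax.plot(self.checkpoints, self.mean_within_width, color="blue",
                label="mean within width")
        ax.axhline(1.0, color="grey", lw=0.5, ls=":")
        ax.set_xlabel("kept draws")
        if title:
            ax.set_title(title)
        ax.legend()
        return ax


def _central_width(x: np.ndarray, mass: float) -> float:
    alpha = (1.0 - mass) / 2.0
    lo, hi = np.quantile(x, [alpha, 1.0 - alpha])
    return float(hi - lo)


def bgr(
    chains: ChainSet,
    parameter: str,
    n_checkpoints: int = 20,
    interval: float = 0.80,
) -> BgrSeries:
    """Brooks-Gelman-Rubin interval diagnostic for one parameter.

    At each checkpoint t the first t kept draws of every chain are used:
    green = width of the central ``interval`` mass of the pooled draws,
    blue = mean central-interval width across chains, red = green/blue.
    Requires at least two chains and 20 kept draws.
    """
    draws = chains.get(parameter)
    m, n = draws.shape
    if m < 2:
        raise ValueError("BGR needs at least two chains")
    if n < 20:
        raise ValueError("BGR needs at least 20 kept draws")
    ts = np.unique(np.linspace(max(2, n // n_checkpoints), n,
                               min(n_checkpoints, n), dtype=int))
    pooled = np.empty(ts.size)
    within = np.empty(ts.size)
    ratio = np.empty(ts.size)
    for k, t in enumerate(ts):
        prefix = draws[:, :t]
        pooled[k] = _central_width(prefix.reshape(-1), interval)
        within[k] = float(
            np.mean([_central_width(prefix[c], interval) for c in range(m)])
        )
        if within[k] > 0:
            ratio[k] = pooled[k] / within[k]
        elif pooled[k] == 0:
            ratio[k] = 1.0  # degenerate: identical constant chains
        else:
            ratio[k] = np.inf
    return BgrSeries(ts, pooled, within, ratio)


def psrf(chains: ChainSet, parameter: str) -> float:
    """Classical potential scale reduction factor (between/within variance).

    sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain variance
    and B/n the variance of chain means; approaches 1 under convergence
    and is invariant under a common affine transform of all draws.
    """
    draws = chains.get(parameter)
    m, n = draws.shape
    if m < 2:
        raise ValueError("PSRF needs at least two chains")
    if n < 2:
        raise ValueError("PSRF needs at least two kept draws")
    W = float(np.mean(np.var(draws, axis=1, ddof=1)))
    B_over_n = float(np.var(np.mean(draws, axis=1), ddof=1))
    if W == 0:
        return 1.0 if B_over_n == 0 else np.inf
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


def summarize(chains: ChainSet, spec: ModelSpec) -> pd.DataFrame:
    """Exponentiated posterior summary per explanatory variable.

    Pooled over chains, for each covariate coefficient: ``mean`` =
    exp(mean of the draws), ``sd`` = SD of the exponentiated draws,
    ``p2_5``/``p97_5`` = exp of the 2.5/97.5 percentiles of the draws
    (rate-ratio scale).  Warns when any covariate PSRF exceeds
    ``PSRF_WARN_THRESHOLD``.
    """
    if chains.n_kept == 0:
        raise ValueError("empty chains")
    rows = {}
    for name in spec.covariate_names:
        r = psrf(chains, name)
        if r > PSRF_WARN_THRESHOLD:
            logger.warning(
                "parameter %s: PSRF %.3f > %.2f — chains may not have converged",
                name, r, PSRF_WARN_THRESHOLD,
            )
        b = chains.pooled(name)
        lo, hi = np.quantile(b, [0.025, 0.975])
        rows[name] = {
            "mean": float(np.exp(b.mean())),
            "sd": float(np.std(np.exp(b), ddof=1)),
            "p2_5": float(np.exp(lo)),
            "p97_5": float(np.exp(hi)),
            "psrf": float(r),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "variable"
    return out


def flag_credible(summary: pd.DataFrame) -> pd.Series:
    """True where the 95% credible interval excludes the unit rate ratio."""
    return ((summary["p2_5"] > 1.0) | (summary["p97_5"] < 1.0)).rename("credible")
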