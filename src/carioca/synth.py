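"""Synthetic areal data with the statistical structure the analysis assumes.

Generates intrinsic-CAR spatial fields, Poisson count panels under the
log-linear predictor with population offsets, the packaged 10-planning-area
covariate fixture, and the data pathologies the preprocessing stage must
handle (an epidemic-year spike; a multi-year facility-closure gap).

Seed policy: every operation takes an explicit integer seed; pipelines
derive stream seeds as ``base_seed + stream_index`` so runs are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .graphs import AreaGraph, make_lattice_graph, read_gal

__all__ = [
    "SimulationTruth",
    "sample_icar_field",
    "simulate_counts",
    "make_rio_fixture",
    "simulate_panel_with_artifacts",
    "make_lattice_graph",
    "STRATA",
    "DEFAULT_YEARS",
]

#: Closed set of outcome strata: total population, each sex, three age bands.
STRATA = ("total", "male", "female", "age_0_4", "age_15_59", "age_60_plus")

#: Study window for the regression stage.
DEFAULT_YEARS = tuple(range(2013, 2018))

#: Default multiplier applied to an epidemic year's counts.
EPIDEMIC_FACTOR = 2.0


@dataclass
class SimulationTruth:
    """Ground-truth parameters behind a synthetic dataset.

    ``beta`` is the length-7 coefficient vector (intercept followed by the
    six pollution-source effects); ``sigma_s`` the marginal spatial SD scale
    with precision ``tau = 1/sigma_s**2``; ``s`` the zero-sum spatial field.
    """

    beta: np.ndarray
    sigma_s: float
    s: np.ndarray
    seed: int
    tau: float = field(init=False)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.beta.shape != (7,):
            raise ValueError("beta must have length 7 (intercept + 6 covariates)")
        if self.sigma_s < 0:
            raise ValueError("sigma_s must be nonnegative")
        if abs(self.s.sum()) > 1e-10:
            raise ValueError("spatial field must sum to zero")
        self.tau = np.inf if self.sigma_s == 0 else 1.0 / self.sigma_s**2


def sample_icar_field(
    graph: AreaGraph, tau: float, seed: int, size: int | None = None
) -> np.ndarray:
    """Draw from the intrinsic CAR distribution on the sum-to-zero subspace.

    Uses the spectral construction: for Laplacian eigenpairs
    ``(lambda_k, v_k)`` with ``lambda_k > 0``, the field is
    ``s = sum_k z_k v_k`` with independent ``z_k ~ N(0, 1/(tau*lambda_k))``.
    Exact at O(N^3), which is fine at areal-study scale.

    Returns shape ``(n_areas,)``, or ``(size, n_areas)`` when ``size`` is
    given.  Each draw sums to zero within 1e-10 by construction.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if graph.n_components != 1:
        raise ValueError("intrinsic CAR sampling requires a connected graph")
    lam, vec = np.linalg.eigh(graph.laplacian())
    positive = lam > 1e-10 * lam.max()
    lam, vec = lam[positive], vec[:, positive]
    rng = np.random.default_rng(seed)
    n_draws = 1 if size is None else size
    z = rng.standard_normal((n_draws, lam.size)) / np.sqrt(tau * lam)
    s = z @ vec.T
    s -= s.mean(axis=1, keepdims=True)  # clear rounding residue; exact zero-sum
    return s[0] if size is None else s


def simulate_counts(
    covariates: pd.DataFrame,
    truth: SimulationTruth,
    seed: int,
    years: tuple[int, ...] = DEFAULT_YEARS,
    stratum: str = "total",
) -> pd.DataFrame:
    """Simulate a Poisson hospitalization count panel.

    ``covariates`` must carry the six design columns (``airport``,
    ``industry_pct``, ``traffic_score``, ``construction``, ``seaport``,
    ``tunnel_score``) plus the offset denominator ``tot`` (person-period
    population, split evenly across ``years``).  Counts follow
    ``y ~ Poisson(exp(log tot + beta[0] + X beta[1:] + s))`` and are
    reproducible given ``seed``.
    """
    from .model import DESIGN_COLUMNS  # local import avoids a cycle

    if "tot" not in covariates.columns:
        raise ValueError("covariates must include the offset column 'tot'")
    tot = covariates["tot"].to_numpy(dtype=float)
    if np.any(tot <= 0):
        raise ValueError("offsets tot must be positive")
    X = covariates[list(DESIGN_COLUMNS)].to_numpy(dtype=float)
    if np.any(~np.isfinite(X)):
        raise ValueError("covariates contain NaN/Inf")
    if len(covariates) != truth.s.size:
        raise ValueError("covariate rows must align with the spatial field")
    eta = truth.beta[0] + X @ truth.beta[1:] + truth.s
    rng = np.random.default_rng(seed)
    rows = []
    for year in years:
        mu = (tot / len(years)) * np.exp(eta)
        y = rng.poisson(mu)
        for area_id, count in zip(covariates["area_id"], y):
            rows.append((area_id, year, stratum, int(count)))
    return pd.DataFrame(rows, columns=["area_id", "year", "stratum", "count"])


# --- packaged 10-planning-area fixture -------------------------------------

def make_rio_fixture() -> tuple[AreaGraph, pd.DataFrame]:
    """Load the packaged 10-planning-area covariate fixture.

    Covariates reproduce the published air-pollution-source table for the
    ten planning areas (airport, seaport, construction as 0/1 presence;
    industrial-district area coverage in percent; traffic and tunnel
    exposure as printed categories plus ordinal 1-5 codebook scores:
    traffic "0-55"→1 ... ">=96"→5, tunnels "0"→1 ... ">30"→5).

    The adjacency is a declared package convention (a ring with chords
    approximating the city map), shipped as a GAL file; it is NOT derived
    from GIS contiguity.
    """
    data = resources.files("carioca.data")
    with resources.as_file(data / "rio_pa_adjacency.gal") as p:
        graph = read_gal(p)
    with resources.as_file(data / "rio_pa_covariates.csv") as p:
        covariates = pd.read_csv(p, dtype={"area_id": str})
    covariates = covariates.set_index("area_id").loc[graph.area_ids].reset_index()
    return graph, covariates


def simulate_panel_with_artifacts(
    base: pd.DataFrame,
    epidemic_year: int | None = None,
    closure: tuple[str, tuple[int, int], tuple[int, int]] | None = None,
    epidemic_factor: float = EPIDEMIC_FACTOR,
) -> pd.DataFrame:
    """Inject the study's data pathologies into a count panel.

    ``epidemic_year`` counts are scaled by ``epidemic_factor`` (an
    influenza-like spike).  ``closure = (area_id, (y0, m0), (y1, m1))``
    marks a facility closed from month ``m0`` of ``y0`` through month
    ``m1`` of ``y1`` inclusive (months 1-12); the area's counts in each
    affected year are reduced proportionally to months closed (a 12-month
    closure zeroes the year).  Counts are rounded half-to-even back to
    integers.
    """
    panel = base.copy()
    years = set(panel["year"].unique())
    if epidemic_year is not None:
        if epidemic_year not in years:
            raise ValueError(f"epidemic year {epidemic_year} not in panel")
        mask = panel["year"] == epidemic_year
        panel.loc[mask, "count"] = np.rint(
            panel.loc[mask, "count"] * epidemic_factor
        ).astype(int)
    if closure is not None:
        area_id, (y0, m0), (y1, m1) = closure
        if area_id not in set(panel["area_id"].unique()):
            raise ValueError(f"closure area {area_id!r} not in panel")
        if not (1 <= m0 <= 12 and 1 <= m1 <= 12):
            raise ValueError("closure months must be in 1..12")
        if (y0, m0) > (y1, m1):
            return panel  # zero-length closure: no-op
        if y0 not in years or y1 not in years:
            raise ValueError("closure interval must lie within panel years")
        for year in range(y0, y1 + 1):
            lo = m0 if year == y0 else 1
            hi = m1 if year == y1 else 12
            months_closed = hi - lo + 1
            mask = (panel["area_id"] == area_id) & (panel["year"] == year)
            panel.loc[mask, "count"] = np.rint(
                panel.loc[mask, "count"] * (1 - months_closed / 12)
            ).astype(int)
    return panel
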