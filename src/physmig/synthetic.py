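"""Synthetic prefecture-panel generator with known migration ground truth.

The generator emulates the data-generating process the residual estimator
assumes: a closed national system of practicing physicians in which each
prefecture gains an annual licensing cohort, loses physicians to death and
retirement, and exchanges net migrants with the rest of the country. Stocks
are observed only at survey years (biennial by default, mirroring the
underlying survey cadence), licensing cohorts are annual, and the truth
object records the exact cumulative flows so every downstream stage can be
tested for recovery without any external data.

Migration is modelled at the resolution the estimator identifies: net annual
flows per prefecture, not origin-destination matrices. Each year prefecture
*i* receives a net-outflow propensity ``gamma0 + gamma_newppr * newPPR_i``
plus Gaussian noise, and the propensities are centered across prefectures so
national net migration is exactly zero (domestic migration is closed; an
uncentered flow would masquerade as attrition in the national residual).

Attrition supports two bases:

``"stock"`` (default)
    Binomial draws on the current stock (expectation ``rate * stock`` in
    deterministic mode). Realistic; under it the estimator's proportional
    allocation is only approximately correct, which is the point of the
    bias experiments.

``"mean_stock"`` (deterministic mode only)
    Each prefecture loses a constant ``rate * (its own window-mean observed
    stock)`` per year, solved in closed form, so the estimator's identifying
    assumption — per-prefecture attrition proportional to mean observed
    stock under a uniform rate — holds *exactly* and estimated net migrants
    must reproduce the truth to floating-point accuracy. This is the oracle
    configuration for validating the estimator.

The ``deterministic`` flag replaces process noise (Poisson licensing,
binomial attrition, migration noise) with expectations; per-prefecture
structural heterogeneity (licensing rates, covariates, initial stocks)
remains seeded-random, since identical prefectures would make recovery
tests vacuous.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    COVARIATE_NAMES,
    PrefectureCovariates,
    PrefecturePanel,
    PrefectureRecord,
)
from .errors import ValidationError

logger = logging.getLogger(__name__)

# --- calibration of the default ("paperlike") study conditions -------------
# National mean annual flows over a 20-year, 47-prefecture window:
# 7416 newly licensed, 3382 deceased/retired, 4034 net increase per year.
MEAN_ANNUAL_NEW_LICENSED = 7416.0
MEAN_ANNUAL_ATTRITION = 3382.0
MEAN_ANNUAL_INCREASE = 4034.0
#: stated mean national practicing stock over the window, used to convert the
#: national attrition flow into a per-physician annual rate.
MEAN_NATIONAL_STOCK = 250_000.0

_N_PREFECTURES = 47
_BASELINE_YEAR = 1994
_FINAL_YEAR = 2014
_N_YEARS = _FINAL_YEAR - _BASELINE_YEAR

#: per-prefecture annual licensing rate range; the mean matches the national
#: licensing flow: 47 * (61 + max) / 2 = 7416.
_RATE_MIN = 61.0
_RATE_MAX = 2.0 * MEAN_ANNUAL_NEW_LICENSED / _N_PREFECTURES - _RATE_MIN

#: implied initial national stock: mean stock minus half-window growth
#: (attrition acts on start-of-year stocks, hence the 9.5-year offset).
_INITIAL_TOTAL = MEAN_NATIONAL_STOCK - (_N_YEARS / 2 - 0.5) * MEAN_ANNUAL_INCREASE
_STOCK_MIN = 1500.0
_STOCK_MAX = 2.0 * _INITIAL_TOTAL / _N_PREFECTURES - _STOCK_MIN

#: annual newly licensed physicians per 100,000 population, observed range.
_NEWPPR_RANGE = (1.5, 16.5)

# Plausible ranges for covariates not derived from the simulated stocks.
_COVARIATE_RANGES = {
    "physician_mean_age": (48.0, 53.0),
    "female_ratio": (0.12, 0.28),
    "pop_density": (250.0, 4200.0),
    "unemployment": (0.02, 0.05),
    "aged_ratio": (0.20, 0.31),
    "income": (2.4e6, 3.4e6),
}

TRUTH_COLUMNS = (
    "prefecture",
    "true_net_migrants",
    "true_attrition",
    "true_migration_ratio",
)


@dataclass(frozen=True)
class MigrationModel:
    """Covariate-driven net-outflow propensity.

    Annual expected net outflow of prefecture *i*, before centering, is
    ``gamma0 + gamma_newppr * newPPR_i`` physicians; ``noise_sd`` is the sd
    of the annual Gaussian disturbance (physicians/year). A positive
    ``gamma_newppr`` makes high-licensing prefectures net exporters.
    """

    gamma0: float = 0.0
    gamma_newppr: float = 8.0
    noise_sd: float = 12.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic panel.

    Defaults reproduce the calibrated national conditions: 47 prefectures
    over 1994-2014 with ~7416 licensed, ~3382 attrited and ~4034 net increase
    per year in expectation, biennial surveys.
    """

    n_prefectures: int = _N_PREFECTURES
    baseline_year: int = _BASELINE_YEAR
    final_year: int = _FINAL_YEAR
    initial_stock_range: tuple[float, float] = (_STOCK_MIN, _STOCK_MAX)
    licensing_rate_range: tuple[float, float] = (_RATE_MIN, _RATE_MAX)
    attrition_rate: float | tuple[float, ...] = (
        MEAN_ANNUAL_ATTRITION / MEAN_NATIONAL_STOCK
    )
    migration_model: MigrationModel = field(default_factory=MigrationModel)
    new_licensed_ppr_range: tuple[float, float] = _NEWPPR_RANGE
    survey_interval: int = 2
    deterministic: bool = False
    attrition_base: str = "stock"  # "stock" | "mean_stock"
    seed: int = 0

    def validate(self) -> None:
        if self.n_prefectures < 2:
            raise ValidationError("n_prefectures must be >= 2")
        if self.baseline_year >= self.final_year:
            raise ValidationError("baseline_year must precede final_year")
        if self.survey_interval < 1:
            raise ValidationError("survey_interval must be >= 1")
        rates = np.atleast_1d(np.asarray(self.attrition_rate, dtype=float))
        if rates.size not in (1, self.n_prefectures):
            raise ValidationError(
                "attrition_rate must be scalar or one value per prefecture"
            )
        if np.any(rates < 0) or np.any(rates >= 1):
            raise ValidationError("attrition_rate values must lie in [0, 1)")
        for name in ("initial_stock_range", "licensing_rate_range",
                     "new_licensed_ppr_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValidationError(f"{name} must satisfy 0 <= min <= max")
        if self.attrition_base not in ("stock", "mean_stock"):
            raise ValidationError("attrition_base must be 'stock' or 'mean_stock'")
        if self.attrition_base == "mean_stock" and not self.deterministic:
            raise ValidationError(
                "attrition_base='mean_stock' requires deterministic=True"
            )

    def attrition_rates(self) -> np.ndarray:
        rates = np.atleast_1d(np.asarray(self.attrition_rate, dtype=float))
        if rates.size == 1:
            rates = np.full(self.n_prefectures, rates[0])
        return rates


@dataclass
class SyntheticTruth:
    """Exact per-prefecture ground truth of one realization.

    ``true_net_migrants`` is signed cumulative net migration over the window
    (positive = net departure/outflow, matching the estimator's convention)
    and sums to zero across prefectures. ``events`` is the full annual flow
    log (one row per prefecture-year) from which the cumulative fields can
    be independently re-accumulated.
    """

    true_net_migrants: dict[str, float]
    true_attrition: dict[str, float]
    true_migration_ratio: dict[str, float]
    events: pd.DataFrame


def make_paperlike_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Config calibrated to the national study conditions (see module docs)."""
    return dataclasses.replace(SimulationConfig(seed=seed), **overrides)


def _prefecture_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def _survey_years(config: SimulationConfig) -> list[int]:
    years = list(
        range(config.baseline_year, config.final_year + 1, config.survey_interval)
    )
    if years[-1] != config.final_year:
        years.append(config.final_year)
    return years


def _resolve_annual_outflow(
    out: np.ndarray, available: np.ndarray, year: int
) -> np.ndarray:
    """Clip outflows that would drive a stock negative, preserving zero sum.

    The clipped shortfall is redistributed as extra outflow over prefectures
    still below their cap; with realistic configurations this never triggers.
    """
    tol = 1e-9
    if not np.any(out > available + tol):
        return out
    logger.warning("year %d: truncating migration outflow to keep stocks >= 0", year)
    out = out.copy()
    for _ in range(out.size):
        violated = out > available + tol
        if not violated.any():
            break
        out[violated] = available[violated]
        free = out < available - tol
        if not free.any():
            raise ValidationError(
                f"year {year}: cannot redistribute migration outflow without "
                "negative stocks; reduce flow magnitudes"
            )
        out[free] += -out.sum() / free.sum()
    return out


def _run_path(
    config: SimulationConfig,
    rng: np.random.Generator,
    initial_stocks: np.ndarray,
    licensing_rates: np.ndarray,
    propensity: np.ndarray,
    fixed_attrition: np.ndarray | None,
):
    """One forward pass. Returns (stock path by year, event rows)."""
    n = config.n_prefectures
    attr_rates = config.attrition_rates()
    mm = config.migration_model
    stocks = initial_stocks.astype(float).copy()
    path = {config.baseline_year: stocks.copy()}
    events: list[dict] = []

    for year in range(config.baseline_year + 1, config.final_year + 1):
        if config.deterministic:
            licensed = licensing_rates.copy()
        else:
            licensed = rng.poisson(licensing_rates).astype(float)

        if fixed_attrition is not None:
            attrited = fixed_attrition.copy()
        elif config.deterministic:
            attrited = attr_rates * stocks
        else:
            attrited = rng.binomial(
                np.maximum(stocks, 0.0).astype(np.int64), attr_rates
            ).astype(float)
        attrited = np.minimum(attrited, stocks + licensed)

        raw = propensity.copy()
        if not config.deterministic and mm.noise_sd > 0:
            raw = raw + rng.normal(0.0, mm.noise_sd, n)
        out = raw - raw.mean()
        out = _resolve_annual_outflow(out, stocks + licensed - attrited, year)

        stocks = stocks + licensed - attrited - out
        path[year] = stocks.copy()
        events.append(
            {"year": year, "new_licensed": licensed, "attrited": attrited,
             "net_out": out}
        )
    return path, events


def simulate_panel(
    config: SimulationConfig | None = None,
) -> tuple[PrefecturePanel, SyntheticTruth]:
    """Simulate one panel realization and its exact ground truth."""
    config = config or SimulationConfig()
    config.validate()
    n = config.n_prefectures
    ids = _prefecture_ids(n)
    rng = np.random.default_rng(config.seed)

    # structural heterogeneity (drawn even in deterministic mode)
    initial_stocks = rng.uniform(*config.initial_stock_range, n)
    licensing_rates = rng.uniform(*config.licensing_rate_range, n)
    new_ppr = rng.uniform(*config.new_licensed_ppr_range, n)
    populations = licensing_rates * 1e5 / new_ppr
    other_covariates = {
        name: rng.uniform(lo, hi, n) for name, (lo, hi) in _COVARIATE_RANGES.items()
    }
    mm = config.migration_model
    propensity = mm.gamma0 + mm.gamma_newppr * new_ppr

    fixed_attrition = None
    if config.attrition_base == "mean_stock":
        # closed-form constant annual attrition a_i = r_i * m_i, with m_i the
        # prefecture's own realized window-mean observed stock. Because
        # migration propensities do not depend on stocks, the stock path is
        # linear in a_i: m_i = m_i0 - k * a_i with k the mean years elapsed at
        # the survey points, giving a_i = r_i * m_i0 / (1 + k * r_i).
        obs_years = _survey_years(config)
        k = float(np.mean([y - config.baseline_year for y in obs_years]))
        free_path, _ = _run_path(
            config, np.random.default_rng(config.seed),
            initial_stocks, licensing_rates, propensity,
            fixed_attrition=np.zeros(n),
        )
        m0 = np.mean([free_path[y] for y in obs_years], axis=0)
        rates = config.attrition_rates()
        fixed_attrition = rates * m0 / (1.0 + k * rates)

    path, events = _run_path(
        config, rng, initial_stocks, licensing_rates, propensity, fixed_attrition
    )

    obs_years = _survey_years(config)
    records = []
    for i, pid in enumerate(ids):
        stock_by_year = {y: float(path[y][i]) for y in obs_years}
        new_by_year = {
            ev["year"]: float(ev["new_licensed"][i]) for ev in events
        }
        records.append(PrefectureRecord(pid, stock_by_year, new_by_year))

    covariates = {}
    final = path[config.final_year]
    for i, pid in enumerate(ids):
        covariates[pid] = PrefectureCovariates(
            practicing_ppr=float(final[i] * 1e5 / populations[i]),
            new_licensed_ppr=float(new_ppr[i]),
            physician_mean_age=float(other_covariates["physician_mean_age"][i]),
            female_ratio=float(other_covariates["female_ratio"][i]),
            pop_density=float(other_covariates["pop_density"][i]),
            unemployment=float(other_covariates["unemployment"][i]),
            aged_ratio=float(other_covariates["aged_ratio"][i]),
            income=float(other_covariates["income"][i]),
        )

    panel = PrefecturePanel(
        records, config.baseline_year, config.final_year, covariates
    )
    panel.validate()

    net = np.sum([ev["net_out"] for ev in events], axis=0)
    attr = np.sum([ev["attrited"] for ev in events], axis=0)
    licensed_tot = np.sum([ev["new_licensed"] for ev in events], axis=0)
    event_rows = []
    for ev in events:
        for i, pid in enumerate(ids):
            event_rows.append(
                {
                    "prefecture": pid,
                    "year": ev["year"],
                    "new_licensed": float(ev["new_licensed"][i]),
                    "attrited": float(ev["attrited"][i]),
                    "net_out": float(ev["net_out"][i]),
                }
            )
    truth = SyntheticTruth(
        true_net_migrants={pid: float(net[i]) for i, pid in enumerate(ids)},
        true_attrition={pid: float(attr[i]) for i, pid in enumerate(ids)},
        true_migration_ratio={
            pid: float(net[i] / licensed_tot[i]) if licensed_tot[i] > 0 else float("nan")
            for i, pid in enumerate(ids)
        },
        events=pd.DataFrame(
            event_rows,
            columns=["prefecture", "year", "new_licensed", "attrited", "net_out"],
        ),
    )
    return panel, truth


def write_truth(truth: SyntheticTruth, path) -> None:
    rows = [
        {
            "prefecture": pid,
            "true_net_migrants": truth.true_net_migrants[pid],
            "true_attrition": truth.true_attrition[pid],
            "true_migration_ratio": truth.true_migration_ratio[pid],
        }
        for pid in sorted(truth.true_net_migrants)
    ]
    pd.DataFrame(rows, columns=list(TRUTH_COLUMNS)).to_csv(path, index=False)


def draw_covariate_table(
    rng: np.random.Generator, n: int
) -> pd.DataFrame:
    """Independent draws of all eight covariates from their plausible ranges.

    Used by regression recovery simulations where every covariate (including
    the PPRs) must be exogenous noise unless an effect is planted explicitly.
    """
    data = {
        "practicing_ppr": rng.uniform(160.0, 320.0, n),
        "new_licensed_ppr": rng.uniform(*_NEWPPR_RANGE, n),
    }
    for name, (lo, hi) in _COVARIATE_RANGES.items():
        data[name] = rng.uniform(lo, hi, n)
    return pd.DataFrame(data, columns=list(COVARIATE_NAMES))
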