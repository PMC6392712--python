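"""Domain types and CSV I/O for prefecture-level physician panels.

The panel is long-format CSV with columns ``prefecture,year,stock,new_licensed``:
``stock`` is the practicing-physician headcount observed at a survey year
(may be empty for licensing-only years, since the underlying survey is
biennial) and ``new_licensed`` the count of physicians newly licensed in that
year and attributed to the prefecture of their medical school (may be empty
for stock-only rows). Covariates live in a separate CSV keyed by prefecture.

Counts are stored as floats: proportional allocation downstream produces
fractional counts, and exact conservation of totals is a core invariant that
per-prefecture integer rounding would break. Survey years may be biennial
with gaps; only observed years are stored and nothing is interpolated.
Prefecture identifiers are opaque strings ordered lexicographically for
deterministic output.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .errors import IntegrityError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

PANEL_COLUMNS = ("prefecture", "year", "stock", "new_licensed")

#: Covariate column names, in the order they enter the joint regression.
COVARIATE_NAMES = (
    "practicing_ppr",
    "new_licensed_ppr",
    "physician_mean_age",
    "female_ratio",
    "pop_density",
    "unemployment",
    "aged_ratio",
    "income",
)

_PROPORTION_COVARIATES = ("female_ratio", "unemployment", "aged_ratio")


@dataclass(frozen=True)
class PrefectureCovariates:
    """Socio-demographic background of one prefecture.

    ``practicing_ppr`` and ``new_licensed_ppr`` are physicians per 100,000
    population (the latter annual); ``pop_density`` is population per unit of
    inhabitable (non-mountain, non-water) land; the three ratio fields are
    proportions in [0, 1]; ``income`` is average income of the general
    population in currency units.
    """

    practicing_ppr: float
    new_licensed_ppr: float
    physician_mean_age: float
    female_ratio: float
    pop_density: float
    unemployment: float
    aged_ratio: float
    income: float

    def __post_init__(self) -> None:
        for name in _PROPORTION_COVARIATES:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v!r}")
        for name in COVARIATE_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v!r}")

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in COVARIATE_NAMES}


@dataclass
class PrefectureRecord:
    """Time series of one prefecture: survey stocks and annual licensing."""

    prefecture_id: str
    stock_by_year: dict[int, float] = field(default_factory=dict)
    new_licensed_by_year: dict[int, float] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.prefecture_id:
            raise ValidationError("prefecture_id must be a non-empty string")
        for year, v in self.stock_by_year.items():
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"{self.prefecture_id}: stock in {year} must be >= 0, got {v!r}"
                )
        for year, v in self.new_licensed_by_year.items():
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"{self.prefecture_id}: new_licensed in {year} must be >= 0, "
                    f"got {v!r}"
                )


@dataclass
class PrefecturePanel:
    """Validated collection of prefecture records plus optional covariates."""

    records: list[PrefectureRecord]
    baseline_year: int
    final_year: int
    covariates: dict[str, PrefectureCovariates] = field(default_factory=dict)

    def validate(self) -> None:
        if self.baseline_year >= self.final_year:
            raise ValidationError(
                f"baseline_year {self.baseline_year} must precede "
                f"final_year {self.final_year}"
            )
        ids = [r.prefecture_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate prefecture ids: {dupes}")
        for r in self.records:
            r.validate()
            for year in (self.baseline_year, self.final_year):
                if year not in r.stock_by_year:
                    raise ValidationError(
                        f"{r.prefecture_id}: missing stock observation for "
                        f"year {year}"
                    )
        extra = set(self.covariates) - set(ids)
        if extra:
            raise IntegrityError(
                f"covariates given for unknown prefectures: {sorted(extra)}"
            )

    @property
    def prefecture_ids(self) -> list[str]:
        return sorted(r.prefecture_id for r in self.records)

    def record(self, prefecture_id: str) -> PrefectureRecord:
        for r in self.records:
            if r.prefecture_id == prefecture_id:
                return r
        raise KeyError(prefecture_id)


@dataclass(frozen=True)
class NationalAggregate:
    """Whole-country totals over the study window.

    ``total_attrition`` is the residual estimate of deceased or retired
    physicians: licensing inflow minus observed stock increase. The identity
    ``total_attrition == total_new_licensed - total_increase`` holds exactly.
    """

    total_new_licensed: float
    total_increase: float
    total_attrition: float


# ---------------------------------------------------------------------------
# CSV readers / writers


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s): {', '.join(missing)}")


def read_panel(
    path,
    baseline_year: int | None = None,
    final_year: int | None = None,
    covariates_path=None,
) -> PrefecturePanel:
    """Read and validate a long-format panel CSV.

    The study window defaults to the earliest and latest years with a stock
    observation. Rows with years outside the window are rejected with a
    logged report. Raises :class:`SchemaError`, :class:`IntegrityError` or
    :class:`ValidationError` on malformed input.
    """
    df = pd.read_csv(path)
    _require_columns(df, PANEL_COLUMNS, "panel CSV")

    df["prefecture"] = df["prefecture"].astype(str)
    try:
        df["year"] = df["year"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"panel CSV: non-integer year: {exc}") from exc

    dup = df.duplicated(subset=["prefecture", "year"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["prefecture", "year"]].drop_duplicates()
        pairs = [f"({p}, {y})" for p, y in keys.itertuples(index=False)]
        raise IntegrityError(f"duplicate (prefecture, year) rows: {', '.join(pairs)}")

    for col in ("stock", "new_licensed"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & vals.isna()
        if bad.any():
            raise ValidationError(f"panel CSV: non-numeric {col} values")
        if (vals.dropna() < 0).any():
            raise ValidationError(f"panel CSV: negative {col} values")
        df[col] = vals

    stock_years = df.loc[df["stock"].notna(), "year"]
    if stock_years.empty:
        raise ValidationError("panel CSV contains no stock observations")
    if baseline_year is None:
        baseline_year = int(stock_years.min())
    if final_year is None:
        final_year = int(stock_years.max())

    in_window = (df["year"] >= baseline_year) & (df["year"] <= final_year)
    if (~in_window).any():
        rejected = df.loc[~in_window]
        logger.warning(
            "rejected %d row(s) outside window [%d, %d] (years: %s)",
            len(rejected),
            baseline_year,
            final_year,
            sorted(rejected["year"].unique().tolist()),
        )
        df = df.loc[in_window]

    records = []
    for pref, grp in df.groupby("prefecture", sort=True):
        stocks = {
            int(y): float(s)
            for y, s in zip(grp["year"], grp["stock"])
            if pd.notna(s)
        }
        licensed = {
            int(y): float(v)
            for y, v in zip(grp["year"], grp["new_licensed"])
            if pd.notna(v)
        }
        records.append(PrefectureRecord(str(pref), stocks, licensed))

    covariates = read_covariates(covariates_path) if covariates_path else {}
    panel = PrefecturePanel(records, baseline_year, final_year, covariates)
    panel.validate()
    return panel


def write_panel(panel: PrefecturePanel, path, covariates_path=None) -> None:
    """Write a panel to CSV with deterministic row order.

    Rows are sorted by prefecture id then year; one row per (prefecture,
    year) with either field empty when unobserved. ``read_panel`` inverts
    this exactly.
    """
    panel.validate()
    rows = []
    for record in sorted(panel.records, key=lambda r: r.prefecture_id):
        years = sorted(set(record.stock_by_year) | set(record.new_licensed_by_year))
        for year in years:
            rows.append(
                {
                    "prefecture": record.prefecture_id,
                    "year": year,
                    "stock": record.stock_by_year.get(year),
                    "new_licensed": record.new_licensed_by_year.get(year),
                }
            )
    pd.DataFrame(rows, columns=list(PANEL_COLUMNS)).to_csv(path, index=False)
    if covariates_path is not None and panel.covariates:
        write_covariates(panel.covariates, covariates_path)


def read_covariates(path) -> dict[str, PrefectureCovariates]:
    """Read the per-prefecture covariate table."""
    df = pd.read_csv(path)
    _require_columns(df, ("prefecture",) + COVARIATE_NAMES, "covariate CSV")
    df["prefecture"] = df["prefecture"].astype(str)
    if df["prefecture"].duplicated().any():
        dupes = sorted(df.loc[df["prefecture"].duplicated(), "prefecture"].unique())
        raise IntegrityError(f"duplicate prefectures in covariate CSV: {dupes}")
    out: dict[str, PrefectureCovariates] = {}
    for row in df.itertuples(index=False):
        out[row.prefecture] = PrefectureCovariates(
            **{name: float(getattr(row, name)) for name in COVARIATE_NAMES}
        )
    return out


def write_covariates(covariates: Mapping[str, PrefectureCovariates], path) -> None:
    rows = [
        {"prefecture": pref, **covariates[pref].as_dict()}
        for pref in sorted(covariates)
    ]
    pd.DataFrame(rows, columns=["prefecture", *COVARIATE_NAMES]).to_csv(
        path, index=False
    )


def panels_equal(a: PrefecturePanel, b: PrefecturePanel, rtol: float = 1e-9) -> bool:
    """Field-by-field panel equality with relative tolerance on values."""

    def close(x: float, y: float) -> bool:
        return math.isclose(x, y, rel_tol=rtol, abs_tol=0.0)

    if (a.baseline_year, a.final_year) != (b.baseline_year, b.final_year):
        return False
    if a.prefecture_ids != b.prefecture_ids:
        return False
    for pid in a.prefecture_ids:
        ra, rb = a.record(pid), b.record(pid)
        for attr in ("stock_by_year", "new_licensed_by_year"):
            da, db = getattr(ra, attr), getattr(rb, attr)
            if set(da) != set(db) or not all(close(da[y], db[y]) for y in da):
                return False
    if set(a.covariates) != set(b.covariates):
        return False
    for pid, ca in a.covariates.items():
        cb = b.covariates[pid].as_dict()
        if not all(close(v, cb[k]) for k, v in ca.as_dict().items()):
            return False
    return True
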