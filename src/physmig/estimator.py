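"""Residual-method estimation of net physician migration.

The method runs in three steps. Step 1 estimates national attrition (deaths
plus retirements, which no registry reports directly) as the residual between
the national licensing inflow and the observed national stock increase over
the study window. Step 2 allocates that national total to prefectures in
proportion to each prefecture's mean practicing stock over the window — the
identifying assumption is a uniform per-physician attrition rate. Step 3
computes, per prefecture, the *adjusted* number of newly licensed physicians
(licensing minus allocated attrition: the hypothetical stock increase under
zero migration) and subtracts the actual increase; the difference is the net
number of migrating physicians, positive for net outflow and negative for net
inflow. The migration ratio divides net migrants by the prefecture's
cumulative licensing count and can therefore exceed 100% in magnitude for
strong inflow.

Net migrants sum to zero across prefectures by construction (the national
residual is fully allocated), which is the method's key internal check.
All quantities stay fractional; nothing is rounded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .data_model import NationalAggregate, PrefecturePanel, PrefectureRecord
from .errors import ValidationError

#: net_migrants within this absolute band of zero is labelled "balanced".
BALANCED_TOL = 1e-9

ESTIMATE_COLUMNS = (
    "prefecture",
    "mean_stock",
    "allocated_attrition",
    "new_licensed_total",
    "adjusted_new_licensed",
    "actual_increase",
    "net_migrants",
    "migration_ratio",
    "label",
)


@dataclass(frozen=True)
class MigrationEstimate:
    """Per-prefecture output of the three-step chain.

    ``net_migrants = adjusted_new_licensed - actual_increase`` holds exactly;
    ``migration_ratio`` is a fraction (0.68 means 68% outflow) and is ``None``
    when the prefecture licensed nobody over the window.
    """

    prefecture_id: str
    mean_stock: float
    allocated_attrition: float
    new_licensed_total: float
    adjusted_new_licensed: float
    actual_increase: float
    net_migrants: float
    migration_ratio: float | None
    label: str  # outflow | inflow | balanced


def estimate_national_attrition(
    total_new_licensed: float,
    total_increase: float,
    *,
    allow_negative: bool = False,
) -> float:
    """Step 1: national attrition as licensing inflow minus stock increase.

    A negative result means the stock grew by more than the licensing inflow,
    which a closed national system cannot do; it flags an implausible panel
    and raises unless ``allow_negative`` is set.
    """
    if total_new_licensed < 0:
        raise ValidationError(
            f"total_new_licensed must be >= 0, got {total_new_licensed!r}"
        )
    attrition = total_new_licensed - total_increase
    # tolerate float cancellation noise around zero
    if attrition < -1e-6 and not allow_negative:
        raise ValidationError(
            f"estimated national attrition is negative ({attrition:g}): the stock "
            "increase exceeds the licensing inflow, which is implausible for a "
            "closed system (pass allow_negative=True to proceed)"
        )
    return attrition


def mean_stock(record: PrefectureRecord, baseline_year: int, final_year: int) -> float:
    """Arithmetic mean of the observed survey stocks within the window.

    Only observed survey years are used; there is no interpolation between
    biennial observations.
    """
    values = [
        v for y, v in record.stock_by_year.items() if baseline_year <= y <= final_year
    ]
    if not values:
        raise ValidationError(
            f"{record.prefecture_id}: no stock observations in "
            f"[{baseline_year}, {final_year}]"
        )
    return sum(values) / len(values)


def allocate_attrition(
    national_attrition: float, mean_stocks: Mapping[str, float]
) -> dict[str, float]:
    """Step 2: split national attrition proportionally to mean stocks.

    Shares are fractional and sum to the national total exactly (up to float
    rounding); no integer rounding is applied anywhere.
    """
    if national_attrition < 0:
        raise ValidationError(
            f"national_attrition must be >= 0, got {national_attrition!r}"
        )
    total = sum(mean_stocks.values())
    if total <= 0:
        raise ValidationError("sum of mean stocks must be positive")
    return {
        pref: national_attrition * stock / total
        for pref, stock in mean_stocks.items()
    }


def national_aggregate(
    panel: PrefecturePanel,
    *,
    allow_negative_attrition: bool = False,
) -> NationalAggregate:
    """National licensing, increase, and residual attrition for a panel.

    Licensing is summed over years strictly after the baseline observation
    through the final year: the baseline stock is the pre-window headcount
    and later cohorts drive the change.
    """
    b, f = panel.baseline_year, panel.final_year
    total_licensed = 0.0
    total_increase = 0.0
    for record in panel.records:
        total_licensed += sum(
            v for y, v in record.new_licensed_by_year.items() if b < y <= f
        )
        total_increase += record.stock_by_year[f] - record.stock_by_year[b]
    attrition = estimate_national_attrition(
        total_licensed, total_increase, allow_negative=allow_negative_attrition
    )
    return NationalAggregate(total_licensed, total_increase, attrition)


def estimate_migration(
    panel: PrefecturePanel,
    *,
    baseline_year: int | None = None,
    final_year: int | None = None,
    strict: bool = True,
) -> list[MigrationEstimate]:
    """Run the full Step 1 → 2 → 3 chain on a panel.

    ``strict`` controls whether a negative national attrition aborts.
    Results are ordered by prefecture id. Negative adjusted licensing counts
    (attrition allocation exceeding licensing) are legitimate for small
    prefectures and propagate; they surface through the sign of the values,
    not as errors.
    """
    if baseline_year is not None or final_year is not None:
        panel = PrefecturePanel(
            panel.records,
            baseline_year if baseline_year is not None else panel.baseline_year,
            final_year if final_year is not None else panel.final_year,
            panel.covariates,
        )
    panel.validate()
    b, f = panel.baseline_year, panel.final_year

    for record in panel.records:
        for year in (b, f):
            if year not in record.stock_by_year:
                raise ValidationError(
                    f"{record.prefecture_id}: missing stock for year {year}"
                )

    agg = national_aggregate(panel, allow_negative_attrition=not strict)
    means = {
        r.prefecture_id: mean_stock(r, b, f)
        for r in sorted(panel.records, key=lambda r: r.prefecture_id)
    }
    allocated = (
        allocate_attrition(agg.total_attrition, means)
        if agg.total_attrition >= 0
        # implausible negative national attrition in non-strict mode: the
        # proportional split still conserves the (negative) total
        else {
            p: agg.total_attrition * s / sum(means.values())
            for p, s in means.items()
        }
    )

    estimates = []
    for pid in sorted(means):
        record = panel.record(pid)
        licensed = sum(v for y, v in record.new_licensed_by_year.items() if b < y <= f)
        adjusted = licensed - allocated[pid]
        increase = record.stock_by_year[f] - record.stock_by_year[b]
        net = adjusted - increase
        ratio = net / licensed if licensed > 0 else None
        if net > BALANCED_TOL:
            label = "outflow"
        elif net < -BALANCED_TOL:
            label = "inflow"
        else:
            label = "balanced"
        estimates.append(
            MigrationEstimate(
                prefecture_id=pid,
                mean_stock=means[pid],
                allocated_attrition=allocated[pid],
                new_licensed_total=licensed,
                adjusted_new_licensed=adjusted,
                actual_increase=increase,
                net_migrants=net,
                migration_ratio=ratio,
                label=label,
            )
        )
    return estimates


def flow_difference(estimates: Iterable[MigrationEstimate]) -> float:
    """Spread between the extreme migration ratios, in percent.

    With outflow positive and inflow negative this equals the maximum outflow
    percentage plus the maximum inflow percentage (e.g. +68% and −245% give a
    flow difference of 313%).
    """
    ratios = [e.migration_ratio for e in estimates if e.migration_ratio is not None]
    if len(ratios) < 2:
        raise ValidationError("flow_difference needs >= 2 defined migration ratios")
    return (max(ratios) - min(ratios)) * 100.0


def estimates_to_frame(estimates: Sequence[MigrationEstimate]) -> pd.DataFrame:
    rows = [
        {
            "prefecture": e.prefecture_id,
            "mean_stock": e.mean_stock,
            "allocated_attrition": e.allocated_attrition,
            "new_licensed_total": e.new_licensed_total,
            "adjusted_new_licensed": e.adjusted_new_licensed,
            "actual_increase": e.actual_increase,
            "net_migrants": e.net_migrants,
            "migration_ratio": e.migration_ratio,
            "label": e.label,
        }
        for e in estimates
    ]
    return pd.DataFrame(rows, columns=list(ESTIMATE_COLUMNS))


def write_estimates(estimates: Sequence[MigrationEstimate], path) -> None:
    estimates_to_frame(estimates).to_csv(path, index=False)


def read_estimates(path) -> list[MigrationEstimate]:
    df = pd.read_csv(path)
    missing = [c for c in ESTIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"estimates CSV missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        ratio = None if pd.isna(row.migration_ratio) else float(row.migration_ratio)
        out.append(
            MigrationEstimate(
                prefecture_id=str(row.prefecture),
                mean_stock=float(row.mean_stock),
                allocated_attrition=float(row.allocated_attrition),
                new_licensed_total=float(row.new_licensed_total),
                adjusted_new_licensed=float(row.adjusted_new_licensed),
                actual_increase=float(row.actual_increase),
                net_migrants=float(row.net_migrants),
                migration_ratio=ratio,
                label=str(row.label),
            )
        )
    return out
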