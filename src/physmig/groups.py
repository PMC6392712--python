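"""Four-group classification of prefectures by migration ratio.

Prefectures are sorted by migration ratio, outflow (positive) first, and
split into four consecutive blocks: high outflow, low outflow, low inflow,
high inflow. Block sizes are as even as possible; when the count is not a
multiple of four the shortfall is taken from the high-outflow extreme (and
any surplus pushed toward the inflow end), which yields the 11/12/12/12
partition for 47 prefectures. Ties in the ratio are broken by prefecture id
so the partition is deterministic. Group summaries are medians (midpoint
convention for even sizes) of the migration ratio and of each covariate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import COVARIATE_NAMES, PrefectureCovariates
from .errors import ValidationError
from .estimator import MigrationEstimate

GROUP_LABELS = ("high_outflow", "low_outflow", "low_inflow", "high_inflow")


@dataclass
class GroupAssignment:
    group_label: str
    members: list[str]
    summaries: dict[str, float]


def group_sizes(n: int, n_groups: int = 4) -> list[int]:
    """Block sizes, most even split with the deficit at the first block."""
    if n < n_groups:
        raise ValidationError(f"need at least {n_groups} prefectures, got {n}")
    base, remainder = divmod(n, n_groups)
    return [base + (1 if i >= n_groups - remainder else 0) for i in range(n_groups)]


def classify(
    estimates: Sequence[MigrationEstimate],
    covariates: Mapping[str, PrefectureCovariates] | None = None,
) -> list[GroupAssignment]:
    """Partition prefectures into the four migration groups.

    All migration ratios must be defined. Returns the groups in order from
    high outflow to high inflow; each carries median summaries of the
    migration ratio and, when covariates are supplied, of every covariate.
    """
    undefined = [e.prefecture_id for e in estimates if e.migration_ratio is None]
    if undefined:
        raise ValidationError(
            f"migration ratio undefined for: {', '.join(sorted(undefined))}"
        )
    ordered = sorted(estimates, key=lambda e: (-e.migration_ratio, e.prefecture_id))
    sizes = group_sizes(len(ordered))

    assignments = []
    start = 0
    for label, size in zip(GROUP_LABELS, sizes):
        block = ordered[start : start + size]
        start += size
        summaries = {
            "migration_ratio": float(
                np.median([e.migration_ratio for e in block])
            )
        }
        if covariates:
            for name in COVARIATE_NAMES:
                values = [
                    getattr(covariates[e.prefecture_id], name)
                    for e in block
                    if e.prefecture_id in covariates
                ]
                if values:
                    summaries[name] = float(np.median(values))
        assignments.append(
            GroupAssignment(label, [e.prefecture_id for e in block], summaries)
        )
    return assignments


def group_summary_table(assignments: Sequence[GroupAssignment]) -> pd.DataFrame:
    """Long-format summary: one row per (group, variable) median."""
    rows = [
        {"group": a.group_label, "variable": var, "median": med}
        for a in assignments
        for var, med in a.summaries.items()
    ]
    return pd.DataFrame(rows, columns=["group", "variable", "median"])


def write_group_summary(assignments: Sequence[GroupAssignment], path) -> None:
    group_summary_table(assignments).to_csv(path, index=False)
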