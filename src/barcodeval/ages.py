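"""Lineage age versus discrimination success.

The study design behind this package asks whether barcode discrimination
collapses in young radiations: per-group identification success is related
to the age of each group's most recent common ancestor. With only a handful
of informal groups, rank order is the only defensible signal, so the
association is summarized by a Spearman rank correlation (average ranks for
ties) plus a simple threshold scan comparing mean success in groups older
versus younger than each candidate age.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .io import BarcodevalError, SampleTable
from .scoring import DiscriminationReport

GROUP_AGE_COLUMNS = ("group", "age_mya", "n_species")


def read_group_ages(path: str | Path) -> pd.DataFrame:
    """Read the per-group age table (TSV: group, age_mya, n_species)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GROUP_AGE_COLUMNS if c not in df.columns]
    if missing:
        raise BarcodevalError(f"{path}: missing columns {missing}")
    if df["group"].duplicated().any():
        raise BarcodevalError(f"{path}: duplicate groups")
    if (df["age_mya"] <= 0).any():
        raise BarcodevalError(f"{path}: ages must be positive")
    return df


def per_group_success(
    report: DiscriminationReport, table: SampleTable
) -> dict[str, float]:
    """Percent of sampled species discriminated, per informal group."""
    group_of = table.group_of_species()
    tally: dict[str, list[int]] = {}
    for sp, info in report.per_species.items():
        grp = group_of.get(sp)
        if grp is None:
            raise BarcodevalError(f"species {sp!r} missing from sample table")
        tally.setdefault(grp, []).append(1 if info["discriminated"] else 0)
    return {
        grp: 100.0 * sum(flags) / len(flags) for grp, flags in sorted(tally.items())
    }


def _ages_as_map(ages: pd.DataFrame | Mapping[str, float]) -> dict[str, float]:
    if isinstance(ages, pd.DataFrame):
        return dict(zip(ages["group"], ages["age_mya"]))
    return dict(ages)


def age_success_association(
    ages: pd.DataFrame | Mapping[str, float], successes: Mapping[str, float]
) -> dict:
    """Spearman rank correlation between group age and success percentage."""
    age_map = _ages_as_map(ages)
    shared = sorted(set(age_map) & set(successes))
    if len(shared) < 3:
        raise BarcodevalError(
            f"age_success_association: need >=3 groups with both age and "
            f"success, got {len(shared)}"
        )
    x = [age_map[g] for g in shared]
    y = [successes[g] for g in shared]
    rho = stats.spearmanr(x, y).statistic
    return {"spearman_rho": float(rho), "n_groups": len(shared)}


def age_threshold_scan(
    ages: pd.DataFrame | Mapping[str, float],
    successes: Mapping[str, float],
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """Mean success among groups at least / strictly younger than each
    threshold age. Empty sides are reported as NaN.
    """
    age_map = _ages_as_map(ages)
    shared = sorted(set(age_map) & set(successes))
    if len(shared) < 2:
        raise BarcodevalError("age_threshold_scan: need >=2 groups")
    rows = []
    for thr in thresholds:
        older = [successes[g] for g in shared if age_map[g] >= thr]
        younger = [successes[g] for g in shared if age_map[g] < thr]
        rows.append(
            {
                "threshold_mya": thr,
                "n_older": len(older),
                "n_younger": len(younger),
                "mean_success_older": sum(older) / len(older) if older else math.nan,
                "mean_success_younger": (
                    sum(younger) / len(younger) if younger else math.nan
                ),
            }
        )
    return pd.DataFrame(rows)
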