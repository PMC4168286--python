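"""Helpers for re-running the evaluation on the originally deposited data.

Sequence download and per-locus alignment are delegated to external tools
the user runs; this module only expands accession ranges into manifests and
compares a freshly computed report table against an expected one, with exact
matching on counts and a tolerance window on percentages (rounding in a
published table plus aligner differences can shift a percentage by a point).
"""

from __future__ import annotations

import re
from typing import Sequence

import pandas as pd

from .io import BarcodevalError

_RANGE_RE = re.compile(r"^([A-Za-z]+)(\d+)\s*[-–—]\s*(?:([A-Za-z]+))?(\d+)$")


def build_accession_manifest(range_spec: str) -> list[str]:
    """Expand e.g. ``"KM372590-KM373057"`` into an ordered id list.

    Accepts ASCII hyphen or en/em dash; the second prefix may be omitted.
    Reversed ranges are an error.
    """
    m = _RANGE_RE.match(range_spec.strip())
    if not m:
        raise BarcodevalError(f"malformed accession range {range_spec!r}")
    prefix, start_s, prefix2, end_s = m.groups()
    if prefix2 is not None and prefix2 != prefix:
        raise BarcodevalError(
            f"accession range {range_spec!r}: prefixes differ ({prefix} vs {prefix2})"
        )
    start, end = int(start_s), int(end_s)
    if end < start:
        raise BarcodevalError(f"accession range {range_spec!r}: reversed")
    width = len(start_s)
    return [f"{prefix}{n:0{width}d}" for n in range(start, end + 1)]


def compare_to_paper(
    report_table: pd.DataFrame,
    expected_table: pd.DataFrame,
    key_columns: Sequence[str] = ("combination", "mode"),
    count_columns: Sequence[str] = (
        "n_species_discriminated",
        "n_endangered_discriminated",
        "n_groups_discriminated",
    ),
    pct_columns: Sequence[str] = ("pct_species",),
    pct_tolerance: float = 1.0,
) -> pd.DataFrame:
    """Row-by-row comparison of a computed report against expected values.

    Counts must match exactly; percentage columns pass within
    ``pct_tolerance`` points. Returns one row per (key, column) with the
    delta and a pass flag; inputs are never mutated.
    """
    for col in key_columns:
        if col not in report_table.columns or col not in expected_table.columns:
            raise BarcodevalError(f"compare_to_paper: key column {col!r} missing")
    merged = expected_table.merge(
        report_table, on=list(key_columns), how="left", suffixes=("_expected", "")
    )
    if merged[
        [c for c in merged.columns if c.endswith("_expected")] or list(key_columns)
    ].isna().any().any():
        pass  # missing rows surface as NaN deltas below
    rows = []
    for _, rec in merged.iterrows():
        key = {k: rec[k] for k in key_columns}
        for col in list(count_columns) + list(pct_columns):
            exp_col = f"{col}_expected"
            if exp_col not in merged.columns:
                continue
            expected = rec[exp_col]
            observed = rec.get(col)
            delta = (
                observed - expected
                if pd.notna(observed) and pd.notna(expected)
                else float("nan")
            )
            if col in pct_columns:
                ok = pd.notna(delta) and abs(delta) <= pct_tolerance
            else:
                ok = pd.notna(delta) and delta == 0
            rows.append({**key, "column": col, "expected": expected,
                         "observed": observed, "delta": delta, "passed": bool(ok)})
    return pd.DataFrame(rows)
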