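"""Kaplan–Meier estimation and the two-group log-rank test.

Thin, validated wrappers around lifelines that take the package's clinical
table convention: one row per sample with non-negative ``time``, binary
``event`` (1 = event observed, 0 = censored) and a ``group`` column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

__all__ = ["km_estimate", "logrank_test", "read_survival_tsv"]


def read_survival_tsv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"sample", "time", "event"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    return table.set_index("sample")


def _validate(table: pd.DataFrame) -> None:
    if (table["time"] < 0).any():
        raise ValueError("survival times must be non-negative")
    if not table["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")


def km_estimate(table: pd.DataFrame, group: str | int | None = None) -> pd.DataFrame:
    """Product-limit survival estimate, optionally restricted to one group.

    Returns a step-function table with columns ``time`` and ``survival``
    (S(0) = 1, non-increasing, dropping only at event times).
    """
    _validate(table)
    sub = table if group is None else table[table["group"] == group]
    if sub.empty:
        raise ValueError(f"no samples in group {group!r}")
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time"], sub["event"])
    sf = kmf.survival_function_.reset_index()
    sf.columns = ["time", "survival"]
    return sf


def logrank_test(table: pd.DataFrame) -> dict:
    """Two-group log-rank chi-squared test (1 df) between the table's groups."""
    _validate(table)
    groups = pd.unique(table["group"])
    if len(groups) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, found {len(groups)}")
    a = table[table["group"] == groups[0]]
    b = table[table["group"] == groups[1]]
    if a.empty or b.empty:
        raise ValueError("both groups must be non-empty")
    if table["event"].sum() < 1:
        raise ValueError("log-rank needs at least one observed event")
    res = _lifelines_logrank(
        a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    return {"statistic": float(res.test_statistic), "p": float(res.p_value)}
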