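"""Survival and response statistics: Kaplan-Meier curves, log-rank tests,
median dichotomization of a continuous marker, and response-rate tests.

Estimation and testing are delegated to lifelines; this module owns the
marker-split convention, input validation, and the chi-square/Fisher choice
for response tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .errors import UndefinedStatisticError, ValidationError

__all__ = [
    "dichotomize",
    "km_estimate",
    "logrank_test",
    "response_test",
]


def dichotomize(values, mirror: bool = False) -> pd.Series:
    """Median split of a continuous marker into ``low`` / ``high`` labels.

    Default convention: values strictly above the median are ``high``, values
    at or below it ``low`` — on an odd number of distinct values this yields
    the larger group on the low side (e.g. 33/32 on 65 values).  ``mirror``
    flips the tie side (at-median -> high).  Heavy ties at the median can make
    the split unbalanced; the rule is deterministic either way.
    """
    values = pd.Series(values).astype(float)
    if len(values) < 4:
        raise ValidationError("dichotomize needs >= 4 values")
    if not np.isfinite(values).all():
        raise ValidationError("marker values must be finite")
    med = float(values.median())
    if values.nunique() == 1:
        raise UndefinedStatisticError("all marker values identical; no split")
    if mirror:
        labels = np.where(values >= med, "high", "low")
    else:
        labels = np.where(values > med, "high", "low")
    return pd.Series(labels, index=values.index, name="group")


def _validate_records(records: pd.DataFrame) -> None:
    for col in ("time", "event"):
        if col not in records.columns:
            raise ValidationError(f"survival table lacks {col!r} column")
    if (records["time"] < 0).any():
        raise ValidationError("survival times must be >= 0")
    if not records["event"].isin([0, 1]).all():
        raise ValidationError("event indicator must be 0/1")


def km_estimate(
    records: pd.DataFrame, group_col: str = "group"
) -> dict[str, pd.DataFrame]:
    """Product-limit survival curve per group.

    Returns, per group, a step table with columns ``time`` and ``survival``
    (right-continuous, non-increasing, S(0) = 1).
    """
    _validate_records(records)
    out: dict[str, pd.DataFrame] = {}
    has_groups = group_col in records.columns
    groups = records[group_col].unique() if has_groups else ["all"]
    for g in groups:
        sub = records[records[group_col] == g] if has_groups else records
        if len(sub) == 0:
            raise ValidationError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        sf = kmf.survival_function_
        out[str(g)] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float),
             "survival": sf.iloc[:, 0].to_numpy(dtype=float)}
        )
    return out


def logrank_test(
    records: pd.DataFrame, group_col: str = "group"
) -> tuple[float, float]:
    """Log-rank chi-square test across groups (k-1 degrees of freedom).

    Standard observed-minus-expected statistic with hypergeometric variance;
    two groups give the familiar 1-df test.
    """
    _validate_records(records)
    if group_col not in records.columns:
        raise ValidationError(f"survival table lacks {group_col!r} column")
    counts = records[group_col].value_counts()
    if len(counts) < 2:
        raise ValidationError("log-rank needs >= 2 non-empty groups")
    if records["event"].sum() == 0:
        raise ValidationError("log-rank needs >= 1 event")
    res = multivariate_logrank_test(
        records["time"], records[group_col], records["event"]
    )
    return float(res.test_statistic), float(res.p_value)


def response_test(
    table: pd.DataFrame,
) -> tuple[float, str, pd.Series]:
    """Objective response rate per arm plus a homogeneity test.

    ``table`` needs columns ``arm``, ``responders`` and ``total``.  Uses the
    chi-square test without continuity correction; falls back to Fisher's
    exact test for 2x2 tables when any expected cell is below 5 or the total
    sample is under 40 (larger sparse tables keep chi-square with a warning).  Returns ``(p, test_name,
    orr_per_arm)``.
    """
    for col in ("arm", "responders", "total"):
        if col not in table.columns:
            raise ValidationError(f"response table lacks {col!r} column")
    if (table["total"] <= 0).any():
        raise ValidationError("every arm needs total > 0")
    if (table["responders"] < 0).any() or (table["responders"] > table["total"]).any():
        raise ValidationError("responders must lie in [0, total]")
    counts = np.column_stack(
        [table["responders"].to_numpy(), (table["total"] - table["responders"]).to_numpy()]
    ).astype(int)
    orr = pd.Series(
        table["responders"].to_numpy() / table["total"].to_numpy(),
        index=table["arm"],
        name="orr",
    )
    # degenerate margins (all responders or none): no heterogeneity testable
    if counts[:, 0].sum() == 0 or counts[:, 1].sum() == 0:
        return 1.0, "chi2", orr
    chi2, p, _, expected = stats.chi2_contingency(counts, correction=False)
    # Cochran's conditions: small expected cells or a small total sample make
    # the chi-square approximation unreliable; use Fisher on 2x2 tables
    small = (expected < 5).any() or counts.sum() < 40
    if small and counts.shape == (2, 2):
        _, p = stats.fisher_exact(counts)
        return float(p), "fisher", orr
    if (expected < 5).any():
        import warnings

        warnings.warn("expected cell < 5 in a non-2x2 table; chi-square kept",
                      stacklevel=2)
    return float(p), "chi2", orr
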