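"""Precision comparison of DBC-determination methods.

Two coefficient-of-variation metrics, both as percentages of the mean:

``cv_sd``
    %CV(SD) = 100 * SD / mean for repeated measurements of one method
    (sample SD, ddof = 1).
``cv_rmse``
    %CV(RMSE) = 100 * RMSE(reference, candidate) / mean(reference) for
    paired values from two methods. The metric is not symmetric: the first
    argument is the reference whose mean normalizes the error.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .pls import rmse

__all__ = ["ComparisonError", "cv_sd", "cv_rmse", "comparison_report"]


class ComparisonError(ValueError):
    """Invalid input to a method-comparison metric."""


def cv_sd(values) -> float:
    """Percent coefficient of variation: 100 * sample SD / mean."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ComparisonError("cv_sd needs at least 2 values")
    mean = float(x.mean())
    if mean == 0:
        raise ComparisonError("cv_sd undefined for zero mean")
    return float(100.0 * np.std(x, ddof=1) / mean)


def cv_rmse(reference, candidate) -> float:
    """Percent RMSE-based CV: 100 * RMSE(reference, candidate) / mean(reference)."""
    r = np.asarray(reference, dtype=float)
    c = np.asarray(candidate, dtype=float)
    if r.shape != c.shape or r.ndim != 1 or r.size == 0:
        raise ComparisonError("reference and candidate must be equal-length vectors")
    mean = float(r.mean())
    if mean == 0:
        raise ComparisonError("cv_rmse undefined for zero reference mean")
    return float(100.0 * rmse(r, c) / mean)


def comparison_report(table: pd.DataFrame, reference: str | None = None) -> dict:
    """Both %CV metrics for a long-format table of DBC determinations.

    ``table`` needs columns ``run_id``, ``method``, ``dbc_mg_per_mL``.
    Returns per-method %CV(SD) over repeated runs, and %CV(RMSE) for every
    method pair on runs where both methods report a value. If ``reference``
    is given, only pairs with that method as reference are produced;
    otherwise both orientations of each pair are reported.
    """
    required = {"run_id", "method", "dbc_mg_per_mL"}
    if not required.issubset(table.columns):
        raise ComparisonError(f"table must have columns {sorted(required)}")
    wide = table.pivot_table(
        index="run_id", columns="method", values="dbc_mg_per_mL", aggfunc="first"
    )
    methods = list(wide.columns)
    out: dict = {"cv_sd_pct": {}, "cv_rmse_pct": {}}
    for m in methods:
        vals = wide[m].dropna().to_numpy()
        if vals.size >= 2:
            out["cv_sd_pct"][m] = cv_sd(vals)
    if reference is not None:
        if reference not in methods:
            raise ComparisonError(f"reference method '{reference}' not in table")
        pairs = [(reference, m) for m in methods if m != reference]
    else:
        pairs = [p for a, b in combinations(methods, 2) for p in ((a, b), (b, a))]
    for ref, cand in pairs:
        both = wide[[ref, cand]].dropna()
        if len(both) >= 1:
            out["cv_rmse_pct"][f"{cand}_vs_{ref}"] = cv_rmse(
                both[ref].to_numpy(), both[cand].to_numpy()
            )
    return out
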