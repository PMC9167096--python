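"""Clinical case tabulation and the Pearson chi-square test.

Works on case tables with columns ``patient_id, group, age, sex, nevus_type,
site``: nevus-type share tables, type-by-site contingency tables, per-group
demographic (age-bracket and sex) summaries, and the Pearson χ² test of
independence at the conventional α = 0.05 level. Percentages are computed in
full precision and rounded half-up to two decimals only at presentation.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

logger = logging.getLogger("nevuscope")

DEFAULT_AGE_BRACKETS = ((6, 17), (18, 38), (39, 58), (59, 74))


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal round-half-up (so 0.125 → 0.13 at 2 decimals)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _require_cases(cases: pd.DataFrame) -> pd.DataFrame:
    if len(cases) == 0:
        raise ValueError("empty case table")
    return cases


def type_distribution(cases: pd.DataFrame) -> pd.DataFrame:
    """Per-nevus-type count and percent-of-total (half-up, 2 decimals)."""
    cases = _require_cases(cases)
    counts = cases["nevus_type"].value_counts()
    total = int(counts.sum())
    order = [t for t in ("mixed", "junctional", "intradermal", "acral") if t in counts.index]
    order += [t for t in counts.index if t not in order]
    counts = counts.reindex(order)
    return pd.DataFrame({
        "nevus_type": counts.index,
        "count": counts.to_numpy(),
        "percent": [round_half_up(100.0 * c / total) for c in counts.to_numpy()],
    }).reset_index(drop=True)


def site_by_type(cases: pd.DataFrame) -> pd.DataFrame:
    """Contingency table: rows = nevus types, columns = lesion sites."""
    cases = _require_cases(cases)
    table = pd.crosstab(cases["nevus_type"], cases["site"])
    type_order = [t for t in ("mixed", "junctional", "intradermal", "acral") if t in table.index]
    type_order += [t for t in table.index if t not in type_order]
    return table.reindex(type_order)


def validate_contingency_totals(table: pd.DataFrame, claimed_totals: dict) -> list[str]:
    """Compare claimed column totals against cell sums; return discrepancy
    messages (totals are always recomputed from cells, never trusted)."""
    issues = []
    sums = table.sum(axis=0)
    for col, claimed in claimed_totals.items():
        actual = int(sums.get(col, 0))
        if actual != claimed:
            issues.append(f"column {col!r}: claimed total {claimed} but cells sum to {actual}")
    for msg in issues:
        logger.warning("contingency total mismatch: %s", msg)
    return issues


def demographic_summary(cases: pd.DataFrame,
                        age_brackets=DEFAULT_AGE_BRACKETS) -> dict:
    """Per-group age-bracket counts/percents plus the overall sex breakdown.

    ``age_brackets`` are inclusive (lo, hi) pairs and must not overlap.
    Percents are of the group's own n (age table) or of the total (sex table).
    """
    cases = _require_cases(cases)
    brackets = sorted(tuple(b) for b in age_brackets)
    for (lo1, hi1), (lo2, hi2) in zip(brackets, brackets[1:]):
        if hi1 >= lo2:
            raise ValueError(f"overlapping age brackets ({lo1}-{hi1}, {lo2}-{hi2})")

    age_rows = []
    for grp, sub in cases.groupby("group"):
        n_grp = len(sub)
        for lo, hi in brackets:
            c = int(((sub["age"] >= lo) & (sub["age"] <= hi)).sum())
            age_rows.append({"group": grp, "bracket": f"{lo}-{hi}", "count": c,
                             "percent": round_half_up(100.0 * c / n_grp)})
    n = len(cases)
    sex_counts = cases["sex"].value_counts()
    sex_rows = [{"sex": s, "count": int(c), "percent": round_half_up(100.0 * c / n)}
                for s, c in sex_counts.items()]
    return {"age": pd.DataFrame(age_rows), "sex": pd.DataFrame(sex_rows)}


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson χ² test of independence on an r×c contingency table.

    Returns ``(statistic, dof, p_value)`` with expected counts from the
    row/column margins and dof = (r−1)(c−1). Rows/columns with zero margins
    are rejected (expected counts would be zero).
    """
    counts = np.asarray(table, dtype=np.float64)
    if counts.ndim != 2 or min(counts.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    if (row == 0).any():
        raise ValueError(f"zero margin in row {int(np.flatnonzero(row == 0)[0])}")
    if (col == 0).any():
        raise ValueError(f"zero margin in column {int(np.flatnonzero(col == 0)[0])}")
    expected = np.outer(row, col) / counts.sum()
    stat = float(np.sum((counts - expected) ** 2 / expected))
    dof = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    p = float(chi2_dist.sf(stat, dof))
    return stat, dof, p
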