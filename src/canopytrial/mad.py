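"""Check-plot spatial adjustment for Type-II Modified Augmented Designs.

Two adjustment methods are implemented for unreplicated trials whose
blocks carry a centred, replicated primary check and two once-per-block
secondary checks:

* **Method I** (adjustment by design structure): a row+column ANOVA model
  of the primary-check values, ``Y_check1 = mu + R_i + C_j + eps``, gives
  the adjusted test value ``Y_adj = Y - R_i - C_j + 2 mu`` where R_i and
  C_j are primary-check means over the *i*-th block row and *j*-th block
  column.  Because each block contributes exactly one centred check, the
  row/column resolution the checks can estimate is the block grid; every
  plot inherits its block's (row, column) effect.
* **Method III** (adjustment by regression): per-block primary-check
  values are regressed on the per-block secondary-check averages,
  ``check1_b = alpha + beta * check2avg_b``, and every plot in block *b*
  is corrected as ``Y_adj = Y - beta * (check1_b - check2_ref) + alpha``.

The choice between raw data, Method I and Method III follows the relative
efficiency RE = 100 x IWP_original / IWP_adjusted, where the intra-whole-
plot (IWP) error pools the squared deviations of each secondary check
about its own across-block mean:

    IWP = (SS_1 + SS_2) / (2 * (n1 + n2 - 2)).

Selection rule: both RE < 100 -> no adjustment; exactly one RE >= 100 ->
that method; both >= 100 -> the higher (ties to Method I, which uses the
design structure of every block).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("block_id", "block_row", "block_col", "role", "value")


class Method3UnavailableError(ValueError):
    """Raised when the regression adjustment is undefined (degenerate checks)."""


def _validate(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise KeyError(f"plot table lacks required columns: {missing}")


@dataclass
class Method1Fit:
    """Primary-check row/column means and grand mean (block-grid resolution)."""

    row_means: dict[int, float]
    col_means: dict[int, float]
    grand_mean: float


@dataclass
class Method3Fit:
    """Regression of per-block primary check on secondary-check average."""

    beta: float
    alpha: float
    check2_reference: float | dict[int, float]
    per_block_reference: bool = False


@dataclass
class AdjustmentDecision:
    """Outcome of the RE-based selection between raw, Method I and Method III."""

    re_method1: float | None
    re_method3: float | None
    chosen: str  # "none" | "method1" | "method3"
    adjusted: pd.DataFrame
    iwp_original: float
    iwp_method1: float | None = None
    iwp_method3: float | None = None
    fit1: Method1Fit | None = None
    fit3: Method3Fit | None = None


def method1_adjust(table: pd.DataFrame) -> tuple[pd.DataFrame, Method1Fit]:
    """Design-structure adjustment ``Y_adj = Y - R_i - C_j + 2 mu``.

    R_i (C_j) is the mean primary-check value over block row *i* (block
    column *j*); block rows/columns without a primary check fall back to
    the grand check mean, i.e. a zero estimated deviation.  All plots,
    checks included, are adjusted (checks are needed for the IWP
    diagnostics of the adjusted table).
    """
    _validate(table)
    check1 = table[table["role"] == "check1"]
    if check1.empty:
        raise ValueError("Method I needs at least one primary-check (check1) plot")
    mu = float(check1["value"].mean())
    row_means = check1.groupby("block_row")["value"].mean().to_dict()
    col_means = check1.groupby("block_col")["value"].mean().to_dict()
    ri = table["block_row"].map(row_means).fillna(mu).to_numpy()
    cj = table["block_col"].map(col_means).fillna(mu).to_numpy()
    out = table.copy()
    out["value"] = table["value"].to_numpy() - ri - cj + 2.0 * mu
    return out, Method1Fit(row_means=row_means, col_means=col_means, grand_mean=mu)


def _per_block_checks(table: pd.DataFrame) -> pd.DataFrame:
    """Per-block primary-check value and secondary-check average."""
    c1 = table[table["role"] == "check1"].groupby("block_id")["value"].mean()
    c2 = (
        table[table["role"].isin(["check2a", "check2b"])]
        .groupby("block_id")["value"]
        .mean()
    )
    return pd.DataFrame({"check1": c1, "check2avg": c2})


def method3_adjust(
    table: pd.DataFrame, per_block_reference: bool = False
) -> tuple[pd.DataFrame, Method3Fit]:
    """Regression adjustment ``Y_adj = Y - beta (check1_b - check2_ref) + alpha``.

    beta and alpha come from ordinary least squares of the per-block
    primary-check value on the per-block secondary-check average (one pair
    per block).  The reference ``check2_ref`` is by default the mean of
    the per-block secondary-check averages over all blocks; with
    ``per_block_reference=True`` each block uses its own average.
    """
    _validate(table)
    pairs = _per_block_checks(table).dropna()
    if len(pairs) < 3:
        raise ValueError(
            "Method III needs >= 3 blocks with both primary and secondary checks"
        )
    x = pairs["check2avg"].to_numpy()
    y = pairs["check1"].to_numpy()
    if np.ptp(x) == 0 or np.var(x) < 1e-30 * max(1.0, np.mean(x) ** 2):
        raise Method3UnavailableError(
            "secondary-check averages have zero variance; regression slope undefined"
        )
    beta, alpha = np.polyfit(x, y, 1)
    if per_block_reference:
        ref_map = pairs["check2avg"].to_dict()
        ref = table["block_id"].map(ref_map).to_numpy()
        reference: float | dict[int, float] = ref_map
    else:
        grand = float(x.mean())
        ref = np.full(len(table), grand)
        reference = grand
    c1_map = pairs["check1"].to_dict()
    c1 = table["block_id"].map(c1_map).to_numpy()
    if np.any(pd.isna(c1)):
        bad = sorted(set(table.loc[pd.isna(c1), "block_id"]))
        raise ValueError(f"blocks without usable checks: {bad}")
    out = table.copy()
    out["value"] = table["value"].to_numpy() - beta * (c1 - ref) + alpha
    return out, Method3Fit(
        beta=float(beta), alpha=float(alpha),
        check2_reference=reference, per_block_reference=per_block_reference,
    )


def iwp_error(table: pd.DataFrame) -> float:
    """Intra-whole-plot error pooled over the two secondary checks.

    ``(SS_1 + SS_2) / (2 (n1 + n2 - 2))`` where SS_k is the sum of squared
    deviations of secondary check *k*'s per-block values about their mean
    and n_k the number of blocks carrying it.
    """
    _validate(table)
    ss = 0.0
    n_total = 0
    for role in ("check2a", "check2b"):
        vals = table.loc[table["role"] == role].groupby("block_id")["value"].mean()
        n_k = len(vals)
        if n_k < 2:
            raise ValueError(
                f"secondary check {role!r} observed in {n_k} block(s); need >= 2"
            )
        ss += float(((vals - vals.mean()) ** 2).sum())
        n_total += n_k
    if n_total <= 2:
        raise ValueError("IWP error undefined: n1 + n2 must exceed 2")
    return ss / (2.0 * (n_total - 2))


def relative_efficiency(iwp_original: float, iwp_adjusted: float) -> float:
    """RE = 100 x IWP_original / IWP_adjusted; >= 100 means adjustment helped."""
    if iwp_original < 0 or iwp_adjusted < 0:
        raise ValueError("IWP errors must be non-negative")
    if iwp_adjusted == 0.0:
        if iwp_original == 0.0:
            return 100.0  # no information either way
        warnings.warn("adjusted IWP error is zero; RE reported as +inf")
        return float("inf")
    return 100.0 * iwp_original / iwp_adjusted


def selection_rule(re1: float, re3: float | None) -> str:
    """The three-rule adjustment decision on a pair of RE values (100 scale).

    Both below 100 -> no adjustment; exactly one at or above 100 -> that
    method; both at or above 100 -> the higher (ties go to Method I, which
    uses the design structure of every block).  ``re3=None`` means
    Method III was unavailable and only Method I competes.
    """
    if re3 is None:
        return "method1" if re1 >= 100.0 else "none"
    if re1 < 100.0 and re3 < 100.0:
        return "none"
    if re1 >= 100.0 and re3 < 100.0:
        return "method1"
    if re3 >= 100.0 and re1 < 100.0:
        return "method3"
    return "method1" if re1 >= re3 else "method3"


def select_adjustment(
    table: pd.DataFrame, per_block_reference: bool = False
) -> AdjustmentDecision:
    """Compute both adjustments and apply the RE selection rule.

    If Method III is unavailable (degenerate secondary checks) only
    Method I competes.  The returned table carries the chosen values (raw
    if no method reaches RE 100).
    """
    _validate(table)
    iwp_orig = iwp_error(table)
    adj1, fit1 = method1_adjust(table)
    iwp1 = iwp_error(adj1)
    re1 = relative_efficiency(iwp_orig, iwp1)
    try:
        adj3, fit3 = method3_adjust(table, per_block_reference=per_block_reference)
        iwp3 = iwp_error(adj3)
        re3: float | None = relative_efficiency(iwp_orig, iwp3)
    except Method3UnavailableError:
        adj3, fit3, iwp3, re3 = None, None, None, None

    chosen = selection_rule(re1, re3)

    adjusted = {"none": table, "method1": adj1, "method3": adj3}[chosen]
    return AdjustmentDecision(
        re_method1=re1, re_method3=re3, chosen=chosen,
        adjusted=adjusted.copy(), iwp_original=iwp_orig,
        iwp_method1=iwp1, iwp_method3=iwp3, fit1=fit1, fit3=fit3,
    )


def adjust_by_stratum(
    table: pd.DataFrame,
    strata: tuple[str, ...] = ("location", "spacing"),
    per_block_reference: bool = False,
) -> tuple[pd.DataFrame, dict[tuple, AdjustmentDecision]]:
    """Apply :func:`select_adjustment` independently within each stratum.

    Mirrors running the adjustment separately per location x row-spacing
    combination.  Returns the concatenated adjusted table and the decision
    per stratum key.
    """
    for col in strata:
        if col not in table.columns:
            raise KeyError(f"stratum column {col!r} missing from table")
    decisions: dict[tuple, AdjustmentDecision] = {}
    pieces = []
    for key, grp in table.groupby(list(strata), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        dec = select_adjustment(grp, per_block_reference=per_block_reference)
        decisions[key] = dec
        pieces.append(dec.adjusted)
    return pd.concat(pieces).loc[table.index], decisions
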