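"""Shared fixtures and independent brute-force oracles.

The oracles recompute the spatial-adjustment quantities with plain Python
loops over the plot records, independently of the vectorized
implementations they are used to check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from canopytrial import synthetic as syn


# ---------------------------------------------------------------------------
# brute-force oracles (loops only)


def brute_method1(table: pd.DataFrame) -> pd.DataFrame:
    """Design-structure adjustment recomputed with explicit loops."""
    checks = [rec for rec in table.to_dict("records") if rec["role"] == "check1"]
    mu = sum(r["value"] for r in checks) / len(checks)
    row_sum: dict = {}
    col_sum: dict = {}
    for r in checks:
        row_sum.setdefault(r["block_row"], []).append(r["value"])
        col_sum.setdefault(r["block_col"], []).append(r["value"])
    row_mean = {k: sum(v) / len(v) for k, v in row_sum.items()}
    col_mean = {k: sum(v) / len(v) for k, v in col_sum.items()}
    out = table.copy()
    vals = []
    for rec in table.to_dict("records"):
        ri = row_mean.get(rec["block_row"], mu)
        cj = col_mean.get(rec["block_col"], mu)
        vals.append(rec["value"] - ri - cj + 2 * mu)
    out["value"] = vals
    return out


def brute_method3(table: pd.DataFrame, per_block_reference: bool = False) -> pd.DataFrame:
    """Regression adjustment recomputed with explicit loops and closed-form OLS."""
    c1: dict = {}
    c2: dict = {}
    for rec in table.to_dict("records"):
        if rec["role"] == "check1":
            c1.setdefault(rec["block_id"], []).append(rec["value"])
        elif rec["role"] in ("check2a", "check2b"):
            c2.setdefault(rec["block_id"], []).append(rec["value"])
    blocks = sorted(set(c1) & set(c2))
    x = [sum(c2[b]) / len(c2[b]) for b in blocks]
    y = [sum(c1[b]) / len(c1[b]) for b in blocks]
    n = len(blocks)
    xbar, ybar = sum(x) / n, sum(y) / n
    sxx = sum((xi - xbar) ** 2 for xi in x)
    sxy = sum((xi - xbar) * (yi - ybar) for xi, yi in zip(x, y))
    beta = sxy / sxx
    alpha = ybar - beta * xbar
    c1b = {b: sum(c1[b]) / len(c1[b]) for b in blocks}
    c2b = {b: sum(c2[b]) / len(c2[b]) for b in blocks}
    out = table.copy()
    vals = []
    for rec in table.to_dict("records"):
        b = rec["block_id"]
        ref = c2b[b] if per_block_reference else xbar
        vals.append(rec["value"] - beta * (c1b[b] - ref) + alpha)
    out["value"] = vals
    return out


def brute_iwp(table: pd.DataFrame) -> float:
    """Intra-whole-plot error recomputed with explicit loops."""
    ss_total = 0.0
    n_total = 0
    for role in ("check2a", "check2b"):
        per_block: dict = {}
        for rec in table.to_dict("records"):
            if rec["role"] == role:
                per_block.setdefault(rec["block_id"], []).append(rec["value"])
        vals = [sum(v) / len(v) for v in per_block.values()]
        mean = sum(vals) / len(vals)
        ss_total += sum((v - mean) ** 2 for v in vals)
        n_total += len(vals)
    return ss_total / (2 * (n_total - 2))


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def small_layout() -> syn.FieldLayout:
    """3x3 block grid of 5x5 blocks: 9 blocks, 225 plots."""
    return syn.generate_layout(9, (5, 5), seed=11, n_test_genotypes=20)


def random_trial(seed: int, n_blocks: int = 6, spatial_sd: float = 2.0,
                 noise_sd: float = 0.5) -> pd.DataFrame:
    """A random small MAD trial table for oracle-equivalence checks."""
    rng = np.random.default_rng(seed)
    lay = syn.generate_layout(n_blocks, (3, 3), seed=seed, n_test_genotypes=8)
    effects = {g: float(rng.normal(0, 1)) for g in {p.genotype_id for p in lay.plots}}
    bg_rows, bg_cols = lay.block_grid
    r = rng.normal(0, spatial_sd, bg_rows)
    c = rng.normal(0, spatial_sd, bg_cols)
    truth = syn.TrialTruth(effects, r - r.mean(), c - c.mean(),
                           grand_mean=10.0, noise_sd=noise_sd)
    return syn.simulate_trial(lay, truth, seed=seed + 1)
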