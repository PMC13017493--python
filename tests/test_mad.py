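"""Spatial adjustment: oracle equivalence, identities and the selection rule."""

import numpy as np
import pandas as pd
import pytest
from conftest import brute_iwp, brute_method1, brute_method3, random_trial

from canopytrial import mad, synthetic as syn


def toy_table(values_by_role_block, block_positions):
    """Assemble a minimal plot table from explicit per-block role values."""
    rows = []
    for (block, role), value in values_by_role_block.items():
        br, bc = block_positions[block]
        rows.append({"block_id": block, "block_row": br, "block_col": bc,
                     "role": role, "value": float(value)})
    return pd.DataFrame(rows)


class TestMethod1:
    def test_flat_checks_leave_values_unchanged(self, small_layout):
        tab = small_layout.to_frame()
        rng = np.random.default_rng(0)
        tab["value"] = rng.normal(10, 2, len(tab))
        tab.loc[tab.role == "check1", "value"] = 10.0
        adj, fit = mad.method1_adjust(tab)
        assert np.allclose(adj["value"], tab["value"])
        assert fit.grand_mean == 10.0

    def test_noiseless_gradient_fully_removed(self):
        # 3x3 block grid with additive block-row/block-column offsets:
        # every adjusted value collapses to g + mean(r) + mean(c)
        lay = syn.generate_layout(9, (5, 5), seed=2, n_test_genotypes=6)
        rng = np.random.default_rng(3)
        effects = {g: float(rng.normal(0, 1))
                   for g in {p.genotype_id for p in lay.plots}}
        r = np.array([-2.0, 0.5, 1.5])
        c = np.array([1.0, 1.0, -2.0])
        truth = syn.TrialTruth(effects, r, c, grand_mean=7.0, noise_sd=0.0)
        tab = syn.simulate_trial(lay, truth, seed=4)
        adj, _ = mad.method1_adjust(tab)
        expected = (
            adj["genotype_id"].map(effects) + 7.0 + r.mean() + c.mean()
        )
        assert np.allclose(adj["value"], expected, atol=1e-9)
        spread = adj.groupby("genotype_id")["value"].agg(np.ptp)
        assert spread.max() < 1e-9

    def test_single_block_row_reduces_to_column_centering(self):
        # 1x5 strip of blocks: R_i is constant (= mu), C_j varies per block
        lay = syn.generate_layout(5, (3, 3), seed=1, block_grid=(1, 5))
        tab = lay.to_frame()
        tab["value"] = 1.0
        col_vals = {0: 3.0, 1: 5.0, 2: 4.0, 3: 6.0, 4: 2.0}
        tab.loc[tab.role == "check1", "value"] = tab.loc[
            tab.role == "check1", "block_col"].map(col_vals)
        adj, fit = mad.method1_adjust(tab)
        assert len(set(fit.row_means.values())) == 1
        assert np.isclose(list(fit.row_means.values())[0], fit.grand_mean)
        mu = np.mean(list(col_vals.values()))
        expected = tab["value"] - tab["block_col"].map(col_vals) + mu
        assert np.allclose(adj["value"], expected)

    def test_mean_preserved_when_checks_flat(self, small_layout):
        tab = small_layout.to_frame()
        rng = np.random.default_rng(5)
        tab["value"] = rng.normal(0, 1, len(tab))
        tab.loc[tab.role == "check1", "value"] = 2.5
        adj, _ = mad.method1_adjust(tab)
        assert np.isclose(adj["value"].mean(), tab["value"].mean())

    def test_no_checks_rejected(self, small_layout):
        tab = small_layout.to_frame()
        tab["value"] = 1.0
        with pytest.raises(ValueError, match="check1"):
            mad.method1_adjust(tab[tab.role != "check1"])


class TestMethod3:
    def test_exact_regression_recovered(self):
        # check1_b = 2 * check2avg_b + 1 over 5 blocks -> beta=2, alpha=1
        vals = {}
        pos = {b: (0, b) for b in range(5)}
        c2avg = [3.0, 4.0, 5.0, 6.0, 7.0]
        for b, x in enumerate(c2avg):
            vals[(b, "check2a")] = x - 0.5
            vals[(b, "check2b")] = x + 0.5
            vals[(b, "check1")] = 2 * x + 1
            vals[(b, "test")] = 10.0
        tab = toy_table(vals, pos)
        _, fit = mad.method3_adjust(tab)
        assert np.isclose(fit.beta, 2.0)
        assert np.isclose(fit.alpha, 1.0)

    def test_perfect_agreement_per_block_reference_is_identity(self):
        vals = {}
        pos = {b: (0, b) for b in range(4)}
        for b, x in enumerate([3.0, 5.0, 4.0, 6.0]):
            vals[(b, "check2a")] = x
            vals[(b, "check2b")] = x
            vals[(b, "check1")] = x
            vals[(b, "test")] = 8.0 + b
        tab = toy_table(vals, pos)
        adj, fit = mad.method3_adjust(tab, per_block_reference=True)
        assert np.isclose(fit.beta, 1.0) and np.isclose(fit.alpha, 0.0, atol=1e-12)
        assert np.allclose(adj["value"], tab["value"])

    def test_constant_secondary_checks_unavailable(self):
        vals = {}
        pos = {b: (0, b) for b in range(4)}
        for b in range(4):
            vals[(b, "check2a")] = 5.0
            vals[(b, "check2b")] = 5.0
            vals[(b, "check1")] = 4.0 + b
            vals[(b, "test")] = 1.0
        with pytest.raises(mad.Method3UnavailableError):
            mad.method3_adjust(toy_table(vals, pos))

    def test_too_few_blocks_rejected(self):
        vals = {(0, "check1"): 1.0, (0, "check2a"): 1.0, (0, "check2b"): 2.0,
                (1, "check1"): 2.0, (1, "check2a"): 2.0, (1, "check2b"): 3.0}
        with pytest.raises(ValueError, match="3 blocks"):
            mad.method3_adjust(toy_table(vals, {0: (0, 0), 1: (0, 1)}))


class TestIWPError:
    def test_hand_computed_example(self):
        # check A per-block {1,2,3}, check B {2,4} -> (2+2)/(2*3)
        vals = {(0, "check2a"): 1, (1, "check2a"): 2, (2, "check2a"): 3,
                (0, "check2b"): 2, (1, "check2b"): 4}
        tab = toy_table(vals, {b: (0, b) for b in range(3)})
        assert np.isclose(mad.iwp_error(tab), 4.0 / 6.0)

    def test_constant_checks_zero_error(self):
        vals = {(b, r): 5.0 for b in range(3) for r in ("check2a", "check2b")}
        tab = toy_table(vals, {b: (0, b) for b in range(3)})
        assert mad.iwp_error(tab) == 0.0

    def test_single_observation_rejected(self):
        vals = {(0, "check2a"): 1.0, (0, "check2b"): 2.0}
        with pytest.raises(ValueError, match=">= 2"):
            mad.iwp_error(toy_table(vals, {0: (0, 0)}))


class TestRelativeEfficiency:
    def test_arithmetic(self):
        assert mad.relative_efficiency(1.0, 1.0) == 100.0
        assert np.isclose(mad.relative_efficiency(0.6667, 0.33335), 200.0)
        assert mad.relative_efficiency(1.0, 2.0) < 100.0

    def test_degenerate_cases(self):
        assert mad.relative_efficiency(0.0, 0.0) == 100.0
        with pytest.warns(UserWarning):
            assert mad.relative_efficiency(1.0, 0.0) == np.inf

    @pytest.mark.parametrize("c", [0.1, 3.0, 1e4])
    def test_scale_invariance(self, c):
        tab = random_trial(21)
        re_base = mad.relative_efficiency(
            mad.iwp_error(tab), mad.iwp_error(mad.method1_adjust(tab)[0]))
        scaled = tab.copy()
        scaled["value"] *= c
        re_scaled = mad.relative_efficiency(
            mad.iwp_error(scaled), mad.iwp_error(mad.method1_adjust(scaled)[0]))
        assert np.isclose(re_base, re_scaled)


class TestSelectionRule:
    @pytest.mark.parametrize("re1,re3,expected", [
        (95.0, 80.0, "none"),
        (90.0, 130.0, "method3"),
        (130.0, 90.0, "method1"),
        (140.0, 120.0, "method1"),
        (120.0, 140.0, "method3"),
        (120.0, 120.0, "method1"),   # tie at/above 100 -> design structure
        (99.999, 99.999, "none"),
        (100.0, 99.0, "method1"),
        (95.0, None, "none"),
        (105.0, None, "method1"),
    ])
    def test_three_rules(self, re1, re3, expected):
        assert mad.selection_rule(re1, re3) == expected

    def test_decision_carries_chosen_values(self):
        tab = random_trial(33, spatial_sd=3.0, noise_sd=0.3)
        dec = mad.select_adjustment(tab)
        assert dec.chosen in ("none", "method1", "method3")
        assert dec.re_method1 == mad.relative_efficiency(
            dec.iwp_original, dec.iwp_method1)
        if dec.chosen == "none":
            assert np.allclose(dec.adjusted["value"], tab["value"])


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force(self, seed):
        tab = random_trial(seed)
        adj1, _ = mad.method1_adjust(tab)
        assert np.allclose(adj1["value"], brute_method1(tab)["value"], rtol=1e-12)
        adj3, _ = mad.method3_adjust(tab)
        assert np.allclose(adj3["value"], brute_method3(tab)["value"], rtol=1e-12)
        assert np.isclose(mad.iwp_error(tab), brute_iwp(tab), rtol=1e-12)

    def test_stratified_adjustment_independent(self):
        a = random_trial(51, spatial_sd=3.0, noise_sd=0.3)
        b = random_trial(52, spatial_sd=0.1, noise_sd=1.0)
        a["location"], a["spacing"] = "SF", "76cm"
        b["location"], b["spacing"] = "EF", "38cm"
        both = pd.concat([a, b], ignore_index=True)
        adjusted, decisions = mad.adjust_by_stratum(both)
        assert set(decisions) == {("EF", "38cm"), ("SF", "76cm")}
        solo = mad.select_adjustment(a)
        stratum_a = adjusted[both["location"] == "SF"]
        assert np.allclose(stratum_a["value"], solo.adjusted["value"])
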