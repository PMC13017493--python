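"""Generator contracts: layout geometry, trial truth, curves, images, clouds."""

import numpy as np
import pandas as pd
import pytest

from canopytrial import aci, synthetic as syn


class TestGenerateLayout:
    def test_mad_geometry(self, small_layout):
        df = small_layout.to_frame()
        assert len(df) == 9 * 25
        checks = df[df.role == "check1"]
        assert len(checks) == 9
        # primary check sits at the central cell (2, 2) of every 5x5 block
        for _, rec in checks.iterrows():
            assert rec.row_index % 5 == 2 and rec.column_index % 5 == 2
        # each secondary check exactly once per block, never central
        for role in ("check2a", "check2b"):
            sec = df[df.role == role]
            assert sorted(sec.block_id) == list(range(9))
            assert not ((sec.row_index % 5 == 2) & (sec.column_index % 5 == 2)).any()

    def test_unique_addresses_and_roles(self, small_layout):
        df = small_layout.to_frame()
        assert not df.duplicated(["block_id", "row_index", "column_index"]).any()
        assert not df.duplicated(["row_index", "column_index"]).any()
        assert set(df.role) == set(syn.ROLES)
        assert (df.row_index >= 0).all() and (df.column_index >= 0).all()

    def test_seed_determinism(self):
        a = syn.generate_layout(4, (5, 5), seed=3).to_frame()
        b = syn.generate_layout(4, (5, 5), seed=3).to_frame()
        pd.testing.assert_frame_equal(a, b)
        c = syn.generate_layout(4, (5, 5), seed=4).to_frame()
        assert not a.equals(c)

    @pytest.mark.parametrize("shape", [(4, 5), (5, 4), (2, 2)])
    def test_even_block_shape_rejected(self, shape):
        with pytest.raises(ValueError, match="centre"):
            syn.generate_layout(2, shape, seed=0)

    def test_check_plots_carry_parental_genotypes(self, small_layout):
        df = small_layout.to_frame()
        for role, gid in syn.CHECK_GENOTYPES.items():
            assert (df.loc[df.role == role, "genotype_id"] == gid).all()


class TestSimulateTrial:
    def _flat_truth(self, layout, mu=10.0, sd=0.0):
        effects = dict.fromkeys({p.genotype_id for p in layout.plots}, 0.0)
        r, c = layout.block_grid
        return syn.TrialTruth(effects, np.zeros(r), np.zeros(c),
                              grand_mean=mu, noise_sd=sd)

    def test_flat_noiseless_field_is_constant(self, small_layout):
        tab = syn.simulate_trial(small_layout, self._flat_truth(small_layout), seed=0)
        assert np.allclose(tab["value"], 10.0)

    def test_additivity_of_row_effect(self):
        lay = syn.generate_layout(9, (5, 5), seed=0, n_test_genotypes=5)
        effects = dict.fromkeys({p.genotype_id for p in lay.plots}, 5.0)
        truth = syn.TrialTruth(effects, np.array([-1.0, 0.0, 1.0]), np.zeros(3),
                               grand_mean=0.0, noise_sd=0.0)
        tab = syn.simulate_trial(lay, truth, seed=0)
        top = tab[(tab.block_row == 0) & (tab.block_col == 1)]
        assert np.allclose(top["value"], 4.0)

    def test_missing_genotype_effect_named(self, small_layout):
        truth = self._flat_truth(small_layout)
        del truth.genotype_effects["recurrent_parent"]
        with pytest.raises(KeyError, match="recurrent_parent"):
            syn.simulate_trial(small_layout, truth, seed=0)

    def test_check_mean_within_clt_bound(self):
        # 36 blocks -> 36 primary checks; sample mean within 3 SE of truth
        lay = syn.generate_layout(36, (3, 3), seed=5, n_test_genotypes=10)
        truth = self._flat_truth(lay, mu=10.0, sd=0.5)
        tab = syn.simulate_trial(lay, truth, seed=7)
        c1 = tab.loc[tab.role == "check1", "value"]
        assert abs(c1.mean() - 10.0) < 3 * 0.5 / np.sqrt(len(c1))

    def test_uncentered_effects_rejected(self, small_layout):
        effects = dict.fromkeys(
            {p.genotype_id for p in small_layout.plots}, 0.0)
        with pytest.raises(ValueError, match="summing to 0"):
            syn.TrialTruth(effects, np.array([1.0, 1.0, 1.0]), np.zeros(3))


class TestTimecourse:
    def test_logistic_midpoint_and_length(self):
        lay = syn.generate_layout(1, (3, 3), seed=0)
        p = syn.CurveParams(family="logistic", asymptote=100.0,
                            midpoint_day=38.0, rate=0.2, noise_sd=0.0)
        days = np.linspace(25, 95, 10)
        df, truth = syn.simulate_timecourse(lay, p, days, seed=0)
        assert (df.groupby("plot_id").size() == 10).all()
        assert truth["cc50_day"] == 38.0
        at38 = p.evaluate([38.0])
        assert np.isclose(at38, 50.0)

    def test_seed_determinism_and_validation(self):
        lay = syn.generate_layout(1, (3, 3), seed=0)
        p = syn.CurveParams(noise_sd=1.0)
        days = [25, 40, 60, 80]
        a, _ = syn.simulate_timecourse(lay, p, days, seed=9)
        b, _ = syn.simulate_timecourse(lay, p, days, seed=9)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError, match="empty"):
            syn.simulate_timecourse(lay, p, [], seed=0)
        with pytest.raises(ValueError, match="increasing"):
            syn.simulate_timecourse(lay, p, [25, 25, 40], seed=0)


class TestPlotImage:
    def test_exact_pixel_budget(self):
        img, mask = syn.simulate_plot_image(0.635, (100, 100), seed=1)
        assert mask.sum() == 6350
        assert img.shape == (100, 100, 4)
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_zero_coverage_all_soil(self):
        _, mask = syn.simulate_plot_image(0.0, (20, 20), seed=0)
        assert not mask.any()

    def test_exg_sign_separates_classes(self):
        img, mask = syn.simulate_plot_image(0.4, (50, 50), seed=2)
        exg = 2 * img[:, :, 1] - img[:, :, 0] - img[:, :, 2]
        assert (exg[mask] > 0).all()
        assert (exg[~mask] <= 0).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            syn.simulate_plot_image(0.5, (0, 10), seed=0)
        with pytest.raises(ValueError):
            syn.simulate_plot_image(1.5, (10, 10), seed=0)


class TestPointCloud:
    def test_count_and_containment(self):
        cloud = syn.simulate_point_cloud((2.0, 1.0), 0.5, 1e4, seed=0)
        assert cloud.points.shape == (10000, 3)
        lo = cloud.points.min(axis=0)
        hi = cloud.points.max(axis=0)
        assert (lo >= 0).all()
        assert (hi <= np.array([2.0, 1.0, 0.5])).all()

    def test_zero_height_empty(self):
        cloud = syn.simulate_point_cloud((2.0, 1.0), 0.0, 1e4, seed=0)
        assert cloud.points.shape[0] == 0

    def test_zero_density_rejected(self):
        with pytest.raises(ValueError, match="density"):
            syn.simulate_point_cloud((2.0, 1.0), 0.5, 0.0, seed=0)


class TestACiGeneration:
    def test_protocol_length_14(self):
        curve = syn.simulate_aci_curve(100.0, 180.0, 1.2)
        assert len(curve) == 14
        assert np.allclose(curve.ci, aci.PROTOCOL_CI_SETPOINTS)

    def test_compensation_point(self):
        gamma_star, _, _ = aci.BERNACCHI.at(25.0)
        curve = syn.simulate_aci_curve(
            100.0, 180.0, 1.2, ci_setpoints=list(aci.PROTOCOL_CI_SETPOINTS) + [gamma_star]
        )
        assert np.isclose(curve.a[-1], -1.2, atol=1e-10)

    def test_invalid_setpoints_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            syn.simulate_aci_curve(100.0, 180.0, 1.2, ci_setpoints=[400.0, -1.0])


def test_leaf_ratio_bimodal_means():
    df = syn.simulate_leaf_ratios(2000, seed=0)
    for shape, mean, sd in (("broad", 1.3, 0.12), ("narrow", 2.4, 0.25)):
        vals = df.loc[df.leaf_shape == shape, "leaf_ratio"]
        assert abs(vals.mean() - mean) < 3 * sd / np.sqrt(len(vals))
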