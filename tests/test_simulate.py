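"""Synthetic-data generator: shapes, ground truth, statistical structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from larvascreen.devassay import cumulative_fraction
from larvascreen.layout import Role, default_screen_layout
from larvascreen.simulate import (ArtifactModel, DevArm, LarvaSpec,
                                  PlateGeometry, ScreenConfig, SizeModel,
                                  render_larva, render_plate,
                                  sample_well_specs, simulate_dev_events,
                                  simulate_screen_areas)
from larvascreen import screen_stats as ss

GEO = PlateGeometry()


class TestRenderLarva:
    @pytest.mark.parametrize("length,width", [(0, 8), (-3, 8), (40, 0), (5, 8)])
    def test_degenerate_dimensions_rejected(self, length, width):
        with pytest.raises(ValueError):
            LarvaSpec(length=length, width=width)

    def test_straight_capsule_matches_analytic_area(self):
        # stadium area oracle; generic sub-pixel position avoids lattice ties
        spec = LarvaSpec(length=40, width=8, curvature=0.0, position=(0.5, 0.37))
        analytic = 40 * 8 + np.pi * 8 ** 2 / 4
        r = render_larva(spec)
        assert abs(r.area - analytic) / analytic < 0.05
        assert r.area == int(r.mask.sum())

    def test_sampled_larvae_fit_inside_well_disc(self):
        rng = np.random.default_rng(5)
        center = GEO.well_center(3, 4)
        specs, rends = sample_well_specs(3, 280.0, 0.15, center, GEO, rng)
        for s, r in zip(specs, rends):
            ys, xs = np.nonzero(r.mask)
            yy = ys + r.offset[0] - center[0]
            xx = xs + r.offset[1] - center[1]
            assert np.hypot(yy, xx).max() <= GEO.well_radius


class TestRenderPlate:
    def test_empty_plate_has_zero_ground_truth(self):
        layout = default_screen_layout("E")
        img, truth = render_plate(layout, {}, rng=np.random.default_rng(0),
                                  geometry=GEO)
        assert (truth["true_area"] == 0).all()
        assert img.shape == GEO.image_shape

    def test_ground_truth_is_sum_of_disjoint_masks(self):
        layout = default_screen_layout("B")
        cy, cx = GEO.well_center(0, 0)
        specs = [LarvaSpec(30, 7, 0.0, position=(cy - 30, cx), orientation=0.3),
                 LarvaSpec(30, 7, 0.0, position=(cy + 30, cx), orientation=1.2),
                 LarvaSpec(30, 7, 0.0, position=(cy, cx + 30), orientation=2.0)]
        areas = [render_larva(s).area for s in specs]
        _, truth = render_plate(layout, {(0, 0): specs},
                                rng=np.random.default_rng(0), geometry=GEO)
        assert truth.loc[(truth.row == 0) & (truth.col == 0),
                         "true_area"].iloc[0] == sum(areas)

    def test_oversized_larva_rejected(self):
        layout = default_screen_layout("B")
        cy, cx = GEO.well_center(0, 0)
        bad = LarvaSpec(length=200, width=40, position=(cy, cx))
        with pytest.raises(ValueError, match="does not fit"):
            render_plate(layout, {(0, 0): [bad]},
                         rng=np.random.default_rng(0), geometry=GEO)

    def test_overlapping_well_geometry_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            PlateGeometry(pitch=100, well_radius=60)


class TestSizeModel:
    def test_dose_response_is_monotone_and_calibrated(self):
        m = SizeModel()
        doses = np.linspace(0.0, 0.4, 81)
        f = np.array([m.dmso_size_factor(d) for d in doses])
        assert (np.diff(f) <= 1e-12).all()
        assert m.dmso_size_factor(0.02) == 1.0  # below onset
        # at the MTD the in-plate ratio is reached
        assert m.mean_area("hom", 0.1) / m.mean_area("het", 0.1) == pytest.approx(0.5)
        assert m.mean_area("hom") / m.mean_area("het") == pytest.approx(0.75)

    def test_survival_ramp(self):
        m = SizeModel()
        assert m.hom_survival(0.1) == 1.0
        assert m.hom_survival(0.4) == 0.0
        assert 0 < m.hom_survival(0.25) < 1

    def test_rescue_moves_toward_heterozygote(self):
        m = SizeModel()
        full = m.mean_area("hom", 0.1, rescue=1.0)
        assert full == pytest.approx(m.het_mean_area)
        assert m.mean_area("hom", 0.1, rescue=0.5) == pytest.approx(
            (m.mean_area("hom", 0.1) + m.het_mean_area) / 2)


class TestSimulateScreenAreas:
    def test_same_seed_is_byte_identical(self):
        cfg = ScreenConfig(n_plates=2, rng_seed=9)
        t1, truth1 = simulate_screen_areas(cfg)
        t2, truth2 = simulate_screen_areas(cfg)
        pd.testing.assert_frame_equal(truth1, truth2)
        for a, b in zip(t1, t2):
            pd.testing.assert_frame_equal(a, b)

    def test_null_controls_indistinguishable(self):
        # no genotype or vehicle effect: NEG and POS1 wells share one
        # distribution, so a two-sample test is non-significant at alpha=0.01
        # in >= 95% of seeded runs
        null = SizeModel(genotype_ratio=1.0, vehicle_genotype_ratio=1.0)
        ok = 0
        for seed in range(100):
            cfg = ScreenConfig(n_plates=1, n_replicates=1, rng_seed=seed,
                               toxic_fraction=0.0)
            (tbl,), _ = simulate_screen_areas(cfg, null, ArtifactModel.none())
            neg = tbl.loc[tbl.role == Role.NEG.value, "area"]
            pos = tbl.loc[tbl.role == Role.POS1.value, "area"]
            ok += stats.ttest_ind(neg, pos).pvalue > 0.01
        assert ok >= 95

    def test_null_prehit_rate_matches_monte_carlo_oracle(self):
        # brute-force oracle: the 2-of-3 exceedance probability of a well
        # Z-scored against 8 same-plate negative controls, all null lognormal
        m = SizeModel()
        rng = np.random.default_rng(314)
        n, k = 10 ** 5, 3
        sig2 = np.log1p(m.cv ** 2)
        def draw(size):
            # a well readout is the sum of 3 per-larva lognormal areas
            larvae = np.exp(rng.normal(-sig2 / 2, np.sqrt(sig2), size=size + (k,)))
            return larvae.sum(axis=-1)
        neg = draw((n, 8))
        x = draw((n,))
        z = (x - neg.mean(axis=1)) / neg.std(axis=1, ddof=1)
        p = (z > 2).mean()
        oracle_rate = 3 * p ** 2 * (1 - p) + p ** 3

        hitless = 0
        n_cpds = 0
        for seed in (1, 2, 3):
            cfg = ScreenConfig(n_plates=32, rng_seed=seed, toxic_fraction=0.0)
            tables, _ = simulate_screen_areas(cfg, m, ArtifactModel.none())
            merged = ss.merge_replicates([ss.zscore_screen(t) for t in tables])
            above = sum((merged[f"z_rep{r}"] > 2).astype(int) for r in (1, 2, 3))
            hitless += int((above >= 2).sum())
            n_cpds += len(merged)
        emp = hitless / n_cpds
        se = np.sqrt(oracle_rate * (1 - oracle_rate) / n_cpds)
        assert abs(emp - oracle_rate) < 4 * se + 0.2 * oracle_rate

    def test_null_zscore_calibration_over_fifty_plates(self):
        # no effects anywhere: test-well Z-scores are centred with unit-ish
        # spread (plug-in sigma from n=8 controls inflates the SD slightly)
        null = SizeModel(genotype_ratio=1.0, vehicle_genotype_ratio=1.0)
        cfg = ScreenConfig(n_plates=50, n_replicates=1, rng_seed=77,
                           toxic_fraction=0.0)
        (tbl,), _ = simulate_screen_areas(cfg, null, ArtifactModel.none())
        z = ss.zscore_screen(tbl)["z"]
        assert abs(z.mean()) < 0.1
        assert 0.8 < z.std() < 1.2

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = ScreenConfig(n_plates=4, true_hit_ids=("C0007", "C0123"),
                           rng_seed=42)
        path = tmp_path / "screen.yaml"
        cfg.to_yaml(path)
        assert ScreenConfig.from_yaml(path) == cfg

    def test_artifact_flags_present_and_inflate_area(self):
        cfg = ScreenConfig(n_plates=8, rng_seed=3, toxic_fraction=0.0)
        _, truth = simulate_screen_areas(cfg, SizeModel(), ArtifactModel())
        bg = truth[truth.flag_high_bg]
        assert len(bg) > 0
        assert (bg["area"] > bg["true_area"]).all()
        low = truth[truth.flag_low_dmso & ~truth.flag_high_bg]
        assert len(low) > 0
        assert np.allclose(low["area"] / low["true_area"],
                           ArtifactModel().low_dmso_size_boost)


class TestSimulateDevEvents:
    def test_delay_shifts_median_eclosion_day(self):
        arms = [DevArm("ref", 500, median_day=10, sd_days=0.8),
                DevArm("delayed", 500, median_day=10, sd_days=0.8, delay_days=2)]
        ev = simulate_dev_events(arms, day_grid=range(6, 17),
                                 rng=np.random.default_rng(4))
        med = {}
        for label, sub in ev.groupby("label"):
            tc = cumulative_fraction(pd.Series(sub["count"].to_numpy(),
                                               index=sub["day"].to_numpy()),
                                     int(sub["n_survivors"].iloc[0]))
            med[label] = tc.median_day
        assert med["delayed"] - med["ref"] == 2

    def test_survival_fraction_recovered(self):
        # 32% homozygote eclosion vs full survival, recovered within
        # binomial error at n=200
        arms = [DevArm("hom", 200, survival=0.32), DevArm("het", 200, survival=1.0)]
        ev = simulate_dev_events(arms, rng=np.random.default_rng(8))
        frac = ev.groupby("label")["n_survivors"].first() / 200
        se = np.sqrt(0.32 * 0.68 / 200)
        assert abs(frac["hom"] - 0.32) < 3 * se
        assert frac["het"] == 1.0

    def test_zero_individuals_yield_empty_course_and_error_downstream(self):
        ev = simulate_dev_events([DevArm("none", 0)],
                                 rng=np.random.default_rng(0))
        assert ev["count"].sum() == 0
        with pytest.raises(ValueError):
            cumulative_fraction(pd.Series(ev["count"].to_numpy(),
                                          index=ev["day"].to_numpy()),
                                n_survivors=0)

    def test_counts_are_non_negative_and_conserved(self):
        arms = [DevArm("a", 137, survival=0.8)]
        ev = simulate_dev_events(arms, rng=np.random.default_rng(1))
        assert (ev["count"] >= 0).all()
        assert ev["count"].sum() == ev["n_survivors"].iloc[0] <= 137
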