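"""Plate QC (Z'), per-well Z-scores, replicate merging and correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from larvascreen import screen_stats as ss
from larvascreen.simulate import (ArtifactModel, ScreenConfig, SizeModel,
                                  simulate_screen_areas)


class TestZprime:
    def test_zero_variance_groups_give_one(self):
        assert ss.zprime([10, 10, 10], [1, 1, 1]) == 1.0

    def test_exact_moments_example(self):
        assert ss.zprime_from_moments(10, 1, 0, 1) == pytest.approx(0.4)

    def test_equal_means_error(self):
        with pytest.raises(ValueError, match="no separation"):
            ss.zprime([5, 5, 5], [5, 5, 5])

    def test_singleton_group_error(self):
        with pytest.raises(ValueError):
            ss.zprime([10], [1, 2, 3])

    @given(st.floats(0.01, 5), st.floats(0.01, 5), st.floats(0.01, 10))
    @settings(deadline=None, max_examples=50)
    def test_increasing_spread_strictly_decreases_zprime(self, sd_pos, sd_neg, bump):
        base = ss.zprime_from_moments(10, sd_pos, 0, sd_neg)
        assert ss.zprime_from_moments(10, sd_pos + bump, 0, sd_neg) < base
        assert ss.zprime_from_moments(10, sd_pos, 0, sd_neg + bump) < base

    def test_most_default_screen_plates_pass_qc(self):
        # mirrors the observed plate-quality fraction (73/96 with Z' > 0):
        # the default simulated screen keeps at least 70% of plates above 0
        cfg = ScreenConfig(n_plates=32, rng_seed=11)
        _, truth = simulate_screen_areas(cfg)
        ps = ss.screen_plate_stats(truth)
        assert len(ps) == 96
        assert (ps["zprime"] > 0).mean() >= 0.70


class TestZscoreWells:
    def test_exact_values_against_control_moments(self):
        neg = [1.0, 2.0, 3.0]  # mean 2, sd 1
        z = ss.zscore_wells([2.0, 4.0, 0.0], neg)
        assert np.allclose(z, [0.0, 2.0, -2.0])

    def test_zero_scale_error(self):
        with pytest.raises(ValueError):
            ss.zscore_wells([1.0], [2.0, 2.0, 2.0])

    def test_null_tail_matches_monte_carlo_oracle(self):
        # brute-force oracle for P(|Z| > 2) when a lognormal well is scored
        # against 8 same-plate controls of the same distribution
        rng = np.random.default_rng(99)
        n = 10 ** 5
        sig = np.sqrt(np.log1p(0.0866 ** 2))
        neg = np.exp(rng.normal(0, sig, (n, 8)))
        x = np.exp(rng.normal(0, sig, n))
        z = (x - neg.mean(axis=1)) / neg.std(axis=1, ddof=1)
        oracle = (np.abs(z) > 2).mean()

        null = SizeModel(genotype_ratio=1.0, vehicle_genotype_ratio=1.0, cv=0.15)
        cfg = ScreenConfig(n_plates=40, n_replicates=1, rng_seed=5,
                           toxic_fraction=0.0)
        (tbl,), _ = simulate_screen_areas(cfg, null, ArtifactModel.none())
        frac = (ss.zscore_screen(tbl)["z"].abs() > 2).mean()
        se = np.sqrt(oracle * (1 - oracle) / 3200)
        assert abs(frac - oracle) < 4 * se + 0.15 * oracle


class TestMergeReplicates:
    def test_duplicate_substance_stays_as_two_rows(self):
        cfg = ScreenConfig(n_plates=1, rng_seed=2)
        tables, _ = simulate_screen_areas(cfg)
        merged = ss.merge_replicates([ss.zscore_screen(t) for t in tables])
        assert merged["compound_id"].is_unique
        dup = merged["substance"].value_counts()
        assert (dup == 2).sum() == 1  # the library's duplicated substance
        assert {"z_rep1", "z_rep2", "z_rep3"} <= set(merged.columns)

    def test_missing_replicate_kept_as_nan(self):
        t1 = pd.DataFrame({"plate": ["P"], "row": [0], "col": [1],
                           "well": ["A2"], "compound_id": ["C1"],
                           "substance": ["S1"], "z": [1.5]})
        t2 = t1.assign(compound_id=["C2"], substance=["S2"], z=[0.5])
        merged = ss.merge_replicates([t1, t2])
        assert len(merged) == 2
        row = merged.set_index("compound_id")
        assert np.isnan(row.loc["C1", "z_rep2"])
        assert np.isnan(row.loc["C2", "z_rep1"])

    def test_empty_input_gives_empty_table(self):
        assert ss.merge_replicates([]).empty


class TestPairwiseR2:
    def test_identical_and_linear_vectors(self):
        z = np.array([1.0, 2.0, 3.0, 4.0])
        assert ss.pairwise_r2(z, z) == pytest.approx(1.0)
        assert ss.pairwise_r2(z, 2 * z) == pytest.approx(1.0)

    def test_ten_pair_hand_computed_oracle(self):
        za = np.array([0.3, -1.2, 2.5, 0.8, -0.4, 3.1, -2.2, 0.0, 1.7, -0.9])
        zb = np.array([0.1, -0.8, 2.0, 1.2, 0.3, 2.6, -1.9, 0.4, 1.1, -1.3])
        # explicit formula evaluation as the oracle
        ca = za - za.mean()
        cb = zb - zb.mean()
        oracle = (ca @ cb) ** 2 / ((ca @ ca) * (cb @ cb))
        assert ss.pairwise_r2(za, zb) == pytest.approx(oracle)

    def test_extreme_mode_keeps_pairs_with_either_member_extreme(self):
        za = np.array([0.1, 2.5, 0.2, -3.0, 0.4, 1.0])
        zb = np.array([0.2, 0.1, 2.6, -2.5, 0.3, 1.5])
        kept = (np.abs(za) > 2) | (np.abs(zb) > 2)
        oracle = ss.pairwise_r2(za[kept], zb[kept], mode="full")
        assert ss.pairwise_r2(za, zb, mode="extreme") == pytest.approx(oracle)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            ss.pairwise_r2([1, 2], [1, 2])
        with pytest.raises(ValueError, match="constant"):
            ss.pairwise_r2([1, 1, 1, 1], [1, 2, 3, 4])

    def test_extreme_subset_correlation_exceeds_full(self):
        # with planted hits the extreme subset is enriched for reproducible
        # effects, so its replicate correlation beats the full-set one
        from larvascreen.experiments import r2_enrichment_experiment

        res = r2_enrichment_experiment(seed=4, n_runs=10)
        assert res["frac_extreme_wins"] >= 0.9
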