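import numpy as np
import pandas as pd
import pytest

from mcisurv.classical import kaplan_meier
from mcisurv.io import region_columns
from mcisurv.simulate import (
    GROUPS,
    ImageConfig,
    SimulationConfig,
    default_atrophy_means,
    make_region_layout,
    simulate_cohort,
    simulate_images,
    split_folds,
)
from mcisurv.volumetrics import zscore_to_reference


class TestSimulateCohort:
    def test_empty_cohort(self):
        cohort, truth = simulate_cohort(SimulationConfig(n_subjects=0, seed=1))
        assert len(cohort) == 0 and len(truth) == 0

    def test_certain_first_bin_conversion(self):
        cfg = SimulationConfig(
            n_subjects=50, seed=2, censor_rate=0.0,
            bin_hazards=tuple((1.0, 0.5, 0.5) for _ in range(4)),
        )
        cohort, _ = simulate_cohort(cfg)
        assert cohort["event"].all()
        assert (cohort["time_months"] < 24).all()
        assert (cohort["time_months"] > 0).all()

    def test_binomial_oracle_uniform_hazards(self):
        """Per-bin event fractions match the sequential-Bernoulli process."""
        n = 10_000
        cfg = SimulationConfig(
            n_subjects=n, seed=3, censor_rate=0.0,
            bin_hazards=tuple((0.2, 0.2, 0.2) for _ in range(4)),
        )
        cohort, _ = simulate_cohort(cfg)
        frac_bin1 = (cohort["event"] & (cohort["time_months"] < 24)).mean()
        se1 = np.sqrt(0.2 * 0.8 / n)
        assert abs(frac_bin1 - 0.2) < 3 * se1
        p_event = 1 - 0.8**3  # 0.488
        se = np.sqrt(p_event * (1 - p_event) / n)
        assert abs(cohort["event"].mean() - p_event) < 3 * se

    def test_censoring_calibration(self):
        cohort, _ = simulate_cohort(SimulationConfig(n_subjects=4000, seed=4))
        assert abs((1 - cohort["event"].mean()) - 0.72) < 0.03

    def test_truth_invariants(self, small_cohort):
        cohort, truth = small_cohort
        obs = np.minimum(truth["latent_event_time"], truth["censor_time"])
        assert np.allclose(obs, cohort["time_months"])
        assert (
            (truth["latent_event_time"] <= truth["censor_time"])
            == cohort["event"].to_numpy()
        ).all()
        assert not cohort["subject_id"].duplicated().any()
        vols = cohort[region_columns(cohort)].to_numpy()
        assert np.isfinite(vols).all() and (vols >= 0).all()

    def test_zprofile_recovery(self, catalog):
        """Re-standardized volumes recover the group atrophy means."""
        cfg = SimulationConfig(n_subjects=4000, seed=5,
                               group_fractions=(0.25, 0.25, 0.25, 0.25))
        cohort, truth = simulate_cohort(cfg, catalog)
        z = zscore_to_reference(
            cohort.set_index("subject_id")[region_columns(cohort)],
            catalog.reference(),
        )
        means = default_atrophy_means(catalog)
        groups = truth.set_index("subject_id")["true_group"]
        for g, name in enumerate(GROUPS):
            sub = z.loc[groups[groups == name].index]
            se = cfg.noise_sd / np.sqrt(len(sub))
            err = np.abs(sub.mean(axis=0).to_numpy() - means[g])
            assert (err < 3 * se + 1e-9).mean() > 0.98  # allow rare 3-SE excursions

    def test_km_group_ordering(self, catalog):
        """Group Kaplan-Meier curves are ordered like the generating hazards."""
        cfg = SimulationConfig(n_subjects=2000, seed=6)
        cohort, truth = simulate_cohort(cfg, catalog)
        groups = truth["true_group"].to_numpy()
        surv = {}
        for name in GROUPS:
            sel = groups == name
            km = kaplan_meier(cohort.loc[sel, "time_months"], cohort.loc[sel, "event"])
            surv[name] = [km.survival_at(t) for t in (24, 48, 108)]
        for t_idx in range(3):
            values = [surv[name][t_idx] for name in GROUPS]
            assert values == sorted(values)  # H lowest survival ... L highest

    def test_determinism(self):
        cfg = SimulationConfig(n_subjects=100, seed=7)
        a1, t1 = simulate_cohort(cfg)
        a2, t2 = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(t1, t2)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_subjects": -1},
            {"n_subjects": 10, "group_fractions": (0.5, 0.5, 0.5, 0.5)},
            {"n_subjects": 10, "bin_hazards": tuple((1.5, 0.1, 0.1) for _ in range(4))},
            {"n_subjects": 10, "noise_sd": 0.0},
            {"n_subjects": 10, "abeta_ranges": ((100, 500), (500, 900), (900, 1300), (1300, 1700))},
        ],
    )
    def test_invalid_configs(self, kwargs):
        with pytest.raises(ValueError):
            simulate_cohort(SimulationConfig(seed=0, **kwargs))


class TestSimulateImages:
    def _tiny(self, catalog, n=3, noise=0.0, effect=0.25, seed=0):
        cfg = SimulationConfig(n_subjects=n, seed=8,
                               group_fractions=(0.25, 0.25, 0.25, 0.25))
        cohort, truth = simulate_cohort(cfg, catalog)
        z = zscore_to_reference(
            cohort.set_index("subject_id")[region_columns(cohort)],
            catalog.reference(),
        )
        return cohort, z, ImageConfig(effect_scale=effect, noise_sd=noise, seed=seed)

    def test_degenerate_all_identical(self, catalog):
        cohort, z, _ = self._tiny(catalog)
        cfg = ImageConfig(effect_scale=0.0, noise_sd=0.0, seed=1)
        imgs = simulate_images(cohort, z, cfg)
        for im in imgs[1:]:
            assert np.array_equal(im.voxels, imgs[0].voxels)

    def test_intensity_formula(self, catalog):
        cohort, z, _ = self._tiny(catalog, n=1)
        z_forced = z.copy()
        z_forced.iloc[0, :] = 0.0
        z_forced.iloc[0, 0] = -2.0
        imgs = simulate_images(cohort.iloc[:1], z_forced,
                               ImageConfig(effect_scale=0.25, noise_sd=0.0, seed=2))
        im = imgs[0]
        region1 = im.region_ids == 1
        assert np.allclose(im.voxels[region1], 0.5 * 1.0)  # baseline * (1 - 0.5)
        assert np.allclose(im.voxels[~im.mask], 0.0)

    def test_difference_confined_to_region(self, catalog):
        cohort, z, _ = self._tiny(catalog, n=2)
        z2 = z.copy()
        z2.iloc[:, :] = 0.0
        z3 = z2.copy()
        z3.iloc[1, 5] = -1.0  # subjects differ only in region 6
        cfg = ImageConfig(effect_scale=0.25, noise_sd=0.0, seed=3)
        imgs = simulate_images(cohort.iloc[:2], z3, cfg)
        diff = imgs[0].voxels != imgs[1].voxels
        assert diff.any()
        assert not diff[imgs[0].region_ids != 6].any()

    def test_seed_determinism(self, catalog):
        cohort, z, cfg = self._tiny(catalog, noise=0.05)
        a = simulate_images(cohort, z, cfg)
        b = simulate_images(cohort, z, cfg)
        assert np.array_equal(a[0].voxels, b[0].voxels)

    def test_grid_too_small(self):
        with pytest.raises(ValueError):
            make_region_layout((8, 8, 8), 66)


class TestSplitFolds:
    def test_five_fold_sizes(self):
        folds = split_folds(100, k=5, seed=0)
        assert len(folds) == 5
        for tr, va, te in folds:
            assert (len(tr), len(va), len(te)) == (60, 20, 20)
            assert not set(tr) & set(va) and not set(tr) & set(te) and not set(va) & set(te)
        all_test = np.sort(np.concatenate([te for _, _, te in folds]))
        assert np.array_equal(all_test, np.arange(100))

    def test_tiny_cohort(self):
        folds = split_folds(10, k=5, seed=1)
        for tr, va, te in folds:
            assert (len(tr), len(va), len(te)) == (6, 2, 2)

    def test_seed_behaviour(self):
        a = split_folds(50, k=5, seed=2)
        b = split_folds(50, k=5, seed=2)
        c = split_folds(50, k=5, seed=3)
        for (t1, v1, s1), (t2, v2, s2) in zip(a, b):
            assert np.array_equal(t1, t2) and np.array_equal(v1, v2) and np.array_equal(s1, s2)
        assert any(not np.array_equal(s1, s3) for (_, _, s1), (_, _, s3) in zip(a, c))

    def test_more_folds_than_subjects(self):
        with pytest.raises(ValueError):
            split_folds(3, k=5, seed=0)
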