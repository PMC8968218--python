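"""Exclusion rules, imputation contracts, scoring, alpha and gaussianization."""

import numpy as np
import pandas as pd
import pytest

from dissonet.preprocess import (
    EmptyCohortError,
    cronbach_alpha,
    filter_participants,
    gaussianize,
    impute,
    score_scales,
)
from dissonet.scales import ScaleSpec
from dissonet.synthetic import (
    GeneratorConfig,
    LikertDataset,
    demo_dag_small,
    generate_study,
    inject_missingness,
    likertize,
)


def _toy_dataset(n=10, n_items=13, missing_rows=()):
    """One 13-item scale (0-4); selected rows get 3 missing items (23%)."""
    rng = np.random.default_rng(0)
    spec = ScaleSpec("cad", n_items, 0, 4)
    items = pd.DataFrame(
        rng.integers(0, 5, size=(n, n_items)).astype(float),
        columns=spec.item_columns(),
    )
    for r in missing_rows:
        items.iloc[r, :3] = np.nan
    return LikertDataset(items, [spec])


class TestFilterParticipants:
    def test_per_scale_missingness_rule(self):
        data = _toy_dataset(n=6, missing_rows=(2,))
        ages = pd.Series([30] * 6)
        kept, _, log = filter_participants(data, ages)
        assert len(kept.items) == 5
        assert log.set_index("id").loc[2, "reason"] == "missingness"

    def test_age_outlier_boundary_matches_published_cutoff(self):
        # cohort with mean ~45.6, SD ~14.7: cutoff 75.0, so a 76-year-old goes
        rng = np.random.default_rng(1)
        ages = np.round(np.clip(rng.normal(45.6, 14.7, size=400), 18, 74))
        ages = pd.Series(np.append(ages, 76.0))
        data = _toy_dataset(n=401)
        cutoff = ages.mean() + 2 * ages.std()
        assert cutoff < 76
        kept, _, log = filter_participants(data, ages)
        assert 400 in log["id"].values
        assert log.set_index("id").loc[400, "reason"] == "age_outlier"

    def test_nothing_removed_when_clean(self):
        data = _toy_dataset(n=8)
        kept, _, log = filter_participants(data, pd.Series([30] * 8))
        assert len(kept.items) == 8 and log.empty

    def test_reason_priority_age_ineligible_first(self):
        data = _toy_dataset(n=5, missing_rows=(0,))
        ages = pd.Series([17, 30, 30, 30, 30])
        _, _, log = filter_participants(data, ages)
        assert log.set_index("id").loc[0, "reason"] == "age_ineligible"

    def test_refiltering_is_idempotent(self):
        study = generate_study(GeneratorConfig(n=300, seed=2, missing_rate=0.05), demo_dag_small())
        kept, kept_ages, log = filter_participants(study.data, study.ages)
        kept2, _, log2 = filter_participants(kept, kept_ages, age_cutoff=log.attrs["age_cutoff"])
        assert len(kept2.items) == len(kept.items) and log2.empty

    def test_empty_cohort_signalled(self):
        data = _toy_dataset(n=3)
        with pytest.raises(EmptyCohortError):
            filter_participants(data, pd.Series([15, 16, 17]))


class TestImpute:
    def test_no_missing_is_identity(self):
        data = _toy_dataset(n=20)
        for comp in impute(data, m=3, seed=0):
            pd.testing.assert_frame_equal(comp.items, data.items)

    def test_observed_cells_never_altered_and_support_respected(self):
        study = generate_study(GeneratorConfig(n=200, seed=3, missing_rate=0.1), demo_dag_small())
        obs = ~study.data.mask.to_numpy()
        for comp in impute(study.data, m=2, iterations=3, seed=1):
            got = comp.items.to_numpy()
            assert np.array_equal(got[obs], study.data.items.to_numpy()[obs])
            for col in comp.items.columns:
                observed_vals = set(study.data.items[col].dropna())
                assert set(comp.items[col]) <= observed_vals

    def test_seed_determinism(self):
        study = generate_study(GeneratorConfig(n=120, seed=4, missing_rate=0.1), demo_dag_small())
        a = impute(study.data, m=2, iterations=2, seed=9)
        b = impute(study.data, m=2, iterations=2, seed=9)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.items, y.items)

    def test_mcar_means_preserved(self):
        study = generate_study(GeneratorConfig(n=2000, seed=5, missing_rate=0.0), demo_dag_small())
        masked = inject_missingness(study.data, 0.1, seed=6)
        comp = impute(masked, m=1, iterations=4, seed=2)[0]
        mask = masked.mask.to_numpy()
        X = comp.items.to_numpy()
        full = study.data.items.to_numpy()
        for j in range(X.shape[1]):
            mj = mask[:, j]
            if mj.sum() < 30:
                continue
            se = full[:, j].std() / np.sqrt(mj.sum())
            assert abs(X[mj, j].mean() - full[~mj, j].mean()) < 3.5 * se

    def test_constant_column_imputed_by_mode_with_warning(self):
        spec = ScaleSpec("s", 2, 0, 4)
        items = pd.DataFrame({"s_1": [2.0, 2, 2, 2, np.nan, 2], "s_2": [0.0, 1, 2, 3, 4, 0]})
        data = LikertDataset(items, [spec])
        with pytest.warns(UserWarning, match="constant column"):
            comp = impute(data, m=1, iterations=2, seed=0)[0]
        assert comp.items.loc[4, "s_1"] == 2.0


class TestScoreScales:
    def test_published_scale_extremes(self):
        # self-efficacy: 10 items 1-4, all 4s -> 40; affect intolerance: 30 items 1-6, all 1s -> 30
        gse = ScaleSpec("gse", 10, 1, 4)
        ais = ScaleSpec("ais", 30, 1, 6)
        items = pd.DataFrame(
            {**{c: [4.0] for c in gse.item_columns()}, **{c: [1.0] for c in ais.item_columns()}}
        )
        totals = score_scales(items, [gse, ais])
        assert totals.loc[0, "gse"] == 40
        assert totals.loc[0, "ais"] == 30

    def test_reverse_item_contributes_minimum_at_maximum_response(self):
        spec = ScaleSpec("s", 2, 1, 5, reverse_items=frozenset({2}))
        items = pd.DataFrame({"s_1": [1.0], "s_2": [5.0]})
        assert score_scales(items, [spec]).loc[0, "s"] == 1 + 1

    def test_out_of_range_named_in_error(self):
        spec = ScaleSpec("s", 2, 0, 4)
        items = pd.DataFrame({"s_1": [2.0, 9.0], "s_2": [1.0, 1.0]})
        with pytest.raises(ValueError, match="row 1"):
            score_scales(items, [spec])

    def test_missing_values_rejected(self):
        spec = ScaleSpec("s", 2, 0, 4)
        items = pd.DataFrame({"s_1": [2.0, np.nan], "s_2": [1.0, 1.0]})
        with pytest.raises(ValueError, match="impute"):
            score_scales(items, [spec])


class TestCronbachAlpha:
    def test_perfectly_correlated_items(self):
        x = np.random.default_rng(0).standard_normal(100)
        assert cronbach_alpha(np.column_stack([x, x])) == pytest.approx(1.0)

    def test_independent_items_near_zero(self):
        X = np.random.default_rng(1).standard_normal((10_000, 8))
        assert abs(cronbach_alpha(X)) < 0.05

    @pytest.mark.parametrize("lam", [0.4, 0.6, 0.8])
    def test_one_factor_alpha_matches_monte_carlo_oracle(self, lam):
        spec = ScaleSpec("c", 15, 0, 4)

        def alpha_at(n, seed):
            scores = pd.DataFrame({"c": np.random.default_rng(seed).standard_normal(n)})
            ds = likertize(scores, [spec], reliability=lam, seed=seed + 1)
            return cronbach_alpha(ds.items.to_numpy())

        assert abs(alpha_at(20_000, 11) - alpha_at(200_000, 77)) < 0.03

    def test_zero_variance_undefined(self):
        with pytest.raises(ZeroDivisionError):
            cronbach_alpha(np.ones((10, 3)))


class TestGaussianize:
    def test_exact_moments_and_monotonicity(self):
        rng = np.random.default_rng(2)
        x = rng.gamma(2.0, size=500)
        z = gaussianize(pd.DataFrame({"x": x}))["x"].to_numpy()
        assert abs(z.mean()) < 1e-8
        assert abs(z.std(ddof=0) - 1) < 1e-6
        order = np.argsort(x)
        assert np.all(np.diff(z[order]) > 0)  # strictly monotone, no ties here

    def test_ties_get_identical_z(self):
        z = gaussianize(pd.DataFrame({"x": [1.0, 2.0, 2.0, 4.0]}))["x"]
        assert z[1] == z[2]

    def test_invariance_to_monotone_transform(self):
        x = np.random.default_rng(3).uniform(1, 5, size=200)
        z1 = gaussianize(pd.DataFrame({"x": x}))
        z2 = gaussianize(pd.DataFrame({"x": np.exp(x)}))
        np.testing.assert_allclose(z1["x"], z2["x"])

    def test_normality_not_degraded_for_normal_input(self):
        from scipy.stats import kstest

        x = np.random.default_rng(4).standard_normal(2000)
        z = gaussianize(pd.DataFrame({"x": x}))["x"].to_numpy()
        d_in = kstest(x, "norm").statistic
        d_out = kstest(z, "norm").statistic
        assert d_out <= d_in + 0.01

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            gaussianize(pd.DataFrame({"x": [1.0, 1.0, 1.0]}))
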