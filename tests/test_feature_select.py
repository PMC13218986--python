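"""Variance/correlation filters, OR/CI arithmetic, logistic screen and CV vote."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from facerisk import feature_select as fs
from facerisk import synth_data as sd

# Published multivariable logistic coefficient table (feature, beta, SE, OR,
# CI low, CI high).  The OR/CI columns are pure arithmetic on (beta, SE), so
# they double as an oracle for or_ci; the printed values were computed from
# unrounded coefficients, so agreement is to the rounding uncertainty of the
# printed inputs.
PUBLISHED_EFFECTS = [
    ("lipcolor-H", 0.6011, 0.152, 1.824, 1.3540, 2.4572),
    ("lipcolor-S", -0.6358, 0.2665, 0.5295, 0.3141, 0.8927),
    ("lipcolor-a", 0.5339, 0.1857, 1.7056, 1.1854, 2.4542),
    ("GLCM-asm_0", -0.4186, 0.1433, 0.658, 0.4968, 0.8714),
    ("GLCM-ent_0", 0.3865, 0.1648, 1.4718, 1.0655, 2.0331),
    ("GLCM-idm_0", 0.9262, 0.2858, 2.525, 1.4421, 4.4213),
    ("GLCM-con_1", -0.5689, 0.1829, 0.5661, 0.3956, 0.8102),
    ("GLCM-idm_1", 1.5433, 0.2484, 4.6799, 2.8759, 7.6156),
    ("GLCM-con_2", -0.8247, 0.2115, 0.4384, 0.2896, 0.6636),
    ("GLCM-idm_2", -1.1943, 0.2551, 0.3029, 0.1837, 0.4993),
    ("GLCM-con_3", 0.9838, 0.2016, 2.6746, 1.8016, 3.9706),
    ("GLCM-idm_3", -1.369, 0.3072, 0.2544, 0.1393, 0.4644),
    ("color-R-0", -0.5971, 0.161, 0.5504, 0.4015, 0.7546),
    ("color-G-0", -1.5985, 0.4862, 0.2022, 0.0780, 0.5243),
    ("color-H-0", -0.7421, 0.3195, 0.4761, 0.2545, 0.8905),
    ("color-S-0", 2.1459, 0.7644, 8.5501, 1.9113, 38.2484),
    ("color-b-0", -4.2561, 0.9845, 0.0142, 0.0021, 0.0976),
    ("color-R-1", -0.5293, 0.2076, 0.589, 0.3922, 0.8848),
    ("color-R-2", -0.6456, 0.1719, 0.5244, 0.3744, 0.7344),
    ("color-G-2", 0.6966, 0.2496, 2.0069, 1.2305, 3.2730),
    ("color-b-3", 0.5782, 0.2642, 1.7829, 1.0623, 2.9924),
    ("color-S-4", 1.0384, 0.4828, 2.8247, 1.0965, 7.2765),
    ("color-b-4", -2.4067, 0.7823, 0.0901, 0.0194, 0.4175),
    ("color-R-5", 0.3147, 0.1336, 1.3698, 1.0542, 1.7800),
    ("color-R-6", -0.5351, 0.1708, 0.5856, 0.4190, 0.8184),
    ("color-G-6", 0.9144, 0.4219, 2.4953, 1.0914, 5.7054),
    ("color-H-6", -0.9115, 0.3208, 0.4019, 0.2143, 0.7538),
    ("color-a-6", -1.0653, 0.3616, 0.3446, 0.1697, 0.7000),
    ("color-H-7", 0.901, 0.2304, 2.462, 1.5672, 3.8675),
    ("color-a-7", 1.3819, 0.2881, 3.9826, 2.2642, 7.0050),
]


class TestOrCi:
    @pytest.mark.parametrize("name,beta,se,or_,lo,hi", PUBLISHED_EFFECTS)
    def test_reproduces_published_arithmetic(self, name, beta, se, or_, lo, hi):
        oratio, (ci_lo, ci_hi) = fs.or_ci(beta, se)
        assert oratio == pytest.approx(or_, rel=2e-3, abs=1e-3)
        assert ci_lo == pytest.approx(lo, rel=2e-3, abs=1e-3)
        assert ci_hi == pytest.approx(hi, rel=2e-3, abs=1e-3)

    def test_zero_coefficient_symmetric_on_log_scale(self):
        oratio, (lo, hi) = fs.or_ci(0.0, 0.3)
        assert oratio == 1.0
        assert lo * hi == pytest.approx(1.0)

    def test_se_must_be_positive(self):
        with pytest.raises(ValueError):
            fs.or_ci(0.5, 0.0)


class TestFilters:
    def test_constant_column_dropped(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [7.0, 7, 7], "label": [0, 1, 0]})
        out = fs.drop_zero_variance(df)
        assert list(out.columns) == ["a", "label"]

    def test_no_constant_is_identity(self, null_table):
        assert fs.drop_zero_variance(null_table).shape == null_table.shape

    def test_duplicate_column_pruned_keeps_earlier(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4], "c": [4.0, 1, 3, 2]})
        df["label"] = [0, 1, 0, 1]
        out = fs.prune_correlated(df)
        assert list(out.columns) == ["a", "c", "label"]

    def test_chain_leaves_single_survivor(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=500)
        df = pd.DataFrame(
            {
                "a": base,
                "b": base + rng.normal(0, 0.02, 500),
                "c": base + rng.normal(0, 0.02, 500),
                "label": np.resize([0, 1], 500),
            }
        )
        out = fs.prune_correlated(df, threshold=0.95)
        assert [c for c in out.columns if c != "label"] == ["a"]

    def test_survivor_set_has_bounded_correlation(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(300, 12))
        X[:, 5] = X[:, 0] * 0.99 + rng.normal(0, 0.05, 300)
        X[:, 9] = X[:, 2]
        df = pd.DataFrame(X, columns=[f"f{j}" for j in range(12)])
        df["label"] = np.resize([0, 1], 300)
        out = fs.prune_correlated(df, 0.95)
        feats = [c for c in out.columns if c != "label"]
        corr = np.corrcoef(out[feats].to_numpy(), rowvar=False)
        off = corr[~np.eye(len(feats), dtype=bool)]
        assert np.abs(off).max() <= 0.95


class TestLogisticFit:
    def test_matches_statsmodels_without_penalty(self, small_model_table):
        crit = fs.SelectionCriteria(ridge=0.0, perturb_reps=0)
        effects = fs.fit_effects(small_model_table, crit)
        X = small_model_table.drop(columns=["label"]).to_numpy()
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        res = sm.Logit(small_model_table["label"], sm.add_constant(Z)).fit(disp=0)
        for j, e in enumerate(effects):
            assert e.coef == pytest.approx(res.params.iloc[j + 1], abs=1e-6)
            assert e.se == pytest.approx(res.bse.iloc[j + 1], rel=1e-4)

    def test_null_feature_or_near_one(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"x": rng.normal(size=4000), "label": np.resize([0, 1], 4000)})
        e = fs.fit_effects(df)[0]
        assert e.ci_low < 1.0 < e.ci_high
        assert e.odds_ratio == pytest.approx(1.0, abs=0.1)

    def test_planted_effect_coverage(self):
        """The per-SD log-odds CI covers the planted value at ~95% rate."""
        hits = 0
        reps = 30
        for s in range(reps):
            cfg = sd.SyntheticConfig(
                n_per_class=1000, seed=900 + s, corr_structure=None,
                effect_sizes={"color-S-0": 1.0},
            )
            t = sd.generate_feature_table(cfg)[["color-S-0", "label"]]
            e = fs.fit_effects(t)[0]
            # class-conditional Gaussians with unit shift give slope ~1 per SD
            # of the pooled predictor; pooled SD inflates by the shift
            pooled_sd = np.sqrt(1 + 0.25)
            hits += e.coef - 1.96 * e.se <= pooled_sd <= e.coef + 1.96 * e.se
        assert hits >= 26

    def test_separation_flagged_anomalous(self):
        df = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)],
                           "label": np.r_[np.zeros(20), np.ones(20)].astype(int)})
        df["x"] += np.random.default_rng(0).normal(0, 1e-3, 40)
        with pytest.warns(UserWarning, match="did not converge"):
            effects = fs.fit_effects(df, fs.SelectionCriteria(ridge=0.0))
        assert effects[0].anomalous or effects[0].se > 10


class TestCriteria:
    def _effect(self, or_, lo, hi, anomalous=False):
        beta = np.log(or_)
        return fs.FeatureEffect("f", beta, 0.1, or_, lo, hi, 0.01, anomalous)

    def test_extreme_or_dropped(self):
        assert fs.apply_criteria([self._effect(2000.0, 1500, 2600)]) == []
        assert fs.apply_criteria([self._effect(0.0005, 0.0002, 0.0009)]) == []

    def test_wide_ci_ratio_dropped(self):
        assert fs.apply_criteria([self._effect(0.05, 0.002, 0.9)]) == []

    def test_published_like_effect_retained(self):
        e = fs.FeatureEffect("lipcolor-H", 0.6011, 0.152, 1.824, 1.354, 2.457, 0.0001)
        crit = fs.SelectionCriteria(require_significant=True)
        assert fs.apply_criteria([e], crit) == ["lipcolor-H"]

    def test_ci_crossing_one_needs_flag(self):
        e = self._effect(1.2, 0.9, 1.6)
        assert fs.apply_criteria([e]) == ["f"]
        assert fs.apply_criteria([e], fs.SelectionCriteria(require_significant=True)) == []

    def test_monotone_in_bounds(self):
        effects = [
            self._effect(or_, or_ / 2, or_ * 2) for or_ in (0.0005, 0.5, 2.0, 1500.0)
        ]
        tight = fs.apply_criteria(effects, fs.SelectionCriteria())
        loose = fs.apply_criteria(
            effects, fs.SelectionCriteria(or_low=1e-6, or_high=1e6, ci_ratio_max=1e6)
        )
        assert set(tight) <= set(loose)


class TestRobustnessAndCV:
    def test_zero_reps_trivially_robust(self, small_model_table):
        crit = fs.SelectionCriteria(perturb_reps=0)
        flags = fs.perturbation_robustness(small_model_table, crit)
        assert all(flags.values())

    def test_strong_effect_robust_noise_borderline_not(self):
        cfg = sd.SyntheticConfig(
            n_per_class=500, seed=31, corr_structure=None, effect_sizes={"color-S-0": 1.5}
        )
        t = sd.generate_feature_table(cfg)[["color-S-0", "color-R-0", "label"]]
        crit = fs.SelectionCriteria(require_significant=True, perturb_reps=20)
        flags = fs.perturbation_robustness(t, crit, seed=1)
        assert flags["color-S-0"]

    def test_cv_select_recovers_planted_pair(self):
        planted = {"color-S-0": 1.2, "lipcolor-H": 1.2}
        cfg = sd.SyntheticConfig(
            n_per_class=600, seed=41, corr_structure=None, effect_sizes=planted
        )
        t = sd.generate_feature_table(cfg)
        crit = fs.SelectionCriteria(require_significant=True, perturb_reps=5)
        res = fs.cv_select(t, crit, k=10, seed=2)
        assert sorted(res.selected) == sorted(planted)

    def test_fold_vote_thresholds(self):
        # synthetic ScreenResult bookkeeping: feature in all folds is kept,
        # feature in none is excluded (checked through the public counts)
        cfg = sd.SyntheticConfig(
            n_per_class=300, seed=43, corr_structure=None, effect_sizes={"color-S-0": 2.0}
        )
        t = sd.generate_feature_table(cfg)[["color-S-0", "color-G-3", "label"]]
        res = fs.cv_select(t, fs.SelectionCriteria(require_significant=True, perturb_reps=0), k=5, seed=3)
        assert res.counts.get("color-S-0", 0) == 5
        assert "color-S-0" in res.selected
        assert "color-G-3" not in res.selected

    def test_effects_table_layout(self, small_model_table):
        screen = fs.run_screen(small_model_table, fs.SelectionCriteria(perturb_reps=0))
        table = fs.effects_table(screen)
        assert list(table.columns) == [
            "Feature", "Coefficient", "SE", "OR", "CI_low", "CI_high", "P", "robust", "selected",
        ]
        assert len(table) == 6
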