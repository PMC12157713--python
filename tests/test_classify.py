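"""Cumulative assembly, normalization/PCA, metrics, LOO evaluation and
physiological PCA trajectories."""

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA as SkPCA
from sklearn.linear_model import LogisticRegression

from enose.classify import (
    ModelSpec,
    _fit_fold,
    assemble_cumulative,
    loo_evaluate,
    metrics_with_ci,
    pca_apply,
    pca_fit,
    physio_trajectories,
    zscore_apply,
    zscore_fit,
)
from enose.features import FeatureTable
from enose.io import TIMEPOINTS


def _feature_table(n_animals=19, timepoints=TIMEPOINTS, n_feats=3, seed=0,
                   separation=0.0):
    rng = np.random.default_rng(seed)
    keys, rows, labels = [], [], []
    for i in range(n_animals):
        group = "control" if i < n_animals // 2 else "LPS"
        for tp in timepoints:
            keys.append((f"a{i:02d}", tp))
            shift = separation if group == "LPS" else 0.0
            rows.append(rng.normal(shift, 1.0, n_feats))
            labels.append(group)
    idx = pd.MultiIndex.from_tuples(keys, names=["animal_id", "timepoint"])
    df = pd.DataFrame(rows, index=idx, columns=[f"f{j}" for j in range(n_feats)])
    return FeatureTable(df, pd.Series(labels, index=idx, name="label"))


class TestAssembleCumulative:
    def test_t60_uses_three_timepoints(self):
        t = _feature_table(n_animals=19)
        sub = assemble_cumulative(t, "t60")
        assert len(sub.values) == 19 * 3  # t5, t30, t60
        assert set(sub.values.index.get_level_values("timepoint")) == {"t5", "t30", "t60"}

    def test_t5_single_prefix(self):
        sub = assemble_cumulative(_feature_table(), "t5")
        assert set(sub.values.index.get_level_values("timepoint")) == {"t5"}

    def test_t0_rejected(self):
        with pytest.raises(ValueError):
            assemble_cumulative(_feature_table(), "t0")

    def test_include_t0_flag(self):
        sub = assemble_cumulative(_feature_table(n_animals=4), "t30", include_t0=True)
        assert set(sub.values.index.get_level_values("timepoint")) == {"t0", "t5", "t30"}


class TestZscore:
    def test_self_transform_standardizes(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(3, 7, size=(30, 4)))
        z = zscore_apply(zscore_fit(df), df)
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(ddof=0), 1.0, atol=1e-12)

    def test_constant_column_maps_to_zero_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero-SD"):
            scaler = zscore_fit(df)
        z = zscore_apply(scaler, df)
        np.testing.assert_array_equal(z["b"], 0.0)

    def test_row_at_train_mean_maps_to_zero(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(10, 3)))
        scaler = zscore_fit(df)
        row = pd.DataFrame([df.mean()])
        np.testing.assert_allclose(zscore_apply(scaler, row).to_numpy(), 0.0,
                                   atol=1e-12)


class TestPCA:
    def test_rank1_explains_everything(self):
        t = np.linspace(0, 1, 20)
        df = pd.DataFrame({"x": t, "y": 2 * t})
        proj = pca_fit(df, 1)
        assert proj.explained_variance_ratio_[0] == pytest.approx(1.0)

    def test_orthonormal_loadings(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(15, 6)))
        proj = pca_fit(df, 4)
        np.testing.assert_allclose(
            proj.components_ @ proj.components_.T, np.eye(4), atol=1e-10
        )

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(12, 5)))
        a, b = pca_fit(df, 3), pca_fit(df, 3)
        np.testing.assert_array_equal(a.components_, b.components_)
        for row in a.components_:
            assert row[np.argmax(np.abs(row))] > 0

    def test_full_rank_projection_is_isometric(self):
        """Pairwise distances are preserved when all components are kept."""
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(5, 3)))
        proj = pca_fit(df, 3)
        s = pca_apply(proj, df)
        x = df.to_numpy()
        for i in range(5):
            for j in range(5):
                assert np.linalg.norm(s[i] - s[j]) == pytest.approx(
                    np.linalg.norm(x[i] - x[j]), abs=1e-10
                )

    def test_too_many_components(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 6)))
        with pytest.raises(ValueError):
            pca_fit(df, 5)


class TestMetrics:
    def test_wald_closed_form(self):
        # p_hat=0.8, n=20: 80 +/- 1.96*sqrt(0.8*0.2/20)*100
        r = metrics_with_ci(tp=16, tn=0, fp=0, fn=4)
        lo, hi = r.ci["accuracy"]
        half = 1.96 * np.sqrt(0.8 * 0.2 / 20) * 100
        assert lo == pytest.approx(80 - half, abs=1e-9)
        assert hi == pytest.approx(80 + half, abs=1e-9)
        assert round(lo, 1) == 62.5 and round(hi, 1) == 97.5

    def test_perfect_confusion_clips_to_100(self):
        r = metrics_with_ci(tp=10, tn=10, fp=0, fn=0)
        assert r.accuracy == 100.0
        assert r.ci["accuracy"] == (100.0, 100.0)

    def test_zero_denominator_reported_missing(self):
        r = metrics_with_ci(tp=0, tn=12, fp=3, fn=0)  # no positive truth
        assert np.isnan(r.sensitivity)
        assert np.isnan(r.ci["sensitivity"][0])
        assert r.specificity == pytest.approx(80.0)

    def test_point_estimate_within_ci(self):
        r = metrics_with_ci(tp=7, tn=6, fp=2, fn=4)
        for m in ("accuracy", "sensitivity", "specificity"):
            lo, hi = r.ci[m]
            assert lo <= getattr(r, m) <= hi

    def test_wilson_differs_from_wald(self):
        wald = metrics_with_ci(tp=16, tn=0, fp=0, fn=4)
        wilson = metrics_with_ci(tp=16, tn=0, fp=0, fn=4, ci_method="wilson")
        assert wald.ci["accuracy"] != wilson.ci["accuracy"]


class TestLOO:
    def test_separable_features_perfect_accuracy(self):
        t = _feature_table(n_animals=10, timepoints=("t5", "t30"), separation=8.0,
                           seed=6)
        spec = ModelSpec(variant="enose_raw", n_components=2, seed=0)
        r = loo_evaluate(t, spec)
        assert r.accuracy == 100.0
        assert r.n_samples == 20

    def test_every_sample_predicted_once(self):
        t = _feature_table(n_animals=8, timepoints=("t5",), seed=7)
        spec = ModelSpec(variant="physio", n_components=2)
        r = loo_evaluate(t, spec)
        assert r.n_samples == 8
        assert r.tp + r.tn + r.fp + r.fn == 8

    def test_permuted_labels_near_chance(self):
        """Randomly permuted labels, n=40: accuracy inside the central 95%
        binomial band around 50% (LOO adds variance beyond binomial, so
        this checks the typical-seed case, not every seed)."""
        rng = np.random.default_rng(0)
        t = _feature_table(n_animals=40, timepoints=("t5",), seed=0)
        perm = rng.permutation(t.labels.to_numpy())
        t = FeatureTable(t.values, pd.Series(perm, index=t.labels.index, name="label"))
        r = loo_evaluate(t, ModelSpec(variant="enose_raw", seed=1))
        from scipy.stats import binom

        lo, hi = binom.ppf([0.025, 0.975], 40, 0.5) / 40 * 100
        assert lo <= r.accuracy <= hi

    def test_brute_force_oracle_equivalence(self):
        """Pooled confusion counts match a from-scratch sklearn LOO loop."""
        t = _feature_table(n_animals=12, timepoints=("t5",), n_feats=4,
                           separation=1.0, seed=9)
        spec = ModelSpec(variant="physio", n_components=2, screen_outliers=False)
        r = loo_evaluate(t, spec, unit="sample")

        x = t.values.to_numpy()
        y = (t.labels == "LPS").to_numpy()
        tp = tn = fp = fn = 0
        for i in range(len(x)):
            tr = np.ones(len(x), bool)
            tr[i] = False
            mu, sd = x[tr].mean(0), x[tr].std(0)
            z_train, z_test = (x[tr] - mu) / sd, (x[[i]] - mu) / sd
            p = SkPCA(n_components=2, svd_solver="full").fit(z_train)
            clf = LogisticRegression(C=np.inf, max_iter=2000, class_weight="balanced")
            clf.fit(p.transform(z_train), y[tr])
            pred = bool(clf.predict(p.transform(z_test))[0])
            tp += pred and y[i]
            tn += (not pred) and (not y[i])
            fp += pred and (not y[i])
            fn += (not pred) and y[i]
        assert (r.tp, r.tn, r.fp, r.fn) == (tp, tn, fp, fn)

    def test_fold_missing_class_excluded(self):
        # 2 animals: dropping either leaves one class only -> all folds flagged
        t = _feature_table(n_animals=2, timepoints=("t5", "t30"), seed=10)
        with pytest.raises(ValueError, match="empty confusion"):
            loo_evaluate(t, ModelSpec(variant="physio", n_components=1))

    def test_no_leakage_fold_fit_ignores_held_out_rows(self):
        """Dropping the held-out animal's rows from the table leaves the
        fold's fitted transformations bit-identical."""
        t = _feature_table(n_animals=10, timepoints=("t5", "t30"), seed=12)
        spec = ModelSpec(variant="enose_raw", seed=0)
        animals = t.values.index.get_level_values("animal_id")
        held = "a03"
        train = t.select_rows(np.asarray(animals != held))
        scaler1, proj1, _ = _fit_fold(train.values, train.labels, spec)
        # now delete the held-out rows from the *input* table entirely
        t2 = t.select_rows(np.asarray(animals != held))
        scaler2, proj2, _ = _fit_fold(t2.values, t2.labels, spec)
        pd.testing.assert_series_equal(scaler1.mean_, scaler2.mean_)
        np.testing.assert_array_equal(proj1.components_, proj2.components_)

    def test_determinism(self):
        t = _feature_table(n_animals=10, timepoints=("t5", "t30"), seed=13,
                           separation=0.5)
        spec = ModelSpec(variant="enose_raw", seed=3)
        a = loo_evaluate(t, spec)
        b = loo_evaluate(t, spec)
        assert (a.tp, a.tn, a.fp, a.fn) == (b.tp, b.tn, b.fp, b.fn)


class TestTrajectories:
    def _records(self, shift=None, n=6, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        base = {}
        for i in range(n):
            group = "control" if i < n // 2 else "LPS"
            aid = f"a{i}"
            base[aid] = rng.normal(80, 5, 5)
            for tp in ("t0", "t60", "t180"):
                v = base[aid].copy()
                if shift is not None and group == "LPS" and tp != "t0":
                    v = v + shift
                rows.append(
                    dict(zip(["animal_id", "timepoint", "label"], [aid, tp, group]))
                    | dict(zip(["MAP", "DBP", "SBP", "HR", "T"], v))
                )
        return pd.DataFrame(rows).set_index(["animal_id", "timepoint"])

    def test_static_data_zero_displacement(self):
        traj = physio_trajectories(self._records())
        np.testing.assert_allclose(traj.displacements["modulus"], 0.0, atol=1e-10)
        np.testing.assert_allclose(traj.group_means["mean_modulus"], 0.0, atol=1e-10)

    def test_translated_group_displaces_by_projected_vector(self):
        """Translating one group by v displaces it by the t0-space projection
        of v (linearity of the projection)."""
        shift = np.array([5.0, 3.0, -2.0, 4.0, 1.0])
        recs = self._records(shift=shift, n=8, seed=3)
        traj = physio_trajectories(recs, n_components=2)
        t0 = recs.loc[recs.index.get_level_values("timepoint") == "t0"]
        scaler = zscore_fit(t0.drop(columns="label"))
        proj = pca_fit(zscore_apply(scaler, t0.drop(columns="label")), 2)
        v_proj = (shift / scaler.scale_.to_numpy()) @ proj.components_.T
        pc_cols = ["PC1", "PC2"]
        lps_mean = traj.group_means.loc[("LPS", "t60"), pc_cols].to_numpy(float)
        np.testing.assert_allclose(lps_mean, v_proj, atol=1e-8)
        ctl_mean = traj.group_means.loc[("control", "t60"), pc_cols].to_numpy(float)
        np.testing.assert_allclose(ctl_mean, 0.0, atol=1e-8)

    def test_missing_t0_animal_excluded_with_warning(self):
        recs = self._records()
        keep = ~(
            (recs.index.get_level_values("animal_id") == "a0")
            & (recs.index.get_level_values("timepoint") == "t0")
        )
        with pytest.warns(UserWarning, match="without t0"):
            traj = physio_trajectories(recs.loc[keep])
        assert "a0" not in traj.displacements.index.get_level_values("animal_id")

    def test_group_n_is_animal_count(self):
        recs = self._records(n=6)
        traj = physio_trajectories(recs)
        sub = traj.displacements.loc[
            traj.displacements.index.get_level_values("timepoint") == "t60"
        ]
        assert len(sub) == 6
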