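import numpy as np
import pandas as pd
import pytest

from eprstab.chemometrics import (
    FeatureMatrix,
    PipelineOrderError,
    fuse_variables,
    normalize_total_signal,
    pareto_scale,
    pca,
)
from eprstab.synthetic_data import gen_feature_table


def small_matrix(values, state="raw", assay_cols=()):
    df = pd.DataFrame(
        values,
        index=[f"s{i}" for i in range(len(values))],
        columns=[f"F{j}" for j in range(len(values[0]))],
    )
    return FeatureMatrix(df, scaling_state=state, assay_columns=assay_cols)


@pytest.fixture()
def assay_table():
    return pd.DataFrame(
        {
            "PV": [99.9, 99.5, 121.4],
            "TPC": [0.45, 0.33, 8.87],
            "RSA": [5.0, 4.0, 40.0],
            "AUC": [2.9e7, 1.5e8, 6.8e7],
        },
        index=["s0", "s1", "s2"],
    )


class TestNormalizeTotalSignal:
    def test_row_sums_are_one(self):
        m = normalize_total_signal(small_matrix([[1.0, 3.0], [2.0, 2.0]]))
        assert np.allclose(m.data.sum(axis=1), 1.0)

    def test_scaled_rows_become_identical(self):
        m = normalize_total_signal(small_matrix([[1.0, 3.0], [10.0, 30.0]]))
        assert np.allclose(m.data.iloc[0], m.data.iloc[1])

    def test_assay_columns_excluded(self, assay_table):
        m = small_matrix([[1.0, 3.0], [2.0, 2.0], [5.0, 5.0]])
        fused = fuse_variables(m, assay_table)
        # normalize only applies to raw matrices; fuse first then normalize is
        # out of order, so normalize the raw matrix then fuse
        norm = normalize_total_signal(m)
        fused = fuse_variables(norm, assay_table)
        assert np.allclose(fused.data[fused.feature_columns].sum(axis=1), 1.0)
        assert np.allclose(fused.data["PV"], assay_table["PV"])

    def test_zero_sum_row_named(self):
        with pytest.raises(ValueError, match="s1"):
            normalize_total_signal(small_matrix([[1.0, 1.0], [0.0, 0.0]]))

    def test_requires_raw_state(self):
        m = small_matrix([[1.0, 2.0], [3.0, 4.0]], state="total-normalized")
        with pytest.raises(PipelineOrderError):
            normalize_total_signal(m)


class TestParetoScale:
    def test_unit_sd_column(self):
        m = pareto_scale(small_matrix([[1.0], [2.0], [3.0]]))
        assert np.allclose(m.data["F0"], [-1.0, 0.0, 1.0])

    def test_scaled_variance_equals_original_sd(self, rng):
        values = rng.lognormal(3.0, 1.0, size=(30, 5))
        m = pareto_scale(small_matrix(values.tolist()))
        original_sd = np.std(values, axis=0, ddof=1)
        scaled_var = np.var(m.data.to_numpy(), axis=0, ddof=1)
        assert np.allclose(scaled_var, original_sd, rtol=1e-9)

    def test_column_means_zero(self, rng):
        values = rng.normal(10.0, 2.0, size=(20, 4))
        m = pareto_scale(small_matrix(values.tolist()))
        assert np.allclose(m.data.mean(axis=0), 0.0, atol=1e-12)

    def test_constant_column_left_centred(self):
        with pytest.warns(UserWarning, match="constant"):
            m = pareto_scale(small_matrix([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]))
        assert np.allclose(m.data["F0"], 0.0)

    def test_double_scaling_raises(self):
        m = pareto_scale(small_matrix([[1.0, 2.0], [3.0, 4.0], [5.0, 7.0]]))
        with pytest.raises(PipelineOrderError):
            pareto_scale(m)


class TestPca:
    def test_rank_one_matrix(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        values = np.outer([1.0, 2.0, 3.0], base)
        m = small_matrix(values.tolist(), state="pareto")
        model = pca(m, 1)
        assert model.r2x[0] == pytest.approx(1.0)

    def test_gaussian_cloud_variance_split(self, rng):
        cov = np.diag([9.0, 1.0])
        values = rng.multivariate_normal([0.0, 0.0], cov, size=500)
        df = pd.DataFrame(values, index=[f"s{i}" for i in range(500)], columns=["a", "b"])
        model = pca(FeatureMatrix(df, scaling_state="pareto"), 2)
        assert model.r2x[0] == pytest.approx(0.9, abs=0.03)
        assert model.r2x[1] == pytest.approx(0.1, abs=0.03)

    def test_full_rank_reconstruction(self, rng):
        values = rng.normal(size=(6, 4))
        values -= values.mean(axis=0)
        m = small_matrix(values.tolist(), state="pareto")
        model = pca(m, 4)
        recon = model.scores.to_numpy() @ model.loadings.to_numpy().T
        assert np.allclose(recon, values, atol=1e-9)

    def test_r2x_non_increasing(self, rng):
        values = rng.normal(size=(10, 6))
        m = small_matrix(values.tolist(), state="pareto")
        model = pca(m, 5)
        assert np.all(np.diff(model.r2x) <= 1e-12)

    def test_loadings_orthonormal(self, rng):
        values = rng.normal(size=(8, 5))
        m = small_matrix(values.tolist(), state="pareto")
        model = pca(m, 3)
        L = model.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(3), atol=1e-9)

    def test_warns_when_not_pareto(self):
        m = small_matrix([[1.0, 2.0], [3.0, 4.0], [4.0, 1.0]])
        with pytest.warns(UserWarning, match="Pareto"):
            pca(m, 1)

    def test_too_many_components(self):
        m = small_matrix([[1.0, 2.0], [3.0, 4.0]], state="pareto")
        with pytest.raises(ValueError):
            pca(m, 2)  # max is min(n_samples - 1, n_features) = 1


class TestFuseVariables:
    def test_column_count_plus_four(self, assay_table):
        m = small_matrix([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        fused = fuse_variables(m, assay_table)
        assert fused.data.shape[1] == m.data.shape[1] + 4

    def test_removal_reverts_exactly(self, assay_table):
        m = small_matrix([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        fused = fuse_variables(m, assay_table)
        reverted = fused.data[fused.feature_columns]
        pd.testing.assert_frame_equal(reverted, m.data)

    def test_missing_sample_raises(self, assay_table):
        df = pd.DataFrame([[1.0, 2.0]], index=["unknown"], columns=["F0", "F1"])
        with pytest.raises(ValueError, match="unknown"):
            fuse_variables(FeatureMatrix(df), assay_table)

    def test_fuse_after_pareto_raises(self, assay_table):
        m = pareto_scale(small_matrix([[1.0, 2.0], [3.0, 4.0], [5.0, 7.0]]))
        with pytest.raises(PipelineOrderError):
            fuse_variables(m, assay_table)

    def test_fused_auc_loading_opposes_tpc_on_pc1(self):
        """Constructed groups: high-TPC samples have low AUC, so the two assay
        loadings land on opposite signs of the dominant component."""
        rng = np.random.default_rng(3)
        n_per, n_feat = 10, 30
        rows, tpc, auc = [], [], []
        for level in (0.0, 1.0):  # low-phenolic vs high-phenolic group
            for _ in range(n_per):
                feats = rng.lognormal(2.0 + 2.0 * level, 0.1, n_feat)
                rows.append(feats)
                tpc.append(1.0 + 12.0 * level + rng.normal(0, 0.1))
                auc.append(1.5e2 - 1.4e2 * level + rng.normal(0, 2.0))
        index = [f"s{i}" for i in range(2 * n_per)]
        matrix = FeatureMatrix(pd.DataFrame(rows, index=index))
        assays = pd.DataFrame(
            {
                "PV": 100.0 + rng.normal(0, 1.0, len(index)),
                "TPC": tpc,
                "RSA": tpc,
                "AUC": auc,
            },
            index=index,
        )
        fused = fuse_variables(normalize_total_signal(matrix), assays)
        model = pca(pareto_scale(fused), 2)
        pc1 = model.loadings["PC1"]
        assert pc1["AUC"] * pc1["TPC"] < 0


class TestSyntheticGroupSeparation:
    def test_silhouette_above_half(self):
        from sklearn.metrics import silhouette_score

        matrix, groups = gen_feature_table(
            n_bio=3, n_tech=2, n_features=400, effect=0.10, seed=21
        )
        scaled = pareto_scale(normalize_total_signal(matrix))
        model = pca(scaled, 2)
        score = silhouette_score(model.scores.to_numpy(), groups.to_numpy())
        assert score > 0.5

    def test_no_effect_no_separation(self):
        from sklearn.metrics import silhouette_score

        matrix, groups = gen_feature_table(
            n_bio=3, n_tech=2, n_features=200, effect=0.0, seed=21
        )
        scaled = pareto_scale(normalize_total_signal(matrix))
        model = pca(scaled, 2)
        score = silhouette_score(model.scores.to_numpy(), groups.to_numpy())
        assert abs(score) < 0.3
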