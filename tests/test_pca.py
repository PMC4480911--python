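from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA as SkPCA
from sklearn.metrics import silhouette_score

from spikeflow import (
    ValidationError,
    fit_pca,
    high_loading_genes,
    loading_zscores,
    normalize,
    pc_correlation,
    scale_noncenter,
)
from spikeflow.pca import PCAResult
from spikeflow.simulate import preset, simulate


def _random_frame(rng, g=6, n=5):
    return pd.DataFrame(
        rng.normal(2.0, 1.0, size=(g, n)),
        index=[f"g{i}" for i in range(g)],
        columns=[f"s{j}" for j in range(n)],
    )


class TestScaleNoncenter:
    def test_rows_have_unit_sd_and_keep_mean(self):
        frame = pd.DataFrame({"s1": [1.0], "s2": [2.0], "s3": [3.0]}, index=["g"])
        out = scale_noncenter(frame)
        sd = np.std([1, 2, 3])
        assert out.loc["g"].std(ddof=0) == pytest.approx(1.0)
        assert out.loc["g"].mean() == pytest.approx(2.0 / sd)  # mean NOT removed

    def test_constant_gene_dropped(self, rng):
        frame = _random_frame(rng)
        frame.loc["g0"] = 5.0
        out = scale_noncenter(frame)
        assert "g0" not in out.index
        assert np.allclose(out.std(axis=1, ddof=0), 1.0)

    def test_all_constant_errors(self):
        frame = pd.DataFrame({"s1": [1.0, 2.0], "s2": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValidationError, match="zero variance"):
            scale_noncenter(frame)


class TestFitPca:
    def test_rank_one_matrix_loads_everything_on_pc1(self):
        u = np.array([1.0, 2.0, 3.0])
        v = np.array([1.0, 1.5, 0.5, 2.0])
        frame = pd.DataFrame(np.outer(u, v), index=list("abc"), columns=list("wxyz"))
        result = fit_pca(frame, 2)
        assert result.contribution_ratio["PC1"] == pytest.approx(100.0, abs=1e-8)

    def test_loadings_orthonormal(self, rng):
        result = fit_pca(_random_frame(rng, 10, 6), 4)
        u = result.loadings.to_numpy()
        assert np.allclose(u.T @ u, np.eye(4), atol=1e-8)

    def test_contribution_ratios_sum_to_100_when_all_retained(self, rng):
        result = fit_pca(_random_frame(rng, 8, 5), 5)
        assert result.contribution_ratio.sum() == pytest.approx(100.0, abs=1e-8)

    def test_matches_uncentered_eigendecomposition_oracle(self, rng):
        """Independent oracle: eigendecomposition of the uncentered
        cross-product X X^T must reproduce loadings and scores up to sign."""
        for _ in range(10):
            frame = _random_frame(rng, 6, 5)
            x = frame.to_numpy()
            result = fit_pca(frame, 3)
            evals, evecs = np.linalg.eigh(x @ x.T)
            order = np.argsort(evals)[::-1]
            evals, evecs = evals[order], evecs[:, order]
            for c in range(3):
                u_ref = evecs[:, c]
                u_fit = result.loadings.iloc[:, c].to_numpy()
                sign = np.sign(u_ref @ u_fit)
                assert np.allclose(u_fit, sign * u_ref, atol=1e-8)
                scores_ref = x.T @ (sign * u_ref)
                assert np.allclose(
                    result.sample_scores.iloc[:, c].to_numpy(), scores_ref, atol=1e-8
                )

    def test_sign_convention_deterministic(self, rng):
        frame = _random_frame(rng, 12, 6)
        r1, r2 = fit_pca(frame, 3), fit_pca(frame, 3)
        pd.testing.assert_frame_equal(r1.loadings, r2.loadings)
        for c in r1.components:
            col = r1.loadings[c]
            assert col.iloc[np.abs(col.to_numpy()).argmax()] > 0

    def test_noncentering_is_material(self, rng):
        """A large common offset must dominate PC1 of the uncentered fit but
        not of a centered one — guards against silently centering."""
        frame = _random_frame(rng, 30, 8) + 50.0
        uncentered = fit_pca(frame, 2)
        centered = SkPCA(n_components=2).fit(frame.to_numpy().T)
        u1 = uncentered.loadings["PC1"].to_numpy()
        c1 = centered.components_[0]
        offset = np.ones(30) / np.sqrt(30)
        assert abs(u1 @ offset) > 0.99
        assert abs(c1 @ offset) < 0.5
        assert abs(u1 @ c1) < 0.5


class TestLoadingZ:
    def test_zscores_standardized(self, rng):
        result = fit_pca(_random_frame(rng, 50, 6), 3)
        z = loading_zscores(result, "PC2")
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-12)
        # z of the largest loading equals (loading - mean) / sd by hand
        load = result.loadings["PC2"]
        manual = (load - load.mean()) / load.std(ddof=0)
        pd.testing.assert_series_equal(z, manual.rename("PC2"))

    def test_too_few_genes_or_constant_loadings_error(self):
        small = PCAResult(
            sample_scores=pd.DataFrame({"PC1": [1.0, 2.0]}, index=["s1", "s2"]),
            loadings=pd.DataFrame({"PC1": [0.5, 0.5]}, index=["a", "b"]),
            contribution_ratio=pd.Series({"PC1": 100.0}),
            loading_z=pd.DataFrame({"PC1": [np.nan, np.nan]}, index=["a", "b"]),
        )
        with pytest.raises(ValidationError, match=">= 3 genes"):
            loading_zscores(small, "PC1")
        flat = PCAResult(
            sample_scores=small.sample_scores,
            loadings=pd.DataFrame({"PC1": [0.5, 0.5, 0.5]}, index=["a", "b", "c"]),
            contribution_ratio=small.contribution_ratio,
            loading_z=pd.DataFrame({"PC1": [np.nan] * 3}, index=["a", "b", "c"]),
        )
        with pytest.raises(ValidationError, match="constant"):
            loading_zscores(flat, "PC1")

    def test_unknown_component_errors(self, rng):
        result = fit_pca(_random_frame(rng), 2)
        with pytest.raises(ValidationError, match="PC9"):
            loading_zscores(result, 9)


def _normal_loading_result(rng, n=10_000):
    loadings = pd.DataFrame({"PC1": rng.standard_normal(n)},
                            index=[f"g{i}" for i in range(n)])
    return PCAResult(
        sample_scores=pd.DataFrame({"PC1": [0.0, 1.0]}, index=["s1", "s2"]),
        loadings=loadings,
        contribution_ratio=pd.Series({"PC1": 100.0}),
        loading_z=loadings.copy(),
    )


class TestHighLoadingGenes:
    def test_three_sigma_rate_on_standard_normal(self, rng):
        result = _normal_loading_result(rng)
        pos, neg = high_loading_genes(result, "PC1", 3.0)
        # P(Z > 3) = 0.135 %; 13.5 expected per side, +/- 3 sqrt(13.5)
        for side in (pos, neg):
            assert 2 <= len(side) <= 26

    def test_monotone_in_k_sigma(self, rng):
        result = _normal_loading_result(rng)
        pos3, neg3 = high_loading_genes(result, "PC1", 3.0)
        pos4, neg4 = high_loading_genes(result, "PC1", 4.0)
        assert set(pos4) <= set(pos3)
        assert set(neg4) <= set(neg3)

    def test_infinite_k_selects_nothing(self, rng):
        result = _normal_loading_result(rng)
        pos, neg = high_loading_genes(result, "PC1", np.inf)
        assert len(pos) == 0 and len(neg) == 0


class TestOnSimulatedCohort:
    def test_pc1_separates_tissue_from_culture(self):
        """Across generator seeds, PC1 of the spike-normalized uncentered fit
        separates the tissue samples (SG) from all cultured types."""
        sils = []
        for seed in range(3):
            matrix, meta, _ = simulate(replace(preset("four_types"), seed=seed))
            norm = normalize(matrix, "spike")
            pre = scale_noncenter(np.log1p(norm.loc[~matrix.is_spike]))
            result = fit_pca(pre, 3)
            labels = (meta.set_index("sample_id")["sample_type"] == "SG").to_numpy()
            pc1 = result.sample_scores["PC1"].to_numpy().reshape(-1, 1)
            sils.append(silhouette_score(pc1, labels))
        assert np.median(sils) > 0.5

    def test_pc_correlation_finds_content_axis_genes(self):
        matrix, meta, _ = simulate(replace(preset("four_types"), n_genes=500, seed=1))
        norm = normalize(matrix, "spike")
        pre = scale_noncenter(np.log1p(norm.loc[~matrix.is_spike]))
        result = fit_pca(pre, 2)
        cor = pc_correlation(matrix, result, "PC1", seed=2)
        # the gene whose normalized profile best tracks PC1 must be called
        scores = result.sample_scores["PC1"]
        endog = norm.loc[~matrix.is_spike]
        pearson = endog.apply(lambda row: np.corrcoef(row, scores[endog.columns])[0, 1], axis=1)
        top = pearson.dropna().idxmax()
        assert cor.table.loc[top, "local_fdr"] < 0.01
        assert cor.table.loc[top, "score"] > 0

    def test_pc_correlation_null_calibrated(self, rng):
        matrix, meta, _ = simulate(
            replace(preset("sg_vs_ekc"), n_genes=400, de_fraction=0.0,
                    content={"SG": 1.0, "EKC": 1.0})
        )
        norm = normalize(matrix, "spike")
        pre = scale_noncenter(np.log1p(norm.loc[~matrix.is_spike]))
        result = fit_pca(pre, 2)
        from spikeflow import sam_test

        shuffled = pd.Series(
            rng.permutation(result.sample_scores["PC1"].to_numpy()),
            index=result.sample_scores.index,
        )
        res = sam_test(matrix, shuffled, "quantitative", seed=3)
        assert (res.table["local_fdr"] < 0.01).mean() <= 0.02
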