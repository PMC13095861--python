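import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dynfuse import (
    FusionInput,
    balance_and_concatenate,
    flag_super_gaussian,
    infomax_jica,
    knee_point,
    match_sources,
    select_model_order,
    split_stability,
)
from dynfuse.fusion import _rowcorr


def _input(x, p1=None):
    n, p = x.shape
    p1 = p // 2 if p1 is None else p1
    return FusionInput(
        x=x,
        subjects=[f"s{i}" for i in range(n)],
        snp_cols=[f"snp{j}" for j in range(p1)],
        dfnc_cols=[f"fnc{j}" for j in range(p - p1)],
    )


def _laplace_sources(rng, c, p):
    s = rng.laplace(size=(c, p))
    return (s - s.mean(axis=1, keepdims=True)) / s.std(axis=1, keepdims=True)


class TestBalance:
    def test_equal_feature_counts_give_equal_block_norms(self, rng):
        a = pd.DataFrame(rng.normal(size=(50, 40)), index=[f"s{i}" for i in range(50)])
        b = pd.DataFrame(
            5.0 * rng.normal(size=(50, 40)),
            index=[f"s{i}" for i in range(50)],
            columns=[f"d{j}" for j in range(40)],
        )
        fi = balance_and_concatenate(a, b)
        na = np.linalg.norm(fi.x[:, : fi.p1])
        nb = np.linalg.norm(fi.x[:, fi.p1 :])
        assert abs(na - nb) / nb < 0.05

    def test_unequal_blocks_balanced_to_equal_total_variance(self, rng):
        idx = [f"s{i}" for i in range(60)]
        a = pd.DataFrame(rng.normal(size=(60, 200)), index=idx)
        b = pd.DataFrame(rng.normal(size=(60, 20)), index=idx, columns=[f"d{j}" for j in range(20)])
        fi = balance_and_concatenate(a, b)
        na = np.linalg.norm(fi.x[:, : fi.p1]) ** 2
        nb = np.linalg.norm(fi.x[:, fi.p1 :]) ** 2
        assert abs(na - nb) / nb < 0.1

    def test_constant_column_dropped(self, rng):
        idx = [f"s{i}" for i in range(30)]
        a = pd.DataFrame(rng.normal(size=(30, 5)), index=idx)
        a[2] = 7.0
        b = pd.DataFrame(rng.normal(size=(30, 4)), index=idx, columns=[f"d{j}" for j in range(4)])
        fi = balance_and_concatenate(a, b)
        assert fi.p1 == 4 and "2" not in fi.snp_cols

    def test_balance_off_keeps_raw_zscores(self, rng):
        idx = [f"s{i}" for i in range(30)]
        a = pd.DataFrame(rng.normal(size=(30, 10)), index=idx)
        b = pd.DataFrame(rng.normal(size=(30, 10)), index=idx, columns=[f"d{j}" for j in range(10)])
        fi = balance_and_concatenate(a, b, balance=False)
        np.testing.assert_allclose(fi.x.std(axis=0), 1.0, atol=1e-12)


class TestModelOrder:
    def test_median_of_printed_scree_estimates(self):
        """Pooling knee estimates {35, 40, 39, 33, 33} by the median gives 35."""
        assert select_model_order([], knees=[35, 40, 39, 33, 33], floor_variance=0.0) == 35

    def test_knee_finds_planted_rank(self, rng):
        """Planted low-rank oracle: rank-r signal + flat noise floor."""
        n, p, r = 200, 120, 8
        x = rng.normal(size=(n, r)) * 10 @ rng.normal(size=(r, p)) / np.sqrt(p)
        x = x + 0.5 * rng.normal(size=(n, p))
        lam = np.linalg.svd(x - x.mean(0), compute_uv=False) ** 2 / (n - 1)
        k = knee_point(lam)
        assert abs(k - r) <= 2

    def test_floor_variance_raises_order(self, rng):
        x = rng.normal(size=(50, 30))
        low = select_model_order([x], floor_variance=0.0)
        high = select_model_order([x], floor_variance=0.95)
        assert high >= low
        lam = np.linalg.svd(x - x.mean(0), compute_uv=False) ** 2
        frac = np.cumsum(lam) / lam.sum()
        assert frac[high - 1] >= 0.95

    def test_invalid_floor_rejected(self, rng):
        x = rng.normal(size=(10, 200))
        with pytest.raises(ValueError, match="floor_variance"):
            select_model_order([x], floor_variance=1.5)


class TestInfomax:
    def test_noiseless_identifiability(self, rng):
        """X = A0 S0 exactly, Laplacian sources -> mean best-match |r| > 0.99."""
        s0 = _laplace_sources(rng, 3, 1200)
        a0 = rng.normal(size=(80, 3))
        res = infomax_jica(_input(a0 @ s0), 3, seed=0)
        _, vals = match_sources(s0, res.sources.to_numpy())
        assert vals.mean() > 0.99

    def test_matching_invariant_to_permutation_and_sign(self, rng):
        """ICA ambiguity contract: sign flips and reordering of the planted
        sources do not change the matched recovery quality."""
        s0 = _laplace_sources(rng, 3, 1000)
        a0 = rng.normal(size=(60, 3))
        res = infomax_jica(_input(a0 @ s0), 3, seed=1)
        perm = np.array([2, 0, 1])
        flipped = (np.diag([1.0, -1.0, -1.0]) @ s0)[perm]
        _, v1 = match_sources(s0, res.sources.to_numpy())
        _, v2 = match_sources(flipped, res.sources.to_numpy())
        np.testing.assert_allclose(np.sort(v1), np.sort(v2), atol=1e-9)

    def test_seed_stability_on_noisy_data(self, rng):
        s0 = _laplace_sources(rng, 4, 800)
        a0 = rng.normal(size=(100, 4))
        x = a0 @ s0 + 0.5 * rng.normal(size=(100, 800))
        res_a = infomax_jica(_input(x), 4, seed=10)
        res_b = infomax_jica(_input(x), 4, seed=99)
        _, vals = match_sources(res_a.sources.to_numpy(), res_b.sources.to_numpy())
        assert vals.mean() > 0.9

    def test_reconstruction_matches_rank_c_pca(self, rng):
        x = rng.normal(size=(50, 200))
        fi = _input(x)
        res = infomax_jica(fi, 5, seed=0)
        xc = x - x.mean(axis=0)
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        pca_recon = u[:, :5] * s[:5] @ vt[:5]
        recon = res.loadings.to_numpy() @ res.sources.to_numpy()
        rel = np.linalg.norm(recon - pca_recon) / np.linalg.norm(pca_recon)
        assert rel < 1e-6

    def test_source_rows_uncorrelated_and_unit_variance(self, rng):
        s0 = _laplace_sources(rng, 4, 1500)
        a0 = rng.normal(size=(80, 4))
        res = infomax_jica(_input(a0 @ s0 + 0.2 * rng.normal(size=(80, 1500))), 4, seed=3)
        src = res.sources.to_numpy()
        np.testing.assert_allclose(src.std(axis=1), 1.0, atol=1e-9)
        c = _rowcorr(src, src)
        off = c - np.eye(4)
        assert np.abs(off).max() < 0.05

    def test_positive_skewness_sign_convention(self, rng):
        s0 = _laplace_sources(rng, 3, 1000)
        a0 = rng.normal(size=(60, 3))
        res = infomax_jica(_input(a0 @ s0), 3, seed=2)
        src = res.sources.to_numpy()
        skew = stats.skew(src, axis=1)
        assert (skew >= -1e-9).all()

    def test_agrees_with_fastica_oracle(self, rng):
        """Independent cross-check: sklearn FastICA on the same mixture
        recovers sources that match the Infomax sources component-wise."""
        from sklearn.decomposition import FastICA

        s0 = _laplace_sources(rng, 4, 2000)
        a0 = rng.normal(size=(90, 4))
        x = a0 @ s0
        res = infomax_jica(_input(x), 4, seed=0)
        ica = FastICA(n_components=4, random_state=0, whiten="unit-variance")
        s_ref = ica.fit_transform((x - x.mean(0)).T).T  # features as samples
        _, vals = match_sources(s_ref, res.sources.to_numpy())
        assert vals.mean() > 0.99

    def test_unimodal_snp_only_baseline(self, rng):
        """Baseline mode: an input with an empty connectivity block runs the
        same decomposition on the SNP block alone."""
        s0 = _laplace_sources(rng, 3, 500)
        a0 = rng.normal(size=(60, 3))
        fi = FusionInput(
            x=a0 @ s0,
            subjects=[f"s{i}" for i in range(60)],
            snp_cols=[f"snp{j}" for j in range(500)],
            dfnc_cols=[],
        )
        res = infomax_jica(fi, 3, seed=0)
        _, vals = match_sources(s0, res.sources.to_numpy())
        assert vals.mean() > 0.99
        assert res.sources_dfnc.shape[1] == 0

    def test_order_must_be_below_subjects(self, rng):
        with pytest.raises(ValueError, match="model order"):
            infomax_jica(_input(rng.normal(size=(10, 50))), 10)

    def test_rank_deficient_data_rejected(self, rng):
        x = rng.normal(size=(40, 3)) @ rng.normal(size=(3, 100))
        with pytest.raises(ValueError, match="rank"):
            infomax_jica(_input(x), 10)


class TestSuperGaussian:
    def test_laplace_flagged_gaussian_not(self, rng):
        src = np.vstack([rng.laplace(size=10_000), rng.normal(size=10_000)])
        k = stats.kurtosis(src, axis=1)
        assert k[0] > 0.2 and abs(k[1]) < 0.2

    def test_gaussian_rows_rarely_flagged_at_threshold(self, rng):
        hits = 0
        for _ in range(40):
            k = stats.kurtosis(rng.normal(size=10_000))
            hits += int(k > 0.2)
        assert hits <= 2  # >= 95% not flagged

    def test_threshold_minus_ten_flags_all(self, rng):
        s0 = _laplace_sources(rng, 3, 500)
        res = infomax_jica(_input(rng.normal(size=(40, 3)) @ s0), 3, seed=0)
        flags = flag_super_gaussian(res, kurtosis_threshold=-10.0)
        assert flags.all()


class TestSplitStability:
    def test_noiseless_planted_data_perfectly_stable(self):
        rng = np.random.default_rng(2024)
        s0 = _laplace_sources(rng, 3, 900)
        a0 = rng.normal(size=(120, 3))
        tbl = split_stability(_input(a0 @ s0), 3, n_folds=3, seed=0)
        assert tbl["abs_r"].mean() > 0.98
        # report shape: mean and SD over all components
        summary = tbl.groupby("component")["abs_r"].agg(["mean", "std"])
        assert len(summary) == 3

    def test_single_fold_is_identity(self):
        rng = np.random.default_rng(77)
        s0 = _laplace_sources(rng, 2, 600)
        a0 = rng.normal(size=(50, 2))
        tbl = split_stability(_input(a0 @ s0), 2, n_folds=1, seed=0)
        np.testing.assert_allclose(tbl["abs_r"], 1.0, atol=1e-9)

    def test_fold_too_small_rejected(self, rng):
        with pytest.raises(ValueError, match="too small"):
            split_stability(_input(rng.normal(size=(30, 100))), 12, n_folds=3)
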