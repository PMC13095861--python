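import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dynfuse import (
    combine_fdr,
    group_difference,
    make_validation_fixture,
    partial_association,
    project_dfnc,
)


def _frames(x, s):
    n, p = x.shape
    cols = [f"pair{j}" for j in range(p)]
    xd = pd.DataFrame(x, index=[f"v{i}" for i in range(n)], columns=cols)
    sd = pd.DataFrame(s, index=pd.RangeIndex(s.shape[0], name="component"), columns=cols)
    return xd, sd


class TestProjection:
    def test_recovers_planted_loadings_exactly(self, rng):
        s = rng.laplace(size=(5, 300))
        a0 = rng.normal(size=(40, 5))
        xd, sd = _frames(a0 @ s, s)
        a = project_dfnc(xd, sd)
        rel = np.linalg.norm(a.to_numpy() - a0) / np.linalg.norm(a0)
        assert rel < 1e-8

    def test_orthogonal_data_projects_to_zero(self, rng):
        s = np.zeros((2, 10))
        s[0, 0] = s[1, 1] = 1.0
        x = np.zeros((5, 10))
        x[:, 5:] = rng.normal(size=(5, 5))
        xd, sd = _frames(x, s)
        a = project_dfnc(xd, sd)
        np.testing.assert_allclose(a.to_numpy(), 0.0, atol=1e-12)

    def test_pair_mismatch_raises(self, rng):
        s = rng.normal(size=(2, 10))
        xd, sd = _frames(rng.normal(size=(5, 10)), s)
        xd.columns = [f"other{j}" for j in range(10)]
        with pytest.raises(ValueError, match="pair legend"):
            project_dfnc(xd, sd)


class TestGroupDifference:
    def test_effect_size_closed_form(self):
        """r^2 = t^2/(t^2+df): t=2, df=100 -> 4/104."""
        t, df = 2.0, 100.0
        assert np.isclose(t**2 / (t**2 + df), 4.0 / 104.0)

    def test_null_has_small_t_and_r2(self, rng):
        n = 2000
        load = pd.DataFrame(rng.normal(size=(n, 3)), index=[f"s{i}" for i in range(n)])
        diag = pd.Series(np.repeat([0, 1], n // 2), index=load.index)
        res = group_difference(load, diag)
        assert (res["r2"] < 0.01).all()
        assert (res["df"] == n - 2).all()

    def test_matches_scipy_pooled_ttest(self, rng):
        n = 80
        load = pd.DataFrame(rng.normal(size=(n, 2)), index=[f"s{i}" for i in range(n)])
        load.iloc[: n // 2, 0] += 1.0
        diag = pd.Series(np.repeat([1, 0], n // 2), index=load.index)
        res = group_difference(load, diag)
        t_ref, p_ref = stats.ttest_ind(
            load.iloc[: n // 2, 0], load.iloc[n // 2 :, 0], equal_var=True
        )
        assert np.isclose(res["t"].iloc[0], t_ref)
        assert np.isclose(res["p"].iloc[0], p_ref)

    def test_r2_invariant_to_sign_flip(self, rng):
        n = 60
        load = pd.DataFrame(rng.normal(size=(n, 1)), index=[f"s{i}" for i in range(n)])
        diag = pd.Series(np.repeat([0, 1], n // 2), index=load.index)
        r1 = group_difference(load, diag)["r2"].iloc[0]
        r2 = group_difference(-load, diag)["r2"].iloc[0]
        assert np.isclose(r1, r2)

    def test_covariate_control_removes_confound(self, rng):
        n = 400
        idx = [f"s{i}" for i in range(n)]
        diag = pd.Series(np.repeat([0, 1], n // 2), index=idx)
        age = pd.Series(rng.uniform(20, 70, n) + 10 * diag, index=idx)
        load = pd.DataFrame({"c0": 0.1 * age + rng.normal(size=n)}, index=idx)
        cov = pd.DataFrame({"age": age})
        raw = group_difference(load, diag)
        adj = group_difference(load, diag, cov, ["age"])
        assert adj["r2"].iloc[0] < raw["r2"].iloc[0]

    def test_single_group_raises(self, rng):
        load = pd.DataFrame(rng.normal(size=(10, 1)), index=[f"s{i}" for i in range(10)])
        diag = pd.Series(np.zeros(10, dtype=int), index=load.index)
        with pytest.raises(ValueError, match="two diagnostic groups"):
            group_difference(load, diag)


class TestFDR:
    def test_bh_worked_example(self):
        """Direct enumeration: p = {0.001, 0.02, 0.03, 0.5} -> 3 rejections
        at alpha = 0.05 under the step-up rule."""
        tables = {
            0: pd.DataFrame({"t": [0] * 4, "df": [10] * 4,
                             "p": [0.001, 0.02, 0.03, 0.5], "r2": [0] * 4})
        }
        merged = combine_fdr(tables, alpha=0.05)
        assert int(merged["significant"].sum()) == 3
        # step-up oracle computed by hand: max i with p_(i) <= i/m * alpha = 3
        p_sorted = np.sort([0.001, 0.02, 0.03, 0.5])
        thresh = np.arange(1, 5) / 4 * 0.05
        assert (p_sorted <= thresh).nonzero()[0].max() + 1 == 3

    def test_q_monotone_in_p(self, rng):
        p = rng.uniform(size=30)
        tables = {0: pd.DataFrame({"t": 0.0, "df": 10.0, "p": p, "r2": 0.0})}
        merged = combine_fdr(tables).sort_values("p")
        assert (np.diff(merged["q"]) >= -1e-12).all()
        assert (merged["q"] >= merged["p"] - 1e-12).all()

    def test_family_spans_all_fusions(self, rng):
        tables = {
            s: pd.DataFrame({"t": 0.0, "df": 10.0, "p": rng.uniform(size=5), "r2": 0.0})
            for s in range(4)
        }
        merged = combine_fdr(tables)
        assert len(merged) == 20
        assert set(merged.index.get_level_values("state")) == {0, 1, 2, 3}


class TestPartialAssociation:
    def test_identical_variables_correlate_perfectly(self, rng):
        idx = [f"s{i}" for i in range(30)]
        load = pd.DataFrame({"c0": rng.normal(size=30)}, index=idx)
        scores = pd.DataFrame({"m": load["c0"]}, index=idx)
        res = partial_association(load, scores)
        assert np.isclose(res.loc[("c0", "m"), "r"], 1.0)

    def test_null_false_positive_rate_calibrated(self, rng):
        n, reps, hits = 300, 100, 0
        idx = [f"s{i}" for i in range(n)]
        for _ in range(reps):
            load = pd.DataFrame({"c0": rng.normal(size=n)}, index=idx)
            scores = pd.DataFrame({"m": rng.normal(size=n)}, index=idx)
            r = partial_association(load, scores).loc[("c0", "m"), "r"]
            hits += int(abs(r) > 1.96 / np.sqrt(n))
        assert 0.01 <= hits / reps <= 0.12

    def test_confound_removed_by_partialling(self, rng):
        n = 500
        idx = [f"s{i}" for i in range(n)]
        conf = rng.normal(size=n)
        load = pd.DataFrame({"c0": conf + 0.1 * rng.normal(size=n)}, index=idx)
        scores = pd.DataFrame({"m": conf + 0.1 * rng.normal(size=n)}, index=idx)
        cov = pd.DataFrame({"conf": conf}, index=idx)
        raw = partial_association(load, scores)
        adj = partial_association(load, scores, cov, ["conf"])
        assert abs(raw.loc[("c0", "m"), "r"]) > 0.9
        assert abs(adj.loc[("c0", "m"), "r"]) < 0.2

    def test_listwise_deletion_and_df(self, rng):
        idx = [f"s{i}" for i in range(50)]
        load = pd.DataFrame({"c0": rng.normal(size=50)}, index=idx)
        scores = pd.DataFrame({"m": rng.normal(size=50)}, index=idx)
        scores.iloc[:10, 0] = np.nan
        res = partial_association(load, scores)
        assert res.loc[("c0", "m"), "n"] == 40

    def test_group_filter_restricts_sample(self, rng):
        idx = [f"s{i}" for i in range(40)]
        load = pd.DataFrame({"c0": rng.normal(size=40)}, index=idx)
        scores = pd.DataFrame({"m": rng.normal(size=40)}, index=idx)
        grp = pd.Series([1] * 25 + [0] * 15, index=idx)
        res = partial_association(load, scores, group_filter=grp == 1)
        assert res.loc[("c0", "m"), "n"] == 25

    def test_too_few_subjects_raises(self, rng):
        idx = [f"s{i}" for i in range(4)]
        load = pd.DataFrame({"c0": rng.normal(size=4)}, index=idx)
        scores = pd.DataFrame({"m": [np.nan, np.nan, 1.0, 2.0]}, index=idx)
        cov = pd.DataFrame({"a": rng.normal(size=4), "b": rng.normal(size=4)}, index=idx)
        with pytest.raises(ValueError, match="need at least"):
            partial_association(load, scores, cov, ["a", "b"])


class TestPlantedEffectPipeline:
    def test_planted_shift_detected_by_projection_and_test(self, rng):
        """End-to-end: planted 0.5-SD shift on components {2, 5} is flagged."""
        x, s, _, diag = make_validation_fixture(
            n_subjects=400, n_components=35, n_features=600,
            effect_components=(2, 5), effect_size=0.5, seed=42, noise_sd=0.5,
        )
        xd, sd = _frames(x, s)
        a_val = project_dfnc(xd, sd)
        res = group_difference(a_val, pd.Series(diag, index=xd.index))
        tables = {0: res}
        for st in range(1, 4):
            xn, sn, _, dn = make_validation_fixture(
                n_subjects=400, n_components=35, n_features=600,
                effect_components=(), effect_size=0.0, seed=100 + st,
            )
            xdn, sdn = _frames(xn, sn)
            tables[st] = group_difference(project_dfnc(xdn, sdn), pd.Series(dn, index=xdn.index))
        merged = combine_fdr(tables, alpha=0.05)
        flagged = merged[merged["significant"]].index.tolist()
        assert (0, 2) in flagged and (0, 5) in flagged
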