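"""Independent-cohort validation of the fused components.

The discovery sources' connectivity elements are projected onto an
independent cohort's (residualized) sa-dFNC matrices via the Moore-Penrose
pseudo-inverse, ``A_val = X_val S_dfnc^+``; the projected loadings are tested
for case-control differences with a two-sample t-test after covariate
residualization, effect size ``r^2 = t^2 / (t^2 + df)``, and
Benjamini-Hochberg FDR applied jointly across all components of all
fusions.  Partial correlations relate the projected loadings to cognitive
and symptom scores (reported uncorrected, as an interpretation aid).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .states import residualize_features

__all__ = [
    "project_dfnc",
    "group_difference",
    "combine_fdr",
    "partial_association",
]


def project_dfnc(x_val: pd.DataFrame, s_dfnc: pd.DataFrame) -> pd.DataFrame:
    """Project validation sa-dFNC features onto the discovery dFNC sources.

    ``A_val = X_val @ pinv(S_dfnc)`` (SVD pseudo-inverse, default cutoff).
    Columns of ``x_val`` must match the discovery pair legend exactly.
    """
    if list(x_val.columns) != list(s_dfnc.columns):
        diff = set(map(str, x_val.columns)) ^ set(map(str, s_dfnc.columns))
        raise ValueError(f"pair legend mismatch between cohorts: {sorted(diff)[:10]}")
    a = x_val.to_numpy(dtype=float) @ np.linalg.pinv(s_dfnc.to_numpy(dtype=float))
    return pd.DataFrame(a, index=x_val.index, columns=s_dfnc.index)


def group_difference(
    loadings: pd.DataFrame,
    diagnosis: pd.Series,
    covariates: pd.DataFrame | None = None,
    covariate_names: list[str] | None = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Case-control test of each component's projected loadings.

    Loadings are residualized on the covariates (diagnosis never enters the
    design), then compared between cases (diagnosis == 1) and controls with
    a pooled-variance two-sample t-test (Welch optional), df = n1 + n2 - 2,
    and the explained variance of the group difference
    ``r^2 = t^2 / (t^2 + df)``.

    Returns a per-component table with columns ``t``, ``df``, ``p``, ``r2``.
    FDR across fusions is applied afterwards by :func:`combine_fdr`.
    """
    diag = diagnosis.loc[loadings.index].to_numpy()
    groups = np.unique(diag)
    if len(groups) != 2:
        raise ValueError(f"need exactly two diagnostic groups, got {groups.tolist()}")
    y = loadings
    if covariates is not None and covariate_names:
        y = residualize_features(loadings, covariates, covariate_names)
    cases, controls = y[diag == 1], y[diag == 0]
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("each group needs at least 2 subjects")
    t, p = stats.ttest_ind(
        cases.to_numpy(), controls.to_numpy(), axis=0, equal_var=not welch
    )
    if welch:
        # Welch-Satterthwaite df per component
        v1 = cases.var(axis=0, ddof=1).to_numpy() / len(cases)
        v0 = controls.var(axis=0, ddof=1).to_numpy() / len(controls)
        df = (v1 + v0) ** 2 / (v1**2 / (len(cases) - 1) + v0**2 / (len(controls) - 1))
    else:
        df = np.full(y.shape[1], len(cases) + len(controls) - 2, dtype=float)
    r2 = t**2 / (t**2 + df)
    return pd.DataFrame(
        {"t": t, "df": df, "p": p, "r2": r2},
        index=pd.Index(loadings.columns, name="component"),
    )


def combine_fdr(results: dict[int, pd.DataFrame], alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg step-up jointly across all fusions' components.

    ``results`` maps state -> per-component table from
    :func:`group_difference`.  Returns the merged table keyed by
    (state, component) with added ``q`` and ``significant`` columns; the FDR
    family is the union of all components of all fusions.
    """
    frames = []
    for state, tbl in sorted(results.items()):
        t = tbl.copy()
        t["state"] = state
        t["component"] = t.index
        frames.append(t.reset_index(drop=True))
    merged = pd.concat(frames, ignore_index=True).set_index(["state", "component"])
    reject, q, *_ = multipletests(merged["p"].to_numpy(), alpha=alpha, method="fdr_bh")
    merged["q"] = q
    merged["significant"] = reject
    return merged


def partial_association(
    loadings: pd.DataFrame,
    scores: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    covariate_names: list[str] | None = None,
    group_filter: pd.Series | None = None,
) -> pd.DataFrame:
    """Partial correlation of each (component, measure) pair.

    Subjects are optionally restricted by ``group_filter`` (boolean Series,
    e.g. the patient group for symptom scales); missing scores are removed
    listwise per measure.  Both the loading and the score are residualized
    on the covariates and their Pearson correlation is computed; the
    two-sided p-value uses a t distribution with ``n - 2 - n_covariates``
    degrees of freedom.  P-values are reported uncorrected.
    """
    idx = loadings.index.intersection(scores.index)
    if group_filter is not None:
        idx = idx[group_filter.loc[idx].astype(bool).to_numpy()]
    rows = []
    names = covariate_names or []
    for measure in scores.columns:
        sc = scores.loc[idx, measure]
        keep = idx[sc.notna().to_numpy()]
        n_cov_cols = 0
        if covariates is not None and names:
            cov_ok = covariates.loc[keep, names].notna().all(axis=1)
            keep = keep[cov_ok.to_numpy()]
        if covariates is not None and names:
            n_cov_cols = _n_design_cols(covariates.loc[keep], names)
        n = len(keep)
        if n < n_cov_cols + 3:
            raise ValueError(
                f"only {n} subjects left for measure {measure!r}; "
                f"need at least {n_cov_cols + 3}"
            )
        for comp in loadings.columns:
            y = loadings.loc[keep, comp].to_frame()
            s = scores.loc[keep, [measure]]
            if covariates is not None and names:
                y = residualize_features(y, covariates, names)
                s = residualize_features(s, covariates, names)
            yv, sv = y.to_numpy().ravel(), s.to_numpy().ravel()
            r = float(np.corrcoef(yv, sv)[0, 1])
            df = n - 2 - n_cov_cols
            r_clip = min(max(r, -1 + 1e-15), 1 - 1e-15)
            t = r_clip * np.sqrt(df / (1.0 - r_clip**2))
            p = 2.0 * stats.t.sf(abs(t), df)
            rows.append({"component": comp, "measure": measure, "r": r, "p": p, "n": n})
    return pd.DataFrame(rows).set_index(["component", "measure"])


def _n_design_cols(covariates: pd.DataFrame, names: list[str]) -> int:
    """Number of non-intercept columns the dummy-coded design expands to."""
    n = 0
    for name in names:
        col = covariates[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            n += max(col.nunique() - 1, 0)
        else:
            n += 1
    return n
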