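"""dFNC state estimation, window assignment, state averaging, residualization.

States are recurring whole-brain connectivity patterns: K-means clusters of
the windowed FNC vectors pooled over all subjects.  The number of states is
chosen by the elbow of the inertia curve; each subject's windows are then
assigned to the nearest centroid and averaged per state into subject-level
state-average dFNC (sa-dFNC) features.  A validation cohort's windows are
assigned to the discovery centroids without re-clustering.

Also here: the per-feature OLS residualization used before fusion (age, sex,
dummy-coded site for connectivity; sex, site and genotype principal
components for SNPs) and the genotype PCA that supplies population-
stratification covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .dfnc import WindowedFNCSeries

__all__ = [
    "StateModel",
    "fit_states",
    "assign_windows",
    "state_average",
    "sa_dfnc_matrices",
    "residualize_features",
    "compute_genotype_pcs",
]


@dataclass
class StateModel:
    """K-means state model: centroids, per-subject assignments, scan inertia."""

    k: int
    centroids: np.ndarray  # k x n_pairs
    assignments: dict[str, np.ndarray] = field(default_factory=dict)
    inertia: dict[int, float] = field(default_factory=dict)


def _elbow(k_values: list[int], inertias: list[float]) -> int:
    """k maximizing the second difference of the inertia curve.

    With fewer than three scanned k values the second difference is not
    defined and the smallest k is returned.
    """
    if len(k_values) < 3:
        return k_values[0]
    d2 = [
        inertias[i - 1] - 2.0 * inertias[i] + inertias[i + 1]
        for i in range(1, len(k_values) - 1)
    ]
    return k_values[1 + int(np.argmax(d2))]


def fit_states(
    wfnc_list: list[WindowedFNCSeries],
    k_range=range(2, 9),
    replicates: int = 10,
    seed: int = 0,
) -> StateModel:
    """K-means over all subjects' windows with elbow selection of k.

    For every k in ``k_range`` K-means (k-means++ initialization,
    squared-Euclidean inertia, ``replicates`` restarts, best kept) is fitted
    on the pooled window matrix; the elbow k maximizes the second difference
    of the inertia curve; the model at the elbow k is returned with
    per-subject window assignments.
    """
    k_values = sorted(k_range)
    windows = np.vstack([w.values for w in wfnc_list])
    if windows.shape[0] < 10 * max(k_values):
        raise ValueError(
            f"{windows.shape[0]} windows is too few for k up to {max(k_values)}"
        )
    rng = np.random.default_rng(seed)
    models, inertias = {}, {}
    for k in k_values:
        for attempt in range(10):
            km = KMeans(
                n_clusters=k,
                init="k-means++",
                n_init=replicates,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(windows)
            if len(np.unique(km.labels_)) == k:
                break
        else:
            raise RuntimeError(f"empty cluster persisted over 10 restarts at k={k}")
        models[k] = km
        inertias[k] = float(km.inertia_)

    k_best = _elbow(k_values, [inertias[k] for k in k_values])
    model = StateModel(k=k_best, centroids=models[k_best].cluster_centers_, inertia=inertias)
    for w in wfnc_list:
        model.assignments[w.subject] = assign_windows(model, w)
    return model


def assign_windows(model: StateModel, wfnc: WindowedFNCSeries) -> np.ndarray:
    """Nearest-centroid (Euclidean) state of each window; ties -> lowest state."""
    if wfnc.values.shape[1] != model.centroids.shape[1]:
        raise ValueError(
            f"pair dimension {wfnc.values.shape[1]} does not match centroids "
            f"({model.centroids.shape[1]})"
        )
    if wfnc.n_windows == 0:
        return np.empty(0, dtype=int)
    d = cdist(wfnc.values, model.centroids, metric="sqeuclidean")
    return np.argmin(d, axis=1)  # argmin takes the first (lowest) index on ties


def state_average(
    wfnc: WindowedFNCSeries, assignments: np.ndarray, state: int
) -> np.ndarray | None:
    """Mean pair vector over the subject's windows in ``state``; ``None`` when
    the subject never visits the state (it is then excluded from that
    state's fusion sample)."""
    mask = np.asarray(assignments) == state
    if not mask.any():
        return None
    return wfnc.values[mask].mean(axis=0)


def sa_dfnc_matrices(
    wfnc_list: list[WindowedFNCSeries], model: StateModel
) -> dict[int, pd.DataFrame]:
    """Per-state sa-dFNC matrices (subjects x pairs, only visiting subjects)."""
    out = {}
    for state in range(model.k):
        rows, ids = [], []
        for w in wfnc_list:
            assign = model.assignments.get(w.subject)
            if assign is None:
                assign = assign_windows(model, w)
            sa = state_average(w, assign, state)
            if sa is not None:
                rows.append(sa)
                ids.append(w.subject)
        out[state] = pd.DataFrame(
            np.array(rows) if rows else np.empty((0, model.centroids.shape[1])),
            index=pd.Index(ids, name="subject"),
        )
    return out


def _design_matrix(covariates: pd.DataFrame, names: list[str]) -> pd.DataFrame:
    cols = [pd.Series(1.0, index=covariates.index, name="intercept")]
    for name in names:
        col = covariates[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            cols.extend(dummies[c] for c in dummies)
        else:
            cols.append(col.astype(float))
    return pd.concat(cols, axis=1)


def residualize_features(
    features: pd.DataFrame, covariates: pd.DataFrame, names: list[str]
) -> pd.DataFrame:
    """Per-feature OLS residuals on the named covariates (with intercept).

    Categorical covariates are dummy-coded dropping one level.  Raises on a
    rank-deficient design, listing the collinear columns.
    """
    cov = covariates.loc[features.index, list(names)]
    if cov.isna().any().any():
        missing = cov.columns[cov.isna().any()].tolist()
        raise ValueError(f"covariates contain missing values: {missing}")
    design = _design_matrix(cov, names)
    d = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(d)
    if rank < d.shape[1]:
        _, r = np.linalg.qr(d)
        k = min(r.shape)
        bad = [design.columns[j] for j in range(k) if abs(r[j, j]) < 1e-8]
        bad += list(design.columns[k:])
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    y = features.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(d, y, rcond=None)
    return pd.DataFrame(y - d @ beta, index=features.index, columns=features.columns)


def compute_genotype_pcs(genotypes: pd.DataFrame, n_pcs: int = 4) -> pd.DataFrame:
    """Principal-component scores of the dosage matrix (population structure).

    Columns are standardized (zero-variance SNPs dropped with a warning),
    scores are the top left singular vectors scaled by the singular values.
    Sign convention: the largest-magnitude element of each right singular
    vector is made positive.
    """
    if n_pcs == 0:
        return pd.DataFrame(index=genotypes.index)
    x = genotypes.to_numpy(dtype=float)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        dropped = [genotypes.columns[j] for j in np.flatnonzero(sd == 0)]
        warnings.warn(f"dropping {len(dropped)} zero-variance SNP(s) before PCA", stacklevel=2)
        x = x[:, sd > 0]
        sd = sd[sd > 0]
    if n_pcs >= min(x.shape):
        raise ValueError(f"n_pcs={n_pcs} must be < min(subjects, SNPs)={min(x.shape)}")
    x = (x - x.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    flip = np.sign(vt[np.arange(len(vt)), np.argmax(np.abs(vt), axis=1)])
    u, s = u * flip, s
    scores = u[:, :n_pcs] * s[:n_pcs]
    return pd.DataFrame(
        scores, index=genotypes.index, columns=[f"PC{i + 1}" for i in range(n_pcs)]
    )
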