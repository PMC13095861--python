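"""Joint ICA fusion of a SNP block with one state's sa-dFNC block.

The fusion model is ``X = A S``: the horizontally concatenated, balanced
subjects x (SNP + connectivity) matrix is decomposed into maximally
independent joint source components ``S`` (each row weighting both SNP and
connectivity features) and a shared subject-loading matrix ``A``.  The
decomposition is PCA reduction to the model order followed by Infomax
(natural-gradient maximum-likelihood ICA with a logistic nonlinearity),
which extracts super-Gaussian sources.  The model order is chosen from the
eigenvalue scree of each input matrix (knee = maximum distance to the chord)
pooled by the median, raised if needed to retain a floor fraction of
variance in every connectivity matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kurtosis

logger = logging.getLogger(__name__)

__all__ = [
    "FusionInput",
    "FusionResult",
    "balance_and_concatenate",
    "knee_point",
    "select_model_order",
    "infomax_jica",
    "flag_super_gaussian",
    "match_sources",
    "split_stability",
]


@dataclass
class FusionInput:
    """Balanced, concatenated fusion matrix with its column partition."""

    x: np.ndarray  # subjects x (p1 + p2)
    subjects: list[str]
    snp_cols: list[str]
    dfnc_cols: list[str]

    @property
    def p1(self) -> int:
        return len(self.snp_cols)

    @property
    def p2(self) -> int:
        return len(self.dfnc_cols)


@dataclass
class FusionResult:
    """Joint ICA decomposition ``X ~ A S`` with the SNP | dFNC partition.

    ``loadings`` (A) is subjects x C; ``sources`` (S) is C x (p1 + p2) with
    unit-variance rows, rows ordered by descending explained variance and
    signed to positive skewness.  ``kurtosis`` holds each joint source row's
    excess kurtosis and ``super_gaussian`` the selection flags.
    """

    order: int
    loadings: pd.DataFrame
    sources: pd.DataFrame
    snp_cols: list[str]
    dfnc_cols: list[str]
    kurtosis: np.ndarray
    super_gaussian: np.ndarray
    converged: bool
    n_iter: int
    seed: int
    explained_variance: np.ndarray = field(default=None)

    @property
    def sources_snp(self) -> pd.DataFrame:
        return self.sources[self.snp_cols]

    @property
    def sources_dfnc(self) -> pd.DataFrame:
        return self.sources[self.dfnc_cols]


def balance_and_concatenate(
    x_snp: pd.DataFrame, x_dfnc: pd.DataFrame, balance: bool = True
) -> FusionInput:
    """Z-score features, balance modality scale, concatenate horizontally.

    Subjects are the intersection of the two blocks (in ``x_snp`` order).
    Each feature is z-scored across subjects; zero-variance features are
    dropped (logged).  With ``balance=True`` each block is then rescaled by
    ``1/sqrt(block feature count)`` so both modalities contribute equal
    expected total variance regardless of their feature counts.
    """
    shared = [s for s in x_snp.index if s in set(x_dfnc.index)]
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared subjects between the blocks")
    blocks, kept_cols = [], []
    for block in (x_snp.loc[shared], x_dfnc.loc[shared]):
        v = block.to_numpy(dtype=float)
        sd = v.std(axis=0)
        keep = sd > 0
        if not keep.all():
            dropped = [block.columns[j] for j in np.flatnonzero(~keep)]
            logger.warning("dropping %d zero-variance feature(s): %s", len(dropped), dropped[:10])
        z = (v[:, keep] - v[:, keep].mean(axis=0)) / sd[keep]
        if balance and keep.sum() > 0:
            z = z / np.sqrt(keep.sum())
        blocks.append(z)
        kept_cols.append([block.columns[j] for j in np.flatnonzero(keep)])
    return FusionInput(
        x=np.hstack(blocks),
        subjects=list(shared),
        snp_cols=[str(c) for c in kept_cols[0]],
        dfnc_cols=[str(c) for c in kept_cols[1]],
    )


def _scree(x: np.ndarray) -> np.ndarray:
    """Descending eigenvalues of the feature covariance across subjects."""
    xc = x - x.mean(axis=0)
    s = np.linalg.svd(xc, compute_uv=False)
    return s**2 / (x.shape[0] - 1)


def knee_point(eigvals: np.ndarray) -> int:
    """Knee of a scree curve: the point farthest from the first-last chord.

    The scree is normalized to the unit square before computing perpendicular
    distances.  Returns the number of components at the knee (1-based).
    """
    lam = np.asarray(eigvals, dtype=float)
    m = len(lam)
    if m < 3:
        return m
    x = np.arange(m) / (m - 1)
    y = (lam - lam[-1]) / (lam[0] - lam[-1]) if lam[0] > lam[-1] else np.zeros(m)
    # distance to the chord from (0, y0) to (1, y_last)
    dx, dy = 1.0, y[-1] - y[0]
    dist = np.abs(dy * x - dx * (y - y[0])) / np.hypot(dx, dy)
    return int(np.argmax(dist)) + 1


def select_model_order(
    matrices: list[np.ndarray],
    floor_variance: float = 0.75,
    floor_matrices: list[np.ndarray] | None = None,
    knees: list[int] | None = None,
) -> int:
    """Shared model order: median of per-matrix scree knees, floor-raised.

    For each input matrix the scree knee is estimated (``knees`` may supply
    precomputed estimates instead); the shared order is the median of these,
    raised if necessary to the smallest order whose retained variance is at
    least ``floor_variance`` on every matrix in ``floor_matrices`` (defaults
    to all connectivity inputs = all of ``matrices``).
    """
    if not 0.0 <= floor_variance <= 1.0:
        raise ValueError(f"floor_variance must be in [0, 1], got {floor_variance}")
    screes = {}
    if knees is None:
        if not matrices:
            raise ValueError("need at least one input matrix")
        knees = []
        for m in matrices:
            screes[id(m)] = _scree(np.asarray(m, dtype=float))
            knees.append(knee_point(screes[id(m)]))
    order = int(np.median(knees))
    if floor_variance > 0:
        for m in floor_matrices if floor_matrices is not None else matrices:
            lam = screes.get(id(m))
            if lam is None:
                lam = _scree(np.asarray(m, dtype=float))
            frac = np.cumsum(lam) / lam.sum()
            needed = int(np.searchsorted(frac, floor_variance) + 1)
            order = max(order, needed)
            if order > m.shape[0] - 1:
                raise ValueError(
                    f"floor_variance={floor_variance} needs order {order} > subjects-1"
                )
    return order


def _infomax(y: np.ndarray, seed: int, max_iter: int, tol: float):
    """Natural-gradient Infomax with logistic nonlinearity on whitened rows.

    ``y`` is C x p (rows = whitened mixtures, columns = samples).  Follows
    the standard practice: minibatch natural-gradient updates
    ``W += lr (block*I + (1-2g) u^T) W`` with ``g = logistic(u)``, learning
    rate annealed by 0.9 whenever the angle between successive weight
    updates exceeds 60 degrees, stopping when the weight change drops below
    ``tol``.
    """
    c, p = y.shape
    rng = np.random.default_rng(seed)
    w = np.eye(c)
    bias = np.zeros((c, 1))
    lrate = 0.00065 / max(np.log(c), 1.0)
    block = max(int(np.floor(np.sqrt(p / 3.0))), 8)
    anneal, max_weight = 0.9, 1e8
    old_w = w.copy()
    old_delta = None
    n_iter, converged = 0, False
    for it in range(max_iter):
        n_iter = it + 1
        perm = rng.permutation(p)
        blowup = False
        for start in range(0, p - block + 1, block):
            u = w @ y[:, perm[start : start + block]] + bias
            g = 1.0 / (1.0 + np.exp(-u))
            w = w + lrate * ((block * np.eye(c) + (1.0 - 2.0 * g) @ u.T) @ w)
            bias = bias + lrate * (1.0 - 2.0 * g).sum(axis=1, keepdims=True)
            if not np.isfinite(w).all() or np.abs(w).max() > max_weight:
                blowup = True
                break
        if blowup:
            # restart from identity with a smaller step
            lrate *= 0.5
            w = np.eye(c)
            bias = np.zeros((c, 1))
            old_w = w.copy()
            old_delta = None
            if lrate < 1e-10:
                break
            continue
        delta = w - old_w
        change = float(np.sum(delta**2))
        if old_delta is not None:
            denom = np.linalg.norm(delta) * np.linalg.norm(old_delta)
            if denom > 0:
                cos_angle = float(np.sum(delta * old_delta)) / denom
                if cos_angle < np.cos(np.deg2rad(60.0)):
                    lrate *= anneal
        old_w = w.copy()
        old_delta = delta
        if change < tol:
            converged = True
            break
    return w, bias, converged, n_iter


def infomax_jica(
    fusion_input: FusionInput,
    order: int,
    seed: int = 0,
    max_iter: int = 512,
    tol: float = 1e-6,
    kurtosis_threshold: float = 0.0,
) -> FusionResult:
    """PCA-reduce the fusion matrix to ``order`` and unmix with Infomax.

    The subject dimension is reduced by SVD to ``order`` whitened rows over
    features; Infomax unmixing yields sources ``S`` (standardized rows,
    positive skewness, ordered by descending explained variance) and
    loadings ``A = X S^+``.  ``A S`` equals the rank-``order`` PCA
    reconstruction of the (column-centered) data.
    """
    x = np.asarray(fusion_input.x, dtype=float)
    n, p = x.shape
    if n <= order:
        raise ValueError(f"model order {order} must be < subjects ({n})")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    if s[order - 1] < max(n, p) * np.finfo(float).eps * s[0]:
        raise ValueError(f"rank of the data is below the model order {order}; lower it")
    y = np.sqrt(p) * vt[:order]  # whitened: unit-variance uncorrelated rows

    w, _, converged, n_iter = _infomax(y, seed=seed, max_iter=max_iter, tol=tol)
    if not converged:
        logger.warning("Infomax did not converge in %d iterations", n_iter)

    src = w @ y
    src = src / src.std(axis=1, keepdims=True)
    a, *_ = np.linalg.lstsq(src.T, xc.T, rcond=None)
    a = a.T  # subjects x C; equals Xc @ pinv(src)

    # sign: positive skewness of each source row
    skew = ((src - src.mean(axis=1, keepdims=True)) ** 3).mean(axis=1)
    sign = np.where(skew >= 0, 1.0, -1.0)
    src, a = src * sign[:, None], a * sign[None, :]

    # order by descending explained variance (||a_c||^2 since rows unit var)
    ev = (a**2).sum(axis=0)
    idx = np.argsort(ev)[::-1]
    src, a, ev = src[idx], a[:, idx], ev[idx]

    cols = fusion_input.snp_cols + fusion_input.dfnc_cols
    comp_idx = pd.RangeIndex(order, name="component")
    kurt = kurtosis(src, axis=1, fisher=True, bias=True)
    return FusionResult(
        order=order,
        loadings=pd.DataFrame(a, index=pd.Index(fusion_input.subjects, name="subject"), columns=comp_idx),
        sources=pd.DataFrame(src, index=comp_idx, columns=cols),
        snp_cols=fusion_input.snp_cols,
        dfnc_cols=fusion_input.dfnc_cols,
        kurtosis=kurt,
        super_gaussian=kurt > kurtosis_threshold,
        converged=converged,
        n_iter=n_iter,
        seed=seed,
        explained_variance=ev,
    )


def flag_super_gaussian(result: FusionResult, kurtosis_threshold: float = 0.0) -> np.ndarray:
    """Re-flag components whose joint source row has excess kurtosis above
    ``kurtosis_threshold`` (updates the result in place and returns flags)."""
    result.kurtosis = kurtosis(result.sources.to_numpy(), axis=1, fisher=True, bias=True)
    result.super_gaussian = result.kurtosis > kurtosis_threshold
    return result.super_gaussian


def match_sources(
    s_ref: np.ndarray, s_other: np.ndarray, greedy: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Match rows of ``s_other`` to rows of ``s_ref`` by max ``|r|``.

    With ``greedy=True`` matching is without replacement (each component used
    once), in descending order of achievable correlation.  Returns
    ``(indices, abs_r)`` aligned to the rows of ``s_ref``.
    """
    r = np.abs(_rowcorr(np.asarray(s_ref, float), np.asarray(s_other, float)))
    k = r.shape[0]
    if not greedy:
        return np.argmax(r, axis=1), np.max(r, axis=1)
    idx = np.full(k, -1, dtype=int)
    vals = np.zeros(k)
    r_work = r.copy()
    for _ in range(min(k, r.shape[1])):
        i, j = np.unravel_index(np.argmax(r_work), r_work.shape)
        idx[i], vals[i] = j, r[i, j]
        r_work[i, :] = -1.0
        r_work[:, j] = -1.0
    return idx, vals


def _rowcorr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of ``a`` and every row of ``b``."""
    az = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
    bz = (b - b.mean(axis=1, keepdims=True)) / b.std(axis=1, keepdims=True)
    return az @ bz.T / a.shape[1]


def split_stability(
    fusion_input: FusionInput,
    order: int,
    n_folds: int = 3,
    seed: int = 0,
    max_iter: int = 512,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Split-sample stability of the fusion components.

    Subjects are randomly partitioned into ``n_folds`` subsets; the fusion
    is rerun on each subset and its components are matched (greedy, without
    replacement, by max absolute source correlation) to the full-sample
    components.  Returns a table with one row per (component, fold) holding
    the matched ``|r|``; aggregate with ``groupby('component')`` or report
    the overall mean and SD.
    """
    n = len(fusion_input.subjects)
    if n // n_folds <= order:
        raise ValueError(
            f"folds of ~{n // n_folds} subjects are too small for model order {order}"
        )
    full = infomax_jica(fusion_input, order, seed=seed, max_iter=max_iter, tol=tol)
    s_full = full.sources.to_numpy()
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    rows = []
    for fold, part in enumerate(np.array_split(perm, n_folds)):
        sub_input = FusionInput(
            x=fusion_input.x[np.sort(part)],
            subjects=[fusion_input.subjects[i] for i in np.sort(part)],
            snp_cols=fusion_input.snp_cols,
            dfnc_cols=fusion_input.dfnc_cols,
        )
        res = infomax_jica(sub_input, order, seed=seed + fold + 1, max_iter=max_iter, tol=tol)
        if n_folds == 1:
            res = full
        idx, vals = match_sources(s_full, res.sources.to_numpy())
        for comp in range(order):
            rows.append(
                {"component": comp, "fold": fold, "matched_component": int(idx[comp]), "abs_r": vals[comp]}
            )
    return pd.DataFrame(rows)
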