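"""Time-course post-processing and tapered sliding-window FNC estimation.

The dynamic functional network connectivity (dFNC) front end: per-subject ICN
time courses are detrended, despiked, optionally motion-regressed, band-pass
filtered, and re-standardized; windowed FNC is then computed on a tapered
sliding window (a rectangular window convolved with a Gaussian kernel), with
each window's covariance estimated from an L1-regularized precision matrix
(graphical lasso) and converted to Fisher-z correlations over ICN pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from sklearn.covariance import graphical_lasso

from .pairs import mat_to_vec, n_pairs

__all__ = [
    "TimecourseSet",
    "WindowedFNCSeries",
    "postprocess_timecourses",
    "make_taper",
    "windowed_fnc",
]

#: correlations are capped at this magnitude before the Fisher transform so
#: that atanh stays finite
R_CAP = 1.0 - 1e-6


@dataclass
class TimecourseSet:
    """ICN time courses of one subject: ``data`` is time x n_icns."""

    subject: str
    data: np.ndarray
    tr_seconds: float

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_icns(self) -> int:
        return self.data.shape[1]


@dataclass
class WindowedFNCSeries:
    """Sequence of windowed FNC pair vectors (Fisher z) of one subject.

    ``values`` is n_windows x n_pairs; ``window_starts`` holds the 0-based
    first sample index of each retained window; ``failed_windows`` records
    window starts where the precision estimate did not converge (dropped).
    """

    subject: str
    values: np.ndarray
    window_starts: np.ndarray
    n_icns: int
    failed_windows: list = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.values.shape[1]


def _mad(x: np.ndarray, axis=0):
    med = np.median(x, axis=axis, keepdims=True)
    return med, np.median(np.abs(x - med), axis=axis, keepdims=True)


def postprocess_timecourses(
    tc: TimecourseSet,
    motion: np.ndarray | None = None,
    band: tuple[float, float] = (0.01, 0.15),
    despike_mads: float = 4.0,
    filter_order: int = 5,
) -> TimecourseSet:
    """Detrend, despike, motion-regress, band-pass and standardize time courses.

    Steps, in order: per-ICN linear detrend; despiking by clipping samples
    beyond ``median +/- despike_mads * MAD`` to that boundary; optional
    regression of the motion columns (realignment parameters and their
    derivatives) when ``motion`` is given; zero-phase Butterworth band-pass
    of order ``filter_order`` applied forward and backward; re-standardization
    of each column to unit variance.
    """
    low, high = band
    nyquist = 0.5 / tc.tr_seconds
    if not (0.0 < low < high < nyquist):
        raise ValueError(
            f"band {band} invalid: need 0 < low < high < Nyquist ({nyquist:.4f} Hz)"
        )
    x = np.asarray(tc.data, dtype=float)
    x = signal.detrend(x, axis=0, type="linear")

    med, mad = _mad(x, axis=0)
    lo, hi = med - despike_mads * mad, med + despike_mads * mad
    x = np.clip(x, lo, hi)

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        design = np.column_stack([np.ones(len(x)), motion])
        beta, *_ = np.linalg.lstsq(design, x, rcond=None)
        x = x - design @ beta

    sos = signal.butter(
        filter_order, [low, high], btype="bandpass", fs=1.0 / tc.tr_seconds, output="sos"
    )
    x = signal.sosfiltfilt(sos, x, axis=0)

    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"constant time course after filtering for ICN index(es) {bad.tolist()}")
    x = (x - x.mean(axis=0)) / sd
    return TimecourseSet(subject=tc.subject, data=x, tr_seconds=tc.tr_seconds)


def make_taper(window_trs: int, sigma_trs: float = 3.0) -> np.ndarray:
    """Tapered sliding-window weights: rectangle convolved with a Gaussian.

    A rectangular window of ``window_trs`` ones is convolved with a Gaussian
    kernel of width ``sigma_trs`` (support +/- 3 sigma, in TR units); the
    result is normalized to sum 1.  The support length is
    ``window_trs + 2*ceil(3*sigma_trs)``; weights are symmetric and strictly
    positive.  ``sigma_trs`` close to 0 recovers the plain rectangle.
    """
    if window_trs < 4:
        raise ValueError(f"window_trs must be >= 4, got {window_trs}")
    if sigma_trs < 0:
        raise ValueError("sigma_trs must be >= 0")
    half = int(np.ceil(3.0 * sigma_trs))
    if half == 0 or sigma_trs == 0:
        kernel = np.ones(1)
    else:
        t = np.arange(-half, half + 1, dtype=float)
        kernel = np.exp(-0.5 * (t / sigma_trs) ** 2)
    w = np.convolve(np.ones(window_trs), kernel, mode="full")
    return w / w.sum()


def _weighted_corr(seg: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Taper-weighted sample correlation of one window (weights sum to 1)."""
    mu = w @ seg
    segc = seg - mu
    cov = (segc * w[:, None]).T @ segc / (1.0 - np.sum(w**2))
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def windowed_fnc(
    tc: TimecourseSet,
    taper: np.ndarray,
    stride: int = 1,
    glasso_lambda: float | str = 0.1,
    glasso_tol: float = 5e-3,
    glasso_max_iter: int = 50,
) -> WindowedFNCSeries:
    """Tapered sliding-window FNC from regularized precision matrices.

    For each window position (half-open sample range ``[t, t + support)``,
    advanced by ``stride`` TRs) the taper-weighted sample correlation is
    computed, the graphical lasso with penalty ``glasso_lambda`` (diagonal
    unpenalized) estimates a sparse precision matrix, whose implied
    covariance is converted back to correlation, capped at ``|r| <= 1-1e-6``
    and Fisher r-to-z transformed over the strict upper triangle.

    Windows where the graphical lasso fails to converge are dropped and
    recorded in ``failed_windows``; a warning is emitted when at least 1% of
    windows fail.

    ``glasso_lambda="cv"`` selects the penalty once per subject by
    cross-validation on the full (unwindowed) time courses; the default is
    the fixed penalty 0.1.
    """
    x = np.asarray(tc.data, dtype=float)
    if glasso_lambda == "cv":
        from sklearn.covariance import GraphicalLassoCV

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glasso_lambda = float(GraphicalLassoCV(tol=glasso_tol).fit(x).alpha_)
        glasso_lambda = max(glasso_lambda, 1e-6)
    elif not isinstance(glasso_lambda, (int, float)) or glasso_lambda <= 0:
        raise ValueError("glasso_lambda must be > 0 or 'cv'")
    support = len(taper)
    if tc.n_timepoints < support:
        raise ValueError(
            f"time length {tc.n_timepoints} shorter than taper support {support}"
        )
    w = np.asarray(taper, dtype=float)
    w = w / w.sum()

    starts, rows, failed = [], [], []
    for t in range(0, tc.n_timepoints - support + 1, stride):
        corr = _weighted_corr(x[t : t + support], w)
        with warnings.catch_warnings():
            # slow convergence still yields a usable estimate; only hard
            # failures drop the window
            warnings.simplefilter("ignore")
            try:
                cov_reg, _ = graphical_lasso(
                    corr, alpha=glasso_lambda, tol=glasso_tol, max_iter=glasso_max_iter
                )
            except Exception:  # noqa: BLE001 - retried with shrinkage below
                # degenerate windows (near-singular correlation) get a tiny
                # shrinkage toward the identity before giving up
                shrunk = (1.0 - 1e-4) * corr + 1e-4 * np.eye(corr.shape[0])
                try:
                    cov_reg, _ = graphical_lasso(
                        shrunk, alpha=glasso_lambda, tol=glasso_tol, max_iter=glasso_max_iter
                    )
                except Exception as exc:  # noqa: BLE001 - per-subject report
                    failed.append((t, str(exc)))
                    continue
        d = np.sqrt(np.diag(cov_reg))
        r = cov_reg / np.outer(d, d)
        r = np.clip(mat_to_vec(r), -R_CAP, R_CAP)
        rows.append(np.arctanh(r))
        starts.append(t)

    n_total = len(starts) + len(failed)
    if failed and len(failed) >= 0.01 * n_total:
        warnings.warn(
            f"subject {tc.subject}: {len(failed)}/{n_total} windows dropped "
            "(graphical lasso non-convergence)",
            stacklevel=2,
        )
    values = (
        np.array(rows) if rows else np.empty((0, n_pairs(tc.n_icns)))
    )
    return WindowedFNCSeries(
        subject=tc.subject,
        values=values,
        window_starts=np.asarray(starts, dtype=int),
        n_icns=tc.n_icns,
        failed_windows=failed,
    )
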