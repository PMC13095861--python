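"""Upper-triangle pair indexing for connectivity vectors.

Connectivity between ``n`` intrinsic connectivity networks (ICNs) is stored as
a flat vector over the ``n*(n-1)/2`` unordered pairs ``(i, j)`` with ``i < j``,
ordered row-major over the strict upper triangle: ``(0,1), (0,2), ...,
(0,n-1), (1,2), ...``.  This matches :func:`numpy.triu_indices` with ``k=1``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "n_pairs",
    "pair_rank",
    "pair_unrank",
    "mat_to_vec",
    "vec_to_mat",
    "pair_legend",
]


def n_pairs(n_icns: int) -> int:
    """Number of unordered ICN pairs for ``n_icns`` networks."""
    return n_icns * (n_icns - 1) // 2


def pair_rank(i: int, j: int, n_icns: int) -> int:
    """Flat index of pair ``(i, j)``, requiring ``0 <= i < j < n_icns``."""
    if not (0 <= i < j < n_icns):
        raise ValueError(f"need 0 <= i < j < n_icns, got ({i}, {j}) with n_icns={n_icns}")
    return i * (2 * n_icns - i - 1) // 2 + (j - i - 1)


def pair_unrank(r: int, n_icns: int) -> tuple[int, int]:
    """Inverse of :func:`pair_rank`."""
    if not (0 <= r < n_pairs(n_icns)):
        raise ValueError(f"rank {r} out of range for n_icns={n_icns}")
    i = 0
    # row i holds (n_icns - 1 - i) pairs
    while r >= n_icns - 1 - i:
        r -= n_icns - 1 - i
        i += 1
    return i, i + 1 + r


def mat_to_vec(mat: np.ndarray) -> np.ndarray:
    """Strict upper triangle of a square matrix as a pair vector."""
    mat = np.asarray(mat)
    n = mat.shape[0]
    iu = np.triu_indices(n, k=1)
    return mat[iu]


def vec_to_mat(vec: np.ndarray, n_icns: int, diag: float = 1.0) -> np.ndarray:
    """Symmetric matrix from a pair vector, with ``diag`` on the diagonal."""
    vec = np.asarray(vec)
    if vec.shape[-1] != n_pairs(n_icns):
        raise ValueError(
            f"vector length {vec.shape[-1]} does not match n_pairs({n_icns})={n_pairs(n_icns)}"
        )
    mat = np.full((n_icns, n_icns), 0.0)
    iu = np.triu_indices(n_icns, k=1)
    mat[iu] = vec
    mat = mat + mat.T
    np.fill_diagonal(mat, diag)
    return mat


def pair_legend(labels: pd.DataFrame) -> pd.DataFrame:
    """Pair-index legend from an ICN label table.

    Parameters
    ----------
    labels : DataFrame with columns ``icn`` (0-based index), ``label``,
        ``domain``, one row per ICN, sorted by ``icn``.

    Returns
    -------
    DataFrame with one row per pair in rank order: ``pair``, ``icn_i``,
    ``icn_j``, ``label_i``, ``label_j``, ``domain_i``, ``domain_j``.
    """
    labels = labels.sort_values("icn").reset_index(drop=True)
    n = len(labels)
    rows = []
    for r in range(n_pairs(n)):
        i, j = pair_unrank(r, n)
        rows.append(
            {
                "pair": r,
                "icn_i": i,
                "icn_j": j,
                "label_i": labels.loc[i, "label"],
                "label_j": labels.loc[j, "label"],
                "domain_i": labels.loc[i, "domain"],
                "domain_j": labels.loc[j, "domain"],
            }
        )
    return pd.DataFrame(rows)
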