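"""Across-state similarity of joint components from the parallel fusions.

Each state-specific fusion yields components over the same SNP and
connectivity feature spaces.  For every component, its most similar SNP and
dFNC elements are identified in each of the other fusions by the absolute
Pearson correlation of the corresponding source sub-vectors; averaging the
best matches over the other fusions gives the across-state similarity per
modality, which places each component on a state-invariant (recurring) to
state-variant (fusion-specific) axis.

Matching is directional and with replacement: a component of fusion B may be
the best counterpart of several components of fusion A, and best-match
symmetry is not assumed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fusion import FusionResult, _rowcorr

__all__ = ["match_components", "classify_variability", "sorted_similarity_curves"]


def match_components(results: dict[int, FusionResult], bijective: bool = False) -> pd.DataFrame:
    """Cross-fusion component match table.

    For each component of each fusion and each other fusion, records the
    best-|r| counterpart per modality (SNP and dFNC source sub-vectors,
    ties -> lowest index) and the combined-best counterpart (mean of the two
    modality similarities).  Adds per-modality across-state similarity
    (mean of the best |r| over the other fusions) and the single overall
    best counterpart chosen by combined similarity.

    With ``bijective=True`` the per-fusion counterpart assignment is greedy
    without replacement on the combined similarity (each component of the
    other fusion used at most once) — intended for stability testing only;
    the default directional matching is the reporting convention.

    Returns a DataFrame keyed by (state, component) with columns
    ``snp_similarity``, ``dfnc_similarity`` (across-state means),
    ``state_similar``, ``comp_similar``, ``snp_r_best``, ``dfnc_r_best``
    (the overall best counterpart and its modality similarities).
    """
    states = sorted(results)
    if len(states) < 2:
        raise ValueError("need at least two fusions to compare")
    ref = results[states[0]]
    for s in states[1:]:
        if results[s].snp_cols != ref.snp_cols or results[s].dfnc_cols != ref.dfnc_cols:
            a = set(results[s].snp_cols + results[s].dfnc_cols)
            b = set(ref.snp_cols + ref.dfnc_cols)
            raise ValueError(f"feature spaces differ between fusions: {sorted(a ^ b)[:10]}")

    rows = []
    for sa in states:
        ra = results[sa]
        snp_a = ra.sources_snp.to_numpy()
        dfnc_a = ra.sources_dfnc.to_numpy()
        per_other = {}
        for sb in states:
            if sb == sa:
                continue
            rb = results[sb]
            r_snp = np.abs(_rowcorr(snp_a, rb.sources_snp.to_numpy()))
            r_dfnc = np.abs(_rowcorr(dfnc_a, rb.sources_dfnc.to_numpy()))
            assign = None
            if bijective:
                comb_matrix = 0.5 * (r_snp + r_dfnc)
                assign = np.full(ra.order, -1, dtype=int)
                work = comb_matrix.copy()
                for _ in range(min(work.shape)):
                    i, j = np.unravel_index(np.argmax(work), work.shape)
                    assign[i] = j
                    work[i, :] = -1.0
                    work[:, j] = -1.0
            per_other[sb] = (r_snp, r_dfnc, assign)
        for comp in range(ra.order):
            best_snp, best_dfnc, best_comb = [], [], []
            for sb, (r_snp, r_dfnc, assign) in per_other.items():
                comb = 0.5 * (r_snp[comp] + r_dfnc[comp])
                if assign is not None:
                    j_snp = j_dfnc = j_comb = int(assign[comp])
                else:
                    j_snp = int(np.argmax(r_snp[comp]))
                    j_dfnc = int(np.argmax(r_dfnc[comp]))
                    j_comb = int(np.argmax(comb))
                best_snp.append(r_snp[comp, j_snp])
                best_dfnc.append(r_dfnc[comp, j_dfnc])
                best_comb.append(
                    (comb[j_comb], sb, j_comb, r_snp[comp, j_comb], r_dfnc[comp, j_comb])
                )
            top = max(best_comb, key=lambda t: t[0])
            rows.append(
                {
                    "state": sa,
                    "component": comp,
                    "snp_similarity": float(np.mean(best_snp)),
                    "dfnc_similarity": float(np.mean(best_dfnc)),
                    "state_similar": top[1],
                    "comp_similar": top[2],
                    "snp_r_best": top[3],
                    "dfnc_r_best": top[4],
                }
            )
    return pd.DataFrame(rows).set_index(["state", "component"])


def classify_variability(
    table: pd.DataFrame,
    invariant_cutoff: float = 0.85,
    variant_cutoff: float = 0.40,
) -> pd.DataFrame:
    """Label components per modality on the invariant/variant axis.

    A modality's element is "invariant" when its across-state similarity is
    at least ``invariant_cutoff``, "variant" when at most ``variant_cutoff``,
    else "intermediate".  Cutoffs are reporting conveniences and are echoed
    in the output columns.
    """
    if not (0.0 <= variant_cutoff < invariant_cutoff <= 1.0):
        raise ValueError("need 0 <= variant_cutoff < invariant_cutoff <= 1")

    def lab(x):
        if x >= invariant_cutoff:
            return "invariant"
        if x <= variant_cutoff:
            return "variant"
        return "intermediate"

    out = table.copy()
    out["snp_class"] = out["snp_similarity"].map(lab)
    out["dfnc_class"] = out["dfnc_similarity"].map(lab)
    out.attrs["invariant_cutoff"] = invariant_cutoff
    out.attrs["variant_cutoff"] = variant_cutoff
    return out


def sorted_similarity_curves(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-state similarity values sorted descending, for plotting.

    Returns one DataFrame per modality with a ``rank`` index and one column
    per state.
    """
    curves = {}
    for modality in ("snp", "dfnc"):
        cols = {}
        for state, sub in table.groupby(level="state"):
            vals = np.sort(sub[f"{modality}_similarity"].to_numpy())[::-1]
            cols[f"state{state}"] = vals
        curves[modality] = pd.DataFrame(cols).rename_axis("rank")
    return curves
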