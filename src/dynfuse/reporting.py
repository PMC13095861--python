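"""Top-feature extraction, domain-level summaries, and tabular reports.

Significant joint components are interpreted through their heavily weighted
features: each modality's source sub-vector is z-scored within its block and
features beyond ``|z| > 3`` (by default) are retained as the component's top
SNPs and connectivity pairs.  Connectivity pairs are annotated with ICN
labels and functional domains, SNPs with genes from a user-supplied map;
domain-level aggregation and hub-ICN identification summarize the
connectivity pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fusion import FusionResult
from .pairs import pair_unrank

__all__ = [
    "TopFeatureSet",
    "top_features",
    "overlap_ratio",
    "domain_summary",
    "render_reports",
]


@dataclass
class TopFeatureSet:
    """Top-weighted features of one component at a given |z| threshold."""

    state: int
    component: int
    snps: pd.DataFrame  # columns: z, gene (gene may be empty)
    pairs: pd.DataFrame  # columns: icn_i, icn_j, label_i, label_j, domain_i, domain_j, z
    threshold: float


def _block_z(values: np.ndarray) -> np.ndarray | None:
    sd = values.std()
    if sd == 0:
        return None
    return (values - values.mean()) / sd


def top_features(
    result: FusionResult,
    component: int,
    z_threshold: float = 3.0,
    legend: pd.DataFrame | None = None,
    annotation: pd.DataFrame | None = None,
    state: int = -1,
) -> TopFeatureSet:
    """Features beyond ``|z| > z_threshold``, z-scored within each modality.

    ``legend`` is the ICN label table (columns ``icn``, ``label``,
    ``domain``) and is required to annotate connectivity pairs; ``annotation``
    is the optional SNP -> gene map (index snp id, column ``gene``).  A
    constant source sub-vector yields an empty set with a warning.
    """
    if not 0 <= component < result.order:
        raise ValueError(f"component {component} out of range [0, {result.order})")
    if legend is None:
        raise ValueError("an ICN label legend is required to annotate pairs")
    n_icns = len(legend)
    labels = legend.sort_values("icn").reset_index(drop=True)

    snp_vals = result.sources_snp.iloc[component].to_numpy()
    dfnc_vals = result.sources_dfnc.iloc[component].to_numpy()

    out_snps = pd.DataFrame(columns=["z", "gene"])
    z = _block_z(snp_vals)
    if z is None:
        warnings.warn("constant SNP source sub-vector; returning no top SNPs", stacklevel=2)
    else:
        keep = np.abs(z) > z_threshold
        ids = [result.snp_cols[j] for j in np.flatnonzero(keep)]
        out_snps = pd.DataFrame({"z": z[keep]}, index=pd.Index(ids, name="snp"))
        if annotation is not None:
            out_snps["gene"] = [
                annotation["gene"].get(s, "") if s in annotation.index else ""
                for s in out_snps.index
            ]
        else:
            warnings.warn("no SNP annotation map supplied; gene column left empty", stacklevel=2)
            out_snps["gene"] = ""

    out_pairs = pd.DataFrame(
        columns=["icn_i", "icn_j", "label_i", "label_j", "domain_i", "domain_j", "z"]
    )
    z = _block_z(dfnc_vals)
    if z is None:
        warnings.warn("constant dFNC source sub-vector; returning no top pairs", stacklevel=2)
    else:
        rows = []
        for r in np.flatnonzero(np.abs(z) > z_threshold):
            i, j = pair_unrank(int(r), n_icns)
            rows.append(
                {
                    "pair": int(r),
                    "icn_i": i,
                    "icn_j": j,
                    "label_i": labels.loc[i, "label"],
                    "label_j": labels.loc[j, "label"],
                    "domain_i": labels.loc[i, "domain"],
                    "domain_j": labels.loc[j, "domain"],
                    "z": z[r],
                }
            )
        if rows:
            out_pairs = pd.DataFrame(rows).set_index("pair")
    return TopFeatureSet(
        state=state, component=component, snps=out_snps, pairs=out_pairs, threshold=z_threshold
    )


def overlap_ratio(set_a, set_b, method: str = "jaccard") -> float | None:
    """Overlap of two feature/gene sets as a percentage.

    ``jaccard`` (default) is ``|A & B| / |A | B|``; ``overlap`` is the
    overlap coefficient ``|A & B| / min(|A|, |B|)``.  Both sets empty ->
    undefined, returned as ``None``.
    """
    a, b = set(set_a), set(set_b)
    if not a and not b:
        return None
    if method == "jaccard":
        denom = len(a | b)
    elif method == "overlap":
        denom = min(len(a), len(b))
        if denom == 0:
            return None
    else:
        raise ValueError(f"unknown method {method!r}")
    return 100.0 * len(a & b) / denom


def domain_summary(
    pairs: pd.DataFrame, hub_fraction: float = 0.5
) -> tuple[pd.DataFrame, list]:
    """Aggregate retained pairs into domain x domain counts split by sign.

    Returns ``(table, hubs)``: the table has one row per (domain_i,
    domain_j, sign) with the pair count (domains ordered alphabetically
    within a pair so the summary is upper-triangular); hubs are ICN indices
    participating in at least ``hub_fraction`` of the retained pairs.
    """
    if pairs.empty:
        return (
            pd.DataFrame(columns=["domain_a", "domain_b", "sign", "count"]),
            [],
        )
    if pairs[["domain_i", "domain_j"]].isna().any().any():
        bad = pairs.index[pairs[["domain_i", "domain_j"]].isna().any(axis=1)]
        raise ValueError(f"unlabeled ICN domain for pairs {bad.tolist()}")
    rec = pairs.copy()
    dom = np.sort(rec[["domain_i", "domain_j"]].to_numpy(), axis=1)
    rec["domain_a"], rec["domain_b"] = dom[:, 0], dom[:, 1]
    rec["sign"] = np.where(rec["z"] >= 0, "+", "-")
    table = (
        rec.groupby(["domain_a", "domain_b", "sign"]).size().rename("count").reset_index()
    )
    counts = pd.concat([rec["icn_i"], rec["icn_j"]]).value_counts()
    hubs = sorted(counts.index[counts >= hub_fraction * len(rec)].tolist())
    return table, hubs


def render_reports(
    outdir: str | Path,
    feature_sets: list[TopFeatureSet],
    similarity_curves: dict[str, pd.DataFrame] | None = None,
    annotation: pd.DataFrame | None = None,
    summary: dict | None = None,
    plot: bool = False,
) -> list[Path]:
    """Write the tabular reports of a run.

    Produces a Manhattan-style SNP table (ordered by chromosome/position
    from the annotation map, unmapped SNPs last), a connectogram edge list,
    the sorted across-state similarity curves, and a key-value run summary.
    Optional rendering of simple plots behind ``plot=True`` (requires
    matplotlib).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    snp_frames, edge_frames = [], []
    for fs in feature_sets:
        if not fs.snps.empty:
            t = fs.snps.reset_index()
            t.insert(0, "component", fs.component)
            t.insert(0, "state", fs.state)
            snp_frames.append(t)
        if not fs.pairs.empty:
            t = fs.pairs.reset_index()
            t.insert(0, "component", fs.component)
            t.insert(0, "state", fs.state)
            edge_frames.append(t)

    manhattan = (
        pd.concat(snp_frames, ignore_index=True)
        if snp_frames
        else pd.DataFrame(columns=["state", "component", "snp", "z", "gene"])
    )
    if annotation is not None and not manhattan.empty:
        manhattan = manhattan.join(annotation[["chrom", "pos"]], on="snp")
        manhattan = manhattan.sort_values(
            ["chrom", "pos"], na_position="last", kind="stable"
        )
    path = outdir / "manhattan.tsv"
    manhattan.to_csv(path, sep="\t", index=False)
    written.append(path)

    edges = (
        pd.concat(edge_frames, ignore_index=True)
        if edge_frames
        else pd.DataFrame(
            columns=["state", "component", "pair", "icn_i", "icn_j", "label_i",
                     "label_j", "domain_i", "domain_j", "z"]
        )
    )
    path = outdir / "connectogram_edges.tsv"
    edges.to_csv(path, sep="\t", index=False)
    written.append(path)

    if similarity_curves:
        for modality, curve in similarity_curves.items():
            path = outdir / f"similarity_sorted_{modality}.tsv"
            curve.to_csv(path, sep="\t")
            written.append(path)

    lines = {"n_components_reported": len(feature_sets)}
    if not feature_sets:
        lines["banner"] = "0 components"
    if summary:
        lines.update(summary)
    path = outdir / "run_summary.txt"
    path.write_text("".join(f"{k}\t{v}\n" for k, v in lines.items()))
    written.append(path)

    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if similarity_curves:
            fig, axes = plt.subplots(1, len(similarity_curves), figsize=(10, 4))
            for ax, (modality, curve) in zip(np.atleast_1d(axes), similarity_curves.items()):
                curve.plot(ax=ax, legend=True)
                ax.set_title(f"{modality} across-state similarity")
                ax.set_xlabel("sorted component rank")
            fig.tight_layout()
            p = outdir / "similarity_curves.png"
            fig.savefig(p, dpi=100)
            plt.close(fig)
            written.append(p)
    return written
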