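"""File-based pipeline stages gluing the library into a runnable tool.

Each stage reads its inputs from a working directory, runs the corresponding
library operations and writes its outputs back, so the whole analysis can be
driven stage-by-stage (or end-to-end via :func:`run_all`) from a single
nested configuration dictionary.  The CLI in :mod:`dynfuse.cli` is a thin
wrapper over these functions.

Directory layout under the working directory::

    fixture/           synthetic input bundle (or user-supplied data laid
                       out the same way)
    wfnc.npz           windowed FNC per subject (values + window starts)
    pair_legend.tsv    pair index -> ICN labels/domains
    states/            centroids, assignments, per-state sa-dFNC tables
    fusion/            per-state loadings/sources/metadata
    similarity.tsv     cross-state component match table
    validation/        projected loadings, group tests, associations
    report/            top features, edge lists, summaries
"""

from __future__ import annotations

import copy
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fusion as fus
from . import reporting as rep
from . import similarity as sim
from . import states as st
from . import synthetic as syn
from . import validation as val
from .dfnc import TimecourseSet, WindowedFNCSeries, make_taper, postprocess_timecourses, windowed_fnc
from .pairs import pair_legend

DEFAULT_CONFIG: dict = {
    "design": {},  # SyntheticDesign keyword overrides
    "dfnc": {
        "window_trs": 20,
        "sigma_trs": 3.0,
        "stride": 1,
        "glasso_lambda": 0.1,
        "band": [0.01, 0.15],
    },
    "states": {"k_min": 2, "k_max": 8, "replicates": 10, "seed": 0},
    "fusion": {
        "order": "auto",
        "floor_variance": 0.75,
        "seed": 0,
        "kurtosis_threshold": 0.0,
        "balance": True,
        "n_genotype_pcs": 4,
    },
    "similarity": {"invariant_cutoff": 0.85, "variant_cutoff": 0.40},
    "validation": {"alpha": 0.05},
    "report": {"z_threshold": 3.0, "hub_fraction": 0.5},
}


def load_config(path: str | Path | None) -> dict:
    """Merge a YAML config file over the defaults (missing keys filled in)."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for section, values in user.items():
            cfg.setdefault(section, {}).update(values or {})
    return cfg


# ---------------------------------------------------------------- simulate


def stage_simulate(cfg: dict, workdir: str | Path) -> Path:
    """Generate the synthetic fixture bundle under ``workdir/fixture``."""
    design = syn.SyntheticDesign(**cfg.get("design", {}))
    truth = syn.make_ground_truth(design)
    fixture = Path(workdir) / "fixture"
    syn.write_fixture_bundle(design, truth, fixture)
    return fixture


def _read_timecourses(fixture: Path) -> list[TimecourseSet]:
    tr = float(np.load(fixture / "ground_truth.npz")["tr_seconds"]) if (
        fixture / "ground_truth.npz"
    ).exists() else 0.735
    tcs = []
    for f in sorted((fixture / "tc").glob("*.tsv")):
        data = pd.read_csv(f, sep="\t").to_numpy(dtype=float)
        tcs.append(TimecourseSet(subject=f.stem, data=data, tr_seconds=tr))
    return tcs


# ---------------------------------------------------------------- dfnc


def stage_dfnc(cfg: dict, workdir: str | Path) -> Path:
    """Post-process time courses and compute windowed FNC for all subjects."""
    workdir = Path(workdir)
    fixture = workdir / "fixture"
    c = cfg["dfnc"]
    taper = make_taper(int(c["window_trs"]), float(c["sigma_trs"]))
    arrays = {}
    for tc in _read_timecourses(fixture):
        post = postprocess_timecourses(tc, band=tuple(c["band"]))
        w = windowed_fnc(
            post, taper, stride=int(c["stride"]), glasso_lambda=float(c["glasso_lambda"])
        )
        arrays[f"values_{tc.subject}"] = w.values
        arrays[f"starts_{tc.subject}"] = w.window_starts
    out = workdir / "wfnc.npz"
    np.savez(out, **arrays)

    labels = pd.read_csv(fixture / "icn_labels.tsv", sep="\t")
    pair_legend(labels).to_csv(workdir / "pair_legend.tsv", sep="\t", index=False)
    return out


def _load_wfnc(workdir: Path) -> list[WindowedFNCSeries]:
    data = np.load(workdir / "wfnc.npz")
    subjects = sorted(k[len("values_") :] for k in data.files if k.startswith("values_"))
    n_pairs_ = data[f"values_{subjects[0]}"].shape[1]
    n_icns = int((1 + np.sqrt(1 + 8 * n_pairs_)) / 2)
    return [
        WindowedFNCSeries(
            subject=s,
            values=data[f"values_{s}"],
            window_starts=data[f"starts_{s}"],
            n_icns=n_icns,
        )
        for s in subjects
    ]


# ---------------------------------------------------------------- states


def stage_states(cfg: dict, workdir: str | Path) -> st.StateModel:
    """Fit the K-means state model and write centroids / sa-dFNC tables."""
    workdir = Path(workdir)
    c = cfg["states"]
    wfnc_list = _load_wfnc(workdir)
    model = st.fit_states(
        wfnc_list,
        k_range=range(int(c["k_min"]), int(c["k_max"]) + 1),
        replicates=int(c["replicates"]),
        seed=int(c["seed"]),
    )
    sdir = workdir / "states"
    sdir.mkdir(exist_ok=True)
    pd.DataFrame(model.centroids).rename_axis("state").to_csv(
        sdir / "centroids.tsv", sep="\t"
    )
    pd.Series(model.inertia).rename_axis("k").rename("inertia").to_csv(
        sdir / "inertia.tsv", sep="\t"
    )
    np.savez(sdir / "assignments.npz", **model.assignments)
    for state, sa in st.sa_dfnc_matrices(wfnc_list, model).items():
        sa.to_csv(sdir / f"sa_dfnc_state{state}.tsv", sep="\t")
    return model


def _load_sa_dfnc(workdir: Path) -> dict[int, pd.DataFrame]:
    out = {}
    for f in sorted((Path(workdir) / "states").glob("sa_dfnc_state*.tsv")):
        state = int(f.stem.replace("sa_dfnc_state", ""))
        out[state] = pd.read_csv(f, sep="\t", index_col="subject")
    return out


# ---------------------------------------------------------------- fusion


def _residualized_blocks(cfg: dict, workdir: Path):
    """SNP and per-state dFNC blocks after nuisance residualization."""
    fixture = workdir / "fixture"
    cov = pd.read_csv(fixture / "covariates.tsv", sep="\t", index_col="subject")
    geno = pd.read_csv(fixture / "genotypes.tsv", sep="\t", index_col="subject")
    n_pcs = int(cfg["fusion"]["n_genotype_pcs"])
    cov_geno = cov.copy()
    snp_names = ["sex", "site"]
    if n_pcs > 0 and geno.shape[1] > n_pcs:
        pcs = st.compute_genotype_pcs(geno, n_pcs=n_pcs)
        cov_geno = cov_geno.join(pcs)
        snp_names += list(pcs.columns)
    x_snp = st.residualize_features(geno, cov_geno, snp_names)
    sa = _load_sa_dfnc(workdir)
    x_dfnc = {
        state: st.residualize_features(m, cov, ["age", "sex", "site"])
        for state, m in sa.items()
    }
    return x_snp, x_dfnc, cov


def stage_fuse(cfg: dict, workdir: str | Path, states: list[int] | None = None):
    """Run the parallel joint ICA fusions, one per dFNC state."""
    workdir = Path(workdir)
    c = cfg["fusion"]
    x_snp, x_dfnc, _ = _residualized_blocks(cfg, workdir)
    inputs = {
        state: fus.balance_and_concatenate(x_snp, m, balance=bool(c["balance"]))
        for state, m in x_dfnc.items()
    }
    if c["order"] == "auto":
        order = fus.select_model_order(
            [inp.x for inp in inputs.values()] + [x_snp.to_numpy()],
            floor_variance=float(c["floor_variance"]),
            floor_matrices=[m.to_numpy() for m in x_dfnc.values()],
        )
    else:
        order = int(c["order"])

    fdir = workdir / "fusion"
    fdir.mkdir(exist_ok=True)
    results = {}
    for state, inp in inputs.items():
        if states is not None and state not in states:
            continue
        res = fus.infomax_jica(
            inp,
            order,
            seed=int(c["seed"]) + state,
            kurtosis_threshold=float(c["kurtosis_threshold"]),
        )
        results[state] = res
        res.loadings.to_csv(fdir / f"state{state}_loadings.tsv", sep="\t")
        res.sources.to_csv(fdir / f"state{state}_sources.tsv", sep="\t")
        meta = {
            "order": res.order,
            "seed": res.seed,
            "converged": res.converged,
            "n_iter": res.n_iter,
            "n_snp_cols": len(res.snp_cols),
            "n_dfnc_cols": len(res.dfnc_cols),
            "kurtosis": ",".join(f"{k:.4f}" for k in res.kurtosis),
            "super_gaussian": ",".join(str(bool(f)) for f in res.super_gaussian),
        }
        (fdir / f"state{state}_meta.txt").write_text(
            "".join(f"{k}\t{v}\n" for k, v in meta.items())
        )
    return results


def load_fusion_results(workdir: str | Path) -> dict[int, fus.FusionResult]:
    """Reload fusion results written by :func:`stage_fuse`."""
    fdir = Path(workdir) / "fusion"
    results = {}
    for f in sorted(fdir.glob("state*_meta.txt")):
        state = int(f.stem.split("_")[0].replace("state", ""))
        meta = dict(line.split("\t", 1) for line in f.read_text().splitlines())
        sources = pd.read_csv(fdir / f"state{state}_sources.tsv", sep="\t", index_col="component")
        loadings = pd.read_csv(fdir / f"state{state}_loadings.tsv", sep="\t", index_col="subject")
        loadings.columns = loadings.columns.astype(int)
        n_snp = int(meta["n_snp_cols"])
        cols = list(sources.columns)
        results[state] = fus.FusionResult(
            order=int(meta["order"]),
            loadings=loadings,
            sources=sources,
            snp_cols=cols[:n_snp],
            dfnc_cols=cols[n_snp:],
            kurtosis=np.array([float(x) for x in meta["kurtosis"].split(",")]),
            super_gaussian=np.array([x == "True" for x in meta["super_gaussian"].split(",")]),
            converged=meta["converged"] == "True",
            n_iter=int(meta["n_iter"]),
            seed=int(meta["seed"]),
        )
    return results


# ---------------------------------------------------------------- similarity


def stage_similarity(cfg: dict, workdir: str | Path) -> pd.DataFrame:
    """Match components across fusions and classify state variability."""
    workdir = Path(workdir)
    results = load_fusion_results(workdir)
    c = cfg["similarity"]
    table = sim.classify_variability(
        sim.match_components(results),
        invariant_cutoff=float(c["invariant_cutoff"]),
        variant_cutoff=float(c["variant_cutoff"]),
    )
    table.to_csv(workdir / "similarity.tsv", sep="\t")
    for modality, curve in sim.sorted_similarity_curves(table).items():
        curve.to_csv(workdir / f"similarity_sorted_{modality}.tsv", sep="\t")
    return table


# ---------------------------------------------------------------- validation


def stage_validate(cfg: dict, workdir: str | Path) -> pd.DataFrame:
    """Project dFNC sources onto the cohort and test case-control contrasts.

    The fixture's diagnosed subjects act as the validation cohort: per-state
    sa-dFNC features are residualized on the validation covariates (age,
    sex, site, mean framewise displacement), projected onto the discovery
    dFNC sources, and the projected loadings are tested between cases and
    controls with joint FDR across fusions.  Cognitive scores are tested in
    everyone (controlling diagnosis), symptom scales in patients only.
    """
    workdir = Path(workdir)
    fixture = workdir / "fixture"
    cov = pd.read_csv(fixture / "covariates.tsv", sep="\t", index_col="subject")
    results = load_fusion_results(workdir)
    sa = _load_sa_dfnc(workdir)
    vdir = workdir / "validation"
    vdir.mkdir(exist_ok=True)

    cog_cols = [
        "OverallCompositeScore", "ProcessingSpeed", "AttentionVigilance",
        "WorkingMemory", "VerbalLearning", "VisualLearning", "ReasoningProblemSolving",
    ]
    sym_cols = ["PANSS_Pos", "PANSS_Neg"]

    tests, assoc_frames = {}, []
    for state, res in results.items():
        x_val = st.residualize_features(sa[state], cov, ["age", "sex", "site", "mean_fd"])
        x_val.columns = res.sources_dfnc.columns
        a_val = val.project_dfnc(x_val, res.sources_dfnc)
        a_val.to_csv(vdir / f"state{state}_projected_loadings.tsv", sep="\t")
        tests[state] = val.group_difference(
            a_val, cov["diagnosis"], cov, ["age", "sex", "site", "mean_fd"]
        )
        cog = val.partial_association(
            a_val, cov[cog_cols], cov, ["age", "sex", "site", "diagnosis"]
        ).reset_index()
        cog["state"] = state
        assoc_frames.append(cog)
        if cov.loc[a_val.index, "diagnosis"].sum() >= 10:
            sym = val.partial_association(
                a_val, cov[sym_cols], cov, ["age", "sex", "site"],
                group_filter=cov["diagnosis"] == 1,
            ).reset_index()
            sym["state"] = state
            assoc_frames.append(sym)

    merged = val.combine_fdr(tests, alpha=float(cfg["validation"]["alpha"]))
    sim_path = workdir / "similarity.tsv"
    if sim_path.exists():
        sim_table = pd.read_csv(sim_path, sep="\t", index_col=["state", "component"])
        merged = merged.join(sim_table, how="left")
    merged.to_csv(vdir / "group_tests.tsv", sep="\t")
    pd.concat(assoc_frames, ignore_index=True).to_csv(
        vdir / "associations.tsv", sep="\t", index=False
    )
    return merged


# ---------------------------------------------------------------- report


def stage_report(cfg: dict, workdir: str | Path) -> list[Path]:
    """Extract top features of significant components and render reports."""
    workdir = Path(workdir)
    c = cfg["report"]
    results = load_fusion_results(workdir)
    fixture = workdir / "fixture"
    legend = pd.read_csv(fixture / "icn_labels.tsv", sep="\t")
    annot_path = fixture / "snp_annotation.tsv"
    annotation = (
        pd.read_csv(annot_path, sep="\t", index_col="snp") if annot_path.exists() else None
    )
    tests = pd.read_csv(
        workdir / "validation" / "group_tests.tsv", sep="\t", index_col=["state", "component"]
    )
    feature_sets = []
    for (state, comp), row in tests[tests["significant"]].iterrows():
        feature_sets.append(
            rep.top_features(
                results[state],
                int(comp),
                z_threshold=float(c["z_threshold"]),
                legend=legend,
                annotation=annotation,
                state=int(state),
            )
        )
    curves = {}
    for modality in ("snp", "dfnc"):
        f = workdir / f"similarity_sorted_{modality}.tsv"
        if f.exists():
            curves[modality] = pd.read_csv(f, sep="\t", index_col="rank")
    summary = {
        "n_significant_components": int(tests["significant"].sum()),
        "n_total_components": len(tests),
    }
    return rep.render_reports(
        workdir / "report", feature_sets, similarity_curves=curves,
        annotation=annotation, summary=summary,
    )


def _write_run_manifest(cfg: dict, workdir: Path) -> None:
    """Log parameters, seeds and versions for provenance."""
    from . import __version__

    lines = [f"dynfuse_version\t{__version__}"]
    for section, values in cfg.items():
        if isinstance(values, dict):
            for k, v in values.items():
                lines.append(f"{section}.{k}\t{v}")
        else:
            lines.append(f"{section}\t{values}")
    (workdir / "run_manifest.txt").write_text("".join(f"{ln}\n" for ln in lines))


def run_all(cfg: dict, workdir: str | Path) -> dict:
    """Run every stage in order; returns a summary of key outputs."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    _write_run_manifest(cfg, workdir)
    stage_simulate(cfg, workdir)
    stage_dfnc(cfg, workdir)
    model = stage_states(cfg, workdir)
    results = stage_fuse(cfg, workdir)
    stage_similarity(cfg, workdir)
    tests = stage_validate(cfg, workdir)
    stage_report(cfg, workdir)
    return {
        "k_states": model.k,
        "model_order": next(iter(results.values())).order,
        "n_components_total": sum(r.order for r in results.values()),
        "n_significant": int(tests["significant"].sum()),
    }
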