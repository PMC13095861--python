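"""Synthetic fixtures with planted ground truth for the full fusion pipeline.

The generator emulates the data structure the pipeline consumes: a fixed
subject x SNP dosage matrix under Hardy-Weinberg proportions, per-subject ICN
time courses whose windowed connectivity clusters into a small number of
planted dFNC states, a covariate table, and an SNP -> gene annotation map.
Joint super-Gaussian sources are planted across the SNP and connectivity
blocks through a shared subject-loading matrix, and a case-control loading
shift is planted on designated components, so that every downstream stage
(windowing, state clustering, joint ICA, projection validation) has a
recoverable ground truth.

All randomness flows from the single integer ``seed`` of the design through
fixed-purpose substreams (and one counter-based substream per subject for
time-course synthesis), so any part of a fixture can be regenerated
independently and reproducibly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dfnc import TimecourseSet
from .pairs import n_pairs, vec_to_mat

__all__ = [
    "SyntheticDesign",
    "GroundTruth",
    "GenotypeMatrix",
    "GenerationError",
    "make_ground_truth",
    "generate_genotypes",
    "generate_timecourses",
    "make_covariates",
    "make_fusion_fixture",
    "make_validation_fixture",
    "write_fixture_bundle",
    "nearest_pd_correlation",
]

DOMAINS = ("SC", "AUD", "SM", "VIS", "CC", "DMN", "CB")

# fixed spawn keys for the per-purpose substreams of the master seed
_KEY_SOURCES, _KEY_LOADINGS, _KEY_CENTROIDS, _KEY_GENO, _KEY_COVAR = range(5)
_KEY_SUBJECT = 10  # per-subject streams use (10, subject_index)


class GenerationError(RuntimeError):
    """Raised when a fixture cannot be generated from a valid design."""


@dataclass(frozen=True)
class SyntheticDesign:
    """Study-shape parameters of a synthetic fixture.

    Defaults describe the desk-scale study this package is exercised at:
    200 subjects, 300 SNPs, 10 ICNs (45 connectivity pairs), 400 time points
    at TR = 0.735 s, 4 planted connectivity states, 5 planted joint
    components, signal-to-noise ratio 2, and a 0.5-SD case-control loading
    shift on one component.
    """

    n_subjects: int = 200
    n_snps: int = 300
    n_icns: int = 10
    n_timepoints: int = 400
    tr_seconds: float = 0.735
    k_states: int = 4
    n_components: int = 5
    maf_range: tuple[float, float] = (0.05, 0.5)
    snr: float = 2.0
    dwell_mean: float = 60.0
    effect_components: tuple[int, ...] | None = None
    effect_size: float = 0.5
    seed: int = 0
    source_density: float = 0.2

    def __post_init__(self):
        if self.effect_components is None:
            # default: one shifted component (index 2 when available)
            object.__setattr__(
                self, "effect_components", (min(2, self.n_components - 1),)
            )
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.k_states < 1:
            raise ValueError("k_states must be >= 1")
        if self.n_components >= self.n_subjects:
            raise ValueError("n_components must be < n_subjects")
        if any(c >= self.n_components or c < 0 for c in self.effect_components):
            raise ValueError("effect_components must be valid component indices")
        if self.snr <= 0 or self.tr_seconds <= 0 or self.dwell_mean <= 0:
            raise ValueError("snr, tr_seconds and dwell_mean must be positive")

    @property
    def n_fnc_pairs(self) -> int:
        return n_pairs(self.n_icns)

    @property
    def subject_ids(self) -> list[str]:
        return [f"sub{i:04d}" for i in range(self.n_subjects)]

    @property
    def snp_ids(self) -> list[str]:
        return [f"rs{i:06d}" for i in range(self.n_snps)]


@dataclass
class GroundTruth:
    """Planted quantities of a fixture.

    ``sources`` is n_components x (n_snps + n_fnc_pairs), rows standardized
    and super-Gaussian (sparse Laplace); ``loadings`` is n_subjects x
    n_components and already includes the case-control shift on the designed
    effect components; ``state_centroids`` holds each state's correlation
    pattern as a pair vector; ``state_sequences`` is the per-subject Markov
    state path over time points.
    """

    sources: np.ndarray
    loadings: np.ndarray
    state_centroids: np.ndarray
    state_sequences: np.ndarray
    diagnosis: np.ndarray
    n_snps: int

    @property
    def sources_snp(self) -> np.ndarray:
        return self.sources[:, : self.n_snps]

    @property
    def sources_dfnc(self) -> np.ndarray:
        return self.sources[:, self.n_snps :]


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs dosage block with allele metadata."""

    dosages: pd.DataFrame  # values in {0, 1, 2}, index subjects, columns SNP ids
    mafs: pd.Series
    alleles: pd.DataFrame  # columns: ref, alt

    @property
    def subjects(self) -> list[str]:
        return list(self.dosages.index)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def nearest_pd_correlation(
    mat: np.ndarray, eps: float = 1e-6, max_rounds: int = 10, name: str = ""
) -> np.ndarray:
    """Repair a symmetric matrix into a positive-definite correlation matrix.

    Eigenvalues are clipped at ``eps`` and the matrix re-normalized to unit
    diagonal, iterating because the re-normalization can reintroduce tiny
    negative eigenvalues.  Raises :class:`GenerationError` when the repair
    does not converge.
    """
    m = np.array(mat, dtype=float)
    m = 0.5 * (m + m.T)
    for _ in range(max_rounds):
        vals, vecs = np.linalg.eigh(m)
        if vals.min() >= eps / 2:
            return m
        m = (vecs * np.clip(vals, eps, None)) @ vecs.T
        d = np.sqrt(np.diag(m))
        m = m / np.outer(d, d)
        np.fill_diagonal(m, 1.0)
    raise GenerationError(f"correlation repair failed to converge{f' for {name}' if name else ''}")


def _sparse_laplace_sources(rng, n_components, n_features, density):
    """Standardized sparse-Laplace source rows (positive excess kurtosis)."""
    s = np.zeros((n_components, n_features))
    for c in range(n_components):
        mask = rng.random(n_features) < density
        if not mask.any():
            mask[rng.integers(n_features)] = True
        s[c, mask] = rng.laplace(size=mask.sum())
        # scale-only standardization keeps the inactive features exactly zero
        s[c] = s[c] / s[c].std()
    return s


def _markov_sequence(rng, k, length, dwell_mean):
    """Uniform-switch Markov chain with mean dwell ``dwell_mean`` samples."""
    if k == 1:
        return np.zeros(length, dtype=int)
    stay = max(0.0, 1.0 - 1.0 / dwell_mean)
    seq = np.empty(length, dtype=int)
    seq[0] = rng.integers(k)
    for t in range(1, length):
        if rng.random() < stay:
            seq[t] = seq[t - 1]
        else:
            others = [s for s in range(k) if s != seq[t - 1]]
            seq[t] = others[rng.integers(k - 1)]
    return seq


def _random_state_centroids(rng, k_states, n_icns, factors_per_state=2):
    """Well-separated factor-structured correlation patterns, one per state.

    Each state's correlation matrix has a ``factors_per_state``-factor
    structure; the factor subspaces are drawn mutually orthogonal across
    states (one QR basis split into per-state blocks) so the planted
    connectivity patterns are distinct by construction.
    """
    f = factors_per_state
    need = min(k_states * f, n_icns)
    q, _ = np.linalg.qr(rng.normal(size=(n_icns, need)))
    cents = np.empty((k_states, n_pairs(n_icns)))
    iu = np.triu_indices(n_icns, k=1)
    for s in range(k_states):
        cols = [(s * f + j) % need for j in range(f)]
        b = q[:, cols] * np.sqrt(n_icns / f) * 1.3
        cov = b @ b.T + 0.6 * np.eye(n_icns)
        d = np.sqrt(np.diag(cov))
        cents[s] = (cov / np.outer(d, d))[iu]
    return cents


def make_ground_truth(design: SyntheticDesign) -> GroundTruth:
    """Draw the planted sources, loadings, states and diagnosis of a fixture."""
    n_feat = design.n_snps + design.n_fnc_pairs
    sources = _sparse_laplace_sources(
        _rng(design.seed, _KEY_SOURCES), design.n_components, n_feat, design.source_density
    )
    loadings = _rng(design.seed, _KEY_LOADINGS).normal(
        size=(design.n_subjects, design.n_components)
    )
    # second half of subjects are cases; the shift matches the validation
    # stage's two-sample contrast
    diagnosis = np.zeros(design.n_subjects, dtype=int)
    diagnosis[design.n_subjects // 2 :] = 1
    for c in design.effect_components:
        loadings[diagnosis == 1, c] += design.effect_size

    centroids = _random_state_centroids(
        _rng(design.seed, _KEY_CENTROIDS), design.k_states, design.n_icns
    )
    seqs = np.empty((design.n_subjects, design.n_timepoints), dtype=int)
    for i in range(design.n_subjects):
        seqs[i] = _markov_sequence(
            _rng(design.seed, _KEY_SUBJECT, i),
            design.k_states,
            design.n_timepoints,
            design.dwell_mean,
        )
    return GroundTruth(
        sources=sources,
        loadings=loadings,
        state_centroids=centroids,
        state_sequences=seqs,
        diagnosis=diagnosis,
        n_snps=design.n_snps,
    )


def generate_genotypes(design: SyntheticDesign, truth: GroundTruth) -> GenotypeMatrix:
    """Dosage matrix with planted loading-dosage correlation under HWE.

    A continuous liability ``loadings @ sources_snp + noise`` (noise variance
    set per SNP by the design SNR; unit-variance pure noise for SNPs with no
    planted weight) is discretized by per-SNP empirical quantile cuts at the
    Hardy-Weinberg genotype proportions ``(1-maf)^2`` and
    ``(1-maf)^2 + 2 maf (1-maf)``, which preserves the minor allele frequency
    by construction while the planted correlation survives discretization.
    """
    rng = _rng(design.seed, _KEY_GENO)
    mafs = rng.uniform(*design.maf_range, size=design.n_snps)
    subjects = design.subject_ids
    if design.n_snps == 0:
        return GenotypeMatrix(
            dosages=pd.DataFrame(index=pd.Index(subjects, name="subject")),
            mafs=pd.Series(dtype=float),
            alleles=pd.DataFrame(columns=["ref", "alt"]),
        )

    signal = truth.loadings @ truth.sources_snp
    sig_sd = signal.std(axis=0)
    noise_sd = np.where(sig_sd > 0, sig_sd / np.sqrt(design.snr), 1.0)
    liability = signal + rng.normal(size=signal.shape) * noise_sd

    q0 = (1.0 - mafs) ** 2
    q1 = q0 + 2.0 * mafs * (1.0 - mafs)
    c0 = np.empty(design.n_snps)
    c1 = np.empty(design.n_snps)
    for j in range(design.n_snps):
        c0[j], c1[j] = np.quantile(liability[:, j], [q0[j], q1[j]])
    dosage = (liability > c0).astype(np.int8) + (liability > c1).astype(np.int8)

    bases = np.array(list("ACGT"))
    ref = rng.integers(4, size=design.n_snps)
    alt = (ref + 1 + rng.integers(3, size=design.n_snps)) % 4
    return GenotypeMatrix(
        dosages=pd.DataFrame(
            dosage, index=pd.Index(subjects, name="subject"), columns=design.snp_ids
        ),
        mafs=pd.Series(mafs, index=design.snp_ids, name="maf"),
        alleles=pd.DataFrame(
            {"ref": bases[ref], "alt": bases[alt]}, index=design.snp_ids
        ),
    )


def generate_timecourses(
    design: SyntheticDesign, truth: GroundTruth, coupling: float = 0.05
) -> list[TimecourseSet]:
    """Per-subject time courses following the planted Markov state paths.

    Within a state visit, samples are drawn from a zero-mean multivariate
    normal whose correlation matrix is the state centroid (nearest-PD
    repaired) plus a subject-specific perturbation ``coupling *
    unvec(loadings_i @ sources_dfnc)`` that carries the planted joint
    components into the connectivity domain.
    """
    out = []
    deltas = truth.loadings @ truth.sources_dfnc  # n_subjects x n_pairs
    base = [
        vec_to_mat(truth.state_centroids[s], design.n_icns, diag=1.0)
        for s in range(design.k_states)
    ]
    for i, subj in enumerate(design.subject_ids):
        rng = _rng(design.seed, _KEY_SUBJECT, i, 1)
        delta = vec_to_mat(coupling * deltas[i], design.n_icns, diag=0.0)
        seq = truth.state_sequences[i]
        chols = {}
        x = np.empty((design.n_timepoints, design.n_icns))
        for s in np.unique(seq):
            try:
                corr = nearest_pd_correlation(base[s] + delta, name=f"state {s}")
            except GenerationError as exc:
                raise GenerationError(f"subject {subj}: {exc}") from exc
            chols[s] = np.linalg.cholesky(corr)
        draws = rng.normal(size=(design.n_timepoints, design.n_icns))
        for s, chol in chols.items():
            idx = seq == s
            x[idx] = draws[idx] @ chol.T
        out.append(TimecourseSet(subject=subj, data=x, tr_seconds=design.tr_seconds))
    return out


def make_covariates(design: SyntheticDesign, truth: GroundTruth) -> pd.DataFrame:
    """Covariate table: demographics, site, motion, diagnosis, scores.

    Seven cognitive scores and two symptom subscales (cases only) are drawn
    weakly coupled to the planted effect components so association stages
    have signal to find; age/sex/site/meanFD are independent nuisance draws.
    """
    rng = _rng(design.seed, _KEY_COVAR)
    n = design.n_subjects
    eff = (
        truth.loadings[:, list(design.effect_components)].mean(axis=1)
        if design.effect_components
        else np.zeros(n)
    )
    cog_names = [
        "OverallCompositeScore",
        "ProcessingSpeed",
        "AttentionVigilance",
        "WorkingMemory",
        "VerbalLearning",
        "VisualLearning",
        "ReasoningProblemSolving",
    ]
    df = pd.DataFrame(index=pd.Index(design.subject_ids, name="subject"))
    df["age"] = np.round(rng.uniform(18, 75, size=n), 1)
    df["sex"] = np.where(rng.random(n) < 0.5, "F", "M")
    df["site"] = rng.choice(["siteA", "siteB", "siteC"], size=n)
    df["mean_fd"] = np.round(rng.lognormal(mean=-2.0, sigma=0.4, size=n), 4)
    df["diagnosis"] = truth.diagnosis
    for name in cog_names:
        df[name] = np.round(-0.3 * eff + rng.normal(size=n), 4)
    for name in ["PANSS_Pos", "PANSS_Neg"]:
        vals = np.round(0.3 * eff + rng.normal(size=n), 4)
        df[name] = np.where(truth.diagnosis == 1, vals, np.nan)
    return df


def make_snp_annotation(design: SyntheticDesign) -> pd.DataFrame:
    """Synthetic SNP -> gene map with chromosome/position ordering."""
    rng = _rng(design.seed, _KEY_GENO, 1)
    chrom = np.sort(rng.integers(1, 23, size=design.n_snps))
    pos = rng.integers(1, 2_000_000, size=design.n_snps)
    gene = [f"GENE{g:04d}" for g in rng.integers(0, max(design.n_snps // 3, 1), size=design.n_snps)]
    return pd.DataFrame(
        {"snp": design.snp_ids, "chrom": chrom, "pos": pos, "gene": gene}
    ).set_index("snp")


def make_icn_labels(design: SyntheticDesign) -> pd.DataFrame:
    """ICN label table cycling through the seven functional domains."""
    return pd.DataFrame(
        {
            "icn": np.arange(design.n_icns),
            "label": [f"ICN{i:02d}" for i in range(design.n_icns)],
            "domain": [DOMAINS[i % len(DOMAINS)] for i in range(design.n_icns)],
        }
    )


def make_fusion_fixture(
    design: SyntheticDesign, truth: GroundTruth | None = None, seed_offset: int = 0
) -> np.ndarray:
    """Continuous fusion-input matrix ``loadings @ sources + noise`` at the
    design SNR, as the joint-ICA recovery fixture (subjects x features)."""
    if truth is None:
        truth = make_ground_truth(design)
    rng = _rng(design.seed, _KEY_SOURCES, 99, seed_offset)
    clean = truth.loadings @ truth.sources
    noise = rng.normal(size=clean.shape) * (clean.std(axis=0) / np.sqrt(design.snr))
    return clean + noise


def make_validation_fixture(
    n_subjects: int,
    n_components: int,
    n_features: int,
    effect_components: tuple[int, ...],
    effect_size: float,
    seed: int,
    noise_sd: float = 1.0,
):
    """Validation-cohort fixture for projection and case-control testing.

    Returns ``(X_val, S, loadings, diagnosis)`` where ``X_val = loadings @ S
    + noise``, the planted loadings of the case half are shifted by
    ``effect_size`` on ``effect_components``, and ``S`` plays the role of the
    discovery sources the cohort is projected onto.
    """
    rng = _rng(seed, 7)
    s = _sparse_laplace_sources(rng, n_components, n_features, density=0.2)
    loadings = rng.normal(size=(n_subjects, n_components))
    diagnosis = np.zeros(n_subjects, dtype=int)
    diagnosis[n_subjects // 2 :] = 1
    for c in effect_components:
        loadings[diagnosis == 1, c] += effect_size
    x = loadings @ s + noise_sd * rng.normal(size=(n_subjects, n_features))
    return x, s, loadings, diagnosis


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_bundle(
    design: SyntheticDesign, truth: GroundTruth, outdir: str | Path
) -> pd.DataFrame:
    """Write a complete pipeline-readable fixture to ``outdir``.

    Produces genotypes.tsv, per-subject time-course TSVs under ``tc/``,
    covariates.tsv, icn_labels.tsv, snp_annotation.tsv, a ground_truth.npz
    archive, and a manifest.tsv listing every file with its SHA-256 checksum.
    Deterministic given the design seed (identical reruns give identical
    checksums).
    """
    outdir = Path(outdir)
    (outdir / "tc").mkdir(parents=True, exist_ok=True)

    geno = generate_genotypes(design, truth)
    geno.dosages.to_csv(outdir / "genotypes.tsv", sep="\t")
    make_covariates(design, truth).to_csv(outdir / "covariates.tsv", sep="\t")
    labels = make_icn_labels(design)
    labels.to_csv(outdir / "icn_labels.tsv", sep="\t", index=False)
    make_snp_annotation(design).to_csv(outdir / "snp_annotation.tsv", sep="\t")

    files = ["genotypes.tsv", "covariates.tsv", "icn_labels.tsv", "snp_annotation.tsv"]
    for tc in generate_timecourses(design, truth):
        rel = f"tc/{tc.subject}.tsv"
        pd.DataFrame(np.round(tc.data, 6), columns=labels["label"]).to_csv(
            outdir / rel, sep="\t", index=False
        )
        files.append(rel)

    np.savez(
        outdir / "ground_truth.npz",
        sources=truth.sources,
        loadings=truth.loadings,
        state_centroids=truth.state_centroids,
        state_sequences=truth.state_sequences,
        diagnosis=truth.diagnosis,
        n_snps=np.array(truth.n_snps),
        tr_seconds=np.array(design.tr_seconds),
    )
    files.append("ground_truth.npz")

    manifest = pd.DataFrame(
        {
            "file": files,
            "sha256": [_sha256(outdir / f) for f in files],
            "bytes": [(outdir / f).stat().st_size for f in files],
        }
    )
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest
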