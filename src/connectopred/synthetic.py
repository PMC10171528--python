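"""Synthetic connectome cohorts with a plantable, recoverable signal.

The generator emulates the raw material of a connectome-prediction study:

* per-subject asymmetric streamline-count matrices with per-region seed-voxel
  counts, as produced by ROI-to-ROI probabilistic tractography (5000
  streamlines initiated per seed voxel by default);
* per-subject Fisher-z ROI-to-ROI correlation matrices from a latent-factor
  model, so functional connectivity has genuine positive-definite structure;
* cognitive domain scores with a linear dependence of known strength
  (``planted_r2``) on a designated feature set, computed by the *downstream*
  pipeline itself on the generated matrices, plus i.i.d. Gaussian noise.

Cohorts share a template (region sizes, tract base rates, latent loading
directions); each subject deviates from it by a configurable amount, so the
between-subject variance the regression consumes is under explicit control.
All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .features import assemble_features, compute_cohort_metrics, impute_by_mean
from .prep import fc_from_fisher_z, proportional_threshold, sc_weight_matrix

__all__ = [
    "DOMAIN_LABELS",
    "CohortConfig",
    "StreamlineCounts",
    "CognitiveScores",
    "generate_streamline_counts",
    "generate_fc_fisher_z",
    "generate_cohort",
    "write_cohort",
]

DOMAIN_LABELS = [
    "Executive Function",
    "Self-regulation",
    "Language",
    "Encoding",
    "Sequence Processing",
]

PLANTED_SETS = ("raw_sc", "raw_fc", "node", "edge", "global")

# rng stream tags, to keep template/subject/score streams independent
_SC_TEMPLATE, _FC_TEMPLATE, _SC_SUBJ, _FC_SUBJ, _SCORES = 11, 12, 13, 14, 15


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults follow the source study's scale: 249 subjects, 278 regions,
    5000 streamlines per seed voxel. ``planted_r2`` is the expected fraction
    of cognitive-score variance carried by the planted linear signal;
    ``subject_deviation`` scales how far each subject's connectivity departs
    from the cohort template.
    """

    n_subjects: int = 249
    n_regions: int = 278
    samples_per_voxel: int = 5000
    voxels_per_region: tuple[int, int] = (50, 200)
    sc_density: float = 0.35
    fc_noise_sd: float = 0.05
    planted_r2: float = 0.3
    planted_feature_set: str = "raw_sc"
    n_signal_features: int = 5
    subject_deviation: float = 0.25
    latent_dim: int = 6
    communality: float = 0.6
    retain_fraction: float = 0.2
    seed: int = 0
    domain_labels: tuple[str, ...] = tuple(DOMAIN_LABELS)

    def __post_init__(self) -> None:
        if self.n_regions < 4:
            raise ValueError("n_regions must be >= 4")
        if min(self.n_subjects, self.samples_per_voxel, self.n_signal_features,
               self.latent_dim) < 1:
            raise ValueError("all counts must be positive")
        lo, hi = self.voxels_per_region
        if not (0 < lo <= hi):
            raise ValueError("voxels_per_region must be a positive range")
        if not (0 <= self.sc_density <= 1):
            raise ValueError("sc_density must be in [0, 1]")
        if not (0 <= self.planted_r2 < 1):
            raise ValueError("planted_r2 must be in [0, 1)")
        if self.fc_noise_sd < 0 or self.subject_deviation < 0:
            raise ValueError("noise scales must be nonnegative")
        if not (0 < self.communality < 1):
            raise ValueError("communality must be in (0, 1)")
        if self.planted_feature_set not in PLANTED_SETS:
            raise ValueError(f"planted_feature_set must be one of {PLANTED_SETS}")

    @property
    def region_labels(self) -> list[str]:
        return [f"R{i:03d}" for i in range(self.n_regions)]

    def subject_ids(self) -> list[str]:
        return [f"sub-{i:03d}" for i in range(self.n_subjects)]


@dataclass(frozen=True)
class StreamlineCounts:
    """Asymmetric tract-count matrix M plus per-region seed-voxel counts N.

    ``M[i, j]`` counts streamlines seeded in region i that reached region j;
    at most ``N[i] * samples_per_voxel`` streamlines can leave region i.
    """

    M: np.ndarray
    N: np.ndarray
    samples_per_voxel: int

    def __post_init__(self) -> None:
        M = np.asarray(self.M)
        N = np.asarray(self.N)
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "N", N)
        if np.any(M < 0) or np.any(np.diag(M) != 0):
            raise ValueError("counts must be nonnegative with zero diagonal")
        if np.any(N <= 0):
            raise ValueError("seed-voxel counts must be positive")
        if np.any(M > N[:, None] * self.samples_per_voxel):
            raise ValueError("counts exceed the seeded streamline budget")


@dataclass(frozen=True)
class CognitiveScores:
    """Subjects x domains score table, with ground truth when synthetic."""

    values: pd.DataFrame
    ground_truth: dict | None = None

    @property
    def domain_labels(self) -> list[str]:
        return list(self.values.columns)


def _template_sc(config: CohortConfig):
    """Cohort-level SC template: region sizes, edge mask, tract base rates."""
    rng = np.random.default_rng([config.seed, _SC_TEMPLATE])
    n = config.n_regions
    lo, hi = config.voxels_per_region
    N = rng.integers(lo, hi + 1, size=n)
    iu = np.triu_indices(n, k=1)
    mask = np.zeros((n, n), dtype=bool)
    mask[iu] = rng.random(iu[0].size) < config.sc_density
    mask |= mask.T
    # per-pair base success rate of a seeded streamline reaching the target
    rate = np.zeros((n, n))
    rate[iu] = rng.beta(2.0, 18.0, size=iu[0].size)
    rate = (rate + rate.T) * mask
    return N, mask, rate


def generate_streamline_counts(config: CohortConfig, subject_index: int) -> StreamlineCounts:
    """ProbtrackX-like counts for one subject: for each ordered region pair,
    a binomial draw over the ``N_i * samples_per_voxel`` seeded streamlines
    with a subject-perturbed template success rate."""
    if not 0 <= subject_index:
        raise ValueError("subject_index must be nonnegative")
    N, mask, rate = _template_sc(config)
    rng = np.random.default_rng([config.seed, _SC_SUBJ, subject_index])
    n = config.n_regions
    dev = config.subject_deviation
    jitter = np.exp(rng.normal(-0.5 * dev**2, dev, size=(n, n)))
    p = np.clip(rate * jitter, 0.0, 0.8) * mask
    trials = np.broadcast_to(N[:, None] * config.samples_per_voxel, (n, n))
    M = rng.binomial(trials, p)
    np.fill_diagonal(M, 0)
    return StreamlineCounts(M=M, N=N, samples_per_voxel=config.samples_per_voxel)


def _template_fc(config: CohortConfig) -> np.ndarray:
    """Unit-norm latent loading directions shared by the cohort."""
    rng = np.random.default_rng([config.seed, _FC_TEMPLATE])
    U = rng.normal(size=(config.n_regions, config.latent_dim))
    return U / np.linalg.norm(U, axis=1, keepdims=True)


def generate_fc_fisher_z(config: CohortConfig, subject_index: int) -> np.ndarray:
    """Fisher-z correlation matrix for one subject.

    Correlations come from an equal-communality latent-factor model:
    region i loads ``h * u_i`` on the factors with ``||u_i|| = 1``, so
    ``r_ij = h^2 u_i . u_j`` and the implied covariance with uniqueness
    ``1 - h^2`` is a valid correlation matrix by construction. Measurement
    noise of sd ``fc_noise_sd`` is added on the z scale.
    """
    U = _template_fc(config)
    rng = np.random.default_rng([config.seed, _FC_SUBJ, subject_index])
    dev = config.subject_deviation
    Us = U + dev * rng.normal(size=U.shape)
    Us /= np.linalg.norm(Us, axis=1, keepdims=True)
    R = (config.communality**2) * (Us @ Us.T)
    np.fill_diagonal(R, 0.0)
    z = np.arctanh(R)
    n = config.n_regions
    E = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    E[iu] = rng.normal(0.0, config.fc_noise_sd, size=iu[0].size) \
        if config.fc_noise_sd > 0 else 0.0
    z = z + E + E.T
    np.fill_diagonal(z, 0.0)
    return z


def _planted_design(config: CohortConfig, subjects: list[dict]) -> tuple[np.ndarray, list]:
    """Run the downstream pipeline on the generated matrices and return the
    standardised planted feature matrix (the quantities the models will
    actually see) with its labels."""
    labels = config.region_labels
    sc = [
        proportional_threshold(sc_weight_matrix(s["sc_counts"]), config.retain_fraction)
        for s in subjects
    ]
    fc = [
        proportional_threshold(fc_from_fisher_z(s["fc_z"]), config.retain_fraction)
        for s in subjects
    ]
    by_mod = {"SC": sc, "FC": fc}
    if config.planted_feature_set in ("raw_sc", "raw_fc"):
        modality = "SC" if config.planted_feature_set == "raw_sc" else "FC"
        cm = compute_cohort_metrics(
            {modality: by_mod[modality]}, config.subject_ids(),
            region_labels=labels, seed=config.seed, with_metrics=False,
        )
        fm = assemble_features(cm, modality, "raw")
    else:
        cm = compute_cohort_metrics(
            {"SC": sc}, config.subject_ids(),
            region_labels=labels, seed=config.seed,
        )
        fm = assemble_features(cm, "SC", config.planted_feature_set)
    X, _ = impute_by_mean(fm.X)
    sd = X.std(axis=0)
    ok = sd > 1e-12
    Xs = np.zeros_like(X)
    Xs[:, ok] = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
    return Xs[:, ok], [fm.feature_labels[k] for k in np.flatnonzero(ok)]


def generate_cohort(config: CohortConfig):
    """Generate matrices and scores for a whole cohort.

    Cognitive scores follow ``y = X beta + eps`` where X is the designated
    planted feature set as computed by the pipeline itself on the generated
    matrices, and the signal carries ``planted_r2`` of the score variance in
    expectation. Returns ``(subjects, CognitiveScores)`` where each subject
    is ``{"sc_counts": StreamlineCounts, "fc_z": ndarray}``.
    """
    subjects = [
        {
            "sc_counts": generate_streamline_counts(config, i),
            "fc_z": generate_fc_fisher_z(config, i),
        }
        for i in range(config.n_subjects)
    ]
    rng = np.random.default_rng([config.seed, _SCORES])
    n, r2 = config.n_subjects, config.planted_r2

    X, labels = (None, None)
    if r2 > 0:
        X, labels = _planted_design(config, subjects)
        if X.shape[1] < config.n_signal_features:
            raise ValueError(
                f"planted set {config.planted_feature_set!r} has only "
                f"{X.shape[1]} usable features at n_regions={config.n_regions}"
            )

    Y = np.empty((n, len(config.domain_labels)))
    gt_domains = {}
    for d, dom in enumerate(config.domain_labels):
        eps = rng.normal(size=n)
        if r2 == 0:
            Y[:, d] = eps
            gt_domains[dom] = {"features": [], "coefficients": [],
                               "noise_sd": 1.0}
            continue
        cols = rng.choice(X.shape[1], size=config.n_signal_features, replace=False)
        beta = rng.uniform(0.5, 1.5, size=cols.size) * rng.choice([-1.0, 1.0], size=cols.size)
        s = X[:, cols] @ beta
        s = (s - s.mean()) / s.std()
        Y[:, d] = np.sqrt(r2) * s + np.sqrt(1 - r2) * eps
        scale = np.sqrt(r2) / (X[:, cols] @ beta).std()
        gt_domains[dom] = {
            "features": [list(labels[c]) for c in cols],
            "coefficients": list(beta * scale),
            "noise_sd": float(np.sqrt(1 - r2)),
        }

    values = pd.DataFrame(Y, index=config.subject_ids(),
                          columns=list(config.domain_labels))
    ground_truth = {
        "planted_r2": r2,
        "planted_feature_set": config.planted_feature_set,
        "domains": gt_domains,
    }
    return subjects, CognitiveScores(values=values, ground_truth=ground_truth)


def write_cohort(config: CohortConfig, out_dir: str | Path) -> dict:
    """Materialise a cohort on disk; returns the manifest."""
    out = Path(out_dir)
    (out / "matrices").mkdir(parents=True, exist_ok=True)
    subjects, scores = generate_cohort(config)
    labels = config.region_labels
    manifest: dict = {
        "n_regions": config.n_regions,
        "samples_per_voxel": config.samples_per_voxel,
        "seed": config.seed,
        "voxel_counts_file": "voxel_counts.tsv",
        "scores_file": "scores.csv",
        "ground_truth_file": "ground_truth.json",
        "subjects": {},
    }
    for sid, subj in zip(config.subject_ids(), subjects):
        sc_path = f"matrices/{sid}_sc_counts.tsv"
        fc_path = f"matrices/{sid}_fc_z.tsv"
        cio.write_matrix(out / sc_path, subj["sc_counts"].M, labels)
        cio.write_matrix(out / fc_path, subj["fc_z"], labels)
        manifest["subjects"][sid] = {"sc_counts": sc_path, "fc_z": fc_path}
    pd.DataFrame({"region": labels, "voxels": subjects[0]["sc_counts"].N}).to_csv(
        out / "voxel_counts.tsv", sep="\t", index=False
    )
    cio.write_scores(out / "scores.csv", scores.values)
    cio.write_manifest(out / "ground_truth.json", scores.ground_truth)
    cio.write_manifest(out / "manifest.json", manifest)
    return manifest
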