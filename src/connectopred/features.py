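"""Assemble predictor matrices from connectomes and their graph metrics.

Five feature families per modality feed the regression models: the raw
(vectorised, thresholded) connectivity itself, and the global, node, edge and
combined graph-metric batteries. Combined connectivity (CC) stacks the SC and
FC blocks column-wise. Every column carries a (modality, measure, element)
label so coefficients can be traced back to a region, an edge or a global
property.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import EDGE_MEASURES, GLOBAL_MEASURES, NODE_MEASURES, subject_metrics

__all__ = [
    "FEATURE_SETS",
    "FeatureMatrix",
    "CohortMetrics",
    "compute_cohort_metrics",
    "assemble_features",
    "standardise",
    "impute_by_mean",
]

log = logging.getLogger(__name__)

FEATURE_SETS = ("raw", "global", "node", "edge", "local", "global_and_local")


@dataclass(frozen=True)
class FeatureMatrix:
    """Subjects x features design matrix with label bookkeeping."""

    X: np.ndarray
    feature_labels: list[tuple[str, str, str]]
    set_name: str
    modality: str
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        object.__setattr__(self, "X", X)
        if X.shape[1] != len(self.feature_labels):
            raise ValueError("feature_labels length must match column count")


@dataclass
class CohortMetrics:
    """Per-subject thresholded connectomes and (optionally) their metric
    tables, keyed by modality."""

    subject_ids: list[str]
    region_labels: list[str]
    conns: dict[str, list]
    nodes: dict[str, list[pd.DataFrame]] = field(default_factory=dict)
    edges: dict[str, list[dict[str, np.ndarray]]] = field(default_factory=dict)
    globals_: dict[str, list[dict[str, float]]] = field(default_factory=dict)


def compute_cohort_metrics(
    conns_by_modality: dict[str, list],
    subject_ids: list[str],
    region_labels: list[str] | None = None,
    seed: int = 0,
    swp_nulls: int = 10,
    with_metrics: bool = True,
) -> CohortMetrics:
    """Run the metric battery for every subject and modality."""
    any_mod = next(iter(conns_by_modality.values()))
    labels = region_labels or list(any_mod[0].region_labels)
    cm = CohortMetrics(
        subject_ids=list(subject_ids), region_labels=labels, conns=conns_by_modality
    )
    if not with_metrics:
        return cm
    for mod, conns in conns_by_modality.items():
        nodes, edges, globs = [], [], []
        for si, conn in enumerate(conns):
            sub_seed = int(
                np.random.SeedSequence([seed, si]).generate_state(1)[0] % 2**31
            )
            nd, ed, gl = subject_metrics(conn, seed=sub_seed, swp_nulls=swp_nulls)
            nodes.append(nd)
            edges.append(ed)
            globs.append(gl)
        cm.nodes[mod] = nodes
        cm.edges[mod] = edges
        cm.globals_[mod] = globs
    return cm


def _edge_union(conns) -> list[tuple[int, int]]:
    present = np.zeros_like(conns[0].W, dtype=bool)
    for c in conns:
        present |= c.W > 0
    i, j = np.nonzero(np.triu(present, k=1))
    return list(zip(i.tolist(), j.tolist()))


def _pair_label(labels: list[str], i: int, j: int) -> str:
    return f"{labels[i]}|{labels[j]}"


def _raw_block(cm: CohortMetrics, mod: str) -> tuple[np.ndarray, list]:
    conns = cm.conns[mod]
    n = conns[0].n_regions
    iu = np.triu_indices(n, k=1)
    X = np.stack([c.W[iu] for c in conns])
    labels = [
        (mod, "raw", _pair_label(cm.region_labels, i, j))
        for i, j in zip(iu[0].tolist(), iu[1].tolist())
    ]
    return X, labels


def _global_block(cm: CohortMetrics, mod: str) -> tuple[np.ndarray, list]:
    X = np.array(
        [[g[m] for m in GLOBAL_MEASURES] for g in cm.globals_[mod]], dtype=float
    )
    return X, [(mod, m, "global") for m in GLOBAL_MEASURES]


def _node_block(cm: CohortMetrics, mod: str) -> tuple[np.ndarray, list]:
    tables = cm.nodes[mod]
    cols, labels = [], []
    for m in NODE_MEASURES:
        block = np.stack([t[m].to_numpy() for t in tables])
        cols.append(block)
        labels.extend((mod, m, r) for r in cm.region_labels)
    return np.concatenate(cols, axis=1), labels


def _edge_block(cm: CohortMetrics, mod: str) -> tuple[np.ndarray, list]:
    union = _edge_union(cm.conns[mod])
    ii = np.array([i for i, _ in union], dtype=int)
    jj = np.array([j for _, j in union], dtype=int)
    cols, labels = [], []
    for m in EDGE_MEASURES:
        block = np.stack(
            [
                np.where(c.W[ii, jj] > 0, e[m][ii, jj], 0.0)
                for c, e in zip(cm.conns[mod], cm.edges[mod])
            ]
        )
        cols.append(block)
        labels.extend(
            (mod, m, _pair_label(cm.region_labels, i, j)) for i, j in union
        )
    return np.concatenate(cols, axis=1), labels


def _modality_block(cm: CohortMetrics, mod: str, set_name: str):
    if set_name == "raw":
        return _raw_block(cm, mod)
    if set_name == "global":
        return _global_block(cm, mod)
    if set_name == "node":
        return _node_block(cm, mod)
    if set_name == "edge":
        return _edge_block(cm, mod)
    if set_name == "local":
        parts = [_node_block(cm, mod), _edge_block(cm, mod)]
    elif set_name == "global_and_local":
        parts = [_global_block(cm, mod), _node_block(cm, mod), _edge_block(cm, mod)]
    else:
        raise ValueError(f"unknown feature set {set_name!r}")
    X = np.concatenate([p[0] for p in parts], axis=1)
    labels = [lab for p in parts for lab in p[1]]
    return X, labels


def assemble_features(cm: CohortMetrics, modality: str, set_name: str) -> FeatureMatrix:
    """Build the design matrix for one (modality, feature set) cell.

    ``modality="CC"`` concatenates the SC and FC blocks column-wise. Edge
    features are aligned on the union of edges present in any subject, with
    zeros where a subject lacks the edge. NaN sentinel values (e.g.
    assortativity of a degree-regular graph) are passed through; imputation
    happens at fit time with training-fold means only.
    """
    mods = ["SC", "FC"] if modality == "CC" else [modality]
    for m in mods:
        if m not in cm.conns:
            raise KeyError(f"modality {m!r} missing from cohort metrics")
    parts = [_modality_block(cm, m, set_name) for m in mods]
    X = np.concatenate([p[0] for p in parts], axis=1)
    labels = [lab for p in parts for lab in p[1]]
    return FeatureMatrix(
        X=X,
        feature_labels=labels,
        set_name=set_name,
        modality=modality,
        subject_ids=list(cm.subject_ids),
    )


def impute_by_mean(X: np.ndarray, means: np.ndarray | None = None):
    """Replace NaN entries column-wise; by default with the column means of
    X itself (training data), otherwise with the supplied means."""
    X = np.asarray(X, dtype=float)
    if means is None:
        all_nan = np.isnan(X).all(axis=0)
        means = np.zeros(X.shape[1])
        if not all_nan.all():
            with np.errstate(invalid="ignore"):
                means[~all_nan] = np.nanmean(X[:, ~all_nan], axis=0)
    out = np.where(np.isnan(X), means[None, :], X)
    return out, means


def standardise(fm: FeatureMatrix):
    """Column-wise zero mean, unit sd; returns the scaled matrix and the
    scaling record needed to transform held-out data without leakage."""
    X = fm.X
    if np.isnan(X).any():
        raise ValueError("impute NaN values before standardising")
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    if np.any(scales <= 1e-12):
        bad = [fm.feature_labels[k] for k in np.flatnonzero(scales <= 1e-12)][:5]
        raise ValueError(f"zero-variance columns reached standardise: {bad}")
    Xs = (X - means) / scales
    return replace(fm, X=Xs), {"means": means, "scales": scales}
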