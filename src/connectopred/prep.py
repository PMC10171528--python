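"""Turn raw measurement matrices into analysis-ready weighted connectomes.

Structural connectivity (SC) is built from probabilistic-tractography
streamline counts: the weight between regions i and j is the total streamline
count in both directions divided by the maximum number of streamlines the two
regions could exchange, ``(M_ij + M_ji) / ((N_i + N_j) * samples_per_voxel)``,
which is symmetric and lies in [0, 1] by construction.

Functional connectivity (FC) arrives as Fisher-z ROI-to-ROI correlation
matrices; the Fisher transform is inverted with tanh, negative correlations
are made positive by absolute value, and the result lies in [0, 1).

Both modalities are then proportionally thresholded: the strongest fraction of
edges keeps its original weight, the rest are zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ConnectomeMatrix",
    "sc_weight_matrix",
    "fc_from_fisher_z",
    "proportional_threshold",
]

SYMMETRY_TOL = 1e-12


@dataclass(frozen=True)
class ConnectomeMatrix:
    """Symmetric, nonnegative, zero-diagonal weighted graph for one subject.

    Parameters
    ----------
    W : ndarray
        n x n weight matrix.
    modality : str
        ``"SC"`` or ``"FC"``.
    region_labels : list of str
        One label per region (graph node).
    thresholded : bool
        Whether a proportional threshold has already been applied.
    """

    W: np.ndarray
    modality: str
    region_labels: list[str] = field(default_factory=list)
    thresholded: bool = False
    threshold_fraction: float | None = None

    def __post_init__(self) -> None:
        # C-contiguity matters: scipy's csgraph routines mutate in place
        W = np.ascontiguousarray(self.W, dtype=float)
        object.__setattr__(self, "W", W)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("connectome matrix must be square")
        if self.modality not in ("SC", "FC"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if not np.all(np.isfinite(W)):
            raise ValueError("connectome weights must be finite")
        if np.abs(W - W.T).max(initial=0.0) > SYMMETRY_TOL:
            raise ValueError("connectome matrix must be symmetric")
        if np.abs(np.diag(W)).max(initial=0.0) > 0:
            raise ValueError("connectome diagonal must be zero")
        if W.min(initial=0.0) < 0 or W.max(initial=0.0) > 1:
            raise ValueError("connectome weights must lie in [0, 1]")
        if not self.region_labels:
            object.__setattr__(
                self, "region_labels", [f"R{i:03d}" for i in range(W.shape[0])]
            )
        if len(self.region_labels) != W.shape[0]:
            raise ValueError("region_labels length must match matrix size")

    @property
    def n_regions(self) -> int:
        return self.W.shape[0]


def sc_weight_matrix(counts) -> ConnectomeMatrix:
    """Normalised structural connectivity weights from streamline counts.

    ``W_ij = (M_ij + M_ji) / ((N_i + N_j) * samples_per_voxel)``: the observed
    streamline traffic between i and j over the maximum traffic possible given
    the seed-voxel counts. Saturates at 1 when every streamline seeded in each
    region reaches the other.

    Parameters
    ----------
    counts : StreamlineCounts
        Asymmetric streamline-count matrix with per-region seed-voxel counts.
    """
    M = np.asarray(counts.M, dtype=float)
    N = np.asarray(counts.N, dtype=float)
    if np.any(N <= 0):
        raise ValueError("every region must have a positive seed-voxel count")
    denom = (N[:, None] + N[None, :]) * float(counts.samples_per_voxel)
    W = (M + M.T) / denom
    np.fill_diagonal(W, 0.0)
    return ConnectomeMatrix(W=W, modality="SC", thresholded=False)


def fc_from_fisher_z(z_matrix: np.ndarray) -> ConnectomeMatrix:
    """Functional connectivity from a Fisher-z correlation matrix.

    tanh inverts the Fisher transform back to correlations in (-1, 1); the
    absolute value then folds negative correlations onto the positive axis so
    the graph is nonnegative.
    """
    z = np.asarray(z_matrix, dtype=float)
    if z.ndim != 2 or z.shape[0] != z.shape[1]:
        raise ValueError("z matrix must be square")
    if not np.all(np.isfinite(z)):
        raise ValueError("z matrix must be finite")
    if np.abs(z - z.T).max(initial=0.0) > 1e-9:
        raise ValueError("z matrix must be symmetric")
    W = np.abs(np.tanh(0.5 * (z + z.T)))  # symmetrise exactly
    np.fill_diagonal(W, 0.0)
    return ConnectomeMatrix(W=W, modality="FC", thresholded=False)


def proportional_threshold(
    conn: ConnectomeMatrix, retain_fraction: float
) -> ConnectomeMatrix:
    """Keep the strongest fraction of edges at their original weights.

    The quota is computed over the upper triangle and applied symmetrically.
    For SC only nonzero entries are candidate edges (absent tracts are not
    "weak edges" to be counted against the quota); for FC every off-diagonal
    pair is a candidate. Ties at the boundary are broken by (weight desc,
    row asc, column asc) so the surviving edge set is deterministic and
    nested across retain fractions.
    """
    if not (0 < retain_fraction <= 1):
        raise ValueError("retain_fraction must be in (0, 1]")
    if conn.thresholded and conn.threshold_fraction == retain_fraction:
        return conn  # idempotent re-application
    W = conn.W.copy()
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = W[iu, ju]
    if conn.modality == "SC":
        cand = np.flatnonzero(w > 0)
    else:
        cand = np.arange(w.size)
    n_keep = int(np.ceil(retain_fraction * cand.size))
    # stable sort on (-weight, row, col): lexsort's last key is primary
    order = cand[np.lexsort((ju[cand], iu[cand], -w[cand]))]
    keep = order[:n_keep]
    mask = np.zeros((n, n), dtype=bool)
    mask[iu[keep], ju[keep]] = True
    mask |= mask.T
    out = np.where(mask, W, 0.0)
    return replace(conn, W=out, thresholded=True, threshold_fraction=retain_fraction)
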