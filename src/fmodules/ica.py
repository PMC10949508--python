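"""Restart-ensemble FastICA with correlation-distance clustering.

The fitness matrix F (genes x samples) is decomposed so that the
independent sources live over the gene dimension: each component is a
gene-weight vector whose few outlier genes define a functional module, and
the corresponding mixing coefficients describe the module's activity per
sample.  Because FastICA converges to different local optima from different
starting points, the decomposition is repeated many times from random
seeds; components recurring across restarts are found by DBSCAN on the
correlation distance d = 1 - |rho| (sign-invariant, since ICA recovers
sources only up to sign), and each dense cluster's centroid is taken as one
robust component.  Activities are then recomputed jointly by least squares.

The correlation distance is not a metric (no triangle inequality), which is
fine for DBSCAN: it only thresholds pairwise distances at eps and never
relies on metric shortcuts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .matrix import FitnessMatrix

__all__ = [
    "ComponentEnsemble",
    "RobustDecomposition",
    "run_ica_ensemble",
    "component_distance",
    "pairwise_distances",
    "cluster_components",
    "robust_centroids",
    "compute_activities",
    "decompose",
    "default_min_size",
]

SIGN_MODES = ("absolute", "signed")


@dataclass
class ComponentEnsemble:
    """Pool of unit-norm gene-weight vectors from repeated FastICA runs."""

    components: np.ndarray  # (n_components_total, n_genes)
    run_index: np.ndarray  # run of origin per component
    seeds: np.ndarray  # seed per component's run
    converged: np.ndarray  # convergence flag per component's run
    n_runs: int
    dimension: int
    tol: float

    def __len__(self) -> int:
        return self.components.shape[0]


@dataclass
class RobustDecomposition:
    """Gene-weight matrix M, activity matrix A and per-component quality."""

    M: np.ndarray  # genes x m, unit-norm columns
    A: np.ndarray  # m x samples
    cluster_sizes: list[int]
    mean_within_correlation: list[float]
    dimension: int
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    residual: float = float("nan")

    @property
    def n_components(self) -> int:
        return self.M.shape[1]


def run_ica_ensemble(
    F: FitnessMatrix,
    k: int,
    n_runs: int = 100,
    tol: float = 1e-7,
    base_seed: int = 0,
    max_iter: int = 1000,
    strict: bool = False,
) -> ComponentEnsemble:
    """Run FastICA ``n_runs`` times at dimension ``k`` with seeds
    ``base_seed + run_index``.

    Genes are treated as observations over the sample dimension, so the
    estimated sources are gene-weight vectors; each is normalised to unit
    Euclidean norm.  Non-converged runs are flagged and kept unless
    ``strict`` is set.
    """
    if F.missing_mask.any():
        raise ValueError(
            "fitness matrix contains missing values; apply "
            "filter_complete_genes before decomposition"
        )
    if not 2 <= k <= F.n_samples:
        raise ValueError(
            f"dimension k={k} must satisfy 2 <= k <= n_samples={F.n_samples}"
        )
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")

    X = F.values  # genes x samples; FastICA centres/whitens internally
    comps, runs, seeds, conv = [], [], [], []
    for r in range(n_runs):
        seed = base_seed + r
        ica = FastICA(
            n_components=k,
            tol=tol,
            max_iter=max_iter,
            whiten="unit-variance",
            random_state=seed,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            S = ica.fit_transform(X)  # genes x k
            ok = not any(
                issubclass(w.category, ConvergenceWarning) for w in caught
            )
        if strict and not ok:
            continue
        norms = np.linalg.norm(S, axis=0)
        norms[norms == 0] = 1.0
        S = S / norms
        for j in range(k):
            comps.append(S[:, j])
            runs.append(r)
            seeds.append(seed)
            conv.append(ok)
    return ComponentEnsemble(
        components=np.asarray(comps),
        run_index=np.asarray(runs),
        seeds=np.asarray(seeds),
        converged=np.asarray(conv),
        n_runs=n_runs,
        dimension=k,
        tol=tol,
    )


def component_distance(
    x: np.ndarray, y: np.ndarray, sign_mode: str = "absolute"
) -> float:
    """Correlation distance between two components.

    ``signed`` returns 1 - rho (range [0, 2]); ``absolute`` returns
    1 - |rho| (range [0, 1]), which treats a component and its negation as
    identical — ICA determines sources only up to sign.
    """
    _check_sign_mode(sign_mode)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("components must be equal-length vectors (>=3)")
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ValueError("zero-variance component has no defined correlation")
    rho = float(xc @ yc / (nx * ny))
    rho = max(-1.0, min(1.0, rho))
    return 1.0 - abs(rho) if sign_mode == "absolute" else 1.0 - rho


def pairwise_distances(
    components: np.ndarray, sign_mode: str = "absolute"
) -> np.ndarray:
    """Full pairwise correlation-distance matrix, vectorised."""
    _check_sign_mode(sign_mode)
    X = np.asarray(components, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-variance component in ensemble")
    C = (Xc / norms[:, None]) @ (Xc / norms[:, None]).T
    C = np.clip(C, -1.0, 1.0)
    D = 1.0 - (np.abs(C) if sign_mode == "absolute" else C)
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


def default_min_size(n_runs: int) -> int:
    """Minimum cluster size: 50 for the canonical 100-run ensemble,
    scaled as ceil(n_runs / 2) otherwise."""
    return 50 if n_runs == 100 else math.ceil(0.5 * n_runs)


def cluster_components(
    ensemble: ComponentEnsemble,
    eps: float = 0.1,
    min_size: int | None = None,
    sign_mode: str = "absolute",
) -> list[np.ndarray]:
    """DBSCAN on the precomputed distance matrix.

    Returns the member indices of each cluster of size >= ``min_size``
    (default scales the canonical 50-of-100 ratio to the ensemble size);
    noise points are discarded.  Cluster order follows the smallest member
    index, so output is deterministic.
    """
    if len(ensemble) == 0:
        raise ValueError("empty component ensemble")
    if min_size is None:
        min_size = default_min_size(ensemble.n_runs)
    D = pairwise_distances(ensemble.components, sign_mode)
    labels = DBSCAN(eps=eps, min_samples=min_size, metric="precomputed").fit(
        D
    ).labels_
    clusters = []
    for lab in sorted(set(labels) - {-1}):
        idx = np.flatnonzero(labels == lab)
        if idx.size >= min_size:
            clusters.append(idx)
    clusters.sort(key=lambda idx: int(idx[0]))
    return clusters


def robust_centroids(
    clusters: list[np.ndarray],
    ensemble: ComponentEnsemble,
    F: FitnessMatrix,
    sign_mode: str = "absolute",
    center: bool = True,
) -> RobustDecomposition:
    """Average each cluster into a robust component and recompute activities.

    Members are sign-aligned to the cluster's first member (flipped when
    their correlation with it is negative), averaged elementwise and
    re-normalised; the column sign is fixed so the largest-magnitude gene
    weight is positive.  Activities are the joint least-squares solution of
    F ~ M A on the column-centred matrix.
    """
    _check_sign_mode(sign_mode)
    n_genes = F.n_genes
    cols, sizes, mean_rho = [], [], []
    for idx in clusters:
        members = ensemble.components[idx].copy()
        ref = members[0]
        refc = ref - ref.mean()
        for i in range(1, members.shape[0]):
            m = members[i]
            rho = float((m - m.mean()) @ refc)
            if sign_mode == "absolute" and rho < 0:
                members[i] = -m
        centroid = members.mean(axis=0)
        norm = np.linalg.norm(centroid)
        if norm == 0:
            continue  # perfectly cancelling cluster; cannot orient
        centroid = centroid / norm
        if centroid[np.argmax(np.abs(centroid))] < 0:
            centroid = -centroid
        cols.append(centroid)
        sizes.append(int(len(idx)))
        Dsub = pairwise_distances(members, sign_mode="signed")
        n = len(idx)
        rho_bar = 1.0 if n == 1 else float(
            1.0 - Dsub[np.triu_indices(n, 1)].mean()
        )
        mean_rho.append(rho_bar)

    M = (
        np.column_stack(cols)
        if cols
        else np.empty((n_genes, 0))
    )
    # Every restart's components lie in the same k-dim whitened subspace,
    # so more than k clusters (or rotated noise directions) make M exactly
    # rank deficient.  Keep a maximal independent column set, larger
    # clusters first.
    n_pruned = 0
    if M.shape[1] > 1:
        keep = _independent_columns(M, sizes)
        n_pruned = M.shape[1] - len(keep)
        M = M[:, keep]
        sizes = [sizes[j] for j in keep]
        mean_rho = [mean_rho[j] for j in keep]
    if M.shape[1] > 0:
        A, residual = compute_activities(F, M, center=center)
    else:
        A, residual = np.empty((0, F.n_samples)), float("nan")
    return RobustDecomposition(
        M=M,
        A=A,
        cluster_sizes=sizes,
        mean_within_correlation=mean_rho,
        dimension=ensemble.dimension,
        gene_ids=list(F.gene_ids),
        sample_ids=list(F.sample_ids),
        residual=residual,
        provenance={"n_pruned_dependent": n_pruned},
    )


def centered_values(F: FitnessMatrix) -> np.ndarray:
    """Column-centred fitness values (the centring FastICA applies)."""
    return F.values - F.values.mean(axis=0, keepdims=True)


def compute_activities(
    F: FitnessMatrix, M: np.ndarray, center: bool = True
) -> tuple[np.ndarray, float]:
    """Least-squares activities: A = argmin ||F - M A||_F.

    Solved per sample via the pseudo-inverse on the column-centred matrix
    (matching the decomposition's centring convention).  Rank-deficient M
    is a hard error naming the collinear column pairs.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != F.n_genes:
        raise ValueError("M must be genes x components")
    if M.shape[1] == 0:
        return np.empty((0, F.n_samples)), float("nan")
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        pairs = _collinear_pairs(M)
        raise ValueError(
            f"gene-weight matrix is rank deficient (rank {rank} < "
            f"{M.shape[1]} columns); collinear column pairs: {pairs}"
        )
    X = centered_values(F) if center else F.values
    A = np.linalg.lstsq(M, X, rcond=None)[0]
    residual = float(np.linalg.norm(X - M @ A))
    return A, residual


def decompose(
    F: FitnessMatrix,
    k: int,
    n_runs: int = 100,
    tol: float = 1e-7,
    base_seed: int = 0,
    eps: float = 0.1,
    min_size: int | None = None,
    sign_mode: str = "absolute",
    max_iter: int = 1000,
) -> RobustDecomposition:
    """Full robust decomposition: restart ensemble -> DBSCAN -> centroids."""
    ensemble = run_ica_ensemble(
        F, k, n_runs=n_runs, tol=tol, base_seed=base_seed, max_iter=max_iter
    )
    clusters = cluster_components(
        ensemble, eps=eps, min_size=min_size, sign_mode=sign_mode
    )
    dec = robust_centroids(clusters, ensemble, F, sign_mode=sign_mode)
    dec.provenance = dec.provenance | {
        "dimension": k,
        "n_runs": n_runs,
        "tol": tol,
        "base_seed": base_seed,
        "eps": eps,
        "min_size": (
            min_size if min_size is not None else default_min_size(n_runs)
        ),
        "sign_mode": sign_mode,
        "n_converged_runs": int(
            len(set(ensemble.run_index[ensemble.converged].tolist()))
        ),
    }
    return dec


def _independent_columns(
    M: np.ndarray, sizes: list[int], tol: float = 1e-8
) -> list[int]:
    """Greedy maximal linearly independent column subset.

    Columns are considered in order of descending cluster size (original
    order on ties); a column is kept if its residual after projection onto
    the kept set exceeds ``tol`` (columns are unit norm).
    """
    order = sorted(range(M.shape[1]), key=lambda j: (-sizes[j], j))
    kept: list[int] = []
    for j in order:
        if not kept:
            kept.append(j)
            continue
        B = M[:, kept]
        coef = np.linalg.lstsq(B, M[:, j], rcond=None)[0]
        if np.linalg.norm(M[:, j] - B @ coef) > tol:
            kept.append(j)
    return sorted(kept)


def _collinear_pairs(M: np.ndarray, tol: float = 1e-8) -> list[tuple[int, int]]:
    norms = np.linalg.norm(M, axis=0)
    norms[norms == 0] = 1.0
    C = np.abs((M / norms).T @ (M / norms))
    out = []
    for i in range(M.shape[1]):
        for j in range(i + 1, M.shape[1]):
            if C[i, j] > 1 - tol:
                out.append((i, j))
    return out


def _check_sign_mode(sign_mode: str) -> None:
    if sign_mode not in SIGN_MODES:
        raise ValueError(
            f"sign_mode must be one of {SIGN_MODES}, got {sign_mode!r}"
        )
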