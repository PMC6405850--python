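"""Loop-conformation landscape: coordinate matrix, PCA, density clustering.

The procedure: extract the loop backbone (N, CA, C, O) from one or more
ensembles, superpose each frame on a common reference so only internal loop
motion remains, flatten to an F×3A matrix, fit a full-rank PCA, project, and
cluster the projection with HDBSCAN using a minimum cluster size of a fixed
fraction (default 1%) of the total frame count. Representative conformers
are cluster medoids. For an 18-residue loop the backbone selection is 72
atoms and the matrix has 216 columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import floor

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN

from .structure_io import BACKBONE_ORDER, ConformationEnsemble, select_atoms


def loop_matrix(
    ensembles: list[ConformationEnsemble],
    chain: str,
    res_range: tuple[int, int],
    atom_names: tuple[str, ...] = BACKBONE_ORDER,
    align: str = "scaffold_ca",
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenated loop-backbone coordinate matrix across ensembles.

    Frames are first superposed onto the first frame of the first ensemble:
    with ``align='scaffold_ca'`` the fit uses Cα atoms OUTSIDE the loop range
    (so the PCA sees loop motion relative to the body, not global tumbling),
    falling back to the loop selection itself when no scaffold exists (pure
    loop ensembles); ``align='loop'`` fits on the selection; ``align='none'``
    skips superposition.

    Returns
    -------
    matrix : (F_total, 3A) array; row order = frame order within each
        ensemble, ensembles in input order; columns = (atom, x/y/z) in
        selection order.
    sources : (F_total,) array of each row's ensemble ``source_id``.
    """
    if not ensembles:
        raise ValueError("need at least one ensemble")
    if align not in ("scaffold_ca", "loop", "none"):
        raise ValueError(f"unknown align mode {align!r}")

    selections = []
    for ens in ensembles:
        sel = select_atoms(ens, chain=chain, res_range=res_range,
                           atom_names=atom_names)
        selections.append(sel)
    layout = [(a.res_seq, a.atom_name) for a in selections[0].atoms]
    for ens, sel in zip(ensembles, selections):
        if [(a.res_seq, a.atom_name) for a in sel.atoms] != layout:
            raise ValueError(
                f"ensemble {ens.source_id!r} loop atom layout differs from "
                f"{ensembles[0].source_id!r}"
            )

    # indices of the fit atoms inside each FULL ensemble, plus loop indices
    blocks = []
    sources = []
    ref_full = None
    ref_fit_idx = None
    for ens, sel in zip(ensembles, selections):
        loop_idx = np.array([ens.atom_index(a.chain, a.res_seq, a.atom_name)
                             for a in sel.atoms])
        if align == "none":
            fit_idx = None
        elif align == "loop":
            fit_idx = loop_idx
        else:
            scaffold = [i for i, a in enumerate(ens.atoms)
                        if a.atom_name == "CA" and a.chain == chain
                        and not (res_range[0] <= a.res_seq <= res_range[1])]
            fit_idx = np.array(scaffold) if len(scaffold) >= 3 else loop_idx
        if ref_full is None:
            ref_full = ens.coords[0]
            ref_fit_idx = fit_idx
        frames = np.empty((ens.n_frames, loop_idx.size, 3))
        for t in range(ens.n_frames):
            if fit_idx is None:
                frames[t] = ens.coords[t][loop_idx]
            else:
                moved = _superpose_onto(ens.coords[t], ref_full,
                                        fit_idx, ref_fit_idx)
                frames[t] = moved[loop_idx]
        blocks.append(frames.reshape(ens.n_frames, -1))
        sources.extend([ens.source_id] * ens.n_frames)
    return np.vstack(blocks), np.array(sources)


def _superpose_onto(mobile_full, ref_full, fit_idx, ref_fit_idx):
    """Fit mobile's fit atoms onto the reference's, apply to all atoms."""
    from .ensemble_metrics import kabsch_rotation
    r, cm, cr = kabsch_rotation(mobile_full[fit_idx], ref_full[ref_fit_idx])
    return (mobile_full - cm) @ r.T + cr


@dataclass
class PCAModel:
    """Full-rank PCA of the loop coordinate space.

    ``components`` is an orthonormal 3A×3A matrix, rows = principal axes in
    descending eigenvalue order; rank-deficient directions carry zero
    eigenvalue. ``variance_fraction`` sums to 1.
    """

    mean: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray

    def project(self, matrix: np.ndarray, n_components: int | None = None) -> np.ndarray:
        k = self.components.shape[0] if n_components is None else n_components
        return (np.asarray(matrix) - self.mean) @ self.components[:k].T

    def reconstruct(self, projected: np.ndarray) -> np.ndarray:
        k = projected.shape[1]
        return projected @ self.components[:k] + self.mean


def fit_pca(matrix: np.ndarray) -> PCAModel:
    """Eigendecomposition of the covariance of mean-centred rows.

    Uses the full 3A×3A covariance so every principal axis is reported, even
    when F < 3A (those directions get exactly-zero eigenvalues, clipped at 0
    against round-off).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("PCA needs a 2-D matrix with at least 2 rows")
    mean = matrix.mean(axis=0)
    centered = matrix - mean
    cov = centered.T @ centered / (matrix.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    components = evecs[:, order].T
    total = evals.sum()
    frac = evals / total if total > 0 else np.zeros_like(evals)
    return PCAModel(mean=mean, components=components, eigenvalues=evals,
                    variance_fraction=frac)


def min_cluster_size(n_frames: int, fraction: float = 0.01) -> int:
    """Minimum cluster size as a fraction of total frames, round-half-up.

    Floor of 2 (HDBSCAN cannot form singleton clusters). 8993 frames at the
    default 1% gives 90.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if fraction <= 0:
        raise ValueError("fraction must be positive")
    return max(2, floor(fraction * n_frames + 0.5))


@dataclass
class ClusterAssignment:
    """Density-clustering result: −1 labels noise; clusters sorted by size."""

    labels: np.ndarray
    n_clusters: int
    sizes: np.ndarray  # per cluster, descending
    min_size: int

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def cluster_conformations(projected: np.ndarray, min_size: int,
                          min_samples: int | None = None,
                          allow_single_cluster: bool = True) -> ClusterAssignment:
    """HDBSCAN over projected coordinates (Euclidean, noise allowed).

    ``min_samples`` defaults to ``min_size``, the reference implementation's
    default behaviour. ``allow_single_cluster`` is on so a degenerate
    one-basin landscape reports one cluster instead of dissolving into
    noise (excess-of-mass selection never picks the root otherwise).
    Clusters are relabelled 0-based by descending size.
    """
    projected = np.asarray(projected, dtype=float)
    if projected.ndim == 1:
        projected = projected[:, None]
    f = projected.shape[0]
    if f < min_size:
        warnings.warn(
            f"{f} frames < min cluster size {min_size}; everything is noise",
            stacklevel=2,
        )
        return ClusterAssignment(labels=np.full(f, -1), n_clusters=0,
                                 sizes=np.array([], dtype=int), min_size=min_size)
    model = HDBSCAN(min_cluster_size=min_size,
                    min_samples=min_samples if min_samples is not None else min_size,
                    allow_single_cluster=allow_single_cluster,
                    copy=True)
    raw = model.fit_predict(projected)
    # relabel by descending size, ties by original label for determinism
    uniq = [l for l in np.unique(raw) if l != -1]
    sizes = {l: int(np.sum(raw == l)) for l in uniq}
    order = sorted(uniq, key=lambda l: (-sizes[l], l))
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap.get(l, -1) for l in raw])
    return ClusterAssignment(
        labels=labels,
        n_clusters=len(order),
        sizes=np.array([sizes[l] for l in order], dtype=int),
        min_size=min_size,
    )


def cluster_medoid(assignment: ClusterAssignment, matrix: np.ndarray
                   ) -> dict[int, int]:
    """Medoid frame per cluster: member minimising summed Euclidean distance
    to co-members in the clustering coordinate space; ties → lowest index."""
    matrix = np.asarray(matrix, dtype=float)
    medoids: dict[int, int] = {}
    for cl in range(assignment.n_clusters):
        idx = assignment.members(cl)
        sub = matrix[idx]
        d = np.sqrt(((sub[:, None, :] - sub[None, :, :]) ** 2).sum(axis=2))
        totals = d.sum(axis=1)
        best = int(idx[np.argmin(totals)])  # argmin takes first on ties
        medoids[cl] = best
    return medoids


def cluster_occupancy_table(assignment: ClusterAssignment,
                            sources: np.ndarray) -> pd.DataFrame:
    """Frames per (source, cluster) with fractions; noise under column −1.

    Mirrors per-system cluster-exploration summaries: a zero entry means the
    source never visits that cluster; shared clusters show both sources
    nonzero.
    """
    sources = np.asarray(sources)
    cols = list(range(assignment.n_clusters)) + [-1]
    rows = {}
    for src in pd.unique(sources):
        mask = sources == src
        rows[src] = [int(np.sum(assignment.labels[mask] == c)) for c in cols]
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    counts.index.name = "source"
    fractions = counts.div(counts.sum(axis=1), axis=0)
    name = lambda c: "noise" if c == -1 else f"cluster_{c}"
    counts.columns = [name(c) for c in cols]
    fractions.columns = [name(c) + "_frac" for c in cols]
    return counts.join(fractions)
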