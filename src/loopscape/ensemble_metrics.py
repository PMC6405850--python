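"""Superposition and fluctuation metrics over conformational ensembles.

Implements least-squares rigid superposition (Kabsch), per-frame RMSD series,
per-residue RMSF about an iteratively refined mean structure, and backbone
φ/ψ/ω dihedral series, with optional block averaging so values can be
reported per fixed time window (e.g. 500 ps) via the ensemble's
frame-interval metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structure_io import ConformationEnsemble


@dataclass
class SeriesBlock:
    """A per-frame series with block-averaged summaries.

    ``block_means`` holds the mean of each window of ``block_size`` frames;
    a trailing partial window is retained and flagged by ``last_partial``.
    """

    values: np.ndarray
    block_size: int
    block_means: np.ndarray
    last_partial: bool


def block_average(values: np.ndarray, block_size: int) -> SeriesBlock:
    values = np.asarray(values, dtype=float)
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    n = values.shape[0]
    n_full = n // block_size
    means = []
    for k in range(n_full):
        means.append(values[k * block_size:(k + 1) * block_size].mean(axis=0))
    last_partial = n % block_size != 0
    if last_partial:
        means.append(values[n_full * block_size:].mean(axis=0))
    return SeriesBlock(values=values, block_size=block_size,
                       block_means=np.array(means), last_partial=last_partial)


def _check_fit_selection(ref: np.ndarray) -> None:
    if ref.shape[0] < 3:
        raise ValueError("superposition needs at least 3 fit atoms")
    centered = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("fit atoms are collinear; rotation is ill-determined")


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation mapping mobile onto reference.

    Returns (R, mobile_centroid, reference_centroid) such that
    ``(x - mobile_centroid) @ R.T + reference_centroid`` is the superposed
    position of x. det(R) = +1 always (reflections are excluded).
    """
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    h = (mobile - cm).T @ (reference - cr)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    return r, cm, cr


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_selection: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Superpose ``mobile`` onto ``reference`` and return (coords, fit RMSD).

    The rotation/translation minimise the RMSD over ``fit_selection`` (all
    atoms if None); the transform is then applied to every atom. The returned
    RMSD is the global minimum over rigid motions and is computed over the
    fit selection.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have the same shape")
    sel = np.arange(mobile.shape[0]) if fit_selection is None else np.asarray(fit_selection)
    _check_fit_selection(reference[sel])
    r, cm, cr = kabsch_rotation(mobile[sel], reference[sel])
    moved = (mobile - cm) @ r.T + cr
    rmsd = float(np.sqrt(np.mean(np.sum((moved[sel] - reference[sel]) ** 2, axis=1))))
    return moved, rmsd


def rmsd_series(
    ens: ConformationEnsemble,
    reference_frame: int = 0,
    fit_selection: np.ndarray | None = None,
    block_size: int | None = None,
) -> SeriesBlock:
    """Per-frame RMSD to a reference frame after per-frame superposition."""
    if not -ens.n_frames <= reference_frame < ens.n_frames:
        raise IndexError(
            f"reference frame {reference_frame} outside 0..{ens.n_frames - 1}"
        )
    ref = ens.coords[reference_frame]
    vals = np.empty(ens.n_frames)
    for t in range(ens.n_frames):
        _, vals[t] = kabsch_superpose(ens.coords[t], ref, fit_selection)
    return block_average(vals, block_size or 1)


def superpose_ensemble(
    ens: ConformationEnsemble,
    reference: np.ndarray,
    fit_selection: np.ndarray | None = None,
) -> np.ndarray:
    """Superpose every frame onto a reference coordinate set."""
    out = np.empty_like(ens.coords)
    for t in range(ens.n_frames):
        out[t], _ = kabsch_superpose(ens.coords[t], reference, fit_selection)
    return out


def iterative_mean_structure(
    coords: np.ndarray,
    fit_selection: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose frames onto their mean, recompute, iterate to convergence.

    Returns (superposed frames, mean structure). Convergence: the mean moves
    by less than ``tol`` Å (RMS over atoms) between iterations.
    """
    frames = np.asarray(coords, dtype=float).copy()
    mean = frames[0].copy()
    for _ in range(max_iter):
        for t in range(frames.shape[0]):
            sel = np.arange(frames.shape[1]) if fit_selection is None else fit_selection
            r, cm, cr = kabsch_rotation(frames[t][sel], mean[sel])
            frames[t] = (frames[t] - cm) @ r.T + cr
        new_mean = frames.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < tol:
            break
    return frames, mean


def rmsf_per_residue(
    ens: ConformationEnsemble,
    fit_selection: np.ndarray | None = None,
    measure_atom: str = "CA",
    block_size: int | None = None,
) -> "pd.DataFrame":
    """Per-residue RMSF (Å) of one atom per residue about the mean structure.

    Frames are superposed onto an iteratively refined mean over
    ``fit_selection`` (default: all atoms; pass scaffold Cα indices to
    measure loop motion relative to the body). With ``block_size`` the RMSF
    is computed within each block of frames and then averaged across blocks,
    which reports fast fluctuation rather than slow drift.
    """
    import pandas as pd

    if ens.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    frames, mean = iterative_mean_structure(ens.coords, fit_selection)
    midx = [i for i, a in enumerate(ens.atoms) if a.atom_name == measure_atom]
    if not midx:
        raise ValueError(f"no {measure_atom!r} atoms in ensemble")

    def _rmsf(fr: np.ndarray, ref: np.ndarray) -> np.ndarray:
        dev = fr[:, midx, :] - ref[midx]
        return np.sqrt(np.mean(np.sum(dev ** 2, axis=2), axis=0))

    if block_size is None or block_size >= frames.shape[0]:
        vals = _rmsf(frames, mean)
    else:
        blocks = []
        for k in range(0, frames.shape[0], block_size):
            chunk = frames[k:k + block_size]
            if chunk.shape[0] < 2:
                continue
            blocks.append(_rmsf(chunk, chunk.mean(axis=0)))
        vals = np.mean(blocks, axis=0)
    recs = [ens.atoms[i] for i in midx]
    return pd.DataFrame({
        "chain": [a.chain for a in recs],
        "res_seq": [a.res_seq for a in recs],
        "res_name": [a.res_name for a in recs],
        "rmsf_ang": vals,
    })


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
             ) -> np.ndarray:
    """Signed dihedral angle (degrees, IUPAC convention) for stacked points."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=-1, keepdims=True))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    return np.where(ang <= -180.0, ang + 360.0, ang)


def backbone_dihedrals(ens: ConformationEnsemble) -> dict[str, np.ndarray]:
    """φ, ψ, ω series in degrees; NaN where the flanking residue is missing.

    Returns arrays of shape (F, n_res): ``phi[i]`` needs residue i−1's C
    (NaN for the first residue), ``psi[i]`` / ``omega[i]`` need residue
    i+1's N/CA (NaN for the last). Angles lie in (−180, 180]. ω of residue i
    is the peptide bond between residues i and i+1.
    """
    residues: dict[tuple[str, int], dict[str, int]] = {}
    for i, a in enumerate(ens.atoms):
        residues.setdefault((a.chain, a.res_seq), {})[a.atom_name] = i
    keys = sorted(residues, key=lambda k: (k[0], k[1]))
    n_res = len(keys)
    f = ens.n_frames
    phi = np.full((f, n_res), np.nan)
    psi = np.full((f, n_res), np.nan)
    omega = np.full((f, n_res), np.nan)
    c = ens.coords

    def has(k, *names):
        return all(n in residues[k] for n in names)

    for r, key in enumerate(keys):
        cur = residues[key]
        if not has(key, "N", "CA", "C"):
            warnings.warn(f"residue {key} missing backbone atoms; dihedrals NaN",
                          stacklevel=2)
            continue
        prev_key = keys[r - 1] if r > 0 else None
        next_key = keys[r + 1] if r + 1 < n_res else None
        consecutive_prev = prev_key is not None and prev_key[0] == key[0]
        consecutive_next = next_key is not None and next_key[0] == key[0]
        if consecutive_prev and "C" in residues[prev_key]:
            phi[:, r] = dihedral(c[:, residues[prev_key]["C"]], c[:, cur["N"]],
                                 c[:, cur["CA"]], c[:, cur["C"]])
        if consecutive_next and "N" in residues[next_key]:
            psi[:, r] = dihedral(c[:, cur["N"]], c[:, cur["CA"]],
                                 c[:, cur["C"]], c[:, residues[next_key]["N"]])
            if "CA" in residues[next_key]:
                omega[:, r] = dihedral(c[:, cur["CA"]], c[:, cur["C"]],
                                       c[:, residues[next_key]["N"]],
                                       c[:, residues[next_key]["CA"]])
    return {"phi": phi, "psi": psi, "omega": omega,
            "residues": np.array([k[1] for k in keys])}


def circular_mean_deg(angles: np.ndarray, axis: int = 0) -> np.ndarray:
    """Mean of angles in degrees respecting wrap-around at ±180."""
    rad = np.deg2rad(angles)
    return np.degrees(np.arctan2(np.nanmean(np.sin(rad), axis=axis),
                                 np.nanmean(np.cos(rad), axis=axis)))
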