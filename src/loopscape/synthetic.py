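"""Synthetic inputs with known ground truth for every pipeline stage.

Real serpin trajectories and raw assay traces are rarely shareable, so each
downstream analysis here is exercised on generated data whose true answer is
known by construction: loop ensembles hopping between conformational basins
under a Markov chain, two-state salt-bridge distance series with a known
stationary occupancy, Boltzmann-sigmoid melt curves, linear residual-activity
inhibition assays, and alignments with planted conserved and covarying
columns. All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure_io import AtomRecord, ConformationEnsemble

# Engh–Huber-like ideal backbone geometry (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural extension reference frame: place atom d from a-b-c internals."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    # z-component negated so the placed torsion matches the IUPAC sign
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.cos(dihedral) * np.sin(angle),
        -bond * np.sin(dihedral) * np.sin(angle),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(dihedral_template: np.ndarray | list) -> np.ndarray:
    """Build an ideal-geometry backbone chain from per-residue (φ, ψ, ω).

    Parameters
    ----------
    dihedral_template:
        (n_res, 3) array of (phi, psi, omega) in degrees. The first residue's
        phi and the last residue's psi/omega do not affect any placed atom
        but slots must be present.

    Returns
    -------
    (n_res * 4, 3) array of N, CA, C, O coordinates per residue, in that
    order, Å. Deterministic.
    """
    tpl = np.asarray(dihedral_template, dtype=float)
    if tpl.ndim != 2 or tpl.shape[1] != 3:
        raise ValueError("dihedral template must be (n_res, 3) of (phi, psi, omega)")
    n_res = tpl.shape[0]
    if n_res < 1:
        raise ValueError("need at least one residue")

    coords = np.zeros((n_res, 4, 3))  # N, CA, C, O
    # first residue laid out in the xy-plane
    coords[0, 0] = (0.0, 0.0, 0.0)
    coords[0, 1] = (BOND_N_CA, 0.0, 0.0)
    ang = np.deg2rad(ANGLE_N_CA_C)
    coords[0, 2] = coords[0, 1] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n_res):
        phi_next = tpl[i + 1, 0] if i + 1 < n_res else None
        psi, omega = tpl[i, 1], tpl[i, 2]
        n_i, ca_i, c_i = coords[i, 0], coords[i, 1], coords[i, 2]
        if i + 1 < n_res:
            n_next = _place_atom(n_i, ca_i, c_i, BOND_C_N, ANGLE_CA_C_N, psi)
            coords[i + 1, 0] = n_next
            coords[i + 1, 1] = _place_atom(ca_i, c_i, n_next,
                                           BOND_N_CA, ANGLE_C_N_CA, omega)
            coords[i + 1, 2] = _place_atom(c_i, n_next, coords[i + 1, 1],
                                           BOND_CA_C, ANGLE_N_CA_C, phi_next)
            # carbonyl O anti to the next N across the peptide plane
            coords[i, 3] = _place_atom(n_i, ca_i, c_i,
                                       BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        else:
            coords[i, 3] = _place_atom(n_i, ca_i, c_i,
                                       BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
    return coords.reshape(n_res * 4, 3)


def backbone_atom_records(n_res: int, chain: str = "A", first_res: int = 1,
                          res_name: str = "ALA") -> list[AtomRecord]:
    """Topology matching :func:`build_backbone` output order."""
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O"}
    return [
        AtomRecord(chain=chain, res_seq=first_res + i, res_name=res_name,
                   atom_name=name, element=elements[name])
        for i in range(n_res)
        for name in ("N", "CA", "C", "O")
    ]


@dataclass(frozen=True)
class BasinSpec:
    """One conformational basin: a dihedral template plus Gaussian jitter."""

    dihedral_template: tuple  # (n_res, 3) nested tuples, degrees
    jitter_sigma: float = 0.3  # Å per coordinate
    weight: float = 1.0

    def __post_init__(self):
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")


@dataclass(frozen=True)
class EnsembleSpec:
    """Markov-switching multi-basin loop ensemble specification."""

    n_res: int
    basins: tuple
    stay_prob: float = 0.95
    n_frames: int = 1000
    seed: int = 0
    pose_rotation_deg: float = 0.0
    pose_translation_ang: float = 0.0
    frame_interval_ps: float = 500.0
    source_id: str = "synthetic"

    def __post_init__(self):
        if not 0.0 <= self.stay_prob <= 1.0:
            raise ValueError("stay_prob must be in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def helix_template(n_res: int, phi: float = -60.0, psi: float = -45.0,
                   omega: float = 180.0) -> tuple:
    return tuple((phi, psi, omega) for _ in range(n_res))


def _random_rotation(rng: np.random.Generator, sigma_deg: float) -> np.ndarray:
    """Small random rotation: axis uniform on the sphere, angle ~ N(0, σ)."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.normal(0.0, sigma_deg))
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def _markov_states(rng: np.random.Generator, weights: np.ndarray,
                   stay_prob: float, n: int) -> np.ndarray:
    """Chain: with prob stay_prob keep state, else resample from weights.

    Diagonal mass = stay_prob + (1 - stay_prob) w_i, off-diagonal mass
    proportional to the weights; stationary distribution is exactly w.
    """
    states = np.empty(n, dtype=int)
    states[0] = rng.choice(len(weights), p=weights)
    resample = rng.random(n) >= stay_prob
    draws = rng.choice(len(weights), size=n, p=weights)
    for t in range(1, n):
        states[t] = draws[t] if resample[t] else states[t - 1]
    return states


def sample_ensemble(spec: EnsembleSpec) -> tuple[ConformationEnsemble, np.ndarray]:
    """Draw a loop ensemble; returns the ensemble and true per-frame basin labels."""
    if len(spec.basins) == 0:
        raise ValueError("ensemble spec needs at least one basin")
    weights = np.array([b.weight for b in spec.basins], dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("basin weights must be non-negative and sum > 0")
    weights = weights / weights.sum()
    rng = np.random.default_rng(spec.seed)

    templates = []
    for b in spec.basins:
        tpl = np.asarray(b.dihedral_template, dtype=float)
        if tpl.shape[0] != spec.n_res:
            raise ValueError("basin template length differs from n_res")
        templates.append(build_backbone(tpl))

    labels = _markov_states(rng, weights, spec.stay_prob, spec.n_frames)
    n_atoms = spec.n_res * 4
    coords = np.empty((spec.n_frames, n_atoms, 3))
    for t in range(spec.n_frames):
        b = spec.basins[labels[t]]
        frame = templates[labels[t]].copy()
        if b.jitter_sigma > 0:
            frame = frame + rng.normal(0.0, b.jitter_sigma, size=frame.shape)
        if spec.pose_rotation_deg > 0:
            centroid = frame.mean(axis=0)
            rot = _random_rotation(rng, spec.pose_rotation_deg)
            frame = (frame - centroid) @ rot.T + centroid
        if spec.pose_translation_ang > 0:
            frame = frame + rng.normal(0.0, spec.pose_translation_ang, size=3)
        coords[t] = frame
    ens = ConformationEnsemble(
        coords=coords,
        atoms=backbone_atom_records(spec.n_res),
        frame_interval_ps=spec.frame_interval_ps,
        source_id=spec.source_id,
    )
    return ens, labels


def simulate_saltbridge_series(
    p_formed: float,
    stay_prob: float = 0.95,
    d_on: float = 3.0,
    d_off: float = 6.0,
    noise_sd: float = 0.1,
    n: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Two-state (formed/broken) distance series with stationary P(formed).

    Distances are the state level (``d_on`` formed, ``d_off`` broken) plus
    Gaussian noise; a downstream occupancy estimate at a cutoff between the
    two levels should recover ``p_formed``.
    """
    if not 0.0 <= p_formed <= 1.0:
        raise ValueError("p_formed must be in [0, 1]")
    rng = np.random.default_rng(seed)
    weights = np.array([p_formed, 1.0 - p_formed])
    states = _markov_states(rng, weights, stay_prob, n)
    levels = np.where(states == 0, d_on, d_off)
    if noise_sd > 0:
        levels = levels + rng.normal(0.0, noise_sd, size=n)
    return levels


def saltbridge_ensemble_from_series(
    distances: np.ndarray,
    acidic_res: tuple[int, str] = (342, "GLU"),
    basic_res: tuple[int, str] = (290, "LYS"),
    chain: str = "A",
    source_id: str = "synthetic-saltbridge",
) -> ConformationEnsemble:
    """Minimal two-residue ensemble realising a charged-atom distance series.

    The acidic carboxylate oxygen sits at the origin; the basic nitrogen sits
    at (d, 0, 0) in frame t. Enough topology for occupancy analysis, nothing
    more (synthetic stand-in; no real side-chain geometry).
    """
    distances = np.asarray(distances, dtype=float)
    acid_atoms = {"GLU": "OE1", "ASP": "OD1"}[acidic_res[1]]
    base_atoms = {"LYS": "NZ", "ARG": "NH1", "HIS": "NE2"}[basic_res[1]]
    atoms = [
        AtomRecord(chain, acidic_res[0], acidic_res[1], "CA", "C"),
        AtomRecord(chain, acidic_res[0], acidic_res[1], acid_atoms, "O"),
        AtomRecord(chain, basic_res[0], basic_res[1], "CA", "C"),
        AtomRecord(chain, basic_res[0], basic_res[1], base_atoms, "N"),
    ]
    f = distances.shape[0]
    coords = np.zeros((f, 4, 3))
    coords[:, 0, 0] = -1.5  # acidic CA, inert
    coords[:, 2, 0] = distances + 1.5  # basic CA, inert
    coords[:, 3, 0] = distances
    return ConformationEnsemble(coords=coords, atoms=atoms, source_id=source_id)


def simulate_melt(
    tm: float,
    slope: float,
    base_folded: float,
    base_unfolded: float,
    noise_sd: float = 0.0,
    temps: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Boltzmann-sigmoid thermal melt: columns ``temperature_C``, ``signal``.

    signal(T) = b_f + (b_u − b_f) / (1 + exp((tm − T)/slope)) + ε.
    """
    if slope == 0:
        raise ValueError("slope must be nonzero")
    if temps is None:
        temps = np.arange(35.0, 95.5, 1.0)
    temps = np.asarray(temps, dtype=float)
    if np.any(np.diff(temps) <= 0):
        raise ValueError("temperatures must be strictly ascending")
    rng = np.random.default_rng(seed)
    signal = base_folded + (base_unfolded - base_folded) / (
        1.0 + np.exp((tm - temps) / slope)
    )
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=temps.shape)
    return pd.DataFrame({"temperature_C": temps, "signal": signal})


def simulate_inhibition_assay(
    si: float,
    ratios: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    replicates: int = 3,
) -> pd.DataFrame:
    """Residual protease activity vs serpin:protease ratio, zero-floored.

    a(r) = max(0, 1 − r/SI) + ε; columns ``ratio``, ``residual_activity``.
    Each reported activity is the mean of ``replicates`` noisy measurements,
    emulating the usual triplicate experimental design (``noise_sd`` is the
    per-replicate noise).
    """
    if si <= 0:
        raise ValueError("stoichiometry of inhibition must be positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if ratios is None:
        ratios = np.arange(0.0, 2.01, 0.25)
    ratios = np.asarray(ratios, dtype=float)
    rng = np.random.default_rng(seed)
    activity = np.maximum(0.0, 1.0 - ratios / si)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=(replicates, ratios.size))
        activity = activity + noise.mean(axis=0)
    return pd.DataFrame({"ratio": ratios, "residual_activity": activity})


AA20 = "ACDEFGHIKLMNPQRSTVWY"


def simulate_msa(
    n_seq: int,
    n_col: int,
    conserved_cols: dict[int, str] | None = None,
    covary_pairs: list[tuple[int, int, float]] | None = None,
    background_freqs: dict[str, float] | None = None,
    seed: int = 0,
    ids_prefix: str = "seq",
):
    """Alignment with planted conserved columns and covarying column pairs.

    Independent columns draw i.i.d. from the background; a conserved column
    is fixed to one residue; a covarying pair (i, j, coupling) draws from a
    mixture: with probability ``coupling`` the pair is perfectly coupled
    (j's residue a fixed permutation of i's), otherwise independent.
    Coupling 1 ⇒ deterministic association; coupling 0 ⇒ independence.
    """
    from .structure_io import Msa

    conserved_cols = conserved_cols or {}
    covary_pairs = covary_pairs or []
    claimed = set(conserved_cols)
    for i, j, c in covary_pairs:
        if not 0.0 <= c <= 1.0:
            raise ValueError("coupling must be in [0, 1]")
        for col in (i, j):
            if col in claimed:
                raise ValueError(f"column {col} assigned twice")
            claimed.add(col)
    if any(c >= n_col or c < 0 for c in claimed):
        raise ValueError("planted column index out of range")

    if background_freqs is None:
        p = np.full(len(AA20), 1.0 / len(AA20))
    else:
        p = np.array([background_freqs.get(a, 0.0) for a in AA20], dtype=float)
        p = p / p.sum()
    rng = np.random.default_rng(seed)
    letters = np.frombuffer(AA20.encode(), dtype="S1").astype("U1")
    mat = rng.choice(letters, size=(n_seq, n_col), p=p)
    for col, aa in conserved_cols.items():
        mat[:, col] = aa
    perm = np.roll(np.arange(len(AA20)), 1)  # fixed coupled mapping A->C->D...
    idx_of = {a: k for k, a in enumerate(AA20)}
    for i, j, coupling in covary_pairs:
        coupled = rng.random(n_seq) < coupling
        src = np.array([idx_of[a] for a in mat[:, i]])
        mat[coupled, j] = letters[perm[src[coupled]]]
    rows = ["".join(r) for r in mat]
    ids = [f"{ids_prefix}{k:04d}" for k in range(n_seq)]
    return Msa(ids=ids, rows=rows)
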