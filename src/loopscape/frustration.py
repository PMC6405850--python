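"""Local energetic frustration of residue-residue contacts.

Each native contact's energy is compared with a distribution of "decoy"
energies obtained by mutating the identities of the contacting residues
(geometry fixed, identities drawn from the chain's own composition). The
frustration index is the z-score

    F(i, j) = (⟨E_decoy⟩ − E_native) / σ_decoy

so F > 0 means the native pair is more favourable than typical decoys
(minimally frustrated at F ≥ 0.78; highly frustrated at F ≤ −1.0, the
conventional thresholds). The energy model is a deliberate reduction: a
20×20 contact potential plus a Debye-screened Coulomb term whose strength
constant k defaults to 4.15. F is invariant under affine rescaling of the
energy, so the classification depends on energy contrasts, not units.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations

import numpy as np
import pandas as pd

from .structure_io import STANDARD_RESIDUES, ConformationEnsemble

FORMAL_CHARGE = {"ASP": -1.0, "GLU": -1.0, "LYS": 1.0, "ARG": 1.0, "HIS": 0.0}

MINIMAL_THRESHOLD = 0.78
HIGH_THRESHOLD = -1.0


def load_contact_potential(path=None) -> dict[tuple[str, str], float]:
    """Load a symmetric 20×20 contact potential from CSV (rows/cols = 3-letter codes).

    The shipped default is a constructed hydropathy/charge-complementarity
    table (see the file header); any table with the same layout can be
    substituted.
    """
    if path is None:
        ref = resources.files("loopscape.data") / "contact_potential.csv"
        text = ref.read_text()
    else:
        text = open(path).read()
    lines = [l for l in text.splitlines() if l and not l.startswith("#")]
    reader = csv.reader(lines)
    header = next(reader)[1:]
    table: dict[tuple[str, str], float] = {}
    for row in reader:
        a = row[0]
        for b, val in zip(header, row[1:]):
            table[(a, b)] = float(val)
    for (a, b), v in table.items():
        if abs(table[(b, a)] - v) > 1e-9:
            raise ValueError(f"contact potential not symmetric at ({a}, {b})")
    return table


@dataclass
class EnergyModel:
    """Contact potential + screened electrostatics.

    E(a, b, r) = U(a, b) + q_a q_b exp(−r/λ_D) / (k r)

    with U the 20×20 table, formal charges D/E = −1, K/R = +1, H = 0,
    screening length λ_D in Å and electrostatic strength constant k
    (default 4.15, the conventional default).
    """

    contact_potential: dict = field(default_factory=load_contact_potential)
    charges: dict = field(default_factory=lambda: dict(FORMAL_CHARGE))
    k_elec: float = 4.15
    debye_length: float = 10.0
    contact_cutoff: float = 8.0  # Å between Cβ (Cα for Gly)

    def __post_init__(self):
        if self.k_elec <= 0:
            raise ValueError("k_elec must be positive")


def pair_energy(res_a: str, res_b: str, r: float, model: EnergyModel) -> float:
    """Energy of one contact at distance r (Å)."""
    if r <= 0:
        raise ValueError("distance must be positive")
    e = model.contact_potential[(res_a, res_b)]
    qa = model.charges.get(res_a, 0.0)
    qb = model.charges.get(res_b, 0.0)
    if qa and qb:
        e += qa * qb * np.exp(-r / model.debye_length) / (model.k_elec * r)
    return float(e)


def _interaction_centers(ens: ConformationEnsemble, frame: int = 0):
    """Per-residue (res_seq, res_name, coordinates) using Cβ, Cα for Gly.

    Residues lacking both atoms, or with nonstandard names, are skipped with
    a warning (they carry no statistics in this model).
    """
    by_res: dict[tuple[str, int], dict] = {}
    for i, a in enumerate(ens.atoms):
        d = by_res.setdefault((a.chain, a.res_seq), {"name": a.res_name})
        d[a.atom_name] = i
    out = []
    for (chain, seq), d in sorted(by_res.items()):
        name = d["name"]
        if name not in STANDARD_RESIDUES:
            warnings.warn(f"nonstandard residue {name} {chain}:{seq} excluded",
                          stacklevel=3)
            continue
        if "CB" in d:
            idx = d["CB"]
        elif name == "GLY" and "CA" in d:
            idx = d["CA"]
        elif "CA" in d:
            warnings.warn(
                f"{name} {chain}:{seq} missing CB; using CA", stacklevel=3)
            idx = d["CA"]
        else:
            warnings.warn(f"{name} {chain}:{seq} has no CB/CA; skipped",
                          stacklevel=3)
            continue
        out.append((chain, seq, name, ens.coords[frame, idx]))
    return out


def contact_map(ens: ConformationEnsemble, cutoff: float = 8.0,
                min_separation: int = 2, frame: int = 0) -> list[tuple]:
    """Residue pairs with interaction-centre distance ≤ cutoff and |i−j| ≥ 2.

    Sequence separation is in residue numbering within a chain; inter-chain
    pairs always qualify on separation.
    """
    centers = _interaction_centers(ens, frame)
    contacts = []
    for (c1, s1, n1, x1), (c2, s2, n2, x2) in combinations(centers, 2):
        if c1 == c2 and abs(s1 - s2) < min_separation:
            continue
        r = float(np.linalg.norm(x1 - x2))
        if r <= cutoff:
            contacts.append(((c1, s1, n1), (c2, s2, n2), r))
    return contacts


def _composition(centers) -> tuple[list[str], np.ndarray]:
    names = [n for _, _, n, _ in centers]
    uniq = sorted(set(names))
    freq = np.array([names.count(u) for u in uniq], dtype=float)
    return uniq, freq / freq.sum()


def _decoy_stats_exhaustive(r: float, types: list[str], probs: np.ndarray,
                            model: EnergyModel) -> tuple[float, float]:
    """Exact mean/sd of decoy energy over i.i.d. type pairs from composition."""
    energies = []
    weights = []
    for i, a in enumerate(types):
        for j, b in enumerate(types):
            energies.append(pair_energy(a, b, r, model))
            weights.append(probs[i] * probs[j])
    e = np.array(energies)
    w = np.array(weights)
    mean = float(np.sum(w * e))
    var = float(np.sum(w * (e - mean) ** 2))
    return mean, np.sqrt(var)


def _decoy_stats_sampled(r: float, types: list[str], probs: np.ndarray,
                         model: EnergyModel, n_decoys: int,
                         rng: np.random.Generator) -> tuple[float, float]:
    ia = rng.choice(len(types), size=n_decoys, p=probs)
    ib = rng.choice(len(types), size=n_decoys, p=probs)
    e = np.array([pair_energy(types[a], types[b], r, model)
                  for a, b in zip(ia, ib)])
    return float(e.mean()), float(e.std())


def frustration_index(
    ens: ConformationEnsemble,
    model: EnergyModel | None = None,
    n_decoys: int | None = 2000,
    seed: int = 0,
    frame: int = 0,
) -> pd.DataFrame:
    """Mutational frustration index for every native contact.

    ``n_decoys=None`` switches to exhaustive mode: the decoy distribution is
    enumerated exactly over all residue-type pairs weighted by the chain
    composition. Contacts whose decoy distribution is degenerate (σ = 0,
    e.g. a homopolymer) get F = 0 and ``degenerate=True``.
    """
    if model is None:
        model = EnergyModel()
    if n_decoys is not None and n_decoys < 2:
        raise ValueError("need n_decoys >= 2 or exhaustive mode (None)")
    centers = _interaction_centers(ens, frame)
    types, probs = _composition(centers)
    contacts = contact_map(ens, model.contact_cutoff, frame=frame)
    rng = np.random.default_rng(seed)
    rows = []
    for (c1, s1, n1), (c2, s2, n2), r in contacts:
        e_native = pair_energy(n1, n2, r, model)
        if n_decoys is None:
            mean, sd = _decoy_stats_exhaustive(r, types, probs, model)
        else:
            mean, sd = _decoy_stats_sampled(r, types, probs, model, n_decoys, rng)
        degenerate = sd < 1e-12
        f = 0.0 if degenerate else (mean - e_native) / sd
        rows.append({
            "chain_i": c1, "res_i": s1, "name_i": n1,
            "chain_j": c2, "res_j": s2, "name_j": n2,
            "r_ij": r, "e_native": e_native,
            "decoy_mean": mean, "decoy_sd": sd,
            "f_index": f, "degenerate": degenerate,
            "frustration_class": classify(f),
        })
    return pd.DataFrame(rows)


def classify(f: float) -> str:
    """Conventional frustration classes: minimal ≥ 0.78, high ≤ −1.0."""
    if f >= MINIMAL_THRESHOLD:
        return "minimal"
    if f <= HIGH_THRESHOLD:
        return "high"
    return "neutral"
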