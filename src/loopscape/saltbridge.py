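"""Salt-bridge identification and fractional occupancy over an ensemble.

A salt bridge is counted as formed in a frame when the minimum distance
between the acidic side chain's carboxylate oxygens and the basic side
chain's charged nitrogens falls at or below a cutoff (default 4.0 Å, the
common literature criterion). Occupancy is the fraction of frames formed;
reports keep pairs above a threshold (default 20%) unless asked for all.
Histidine can be included as a basic partner but is protonation-dependent
and therefore off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure_io import ConformationEnsemble

ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE"), "HIS": ("ND1", "NE2")}

DEFAULT_CUTOFF = 4.0  # Å, charged N to carboxylate O
DEFAULT_REPORT_THRESHOLD = 0.20


@dataclass(frozen=True)
class SaltBridgePair:
    """An acidic/basic residue pair considered for bridging."""

    chain_a: str
    acidic_res_seq: int
    acidic_res_name: str
    chain_b: str
    basic_res_seq: int
    basic_res_name: str

    def __post_init__(self):
        if (self.chain_a, self.acidic_res_seq) == (self.chain_b, self.basic_res_seq):
            raise ValueError("acidic and basic residues must be distinct")

    @property
    def label(self) -> str:
        return (f"{self.acidic_res_name}{self.acidic_res_seq}-"
                f"{self.basic_res_name}{self.basic_res_seq}")


def _charged_atom_indices(ens: ConformationEnsemble, chain: str, res_seq: int,
                          res_name: str, table: dict) -> list[int]:
    wanted = table.get(res_name, ())
    return [i for i, a in enumerate(ens.atoms)
            if a.chain == chain and a.res_seq == res_seq
            and a.atom_name in wanted]


def _pair_min_distance(ens: ConformationEnsemble, pair: SaltBridgePair
                       ) -> np.ndarray:
    """Per-frame minimum charged-atom distance; raises if atoms absent."""
    ia = _charged_atom_indices(ens, pair.chain_a, pair.acidic_res_seq,
                               pair.acidic_res_name, ACIDIC_ATOMS)
    ib = _charged_atom_indices(ens, pair.chain_b, pair.basic_res_seq,
                               pair.basic_res_name, BASIC_ATOMS)
    if not ia or not ib:
        raise ValueError(
            f"pair {pair.label}: charged atoms absent from ensemble "
            f"(acidic found {len(ia)}, basic found {len(ib)})"
        )
    a = ens.coords[:, ia, :]  # (F, na, 3)
    b = ens.coords[:, ib, :]
    d = np.linalg.norm(a[:, :, None, :] - b[:, None, :, :], axis=-1)
    return d.reshape(ens.n_frames, -1).min(axis=1)


def _charged_residues(ens: ConformationEnsemble, residues, include_his: bool):
    acidic, basic = [], []
    seen = set()
    for a in ens.atoms:
        key = (a.chain, a.res_seq)
        if key in seen or (a.chain, a.res_seq) not in residues:
            continue
        if a.res_name in ACIDIC_ATOMS:
            acidic.append((a.chain, a.res_seq, a.res_name))
            seen.add(key)
        elif a.res_name in BASIC_ATOMS:
            if a.res_name == "HIS" and not include_his:
                seen.add(key)
                continue
            basic.append((a.chain, a.res_seq, a.res_name))
            seen.add(key)
    return acidic, basic


def find_candidate_pairs(
    ens: ConformationEnsemble,
    group_a: set[tuple[str, int]],
    group_b: set[tuple[str, int]],
    cutoff: float = DEFAULT_CUTOFF,
    include_his: bool = False,
    prescreen_margin: float = 2.0,
) -> list[SaltBridgePair]:
    """All acidic×basic cross pairs between two residue groups, pre-screened.

    ``group_a``/``group_b`` are sets of (chain, res_seq), e.g. the loop and
    the protein body. A pair survives the screen if its minimum charged-atom
    distance ever drops below ``cutoff + prescreen_margin``. Residues present
    in both groups are never paired with themselves.
    """
    acid_a, base_a = _charged_residues(ens, group_a, include_his)
    acid_b, base_b = _charged_residues(ens, group_b, include_his)
    candidates = []
    for acid, base in [(a, b) for a in acid_a for b in base_b] + \
                      [(a, b) for a in acid_b for b in base_a]:
        if (acid[0], acid[1]) == (base[0], base[1]):
            continue
        pair = SaltBridgePair(acid[0], acid[1], acid[2], base[0], base[1], base[2])
        if _pair_min_distance(ens, pair).min() <= cutoff + prescreen_margin:
            candidates.append(pair)
    return candidates


def occupancy(ens: ConformationEnsemble, pair: SaltBridgePair,
              cutoff: float = DEFAULT_CUTOFF) -> float:
    """Fraction of frames with the pair's min charged-atom distance ≤ cutoff."""
    d = _pair_min_distance(ens, pair)
    return float(np.mean(d <= cutoff))


def occupancy_report(
    ensembles: list[ConformationEnsemble] | ConformationEnsemble,
    pairs: list[SaltBridgePair],
    cutoff: float = DEFAULT_CUTOFF,
    report_threshold: float = DEFAULT_REPORT_THRESHOLD,
    include_all: bool = False,
) -> pd.DataFrame:
    """Occupancy table, one row per pair, one column per ensemble source.

    Pairs are sorted by maximum occupancy, descending; pairs at or below the
    threshold in every source are dropped unless ``include_all``. With two
    or more sources a ``max_difference`` column quantifies the contrast
    between systems.
    """
    if isinstance(ensembles, ConformationEnsemble):
        ensembles = [ensembles]
    rows = []
    for pair in pairs:
        row: dict = {"pair": pair.label,
                     "acidic": f"{pair.chain_a}:{pair.acidic_res_seq}",
                     "basic": f"{pair.chain_b}:{pair.basic_res_seq}"}
        occs = []
        for ens in ensembles:
            occ = occupancy(ens, pair, cutoff)
            row[f"occupancy_{ens.source_id}"] = occ
            occs.append(occ)
        row["max_occupancy"] = max(occs)
        if len(occs) > 1:
            row["max_difference"] = max(occs) - min(occs)
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df = df.sort_values("max_occupancy", ascending=False, ignore_index=True)
    if not include_all:
        df = df[df["max_occupancy"] > report_threshold].reset_index(drop=True)
    return df
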