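"""Alignment statistics: percent identity, conservation, covariation.

Percent identity follows the convention
``100 × identity columns / aligned length (including gaps)``. Conservation
is a normalised-entropy score per column with a 1–9 grade (9 = most
conserved). Covariation offers three classic column-pair statistics —
OMES (observed-minus-expected-squared χ² independence test), ELSC (explicit
likelihood of subset covariation) and SCA (statistical-coupling, the
perturbation ΔΔG-statistic formulation) — plus a column-permutation null for
empirical significance with Benjamini–Hochberg correction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .structure_io import Msa

AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


def percent_identity(seq_a: str, seq_b: str, gap_gap_identity: bool = False) -> float:
    """100 × identity columns / aligned length (gaps included in the length).

    Columns where both sequences are gapped count toward the length; whether
    they count as identities is configurable (default no).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"aligned sequences differ in length ({len(seq_a)} vs {len(seq_b)})"
        )
    if not seq_a:
        raise ValueError("empty alignment")
    ident = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a == b:
            if a == GAP and not gap_gap_identity:
                continue
            ident += 1
    return 100.0 * ident / len(seq_a)


def conservation_profile(msa: Msa) -> pd.DataFrame:
    """Per-column conservation score 1 − H/log20 plus a 1–9 grade.

    Gaps are excluded from the frequency estimate; an all-gap column is
    masked (NaN score, grade 0). Grades are 9-quantile bins over the valid
    columns, 9 = most conserved, mirroring the familiar surface-mapping
    colour scale.
    """
    scores = np.full(msa.n_col, np.nan)
    for j in range(msa.n_col):
        col = [c for c in msa.column(j) if c != GAP and c in AA20]
        if not col:
            continue
        vals, counts = np.unique(col, return_counts=True)
        p = counts / counts.sum()
        h = -np.sum(p * np.log(p))
        scores[j] = 1.0 - h / np.log(20.0)
    valid = ~np.isnan(scores)
    grades = np.zeros(msa.n_col, dtype=int)
    if valid.sum():
        # rank-based 9-quantile binning; ties share the bin of their rank
        order = scores[valid]
        ranks = pd.Series(order).rank(method="average").to_numpy()
        g = np.ceil(ranks / len(order) * 9).astype(int)
        g = np.clip(g, 1, 9)
        g[np.isclose(order, 1.0)] = 9  # invariant columns are top grade
        grades[valid] = g
    return pd.DataFrame({"column": np.arange(msa.n_col),
                         "conservation": scores, "grade": grades})


@dataclass
class CovariationMatrix:
    """Symmetric column-pair score matrix with a validity mask."""

    scores: np.ndarray
    method: str
    valid: np.ndarray  # per-column usability mask

    def masked(self) -> np.ndarray:
        """Scores with invalid columns and the diagonal as NaN."""
        out = self.scores.astype(float).copy()
        out[~self.valid, :] = np.nan
        out[:, ~self.valid] = np.nan
        np.fill_diagonal(out, np.nan)
        return out

    def top_pairs(self, n: int = 10) -> pd.DataFrame:
        m = self.masked()
        iu = np.triu_indices_from(m, k=1)
        vals = m[iu]
        ok = ~np.isnan(vals)
        order = np.argsort(vals[ok])[::-1][:n]
        i = iu[0][ok][order]
        j = iu[1][ok][order]
        return pd.DataFrame({"col_i": i, "col_j": j, "score": vals[ok][order],
                             "method": self.method})


def _column_validity(msa: Msa, max_gap_fraction: float) -> np.ndarray:
    arr = msa.to_array()
    gap_frac = np.mean(arr == GAP, axis=0)
    return gap_frac <= max_gap_fraction


def omes(msa: Msa, max_gap_fraction: float = 0.5) -> CovariationMatrix:
    """OMES χ² test of residue independence for every column pair.

    For each pair, over sequences ungapped at both columns:
    χ² = Σ_ab (N_obs(a,b) − N_exp(a,b))² / N_exp, N_exp = N f_i(a) f_j(b).
    Cells with zero expectation contribute nothing; pairs with fewer than
    two usable sequences are masked.
    """
    arr = msa.to_array()
    n_col = msa.n_col
    valid = _column_validity(msa, max_gap_fraction)
    scores = np.full((n_col, n_col), np.nan)
    ungapped = (arr != GAP)
    for i in range(n_col):
        if not valid[i]:
            continue
        for j in range(i + 1, n_col):
            if not valid[j]:
                continue
            use = ungapped[:, i] & ungapped[:, j]
            n = int(use.sum())
            if n < 2:
                continue
            ci = arr[use, i]
            cj = arr[use, j]
            ai, inv_i = np.unique(ci, return_inverse=True)
            aj, inv_j = np.unique(cj, return_inverse=True)
            obs = np.zeros((ai.size, aj.size))
            np.add.at(obs, (inv_i, inv_j), 1.0)
            fi = obs.sum(axis=1) / n
            fj = obs.sum(axis=0) / n
            exp = n * np.outer(fi, fj)
            nz = exp > 0
            chi2 = float(np.sum((obs[nz] - exp[nz]) ** 2 / exp[nz]))
            scores[i, j] = scores[j, i] = chi2
    return CovariationMatrix(scores=scores, method="omes", valid=valid)


def _log_choose(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _apportion(counts: np.ndarray, subset_size: int) -> np.ndarray:
    """Integer expected counts summing to subset_size (largest remainder)."""
    total = counts.sum()
    if total == 0:
        return np.zeros_like(counts)
    exact = counts * subset_size / total
    base = np.floor(exact).astype(int)
    short = subset_size - base.sum()
    if short > 0:
        order = np.argsort(exact - base)[::-1]
        base[order[:short]] += 1
    return np.minimum(base, counts)


def _perturbation_subset(col: np.ndarray) -> np.ndarray:
    """Mask of sequences carrying the most frequent (non-gap) residue."""
    vals, counts = np.unique(col[col != GAP], return_counts=True)
    if vals.size == 0:
        return np.zeros(col.shape, dtype=bool)
    best = vals[np.argmax(counts)]
    return col == best


def elsc(msa: Msa, max_gap_fraction: float = 0.5,
         min_subset: int = 10) -> CovariationMatrix:
    """Explicit likelihood of subset covariation.

    Perturb at column i by keeping the sequences with i's modal residue;
    at column j compare the observed subset composition n_j(b) with the
    size-matched expectation m_j(b) (largest-remainder rounding of the full
    column composition):

        score_ij = −Σ_b ln[ C(N_j(b), n_j(b)) / C(N_j(b), m_j(b)) ]

    Large scores mean the subset's composition at j is improbable under
    random sub-sampling, i.e. j covaries with i. The matrix stores
    max(score_ij, score_ji); subsets smaller than ``min_subset`` are masked.
    """
    arr = msa.to_array()
    n_col = msa.n_col
    valid = _column_validity(msa, max_gap_fraction)
    directed = np.full((n_col, n_col), np.nan)
    for i in range(n_col):
        if not valid[i]:
            continue
        sub = _perturbation_subset(arr[:, i])
        if sub.sum() < min_subset:
            continue
        for j in range(n_col):
            if j == i or not valid[j]:
                continue
            colj = arr[:, j]
            use = colj != GAP
            full = colj[use]
            subset = colj[use & sub]
            if subset.size == 0:
                continue
            vals = np.unique(full)
            n_full = np.array([(full == v).sum() for v in vals])
            n_sub = np.array([(subset == v).sum() for v in vals])
            m = _apportion(n_full, subset.size)
            score = -float(np.sum(_log_choose(n_full, n_sub)
                                  - _log_choose(n_full, m)))
            directed[i, j] = score
    scores = np.fmax(directed, directed.T)  # documented symmetrisation
    return CovariationMatrix(scores=scores, method="elsc", valid=valid)


def load_background_freqs(path=None) -> dict[str, float]:
    """Background amino-acid frequencies (shipped database composition)."""
    if path is None:
        text = (resources.files("loopscape.data")
                / "aa_background_freqs.csv").read_text()
    else:
        text = open(path).read()
    rows = [l for l in text.splitlines() if l and not l.startswith("#")]
    out = {}
    for row in csv.reader(rows[1:]):
        out[row[0]] = float(row[1])
    return out


def sca(msa: Msa, max_gap_fraction: float = 0.5, min_subset: int = 10,
        background: dict[str, float] | None = None,
        regularization: float = 0.03) -> CovariationMatrix:
    """Statistical coupling analysis, perturbation ΔΔG-statistic form.

    Perturb at column i (keep sequences with the modal residue); the
    coupling to column j is the Euclidean norm over residues a of

        ln(f_j^sub(a) / g(a)) − ln(f_j(a) / g(a))

    with g the background frequencies. Frequencies are regularised by
    mixing with the background, f ← (1−w)f + w·g, which keeps the logs
    finite and is sample-size independent (a subset with the same raw
    composition as the full column scores exactly 0). Directional by
    construction; the matrix stores max(score_ij, score_ji).
    """
    if background is None:
        background = load_background_freqs()
    arr = msa.to_array()
    n_col = msa.n_col
    valid = _column_validity(msa, max_gap_fraction)
    aas = np.array(list(AA20))
    g = np.array([background[a] for a in aas])
    w = regularization

    def freqs(col: np.ndarray) -> np.ndarray | None:
        col = col[col != GAP]
        if col.size == 0:
            return None
        counts = np.array([(col == a).sum() for a in aas], dtype=float)
        return (1.0 - w) * counts / counts.sum() + w * g

    directed = np.full((n_col, n_col), np.nan)
    for i in range(n_col):
        if not valid[i]:
            continue
        sub = _perturbation_subset(arr[:, i])
        if sub.sum() < min_subset:
            continue
        for j in range(n_col):
            if j == i or not valid[j]:
                continue
            f_full = freqs(arr[:, j])
            f_sub = freqs(arr[sub, j])
            if f_full is None or f_sub is None:
                continue
            delta = np.log(f_sub / g) - np.log(f_full / g)
            directed[i, j] = float(np.sqrt(np.sum(delta ** 2)))
    scores = np.fmax(directed, directed.T)
    return CovariationMatrix(scores=scores, method="sca", valid=valid)


METHODS = {"omes": omes, "elsc": elsc, "sca": sca}


def covariation_significance(
    msa: Msa,
    method: str = "omes",
    n_permutations: int = 199,
    seed: int = 0,
    **method_kwargs,
) -> pd.DataFrame:
    """Empirical per-pair p-values from a column-permutation null.

    Each null replicate permutes every column's residues independently
    across sequences (destroying inter-column association, preserving
    composition); p = (1 + #{null ≥ observed}) / (1 + n_permutations).
    Benjamini–Hochberg q-values are reported alongside raw p.
    """
    if n_permutations < 19:
        raise ValueError("need >= 19 permutations for p-value resolution")
    fn = METHODS[method]
    obs = fn(msa, **method_kwargs)
    m = obs.masked()
    iu = np.triu_indices_from(m, k=1)
    obs_vals = m[iu]
    pairs_ok = ~np.isnan(obs_vals)
    rng = np.random.default_rng(seed)
    arr = msa.to_array()
    exceed = np.zeros(obs_vals.shape)
    for _ in range(n_permutations):
        perm = arr.copy()
        for j in range(msa.n_col):
            perm[:, j] = perm[rng.permutation(msa.n_seq), j]
        null_msa = Msa(ids=list(msa.ids), rows=["".join(r) for r in perm])
        nv = fn(null_msa, **method_kwargs).masked()[iu]
        with np.errstate(invalid="ignore"):
            exceed += (nv >= obs_vals) & ~np.isnan(nv)
    p = (1.0 + exceed) / (1.0 + n_permutations)
    p[~pairs_ok] = np.nan
    df = pd.DataFrame({"col_i": iu[0], "col_j": iu[1],
                       "score": obs_vals, "p_value": p})
    df = df[pairs_ok].reset_index(drop=True)
    # Benjamini-Hochberg
    order = np.argsort(df["p_value"].to_numpy())
    n = len(df)
    q = np.empty(n)
    ranked = df["p_value"].to_numpy()[order] * n / (np.arange(n) + 1)
    q[order] = np.minimum.accumulate(ranked[::-1])[::-1]
    df["q_value"] = np.clip(q, 0, 1)
    df["method"] = method
    return df
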