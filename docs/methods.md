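# Methods

This note documents the models, conventions and numerical choices behind
`loopscape`, and what the synthetic-data experiments do and do not show.

## Conformational ensembles

An ensemble is an F×A×3 coordinate array (Å) over a fixed topology
(chain, author residue number, residue name, atom name). Multi-model PDB is
the on-disk carrier; atom order is taken from the first MODEL and later
models must match it exactly (the reader pre-scans per-model atom counts so
the error names the first offending model). Altloc resolution keeps the
highest occupancy, ties going to 'A'. Nonstandard residues are parsed and
flagged; they are excluded from frustration and covariation statistics.
Residue ranges are author-numbered and inclusive, matching PDB convention.
Serpin P-position labels (P17 = 342 … P1 = 358, P1′ = 359 in
α1-antitrypsin numbering) are provided as a labelling table only — no
selection logic depends on them, and chimera renumbering schemes are the
user's responsibility via that table.

## Superposition, RMSD, RMSF, dihedrals

Rigid superposition is the Kabsch SVD solution restricted to proper
rotations (det = +1); the returned RMSD over the fit atoms is the global
minimum over rigid motions. RMSF uses an iteratively refined mean
structure: superpose all frames on the current mean, recompute the mean,
repeat until the mean moves < 1e-6 Å (max 20 iterations). The fit
selection defaults to all atoms, but the intended use for loop work is
scaffold Cα only, so the profile measures loop motion relative to the
body. With i.i.d. per-coordinate jitter σ the expected RMSF is σ√3;
superposition absorbs 6 rigid degrees of freedom out of 3A coordinates, a
shrinkage of about √(1 − 6/3A) — under 2% for the 72-atom loop — which is
why the recovery test tolerance is 5%.

Dihedrals follow the IUPAC sign convention, reported in (−180°, 180°]; φ
of the first and ψ/ω of the last residue are NaN, and ω of residue i is
the i→i+1 peptide bond. Averaging of angles uses circular statistics.
Per-time-window reporting ("per 500 ps") is block averaging over frames
via the ensemble's frame-interval metadata; the trailing partial block is
retained and flagged. Block averaging rather than subsampling is the
default reading of a fixed-timestep convention; subsampling is available
by slicing frames.

## Loop-conformation landscape

The loop coordinate matrix concatenates the selected loop backbone
(N, CA, C, O per residue; 18 residues → 72 atoms → 216 columns) across
ensembles, frames first superposed onto the first frame of the first
ensemble. The fit uses scaffold Cα (loop excluded) so the PCA captures
loop motion rather than global tumbling; pure-loop ensembles fall back to
fitting on the loop itself. PCA is an eigendecomposition of the full
3A×3A covariance of mean-centred rows, so the component basis is complete
and orthonormal with zero eigenvalues on rank-deficient directions —
needed for the lossless-reconstruction and rotation-invariance guarantees.

Clustering is HDBSCAN (scikit-learn) in Euclidean metric with
`min_cluster_size = max(2, round_half_up(fraction × frames))`; the 1%
default reproduces 90 from 8993. `min_samples` follows `min_cluster_size`,
the reference implementation's default coupling. `allow_single_cluster` is
on: excess-of-mass selection never picks the root cluster, so without it a
single-basin landscape dissolves into noise instead of reporting one
cluster. Clusters are relabelled by descending size; medoids minimise the
summed Euclidean distance to co-members in the clustering space, ties to
the lowest frame index. Clustering dimensionality defaults to the full PC
space (distance-preserving, hence identical to clustering the centred raw
matrix); a 2-PC projection is supported for plotting-space clustering but
low-dimensional projections can smear well-separated basins when the
superposition of dissimilar conformers is rotationally ill-determined —
the recovery experiments therefore cluster in full space.

The three-basin recovery experiments use 8-residue loops, 500 frames per
system, jitter 0.15 Å against inter-basin separations of several Å
(template separation ≥ 5× jitter), Markov self-transition 0.9, and a
minimum cluster size of 5% of frames — basin scale, since at 1% of 500
frames HDBSCAN legitimately resolves sub-basin density structure that the
basin-level ground truth does not label.

## Salt bridges

A bridge is formed in a frame when the minimum distance over charged-atom
pairs (Asp OD1/OD2, Glu OE1/OE2 × Lys NZ, Arg NH1/NH2/NE, His ND1/NE2)
is ≤ cutoff. The 4.0 Å N–O cutoff is the common literature criterion and
is configurable; His is protonation-dependent and excluded by default.
Candidate enumeration takes all acidic×basic cross pairs between two
residue groups and pre-screens at cutoff + 2 Å over the whole ensemble.
Occupancy is the fraction of frames formed; reports hide pairs at or below
20% unless asked for all. Occupancy is exactly monotone in the cutoff and
exactly frame-weight additive over concatenations. The two-state generator
is a Markov chain whose stationary formed-probability is the requested
occupancy by construction (with self-transition parameter s the chain
resamples from the stationary law with probability 1 − s each step).

## Frustration

The energy model is deliberately reduced: a symmetric 20×20 contact
potential plus a Debye-screened Coulomb term
q_i q_j e^{−r/λ_D}/(k r) with formal charges D/E = −1, K/R = +1, H = 0,
screening length 10 Å, and electrostatic strength constant k = 4.15 (the
conventional default). The shipped contact table is constructed from
Kyte–Doolittle hydropathies plus charge complementarity (header documents
the formula) and is swappable; because the frustration index is a z-score,
it is invariant under any affine rescaling of the energy model (tested),
so classifications depend on energy contrasts, not on the table's units.
Contacts are Cβ pairs (Cα for Gly) within 8 Å at sequence separation ≥ 2.
Decoys are "mutational": residue identities at the contact are redrawn
i.i.d. from the chain's own composition with geometry fixed. Exhaustive
mode enumerates the full decoy distribution (exact mean and sd); sampled
mode draws n pairs with a seeded generator. σ = 0 (e.g. a homopolymer)
gives F = 0 flagged degenerate. Classes follow the conventional
thresholds, minimal at F ≥ 0.78 and high at F ≤ −1.0, both inclusive.
Absolute F values from this reduced model are not comparable to the full
water-mediated Hamiltonian of frustration web servers; ranking and
class contrasts on a fixed structure are the supported use.

## Sequence statistics

Percent identity is 100 × identity columns / aligned length including
gaps. A column where both sequences are gapped counts toward the length
but not the identities by default; the flag `gap_gap_identity` flips that
reading, which is genuinely ambiguous in the usual phrasing of the
formula. Conservation is 1 − H/ln 20 per column with gaps excluded, and a
1–9 grade from rank-based 9-quantile binning (9 = most conserved),
mirroring the familiar structure-colouring scale.

Covariation: columns with > 50% gaps are masked. OMES is the plain χ²
independence statistic over sequences ungapped at both columns, skipping
zero-expectation cells — it matches integer contingency arithmetic exactly
and equals N for a deterministic 2×2 association. ELSC perturbs at column
i by keeping sequences with i's modal residue and scores column j by the
log-likelihood-ratio of observing the subset's composition versus the
size-matched expectation; expected integer counts use largest-remainder
apportionment. SCA is the perturbation (ΔΔG-statistic) formulation with
shipped background frequencies; frequencies are regularised by mixing
with the background (f ← (1−w)f + w·g, w = 0.03), which keeps logs finite
and is sample-size independent, so a subset with the full column's
composition scores exactly 0. ELSC and SCA are directional; matrices
store max(score_ij, score_ji) and record the convention. Significance uses
a column-permutation null (each column permuted independently across
sequences, preserving composition, destroying association), empirical
p = (1 + #{null ≥ obs})/(1 + n_perm), with Benjamini–Hochberg q-values
reported alongside. At small permutation counts the p-value resolution
(1/(n_perm+1)) bounds how small q can get; a "significant" threshold is
left to the user.

## Assay fits

The melt model is the Boltzmann sigmoid in temperature with two baselines.
Initialisation: baselines from the terminal 10% of points, T_m at the
half-amplitude crossing, slope at 1/20 of the scanned range. A fitted
amplitude below 3× the residual sd is flagged unidentifiable — the correct
outcome for a protein that does not unfold over the scanned range — rather
than reported as a (meaningless) T_m. Hysteresis is T_m(heat) − T_m(cool)
from two independent fits. The SI fit is ordinary least squares of
residual activity against serpin:protease ratio restricted to the linear
pre-saturation region (activity > 0.1 by default, configurable); the
x-intercept −b/m is the SI and its standard error comes from first-order
propagation of the coefficient covariance. Points clamped at the zero
floor would bias the slope and are excluded by that window. Both fits are
scale-equivariant in the signal.

## Synthetic generators

All generators are pure functions of (spec, seed) using numpy's seeded
Generator. The backbone builder places N/CA/C/O with ideal
Engh–Huber-like geometry (N–CA 1.458, CA–C 1.525, C–N 1.329, C–O 1.231 Å;
N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°) by natural-extension
internal coordinates; recomputing φ/ψ/ω from the built chain returns the
template to well below 1e-3°. Basin switching is a Markov chain with
self-transition `stay_prob` and off-diagonal mass proportional to basin
weights, so the stationary law equals the weights exactly. Pose noise
(random small rotation + translation per frame) defaults to zero so
superposition invariance can be switched on deliberately. The inhibition
generator reports the mean of three noisy replicates per ratio, emulating
the usual triplicate design; the melt grid is 35–95 °C at 1 °C steps.
MSA covariation is parameterised as a mixture weight between an
independent product distribution and a perfectly coupled joint (a fixed
residue permutation), making coupling 1 a deterministic association and
coupling 0 exact independence.

What passing these tests shows: the estimators recover known parameters
under the generators' idealisations — Gaussian jitter, exact two-state
kinetics, i.i.d. columns, sigmoid melts. What they do not show: behaviour
under force-field artefacts, correlated solvent-driven motions,
phylogenetic structure in alignments, or instrument drift; real-data
conclusions still need the usual controls. Default problem sizes (500
frames × 10 seeds for clustering recovery, 1e5 frames for occupancy, 20–50
replicate fits for assays) were chosen as the smallest at which the
estimators' sampling error is comfortably inside the stated tolerances.

## Known limitations

- The PDB reader targets coordinate records only (no header metadata,
  no mmCIF, no binary trajectories); convert upstream if needed.
- The frustration energy is a reduced model (see above).
- SCA has several published variants; only the perturbation formulation
  is implemented, and the choice is recorded in the matrix metadata.
- Covariation has no phylogenetic correction; with few, related
  sequences the permutation null understates relatedness-driven signal.
- The deposited-structure RMSD check requires the two PDB entries
  locally; the package does not fetch them.
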