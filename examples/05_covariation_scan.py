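"""Conservation and covariation on an alignment with planted signal.

Simulates a 212-sequence alignment with one invariant column and one
perfectly covarying column pair, then shows that the conservation profile
and all three covariation statistics (OMES, ELSC, SCA) find them, with a
column-permutation null giving the covarying pair the smallest possible
empirical p-value.
"""

from loopscape import coevolution as coe
from loopscape import synthetic as syn

msa = syn.simulate_msa(n_seq=212, n_col=30, conserved_cols={3: "C"},
                       covary_pairs=[(10, 22, 1.0)], seed=7)

prof = coe.conservation_profile(msa)
print("conserved column 3: score "
      f"{prof.loc[3, 'conservation']:.3f}, grade {prof.loc[3, 'grade']}")

for method in ("omes", "elsc", "sca"):
    top = coe.METHODS[method](msa).top_pairs(1).iloc[0]
    print(f"{method.upper():4s} argmax pair: ({top['col_i']}, {top['col_j']}) "
          f"score {top['score']:.1f}")

sig = coe.covariation_significance(msa, "omes", n_permutations=199, seed=1)
planted = sig[(sig.col_i == 10) & (sig.col_j == 22)].iloc[0]
print(f"planted pair empirical p = {planted['p_value']:.4f} "
      f"over 199 column permutations")
print("\nAll three statistics rank the planted pair first; the permutation "
      "p-value of 1/200 is the smallest achievable at this replicate count. "
      "On a real serpin alignment the same scan quantifies whether any pair "
      "rises above this null.")
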