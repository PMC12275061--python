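"""Perturb an MSA: substitute binding-site columns with alanine.

Shows the genome encoding — one bit per candidate residue — and what setting
a bit does to the alignment (homolog rows only; the query keeps its sequence).
"""

import numpy as np

from alascreen import MutationMask, apply_alanine_mask, residues_to_columns
from alascreen.synth import FixtureSpec, make_toy_msa

msa = make_toy_msa(FixtureSpec(n_residues=24, n_msa_rows=5, n_site_residues=6),
                   np.random.default_rng(3))

candidates = [4, 7, 11, 15, 19, 22]       # binding-site residues (1-based)
mask = MutationMask(candidates, [1, 0, 1, 1, 0, 0])

print("mask bits  :", mask.as_string(), "over residues", candidates)
print("msa columns:", residues_to_columns(msa, candidates))
mutated = apply_alanine_mask(msa, mask)
for (rid, before), (_, after) in zip(msa.rows, mutated.rows):
    marker = "  <- query (unchanged)" if rid == msa.query_id else ""
    print(f"{rid:>10}: {before}")
    print(f"{'':>10}  {after}{marker}")
# Every bit-1 column has its homolog residues turned to 'A', erasing the
# coevolutionary signal at that position; gaps and insertions are untouched.
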