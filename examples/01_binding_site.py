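"""Select binding-site residues from a holo complex and build the docking box.

Builds a synthetic holo structure, finds every residue with an atom within
8 Å of the ligand, and centers a 20 Å docking cube on the ligand centroid.
"""

import numpy as np

from alascreen import make_docking_box, select_binding_site
from alascreen.synth import FixtureSpec, make_toy_complex

spec = FixtureSpec(n_residues=48, n_site_residues=14)
complex_, query = make_toy_complex(spec, np.random.default_rng(0))

site = select_binding_site(complex_, cutoff=8.0)
box = make_docking_box(complex_)

print(f"query length        : {len(query)} residues")
print(f"binding-site residues ({len(site)}): "
      f"{[num for _, num in site.residues_pdb]}")
print(f"docking box center  : {np.round(box.center, 2)} (Å)")
print(f"docking box size    : {box.size} (Å)")
# The listed residues are the alanine-substitution candidates: each one maps
# to an MSA column, and together they define the search space of the optimizer.
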