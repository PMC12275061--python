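# Methods

## Model and procedure

`alascreen` optimizes a binary *mutation mask* over binding-site candidate
residues. A mask is applied to the query's MSA column-wise: for every bit set
to 1, each aligned homolog residue in that match column is replaced with
alanine. The query row is left unchanged by default — the predicted model
must carry the native sequence to present a native-like pocket for docking —
so the perturbation acts purely through the coevolutionary signal in the
homolog rows. A config flag (`mutate_query`) reverses this choice. A3M
lowercase insertions occupy no match column and are never substituted; gap
characters stay gaps (only residues are substituted). Substituting an
existing alanine is a no-op.

Candidate residues are those of the holo reference complex with any heavy
atom within 8 Å (closed boundary, so the printed cutoff is inclusive) of any
ligand atom; a single qualifying atom admits the whole residue. Hydrogens are
dropped, altlocs other than blank/'A' are discarded, and waters and
non-target hetero groups are excluded. Because PDB author numbering rarely
matches the query, the structure-derived sequence is globally aligned to the
query (free terminal gaps; identity floor 0.9, below which the mapping is
refused) and site residues aligned to query gaps are dropped with a warning.
The site can alternatively be measured on a default predicted model passed
as the reference — the reference argument is just a structure.

Each evaluated structure passes two confidence filters keyed on pLDDT (read
from the B-factor column, the AlphaFold output convention): whole-model
rejection when the mean pre-trim pLDDT is below 50 (rejection applies to the
structure as a whole, hence the pre-trim mean), and per-residue trimming of
pLDDT < 50 (both boundaries strict, as printed). Accepted structures are
superposed onto the reference over the Cα atoms of shared binding-site
residues by least-squares rigid fitting with the reflection-corrected SVD
(proper rotation only), which transfers the docking box — a 20 Å cube
centered on the unweighted ligand-atom centroid — onto the model. Cα-only
fitting is deliberate: it is robust to side-chain rebuilds, and no atom-set
convention is otherwise forced. Binding-site RMSD between two structures is
the minimized Cα RMSD over their shared site residues after fitting on those
same residues.

Fitness is the ROC–AUC of the docking ranking over a labelled library, lower
score first, average-rank credit for ties (the Mann–Whitney convention).
Ligands the engine could not pose (`FAILED`) rank strictly last, tied among
themselves: a structure that cannot accommodate a ligand earns no credit for
it. Activity labels come either from the input table or from potency:
IC50 < 10 nM (strict) is active.

## Search

* **Random search** draws masks i.i.d. with per-bit probability 0.5 and
  spends exactly the budget; it is memoryless by definition.
* **The GA** runs generationally: tournament selection (size 3), uniform
  crossover (probability 0.9), per-bit flip mutation (rate 1/length), one
  elite copied unchanged. Defaults spend the 1100-structure budget as a
  population of 50 over 22 generations. All rates and counts are
  configurable. Duplicate masks are served from a fitness cache and do not
  consume budget — the budget counts unique predicted structures. An
  evaluator failure (rejected model, backend crash) scores 0.0, the floor of
  the AUC range, and the run continues. Elitism makes the best-fitness curve
  non-decreasing, which every run asserts implicitly and the tests check
  explicitly. A JSON checkpoint written after each generation (population,
  records, cache, generator state) makes runs resumable and extendable.
* Test-set scores are observational only: the best individual is re-scored
  against held-out ligands per generation (cheap in mock mode) without
  feeding back into the search.

Exploration/test splitting follows two schemes. Fixed-size draws take three
pairwise-disjoint exploration sets of exactly (30 actives, 1500 inactives)
or (10, 500), the rest of the library being each set's test complement. The
cluster scheme deals whole chemical clusters to three folds balancing active
counts, each fold's exploration set being the other two folds (≈ two
thirds); clusters come from Butina sphere-exclusion on Morgan-fingerprint
(radius 2, 1024 bits) Tanimoto distances at cutoff 0.4, then merged under
single-linkage closure at the same cutoff, which guarantees that no
above-cutoff similarity pair ever straddles a fold's explore/test boundary.
The fingerprint, algorithm and cutoff are package choices, recorded in
config; only the Tanimoto-distance basis is fixed by the method.

## Backends and mocks

Command builders are pure functions producing argument lists for a
LocalColabFold-style predictor (defaults: MSA depth limit 32, 1 recycle, 1
model, fixed seed — shallow MSAs and minimal recycling promote
conformational diversity) and a Uni-Dock/Vina-style docking engine (scoring
"vina", search mode "balance", seed 1, 20 Å box). Nothing is executed at
build time; execution goes through a runner object tests can intercept.
Receptor/ligand preparation is an external step with file-path contracts
only. Engine output is read by a tolerant parser keyed on the first-pose
score line; absence records `FAILED`.

The mock predictor produces a deterministic helix-like Cα fold; every set
bit displaces a Gaussian neighbourhood of its residue along a bit-specific
fixed direction, so masks at Hamming distance 1 always differ geometrically.
pLDDT is drawn so a configurable fraction of structures fails the mean-50
filter (default 0). The mock docking oracle plants a hidden optimal mask h:
active scores ~ N(μa − δ·sim, σ) and inactive ~ N(μi, σ), where sim is one
minus the normalized Hamming distance to h (the simplest strictly monotone
similarity). The induced expected AUC is Φ((μi − μa + δ·sim)/(σ√2)); the
defaults δ = 1.16, σ = 0.5, μa = μi = −7 span expected AUC 0.5 → ≈0.95 over
sim 0 → 1, a realistic range for a screening campaign. All mock draws are
keyed on (run seed, mask bits), so a mask's fitness is a deterministic
function of the run seed — which also makes full runs byte-reproducible.

## Synthetic study conditions

The fixture generator fixes the study conditions: ligand libraries at the
benchmark-standard 1:50 active:decoy ratio, with actives defined by
IC50 < 10 nM draws; ~20 chemically trivial but parseable scaffolds with
enumerated substituents, giving well-separated fingerprint clusters so
scaffold-aware splitting is exercised; toy MSAs with substitutions, gaps and
lowercase insertions; and toy holo complexes whose binding-site size is made
exact by scanning the ligand's axial span and radial offset until the 8 Å
shell holds the requested count (verified by the site selector itself, not
assumed). Optimizer experiments use 30-bit masks, exploration libraries of
30/1500 (ample) or 10/500 (scarce), the 1100-evaluation budget, and 20
seeds. Everything is reproducible bit-identically from (spec, seed), and
fixtures are written in the standard formats (A3M, PDB, delimited SMILES)
so tests exercise the real readers.

What the mocks do *not* emulate: real docking physics, chemistry-dependent
score correlations, pose failures correlated with pocket geometry, MSA depth
effects on prediction confidence, or decoy property matching. Passing tests
therefore demonstrate the correctness of the encoding, filtering, scoring
and search machinery and the qualitative behaviour of the optimization
(recovery of a planted optimum, degradation under data scarcity), not
screening performance on real targets.

## Numerical choices and degenerate inputs

Boundaries are strict exactly as printed: pLDDT < 50 trims, mean < 50
rejects, IC50 < 10 nM is active, distance ≤ 8 Å is in the site. AUC of a
single-class library is an error, as is superposition with fewer than three
shared anchors. Tanimoto of two empty fingerprints is defined as 1. An empty
binding site is legal but logged. Ties in tournament selection resolve to
the first maximal individual; cluster dealing breaks ties by cluster size
then a seed-dependent permutation. The checkpoint is written atomically
(temp file + rename).

## Known limitations

The external-backend path constructs commands and parses results but is not
exercised against real engines here; the baseline "reference structure" in
mock mode is represented by the zero mask (the unperturbed prediction
standing in for the crystal structure), which compresses the spread between
that baseline and the optimizers relative to a real campaign. Cluster-fold
balance is greedy, not optimal; with very few clusters the two-thirds
exploration fraction is only approximate. The GA does not parallelize
evaluations in-process, though individuals within a generation are
independent and the evaluator seam supports external batching.
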