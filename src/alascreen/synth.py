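"""Synthetic fixtures: every stage of the pipeline runnable with no downloads.

The generators emulate the shape of the real inputs — small A3M alignments
with gaps and insertions, toy holo complexes whose binding-site size is exact
by construction, ligand libraries at the benchmark-standard 1 : 50
active : decoy ratio with scaffold clusters, and planted fitness landscapes
where the optimal substitution mask is known. All of it is reproducible
bit-identically from (spec, seed), and fixtures are written in the same
standard formats the real pipeline consumes so tests exercise the real
readers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .backends import PlantedLandscape, mock_dock, mock_predict, _mask_rng
from .msa import MSA, MutationMask
from .screen import LigandRecord, label_by_ic50, roc_auc
from .site import BindingSite, ReferenceComplex, select_binding_site
from .structmodel import accept_structure

__all__ = [
    "FixtureSpec",
    "FixtureError",
    "make_toy_msa",
    "make_toy_complex",
    "make_toy_library",
    "make_landscape",
]

AMINO = "ACDEFGHIKLMNPQRSTVWY"

# scaffold cores; any suffix below concatenates into valid SMILES
_SCAFFOLDS = [
    "c1ccccc1", "c1ccncc1", "c1ccoc1", "c1ccsc1", "c1cc[nH]c1",
    "C1CCCCC1", "C1CCNCC1", "C1CCOCC1", "C1CCSCC1", "C1CCCC1",
    "c1ccc2ccccc2c1", "c1ccc2[nH]ccc2c1", "c1ccc2occc2c1", "c1ccc2sccc2c1",
    "c1cnc2ccccc2n1", "C1CCC2CCCCC2C1", "c1ncncn1", "c1cncnc1",
    "c1ccc(cc1)c1ccccc1", "C1=CCCCC1",
]
_SUFFIXES = [
    "", "C", "CC", "CCC", "CCCC", "CCCCC", "CO", "CCO", "CCCO", "CN",
    "CCN", "CCCN", "C(C)C", "CC(C)C", "C(C)(C)C", "C(=O)O", "CC(=O)O",
    "C(=O)N", "CC(=O)N", "C#N", "CC#N", "CF", "CCl", "CBr", "C(F)(F)F",
    "COC", "CCOC", "CSC", "C=C", "CC=C",
]


class FixtureError(RuntimeError):
    """Fixture construction failed (e.g. geometric placement exhausted retries)."""


@dataclass
class FixtureSpec:
    """Sizes, ratios and landscape parameters of one synthetic study setup."""

    n_residues: int = 48
    n_msa_rows: int = 16
    n_site_residues: int = 30
    n_actives: int = 30
    decoy_ratio: int = 50
    delta: float = 1.16
    sigma: float = 0.5
    hidden_bits: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.decoy_ratio < 1:
            raise ValueError("decoy_ratio must be >= 1")
        if self.n_site_residues >= self.n_residues:
            raise ValueError("n_site_residues must be smaller than n_residues")
        if self.hidden_bits is not None:
            self.hidden_bits = np.asarray(self.hidden_bits, dtype=int)
            if len(self.hidden_bits) != self.n_site_residues:
                raise ValueError("hidden mask length must equal n_site_residues")

    def landscape(self) -> PlantedLandscape:
        bits = self.hidden_bits
        if bits is None:
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, 11]))
            bits = (rng.random(self.n_site_residues) < 0.5).astype(int)
        return PlantedLandscape(hidden_bits=bits, delta=self.delta, sigma=self.sigma)


def make_toy_msa(spec: FixtureSpec, rng: np.random.Generator) -> MSA:
    """A3M-dialect alignment: query plus homologs with substitutions, gaps and inserts."""
    query = "".join(rng.choice(list(AMINO), size=spec.n_residues))
    rows = [("query", query)]
    for i in range(1, spec.n_msa_rows):
        chars = []
        for c in query:
            u = rng.random()
            if u < 0.08:
                chars.append("-")
            elif u < 0.30:
                chars.append(str(rng.choice(list(AMINO))))
            else:
                chars.append(c)
            if rng.random() < 0.03:  # unaligned insertion, no match column
                chars.append(str(rng.choice(list(AMINO))).lower())
        rows.append((f"homolog_{i}", "".join(chars)))
    return MSA(rows=rows, dialect="a3m")


def _helix_backbone(n: int) -> np.ndarray:
    t = np.arange(n, dtype=float)
    return np.stack([2.3 * np.cos(t * 0.6), 2.3 * np.sin(t * 0.6), t], axis=1)


def make_toy_complex(
    spec: FixtureSpec, rng: np.random.Generator, max_retries: int = 20000
) -> tuple[ReferenceComplex, str]:
    """Toy holo complex with an exact binding-site size.

    The protein is a helix-like Cα trace along z; a 5-atom ligand lies on the
    helix axis, and its span and axial position are scanned until
    ``select_binding_site`` at 8 Å returns exactly ``n_site_residues``
    residues (verified, not assumed). A small seed-dependent lateral jitter
    keeps distinct seeds from colliding on identical coordinates.
    """
    n = spec.n_residues
    query = "".join(rng.choice(list(AMINO), size=n))
    three = {  # minimal 1→3 letter map for the fixture alphabet
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
        "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
        "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
        "W": "TRP", "Y": "TYR",
    }
    coords = _helix_backbone(n)
    protein_atoms = [
        ("A", i + 1, three[query[i]], "CA", coords[i]) for i in range(n)
    ]

    z_mid = coords[n // 2, 2]
    jitter = rng.normal(scale=0.1, size=3)
    tries = 0
    site_log = logging.getLogger("alascreen.site")
    old_level = site_log.level
    site_log.setLevel(logging.ERROR)  # empty-site probes during the scan are expected
    try:
        # scan ligand span (axial extent), axial phase, and radial offset; a
        # longer span swallows more residues, a larger radial offset sheds them
        for radial in np.arange(0.0, 14.0, 0.5):
            for span in np.arange(0.5, n + 8.0, 0.5):
                for z_off in (0.0, 0.25, 0.5, 0.75):
                    tries += 1
                    if tries > max_retries:
                        raise FixtureError(
                            f"no placement for exactly {spec.n_site_residues} "
                            f"site residues within {max_retries} attempts"
                        )
                    center = np.array([radial, 0.0, z_mid + z_off]) + jitter
                    half = span / 2.0
                    lig_offsets = np.array(
                        [[0, 0, -half], [0, 0, -half / 2], [0.7, 0, 0],
                         [0, 0, half / 2], [0, 0, half]], float
                    )
                    ligand_atoms = [
                        (f"C{i+1}", center + off) for i, off in enumerate(lig_offsets)
                    ]
                    complex_ = ReferenceComplex(
                        protein_atoms, ligand_atoms, ligand_code="LIG"
                    )
                    site = select_binding_site(complex_, cutoff=8.0)
                    if len(site) == spec.n_site_residues:
                        return complex_, query
    finally:
        site_log.setLevel(old_level)
    raise FixtureError(
        f"could not place ligand for exactly {spec.n_site_residues} site residues"
    )


def make_toy_library(spec: FixtureSpec, rng: np.random.Generator) -> list[LigandRecord]:
    """Labelled library at the 1 : decoy_ratio ratio with scaffold clusters.

    Compounds are scaffold + suffix SMILES; actives and inactives are spread
    over all scaffolds so cluster-granularity splits can balance actives.
    IC50 values are drawn on either side of the 10 nM activity threshold and
    labels derived from them, so the potency-labelling path is exercised.
    """
    n_act = spec.n_actives
    n_inact = spec.n_actives * spec.decoy_ratio
    records: list[LigandRecord] = []
    combos = [(s, x) for s in _SCAFFOLDS for x in _SUFFIXES]
    for j in range(n_act + n_inact):
        scaffold, suffix = combos[j % len(combos)]
        active = j < n_act
        ic50 = float(rng.uniform(0.1, 9.5)) if active else float(10.0 ** rng.uniform(1.5, 5.0))
        records.append(
            LigandRecord(
                ligand_id=f"{'act' if active else 'dec'}_{j:05d}",
                smiles=scaffold + suffix,
                ic50_nM=ic50,
            )
        )
    # actives cycle through scaffolds first, then decoys continue the cycle
    return label_by_ic50(records)


def make_landscape(
    spec: FixtureSpec,
    library: Sequence[LigandRecord] | None = None,
    msa: MSA | None = None,
    seed: int | None = None,
    failure_fraction: float = 0.0,
) -> Callable[[MutationMask], float]:
    """Evaluator mask → fitness composing mock prediction, docking and ROC–AUC.

    Expected fitness is strictly increasing in similarity to the planted
    hidden mask; noise comes only from the finite ligand draw. Deterministic:
    the same mask under the same seed always yields the same fitness. A mask
    whose mock structure fails the mean-pLDDT filter scores 0.0.
    """
    run_seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([run_seed & 0x7FFFFFFF, 3]))
    lib = list(library) if library is not None else make_toy_library(spec, rng)
    the_msa = msa if msa is not None else make_toy_msa(spec, rng)
    oracle = spec.landscape()

    def evaluator(mask: MutationMask) -> float:
        structure = mock_predict(
            the_msa, mask, seed=run_seed, failure_fraction=failure_fraction
        )
        if not accept_structure(structure):
            return 0.0
        dock_rng = _mask_rng(run_seed ^ 0x5A5A5A, mask)
        result = mock_dock(structure, lib, oracle, dock_rng)
        return roc_auc(result, lib)

    return evaluator
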