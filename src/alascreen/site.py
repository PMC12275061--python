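"""Binding-site identification from a holo reference complex.

Alanine-substitution candidates are the residues with any heavy atom within a
distance cutoff (default 8 Å, closed boundary) of any ligand atom in the holo
structure. The site is then mapped onto the query sequence by global pairwise
alignment, since PDB author numbering rarely matches UniProt numbering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1
from scipy.spatial.distance import cdist

__all__ = [
    "ReferenceComplex",
    "BindingSite",
    "MappingUnreliableError",
    "read_reference_complex",
    "write_reference_complex",
    "select_binding_site",
    "map_to_query",
    "ligand_centroid",
]

log = logging.getLogger(__name__)

_WATER = {"HOH", "WAT", "DOD"}


class MappingUnreliableError(ValueError):
    """Structure→query alignment identity fell below the configured floor."""


@dataclass
class ReferenceComplex:
    """Protein heavy atoms plus the bound ligand of a holo structure.

    ``protein_atoms``: (chain, residue_number, residue_name, atom_name, xyz Å).
    """

    protein_atoms: list[tuple[str, int, str, str, np.ndarray]]
    ligand_atoms: list[tuple[str, np.ndarray]]
    ligand_code: str = ""

    def __post_init__(self) -> None:
        for _, xyz in self.ligand_atoms:
            if not np.all(np.isfinite(xyz)):
                raise ValueError("non-finite ligand coordinate")

    def sequence(self) -> str:
        """One-letter protein sequence in (chain, residue_number) order."""
        seen: dict[tuple[str, int], str] = {}
        for chain, resnum, resname, _, _ in self.protein_atoms:
            seen.setdefault((chain, resnum), protein_letters_3to1.get(resname, "X"))
        return "".join(seen[k] for k in sorted(seen))

    def residue_keys(self) -> list[tuple[str, int]]:
        seen = dict.fromkeys(
            (chain, resnum) for chain, resnum, *_ in self.protein_atoms
        )
        return sorted(seen)

    def ca_coordinates(self) -> dict[tuple[str, int], np.ndarray]:
        out = {}
        for chain, resnum, _, aname, xyz in self.protein_atoms:
            if aname == "CA":
                out[(chain, resnum)] = xyz
        return out


@dataclass
class BindingSite:
    """Residues near the ligand, in PDB numbering and (once mapped) query numbering."""

    residues_pdb: list[tuple[str, int]]
    cutoff: float
    residues_query: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    def __len__(self) -> int:
        return len(self.residues_pdb)

    def to_table(self, path: str | Path) -> None:
        lines = ["chain\tresidue_pdb\tresidue_query"]
        q = self.residues_query or [None] * len(self.residues_pdb)
        for (chain, num), qr in zip(self.residues_pdb, q):
            lines.append(f"{chain}\t{num}\t{'' if qr is None else qr}")
        Path(path).write_text("\n".join(lines) + "\n")


def read_reference_complex(
    path: str | Path,
    ligand_code: str,
    ligand_chain: str | None = None,
) -> ReferenceComplex:
    """Read a holo PDB file, splitting protein heavy atoms from the named ligand.

    Keeps altloc '' or 'A' only; drops hydrogens, waters and hetero groups
    other than ``ligand_code``.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("ref", str(path))
    model = next(structure.get_models())
    protein_atoms: list[tuple[str, int, str, str, np.ndarray]] = []
    ligand_atoms: list[tuple[str, np.ndarray]] = []
    for chain in model:
        for residue in chain:
            hetflag, resnum, _ = residue.id
            resname = residue.get_resname().strip()
            if resname in _WATER:
                continue
            for atom in residue:
                if atom.element == "H":
                    continue
                if atom.get_altloc() not in (" ", "", "A"):
                    continue
                xyz = np.asarray(atom.get_coord(), dtype=float)
                if hetflag.strip():  # HETATM
                    if resname == ligand_code and (
                        ligand_chain is None or chain.id == ligand_chain
                    ):
                        ligand_atoms.append((atom.get_name(), xyz))
                else:
                    protein_atoms.append(
                        (chain.id, resnum, resname, atom.get_name(), xyz)
                    )
    if not ligand_atoms:
        raise ValueError(f"ligand {ligand_code!r} not found in {path}")
    return ReferenceComplex(protein_atoms, ligand_atoms, ligand_code)


def write_reference_complex(complex: ReferenceComplex, path: str | Path) -> None:
    """Write the complex as plain PDB ATOM/HETATM records (fixture output)."""
    lines = []
    serial = 1
    for chain, resnum, resname, aname, xyz in complex.protein_atoms:
        lines.append(
            f"ATOM  {serial:5d} {aname:^4s}{resname:>4s} {chain}{resnum:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {aname.strip()[:1]:>2s}"
        )
        serial += 1
    code = (complex.ligand_code or "LIG")[:3]
    for aname, xyz in complex.ligand_atoms:
        lines.append(
            f"HETATM{serial:5d} {aname:^4s}{code:>4s} L{1:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {aname.strip()[:1]:>2s}"
        )
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def select_binding_site(complex: ReferenceComplex, cutoff: float = 8.0) -> BindingSite:
    """Residues with at least one atom within ``cutoff`` Å of any ligand atom.

    The boundary is closed (distance == cutoff is inside). A residue qualifies
    through any single atom — the whole residue is then part of the site.
    Returns residues in (chain, residue_number) order; empty sites are legal
    but logged as a warning.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig = np.array([xyz for _, xyz in complex.ligand_atoms])
    hits: set[tuple[str, int]] = set()
    keys = [(chain, resnum) for chain, resnum, *_ in complex.protein_atoms]
    coords = np.array([a[4] for a in complex.protein_atoms])
    if len(coords):
        dmin = cdist(coords, lig).min(axis=1)
        for key, d in zip(keys, dmin):
            if d <= cutoff:
                hits.add(key)
    if not hits:
        log.warning("no residues within %.1f Å of ligand %s", cutoff, complex.ligand_code)
    return BindingSite(residues_pdb=sorted(hits), cutoff=cutoff)


def map_to_query(
    site: BindingSite,
    pdb_sequence: str,
    query_sequence: str,
    pdb_residue_keys: list[tuple[str, int]] | None = None,
    identity_floor: float = 0.9,
) -> BindingSite:
    """Fill ``residues_query`` by globally aligning the structure sequence to the query.

    ``pdb_residue_keys`` gives the (chain, residue_number) of each character of
    ``pdb_sequence``; when omitted, residue numbers are taken as 1..len on
    chain 'A'. Site residues aligned against a query gap are dropped with a
    warning. Raises :class:`MappingUnreliableError` when alignment identity
    over aligned pairs falls below ``identity_floor``.
    """
    if not pdb_sequence or not query_sequence:
        raise ValueError("both sequences must be non-empty")
    if pdb_residue_keys is None:
        pdb_residue_keys = [("A", i + 1) for i in range(len(pdb_sequence))]

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    # free terminal gaps: tags / truncations should not be punished
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    aln = aligner.align(pdb_sequence, query_sequence)[0]

    pdb_to_query: dict[int, int] = {}
    matches = total = 0
    for (ps, pe), (qs, qe) in zip(*aln.aligned):
        for off in range(pe - ps):
            pdb_to_query[ps + off] = qs + off + 1  # 1-based query position
            total += 1
            if pdb_sequence[ps + off] == query_sequence[qs + off]:
                matches += 1
    if total == 0 or matches / total < identity_floor:
        raise MappingUnreliableError(
            f"alignment identity {matches}/{total} below floor {identity_floor}"
        )

    key_to_index = {k: i for i, k in enumerate(pdb_residue_keys)}
    kept_pdb: list[tuple[str, int]] = []
    kept_query: list[int] = []
    for key in site.residues_pdb:
        idx = key_to_index.get(key)
        if idx is None or idx not in pdb_to_query:
            log.warning("site residue %s unmapped on query; dropped", key)
            continue
        kept_pdb.append(key)
        kept_query.append(pdb_to_query[idx])
    return BindingSite(
        residues_pdb=kept_pdb, cutoff=site.cutoff, residues_query=kept_query
    )


def ligand_centroid(complex: ReferenceComplex) -> np.ndarray:
    """Unweighted mean of ligand atom coordinates (Å)."""
    if not complex.ligand_atoms:
        raise ValueError("ligand has no atoms")
    return np.mean([xyz for _, xyz in complex.ligand_atoms], axis=0)
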