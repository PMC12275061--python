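"""Predicted-structure processing: confidence filtering, superposition, RMSD.

A predicted model carries per-residue pLDDT confidence (0–100, read from the
B-factor column by AlphaFold convention). Residues below 50 are trimmed; whole
models with a pre-trim mean pLDDT below 50 are rejected. Superposition onto
the holo reference uses least-squares rigid fitting (Kabsch, proper rotation
only) over Cα atoms of shared binding-site residues, so the docking box
centered on the reference ligand transfers onto the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.SVDSuperimposer import SVDSuperimposer

from .site import BindingSite, ReferenceComplex, ligand_centroid

__all__ = [
    "PredictedStructure",
    "DockingBox",
    "InsufficientAnchorError",
    "read_predicted_structure",
    "write_predicted_structure",
    "trim_low_plddt",
    "accept_structure",
    "superpose_on_site",
    "make_docking_box",
    "site_rmsd",
]


class InsufficientAnchorError(ValueError):
    """Fewer than three shared site residues available for superposition."""


@dataclass
class PredictedStructure:
    """A predicted model: per-residue atoms plus pLDDT confidence.

    ``residues`` is an ordered list of ``(query_position, residue_name,
    {atom_name: xyz})``; ``plddt`` aligns with it elementwise.
    """

    residues: list[tuple[int, str, dict[str, np.ndarray]]]
    plddt: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.plddt = np.asarray(self.plddt, dtype=float)
        if len(self.plddt) != len(self.residues):
            raise ValueError("plddt length must equal residue count")
        if len(self.plddt) and (self.plddt.min() < 0 or self.plddt.max() > 100):
            raise ValueError("pLDDT must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coordinates(self) -> dict[int, np.ndarray]:
        """Cα coordinate per query position (residues lacking Cα skipped)."""
        out = {}
        for pos, _, atoms in self.residues:
            if "CA" in atoms:
                out[pos] = atoms["CA"]
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PredictedStructure":
        new = [
            (pos, name, {a: xyz @ rotation.T + translation for a, xyz in atoms.items()})
            for pos, name, atoms in self.residues
        ]
        return PredictedStructure(new, self.plddt.copy(), self.provenance)


@dataclass
class DockingBox:
    """Axis-aligned search box for docking: center and edge lengths in Å."""

    center: np.ndarray
    size: tuple[float, float, float] = (20.0, 20.0, 20.0)

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if any(s <= 0 for s in self.size):
            raise ValueError("box edges must be positive")


def read_predicted_structure(path: str | Path, provenance: str = "") -> PredictedStructure:
    """Read a predicted-model PDB; pLDDT is taken from the B-factor column."""
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("model", str(path))
    residues = []
    plddt = []
    for residue in next(structure.get_models()).get_residues():
        if residue.id[0].strip():
            continue
        atoms = {
            a.get_name(): np.asarray(a.get_coord(), dtype=float) for a in residue
        }
        residues.append((residue.id[1], residue.get_resname().strip(), atoms))
        plddt.append(float(next(iter(residue)).get_bfactor()))
    return PredictedStructure(residues, np.array(plddt), provenance or str(path))


def write_predicted_structure(s: PredictedStructure, path: str | Path) -> None:
    """Write as PDB with pLDDT in the B-factor column (AlphaFold convention)."""
    lines = []
    serial = 1
    for (pos, name, atoms), conf in zip(s.residues, s.plddt):
        for aname, xyz in atoms.items():
            element = aname.strip()[:1]
            lines.append(
                f"ATOM  {serial:5d} {aname:^4s}{name:>4s} A{pos:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{conf:6.2f}"
                f"          {element:>2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def trim_low_plddt(s: PredictedStructure, threshold: float = 50.0) -> PredictedStructure:
    """Drop residues with pLDDT strictly below ``threshold``; order preserved."""
    keep = s.plddt >= threshold
    residues = [r for r, k in zip(s.residues, keep) if k]
    return PredictedStructure(residues, s.plddt[keep], s.provenance)


def accept_structure(s: PredictedStructure, threshold: float = 50.0) -> bool:
    """Whole-model filter: mean pre-trim pLDDT must reach ``threshold``.

    Models whose average confidence is below the threshold are discarded
    outright (an empty model is always rejected). The mean is computed before
    any trimming — rejection applies to the predicted structure as a whole.
    """
    if len(s) == 0:
        return False
    return float(np.mean(s.plddt)) >= threshold


def _shared_site_ca(
    mobile: PredictedStructure | ReferenceComplex,
    reference: PredictedStructure | ReferenceComplex,
    site: BindingSite,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired Cα coordinates over site residues present in both structures."""

    def ca_map(s, use_query: bool):
        if isinstance(s, ReferenceComplex):
            return s.ca_coordinates()
        return s.ca_coordinates()

    def keys_for(s):
        if isinstance(s, ReferenceComplex):
            return site.residues_pdb
        return site.residues_query

    ma, ra = ca_map(mobile, True), ca_map(reference, True)
    mk, rk = keys_for(mobile), keys_for(reference)
    if not mk or not rk or len(mk) != len(rk):
        # residues_query may be unset; fall back to identical key lists
        raise InsufficientAnchorError("site residue lists unavailable or unpaired")
    x, y = [], []
    for km, kr in zip(mk, rk):
        if km in ma and kr in ra:
            x.append(ma[km])
            y.append(ra[kr])
    if len(x) < 3:
        raise InsufficientAnchorError(
            f"only {len(x)} shared site residues; need >= 3"
        )
    return np.array(x), np.array(y)


def superpose_on_site(
    s: PredictedStructure,
    ref: ReferenceComplex | PredictedStructure,
    site: BindingSite,
) -> tuple[PredictedStructure, float]:
    """Least-squares rigid superposition on site Cα atoms.

    Returns the transformed copy of ``s`` and the minimized Cα RMSD. The
    rotation is a proper rotation (det +1): reflections are corrected by sign
    flip of the smallest singular axis, per the standard Kabsch treatment.
    """
    x, y = _shared_site_ca(s, ref, site)
    sup = SVDSuperimposer()
    sup.set(y, x)  # fit x (mobile) onto y (reference)
    sup.run()
    rot, tran = sup.get_rotran()
    rmsd = float(sup.get_rms())
    moved = s.transformed(rot.T, tran)
    return moved, rmsd


def make_docking_box(
    ref: ReferenceComplex, size: tuple[float, float, float] = (20.0, 20.0, 20.0)
) -> DockingBox:
    """Docking box centered on the holo ligand centroid; default 20 Å cube."""
    return DockingBox(center=ligand_centroid(ref), size=size)


def site_rmsd(
    a: PredictedStructure,
    b: PredictedStructure | ReferenceComplex,
    site: BindingSite,
) -> float:
    """Minimized Cα RMSD over shared site residues (fit on those same residues)."""
    _, rmsd = superpose_on_site(a, b, site)
    return rmsd
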