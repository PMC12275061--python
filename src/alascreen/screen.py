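"""Ligand libraries, activity labels, ROC–AUC fitness, and scaffold-aware splits.

The fitness of a predicted structure is the ROC–AUC of the ranking its docking
scores induce over a labelled ligand library: the probability that a random
active out-ranks a random inactive, with lower (more negative) scores ranking
first. Compounds the engine could not pose at all (``FAILED``) rank strictly
last — a structure that cannot accommodate a ligand earns no credit for it.

Exploration/test splits follow two schemes: fixed-size disjoint draws
(30 actives + 1500 inactives, or 10 + 500), and a 3-fold split at cluster
granularity, where Butina sphere-exclusion clustering on Morgan-fingerprint
Tanimoto distances keeps near-neighbour compounds on the same side of the
split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit.ML.Cluster import Butina
from sklearn.metrics import roc_auc_score

__all__ = [
    "FAILED",
    "LigandRecord",
    "ScreeningResult",
    "SplitSpec",
    "LabellingError",
    "UndefinedAUCError",
    "SplitError",
    "read_ligand_table",
    "write_ligand_table",
    "label_by_ic50",
    "roc_auc",
    "tanimoto",
    "fingerprints",
    "cluster_split_3fold",
    "sample_fixed_sets",
]

FAILED = "FAILED"


class LabellingError(ValueError):
    """A record has neither a label nor an IC50 to derive one from."""


class UndefinedAUCError(ValueError):
    """ROC–AUC needs at least one active and one inactive."""


class SplitError(ValueError):
    """The library cannot support the requested split."""


@dataclass
class LigandRecord:
    ligand_id: str
    smiles: str
    label: Literal["active", "inactive"] | None = None
    ic50_nM: float | None = None


@dataclass
class ScreeningResult:
    """Docking scores of one structure over a ligand library.

    ``scores`` maps ligand_id → score (kcal/mol-like, lower is better) or the
    sentinel :data:`FAILED`.
    """

    structure_id: str
    scores: dict[str, float | str]


@dataclass
class SplitSpec:
    """Exploration-set sizing. ``middle`` = (30, 1500); ``small`` = (10, 500)."""

    scheme: Literal["large", "middle", "small"]
    n_active_explore: int = 0
    n_inactive_explore: int = 0
    n_replicates: int = 3

    _SIZES = {"middle": (30, 1500), "small": (10, 500)}

    def __post_init__(self) -> None:
        if self.scheme in self._SIZES:
            self.n_active_explore, self.n_inactive_explore = self._SIZES[self.scheme]


def read_ligand_table(path: str | Path) -> list[LigandRecord]:
    """Read a delimited SMILES table with columns smiles, id, and label or ic50_nM."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    records = []
    for _, row in df.iterrows():
        label = row[cols["label"]] if "label" in cols else None
        ic50 = float(row[cols["ic50_nm"]]) if "ic50_nm" in cols and pd.notna(row[cols["ic50_nm"]]) else None
        records.append(
            LigandRecord(
                ligand_id=str(row[cols["id"]]),
                smiles=str(row[cols["smiles"]]),
                label=label if pd.notna(label) else None,
                ic50_nM=ic50,
            )
        )
    return records


def write_ligand_table(records: Sequence[LigandRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [r.ligand_id for r in records],
            "smiles": [r.smiles for r in records],
            "label": [r.label for r in records],
            "ic50_nM": [r.ic50_nM for r in records],
        }
    ).to_csv(path, index=False)


def label_by_ic50(
    records: Iterable[LigandRecord], threshold_nM: float = 10.0
) -> list[LigandRecord]:
    """Label actives by potency: IC50 strictly below ``threshold_nM`` is active.

    Records already labelled are passed through unchanged; unlabelled records
    without an IC50 raise :class:`LabellingError`.
    """
    out = []
    for r in records:
        if r.label is not None:
            out.append(r)
            continue
        if r.ic50_nM is None:
            raise LabellingError(f"{r.ligand_id}: no label and no IC50")
        label = "active" if r.ic50_nM < threshold_nM else "inactive"
        out.append(LigandRecord(r.ligand_id, r.smiles, label, r.ic50_nM))
    return out


def roc_auc(result: ScreeningResult, library: Sequence[LigandRecord]) -> float:
    """ROC–AUC of the docking ranking: lower score ranks first.

    Ties get average-rank credit (Mann–Whitney convention); FAILED ligands
    rank strictly last, tied among themselves below every finite score.
    """
    labels = []
    decision = []
    finite = [
        -float(v)
        for v in ( result.scores[r.ligand_id] for r in library )
        if v != FAILED
    ]
    floor = (min(finite) if finite else 0.0) - 1.0
    for r in library:
        if r.label is None:
            raise LabellingError(f"{r.ligand_id}: unlabelled")
        v = result.scores[r.ligand_id]
        labels.append(1 if r.label == "active" else 0)
        decision.append(floor if v == FAILED else -float(v))
    if len(set(labels)) < 2:
        raise UndefinedAUCError("library must contain both actives and inactives")
    return float(roc_auc_score(labels, decision))


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |A∩B| / |A∪B| on binary fingerprints; 0∪0 → 1."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def fingerprints(
    records: Sequence[LigandRecord], n_bits: int = 1024, radius: int = 2
) -> np.ndarray:
    """Binary Morgan (circular-substructure) fingerprints, one row per record."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    out = np.zeros((len(records), n_bits), dtype=bool)
    for i, r in enumerate(records):
        mol = Chem.MolFromSmiles(r.smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES for {r.ligand_id}: {r.smiles}")
        fp = gen.GetFingerprint(mol)
        out[i, list(fp.GetOnBits())] = True
    return out


def _tanimoto_matrix(fps: np.ndarray) -> np.ndarray:
    x = np.asarray(fps, dtype=np.int32)
    inter = x @ x.T
    on = x.sum(axis=1)
    union = on[:, None] + on[None, :] - inter
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return sim


def _butina_clusters(fps: np.ndarray, distance_cutoff: float) -> list[list[int]]:
    """Sphere-exclusion clustering on Tanimoto distance, closed under linkage.

    Butina clusters are merged whenever any cross-cluster pair lies strictly
    inside the distance cutoff (single-linkage closure), so no above-cutoff
    similarity pair can ever end up in different clusters.
    """
    n = len(fps)
    sim = _tanimoto_matrix(fps)
    dists = [1.0 - sim[i, j] for i in range(1, n) for j in range(i)]
    clusters = [sorted(c) for c in Butina.ClusterData(dists, n, distance_cutoff, isDistData=True)]
    parent = list(range(len(clusters)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    member_of = {i: c for c, cluster in enumerate(clusters) for i in cluster}
    close = sim > 1.0 - distance_cutoff
    for i, j in zip(*np.triu_indices(n, k=1)):
        if close[i, j]:
            a, b = find(member_of[i]), find(member_of[j])
            if a != b:
                parent[b] = a
    merged: dict[int, list[int]] = {}
    for c, cluster in enumerate(clusters):
        merged.setdefault(find(c), []).extend(cluster)
    return [sorted(v) for v in merged.values()]


def cluster_split_3fold(
    library: Sequence[LigandRecord],
    seed: int,
    distance_cutoff: float = 0.4,
    n_bits: int = 1024,
    radius: int = 2,
) -> list[tuple[list[LigandRecord], list[LigandRecord]]]:
    """3-fold split at scaffold-cluster granularity.

    Compounds are Butina-clustered at the given Tanimoto-distance cutoff; whole
    clusters are dealt to three folds so active counts stay balanced. Each
    fold's exploration set is the other two folds (about two-thirds of the
    library) and its test set is its own fold, so no above-cutoff neighbour
    pair straddles explore/test, and the test folds tile the library.
    """
    labelled = label_by_ic50(library)
    fps = fingerprints(labelled, n_bits=n_bits, radius=radius)
    clusters = _butina_clusters(fps, distance_cutoff)
    if len(clusters) < 3:
        raise SplitError(f"only {len(clusters)} clusters; need >= 3 for 3 folds")

    rng = np.random.default_rng(seed)
    order = sorted(
        range(len(clusters)),
        key=lambda c: (
            -sum(labelled[i].label == "active" for i in clusters[c]),
            -len(clusters[c]),
            c,
        ),
    )
    # greedy deal: next cluster goes to the fold with fewest actives (ties by size)
    fold_members: list[list[int]] = [[], [], []]
    fold_actives = [0, 0, 0]
    perm = rng.permutation(3)  # seed-dependent tie-breaking orientation
    for c in order:
        f = min(range(3), key=lambda k: (fold_actives[k], len(fold_members[k]), perm[k]))
        fold_members[f].extend(clusters[c])
        fold_actives[f] += sum(labelled[i].label == "active" for i in clusters[c])

    pairs = []
    for f in range(3):
        test = sorted(fold_members[f])
        explore = sorted(i for k in range(3) if k != f for i in fold_members[k])
        pairs.append(([labelled[i] for i in explore], [labelled[i] for i in test]))
    return pairs


def sample_fixed_sets(
    library: Sequence[LigandRecord], spec: SplitSpec, seed: int
) -> list[tuple[list[LigandRecord], list[LigandRecord]]]:
    """Three pairwise-disjoint exploration sets of fixed size, rest as test.

    Each exploration set holds exactly (n_active_explore, n_inactive_explore)
    compounds; the matching test set is the library minus that exploration set.
    """
    labelled = label_by_ic50(library)
    actives = [i for i, r in enumerate(labelled) if r.label == "active"]
    inactives = [i for i, r in enumerate(labelled) if r.label == "inactive"]
    na, ni = spec.n_active_explore, spec.n_inactive_explore
    k = spec.n_replicates
    if len(actives) < k * na:
        raise SplitError(
            f"need {k * na} actives for {k} disjoint sets of {na}; have {len(actives)}"
        )
    if len(inactives) < k * ni:
        raise SplitError(
            f"need {k * ni} inactives for {k} disjoint sets of {ni}; have {len(inactives)}"
        )
    rng = np.random.default_rng(seed)
    a_perm = rng.permutation(actives)
    i_perm = rng.permutation(inactives)
    pairs = []
    for rep in range(k):
        chosen = set(a_perm[rep * na : (rep + 1) * na]) | set(
            i_perm[rep * ni : (rep + 1) * ni]
        )
        explore = [labelled[i] for i in sorted(chosen)]
        test = [labelled[i] for i in range(len(labelled)) if i not in chosen]
        pairs.append((explore, test))
    return pairs
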