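"""Backend adapters: structure prediction and docking as external processes.

Command builders are pure functions from configuration to argument lists and
never execute anything; execution goes through a runner object so tests (and
dry runs) can intercept. The in-process mocks replace both engines with a
deterministic toy: a smooth mask-dependent fold, and a docking oracle whose
score distributions make the induced ROC–AUC a known monotone function of the
mask's similarity to a hidden optimum — enough to exercise the full search
loop without AlphaFold2 or a docking engine.
"""

from __future__ import annotations

import re
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .msa import MSA, MutationMask
from .screen import FAILED, LigandRecord, ScreeningResult
from .structmodel import DockingBox, PredictedStructure

__all__ = [
    "PredictorConfig",
    "DockerConfig",
    "PlantedLandscape",
    "build_predictor_command",
    "build_docking_command",
    "parse_docking_score",
    "mock_predict",
    "mock_dock",
    "SubprocessRunner",
    "RecordingRunner",
]


@dataclass
class PredictorConfig:
    """Structure-prediction engine settings (LocalColabFold-style CLI).

    Shallow MSAs and few recycles promote conformational diversity; defaults
    keep one model per mask with a fixed seed so a mask maps to one structure.
    """

    executable: str = "colabfold_batch"
    msa_depth_limit: int = 32
    n_recycles: int = 1
    n_models: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_recycles < 1:
            raise ValueError("n_recycles must be >= 1")


@dataclass
class DockerConfig:
    """Docking engine settings (Uni-Dock/Vina-style CLI)."""

    executable: str = "unidock"
    scoring_function: str = "vina"
    search_mode: str = "balance"
    seed: int = 1
    box: DockingBox | None = None


def build_predictor_command(
    msa_path: str | Path, config: PredictorConfig, output_dir: str | Path = "predictions"
) -> list[str]:
    """Argument list for one prediction run on a (mutated) MSA file."""
    return [
        str(config.executable),
        str(msa_path),
        str(output_dir),
        "--num-recycle", str(config.n_recycles),
        "--max-msa", f"{config.msa_depth_limit}:{2 * config.msa_depth_limit}",
        "--num-models", str(config.n_models),
        "--random-seed", str(config.seed),
    ]


def build_docking_command(
    receptor_path: str | Path,
    ligand_paths: Sequence[str | Path],
    config: DockerConfig,
    output_dir: str | Path = "docking",
) -> list[str]:
    """Argument list for one batch docking run against a prepared receptor."""
    if not ligand_paths:
        raise ValueError("ligand list is empty")
    if config.box is None:
        raise ValueError("docking box is not defined")
    c, s = config.box.center, config.box.size
    args = [
        str(config.executable),
        "--receptor", str(receptor_path),
        "--gpu_batch", *[str(p) for p in ligand_paths],
        "--scoring", config.scoring_function,
        "--search_mode", config.search_mode,
        "--seed", str(config.seed),
        "--center_x", f"{c[0]:g}", "--center_y", f"{c[1]:g}", "--center_z", f"{c[2]:g}",
        "--size_x", f"{s[0]:g}", "--size_y", f"{s[1]:g}", "--size_z", f"{s[2]:g}",
        "--dir", str(output_dir),
    ]
    return args


_SCORE_LINE = re.compile(
    r"(?:REMARK VINA RESULT:|^\s*1\s+)\s*(-?\d+\.\d+)", re.MULTILINE
)


def parse_docking_score(result_path: str | Path) -> float | str:
    """Best-pose score from an engine result file, or FAILED when absent.

    Tolerant of both ``REMARK VINA RESULT:`` pose headers (pdbqt output) and
    log-table rows whose first column is the pose index.
    """
    path = Path(result_path)
    if not path.exists():
        return FAILED
    m = _SCORE_LINE.search(path.read_text())
    return float(m.group(1)) if m else FAILED


class SubprocessRunner:
    """Executes command argument lists; the only place a process is spawned."""

    def run(self, args: Sequence[str]) -> int:
        return subprocess.run(list(args), check=False).returncode


class RecordingRunner:
    """Test/dry-run seam: records commands instead of executing them."""

    def __init__(self) -> None:
        self.calls: list[list[str]] = []

    def run(self, args: Sequence[str]) -> int:
        self.calls.append(list(args))
        return 0


# --- in-process mocks ---------------------------------------------------------

_CA_STEP = 3.8  # Å, consecutive Cα spacing


def _mask_rng(seed: int, mask: MutationMask) -> np.random.Generator:
    """Deterministic generator keyed on (seed, mask bits): same mask, same draws."""
    s = mask.as_string() or "0"
    bit_words = [int(s[i : i + 31], 2) for i in range(0, len(s), 31)]
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, len(mask)] + bit_words)
    )


def mock_predict(
    msa: MSA,
    mask: MutationMask,
    seed: int = 0,
    n_residues: int | None = None,
    failure_fraction: float = 0.0,
) -> PredictedStructure:
    """Deterministic toy fold whose geometry is a smooth function of the mask.

    The backbone is a helix-like Cα trace; each set bit displaces a Gaussian
    neighbourhood of its residue along a bit-specific fixed direction, so masks
    at Hamming distance 1 always yield distinct binding-site geometry. pLDDT
    is drawn so that a ``failure_fraction`` share of structures fails the
    mean-50 acceptance filter. Reproducible bit-identically from (seed, mask).
    """
    n = n_residues if n_residues is not None else len(msa.query_sequence)
    t = np.arange(n)
    base = np.stack(
        [2.3 * np.cos(t * 0.6), 2.3 * np.sin(t * 0.6), 1.5 * t * (_CA_STEP / 3.8)],
        axis=1,
    )
    # bit-specific displacement fields: fixed by (seed, bit index), not by mask
    field_rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 7]))
    directions = field_rng.normal(size=(len(mask), 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    coords = base.copy()
    for k, (res, bit) in enumerate(zip(mask.residue_indices, mask.bits)):
        if not bit:
            continue
        center = min(res - 1, n - 1)
        weight = np.exp(-0.5 * ((t - center) / 2.0) ** 2)
        coords += 1.2 * weight[:, None] * directions[k]

    rng = _mask_rng(seed, mask)
    if rng.random() < failure_fraction:
        plddt = rng.uniform(20.0, 45.0, size=n)  # mean < 50: filtered out
    else:
        plddt = np.clip(rng.normal(85.0, 8.0, size=n), 50.0, 100.0)
    residues = [(i + 1, "ALA", {"CA": coords[i]}) for i in range(n)]
    return PredictedStructure(
        residues, plddt, provenance=f"mask={mask.as_string()};backend=mock"
    )


@dataclass
class PlantedLandscape:
    """Docking-score oracle with a hidden optimal mask.

    Active scores are drawn N(mu_active − delta·sim, sigma) and inactives
    N(mu_inactive, sigma), where sim is 1 minus the normalized Hamming
    distance between the evaluated mask and ``hidden_bits``. The expected
    ROC–AUC is then Φ((mu_inactive − mu_active + delta·sim) / (sigma·√2)) —
    strictly increasing in sim whenever delta > 0.
    """

    hidden_bits: np.ndarray
    delta: float = 1.16
    sigma: float = 0.5
    mu_active: float = -7.0
    mu_inactive: float = -7.0

    def __post_init__(self) -> None:
        self.hidden_bits = np.asarray(self.hidden_bits, dtype=int)

    def similarity(self, mask: MutationMask) -> float:
        bits = np.asarray(mask.bits, dtype=int)
        if len(bits) != len(self.hidden_bits):
            raise ValueError("mask length does not match hidden mask")
        return 1.0 - float(np.mean(bits != self.hidden_bits))

    def expected_auc(self, sim: float) -> float:
        gap = self.mu_inactive - self.mu_active + self.delta * sim
        return float(norm.cdf(gap / (self.sigma * np.sqrt(2.0))))


def _mask_from_provenance(provenance: str) -> str:
    m = re.search(r"mask=([01]*)", provenance)
    if not m:
        raise ValueError(f"no mask recorded in provenance {provenance!r}")
    return m.group(1)


def mock_dock(
    structure: PredictedStructure,
    library: Sequence[LigandRecord],
    oracle: PlantedLandscape,
    rng: np.random.Generator,
) -> ScreeningResult:
    """Score every library ligand under the planted-landscape oracle."""
    bits = _mask_from_provenance(structure.provenance)
    mask = MutationMask(list(range(1, len(bits) + 1)), [int(c) for c in bits])
    sim = oracle.similarity(mask)
    labels = np.array([r.label == "active" for r in library])
    mu = np.where(labels, oracle.mu_active - oracle.delta * sim, oracle.mu_inactive)
    scores = rng.normal(mu, oracle.sigma)
    return ScreeningResult(
        structure_id=structure.provenance,
        scores={r.ligand_id: float(s) for r, s in zip(library, scores)},
    )
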