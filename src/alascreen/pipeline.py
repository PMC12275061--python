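"""End-to-end orchestration: exploration runs, baselines, and reports.

One run wires the whole loop together: binding-site residues are selected from
the holo reference and mapped onto the query, the optimizer proposes
substitution masks, each mask perturbs the MSA, a structure is predicted
(mock or external backend), confidence-filtered, superposed onto the
reference site, docked against the exploration ligands and scored by ROC–AUC.
Baselines reproduce the comparison protocol: the reference structure itself,
the average and the best-on-test of randomly perturbed predictions, random
search, and the GA — three trials each, averaged.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .backends import PlantedLandscape, _mask_rng, mock_dock, mock_predict
from .msa import MSA, MutationMask, apply_alanine_mask, read_msa
from .optimize import GAConfig, Individual, Trajectory, evaluate_on_test, random_mask, run_ga, run_random_search
from .screen import (
    LigandRecord,
    SplitSpec,
    cluster_split_3fold,
    read_ligand_table,
    roc_auc,
    sample_fixed_sets,
)
from .site import BindingSite, ReferenceComplex, map_to_query, read_reference_complex, select_binding_site
from .structmodel import PredictedStructure, accept_structure, site_rmsd, superpose_on_site, trim_low_plddt

__all__ = [
    "RunConfig",
    "ComparisonReport",
    "mock_structure_evaluator",
    "run_exploration",
    "run_baselines",
    "report_heatmap",
    "report_rmsd_scatter",
]

log = logging.getLogger(__name__)

METHODS = ("reference_structure", "af2_random_mean", "af2_random_best_on_test", "random_search", "ga")


@dataclass
class RunConfig:
    """Everything one exploration run needs; loadable from a YAML file."""

    msa_path: str = ""
    holo_pdb_path: str = ""
    ligand_table_path: str = ""
    output_dir: str = "runs"
    ligand_code: str = "LIG"
    site_cutoff: float = 8.0
    split_scheme: str = "middle"
    optimizer: str = "ga"            # {"ga", "random"}
    backend: str = "mock"            # {"mock", "localcolabfold+unidock"}
    budget: int = 1100
    seed: int = 0
    n_trials: int = 3
    mutate_query: bool = False
    population_size: int = 50
    n_generations: int = 22
    crossover_prob: float = 0.9
    tournament_size: int = 3
    n_elite: int = 1
    # mock-backend landscape parameters
    landscape_delta: float = 1.16
    landscape_sigma: float = 0.5
    failure_fraction: float = 0.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def ga_config(self, seed: int | None = None) -> GAConfig:
        return GAConfig(
            population_size=self.population_size,
            n_generations=self.n_generations,
            crossover_prob=self.crossover_prob,
            tournament_size=self.tournament_size,
            n_elite=self.n_elite,
            seed=self.seed if seed is None else seed,
            budget=self.budget,
        )

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ComparisonReport:
    """Per-method mean test ROC–AUC with the per-trial values behind it."""

    per_trial: dict[str, list[float]]

    def means(self) -> dict[str, float]:
        return {m: float(np.mean(v)) for m, v in self.per_trial.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for method, values in self.per_trial.items():
            rows.append(
                {
                    "method": method,
                    "mean_test_auc": float(np.mean(values)),
                    "n_trials": len(values),
                    **{f"trial_{i+1}": v for i, v in enumerate(values)},
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


def mock_structure_evaluator(
    msa: MSA,
    site: BindingSite,
    ref: ReferenceComplex,
    library: Sequence[LigandRecord],
    oracle: PlantedLandscape,
    seed: int,
    mutate_query: bool = False,
    failure_fraction: float = 0.0,
    structure_log: list[PredictedStructure] | None = None,
    eval_log: list[dict] | None = None,
) -> Callable[[MutationMask], float]:
    """Full-loop evaluator on the mock backend.

    Per mask: perturb the MSA, predict a toy structure, reject on mean pLDDT,
    trim low-confidence residues, superpose onto the reference site, dock
    under the planted oracle, return the exploration ROC–AUC. Rejected or
    unsuperposable structures score 0.0. ``eval_log`` collects one structured
    record per evaluation (mask, fitness, accept flag, wall time).
    """

    def evaluator(mask: MutationMask) -> float:
        t0 = time.perf_counter()
        mutated = apply_alanine_mask(msa, mask, mutate_query=mutate_query)
        structure = mock_predict(
            mutated, mask, seed=seed, failure_fraction=failure_fraction
        )
        accepted = accept_structure(structure)
        if accepted:
            trimmed = trim_low_plddt(structure)
            fitted, _ = superpose_on_site(trimmed, ref, site)
            if structure_log is not None:
                structure_log.append(fitted)
            result = mock_dock(fitted, library, oracle, _mask_rng(seed ^ 0x5A5A5A, mask))
            fitness = roc_auc(result, library)
        else:
            fitness = 0.0
        if eval_log is not None:
            eval_log.append(
                {
                    "mask": mask.as_string(),
                    "fitness": fitness,
                    "accepted": accepted,
                    "elapsed_s": round(time.perf_counter() - t0, 6),
                }
            )
        return fitness

    return evaluator


def _load_inputs(config: RunConfig):
    msa = read_msa(config.msa_path)
    ref = read_reference_complex(config.holo_pdb_path, config.ligand_code)
    library = read_ligand_table(config.ligand_table_path)
    site = select_binding_site(ref, cutoff=config.site_cutoff)
    site = map_to_query(
        site, ref.sequence(), msa.query_sequence, pdb_residue_keys=ref.residue_keys()
    )
    return msa, ref, library, site


def _splits(config: RunConfig, library: Sequence[LigandRecord]):
    if config.split_scheme == "large":
        return cluster_split_3fold(library, seed=config.seed)
    return sample_fixed_sets(library, SplitSpec(scheme=config.split_scheme), config.seed)


def _oracle(config: RunConfig, site_len: int) -> PlantedLandscape:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 11]))
    hidden = (rng.random(site_len) < 0.5).astype(int)
    return PlantedLandscape(
        hidden_bits=hidden, delta=config.landscape_delta, sigma=config.landscape_sigma
    )


def _write_manifest(config: RunConfig, out: Path) -> None:
    manifest = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def run_exploration(config: RunConfig, trial: int = 0) -> Trajectory:
    """One exploration run: site selection → optimizer loop → artifacts.

    Writes trajectory CSV, best-mask table, heatmap matrix CSV and a manifest
    into ``output_dir``; the GA additionally checkpoints each generation, so
    an interrupted run resumes. Only the mock backend executes in-process; the
    external backend path raises at startup when its executables are absent.
    """
    if config.backend != "mock":
        raise RuntimeError(
            "external backend requested: prediction/docking engines must be "
            "installed and configured; use backend='mock' for desk-scale runs"
        )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    msa, ref, library, site = _load_inputs(config)
    explore, test = _splits(config, library)[trial % 3]
    oracle = _oracle(config, len(site.residues_query))
    trial_seed = (config.seed + 1000 * trial) & 0x7FFFFFFF
    eval_log: list[dict] = []
    evaluator = mock_structure_evaluator(
        msa, site, ref, explore, oracle, trial_seed,
        mutate_query=config.mutate_query, failure_fraction=config.failure_fraction,
        eval_log=eval_log,
    )
    test_evaluator = mock_structure_evaluator(
        msa, site, ref, test, oracle, trial_seed,
        mutate_query=config.mutate_query, failure_fraction=config.failure_fraction,
    )
    length = len(site.residues_query)
    if config.optimizer == "ga":
        traj = run_ga(
            evaluator, length, config.ga_config(seed=trial_seed),
            residue_indices=site.residues_query, test_evaluator=test_evaluator,
            checkpoint_path=out / f"checkpoint_trial{trial}.json",
        )
    else:
        traj = run_random_search(
            evaluator, length, residue_indices=site.residues_query,
            budget=config.budget, seed=trial_seed, test_evaluator=test_evaluator,
        )
    traj.to_csv(out / f"trajectory_trial{trial}.csv")
    traj.best.mask.to_table(out / f"best_mask_trial{trial}.tsv")
    if eval_log:
        pd.DataFrame(eval_log).to_csv(out / f"evaluations_trial{trial}.csv", index=False)
        n_rejected = sum(not r["accepted"] for r in eval_log)
        log.info(
            "trial %d: %d evaluations, %d rejected by the mean-pLDDT filter",
            trial, len(eval_log), n_rejected,
        )
    heat = report_heatmap(traj)
    pd.DataFrame(heat, columns=[str(r) for r in site.residues_query]).to_csv(
        out / f"heatmap_trial{trial}.csv", index=False
    )
    _write_manifest(config, out)
    return traj


def run_baselines(config: RunConfig) -> ComparisonReport:
    """Comparison protocol over ``n_trials`` exploration/test splits.

    Five methods are reported, each as test-set ROC–AUC: the reference
    structure itself; the mean over ``budget`` random p=0.5 perturbations
    ("what an average perturbed prediction gives"); the best of those on the
    test set; random search; and the GA (both evaluated on the test set via
    their best exploration-set individual).
    """
    if config.backend != "mock":
        raise RuntimeError("baseline protocol runs on the mock backend only")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    msa, ref, library, site = _load_inputs(config)
    splits = _splits(config, library)
    oracle = _oracle(config, len(site.residues_query))
    length = len(site.residues_query)
    per_trial: dict[str, list[float]] = {m: [] for m in METHODS}
    for trial in range(config.n_trials):
        explore, test = splits[trial % len(splits)]
        trial_seed = (config.seed + 1000 * trial) & 0x7FFFFFFF
        ev_explore = mock_structure_evaluator(
            msa, site, ref, explore, oracle, trial_seed,
            mutate_query=config.mutate_query, failure_fraction=config.failure_fraction,
        )
        ev_test = mock_structure_evaluator(
            msa, site, ref, test, oracle, trial_seed,
            mutate_query=config.mutate_query, failure_fraction=config.failure_fraction,
        )
        # (a) the reference structure: dock the holo model as-is (zero mask)
        zero = MutationMask(list(site.residues_query), [0] * length)
        per_trial["reference_structure"].append(ev_test(zero))
        # (b)/(c) random perturbations: mean on test, and best-on-test
        rng = np.random.default_rng(np.random.SeedSequence([trial_seed, 17]))
        test_scores = [
            ev_test(random_mask(length, site.residues_query, p=0.5, rng=rng))
            for _ in range(config.budget)
        ]
        per_trial["af2_random_mean"].append(float(np.mean(test_scores)))
        per_trial["af2_random_best_on_test"].append(float(np.max(test_scores)))
        # (d) random search and (e) GA, judged on the held-out test set
        rs = run_random_search(
            ev_explore, length, residue_indices=site.residues_query,
            budget=config.budget, seed=trial_seed,
        )
        per_trial["random_search"].append(evaluate_on_test(rs.best, ev_test))
        ga = run_ga(
            ev_explore, length, config.ga_config(seed=trial_seed),
            residue_indices=site.residues_query,
        )
        per_trial["ga"].append(evaluate_on_test(ga.best, ev_test))
    report = ComparisonReport(per_trial=per_trial)
    report.to_csv(out / "comparison.csv")
    _write_manifest(config, out)
    return report


def report_heatmap(trajectory: Trajectory) -> np.ndarray:
    """0/1 matrix, one row per generation: the best individual's mask bits.

    Columns follow the trajectory's residue order (ascending residue number) —
    the data behind a mutation-transition heatmap.
    """
    if not trajectory.records:
        raise ValueError("trajectory is empty")
    return np.array(
        [[int(c) for c in r.best_mask] for r in trajectory.records], dtype=int
    )


def report_rmsd_scatter(
    structures: Sequence[PredictedStructure],
    apo_ref: ReferenceComplex | PredictedStructure,
    holo_ref: ReferenceComplex | PredictedStructure,
    site: BindingSite,
) -> pd.DataFrame:
    """Binding-site RMSD of each structure to the apo and holo references.

    One row per structure: (id, rmsd_to_apo, rmsd_to_holo). When no apo
    crystal exists, a default prediction stands in as ``apo_ref``.
    """
    rows = []
    for s in structures:
        rows.append(
            {
                "id": s.provenance,
                "rmsd_to_apo": site_rmsd(s, apo_ref, site),
                "rmsd_to_holo": site_rmsd(s, holo_ref, site),
            }
        )
    return pd.DataFrame(rows)
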