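import numpy as np
import pytest
from scipy.stats import norm

from alascreen.backends import (
    DockerConfig,
    PlantedLandscape,
    PredictorConfig,
    RecordingRunner,
    build_docking_command,
    build_predictor_command,
    mock_dock,
    mock_predict,
    parse_docking_score,
)
from alascreen.msa import MutationMask
from alascreen.screen import FAILED, LigandRecord, roc_auc
from alascreen.structmodel import DockingBox, accept_structure
from alascreen.synth import FixtureSpec, make_toy_msa


@pytest.fixture
def msa(rng):
    return make_toy_msa(FixtureSpec(n_residues=40, n_msa_rows=8), rng)


def mask_of(bits):
    return MutationMask(list(range(1, len(bits) + 1)), list(bits))


class TestPredictorCommand:
    def test_contains_configured_parameters(self, tmp_path):
        cfg = PredictorConfig(n_recycles=1, msa_depth_limit=32, n_models=1, seed=5)
        args = build_predictor_command(tmp_path / "in.a3m", cfg)
        assert str(tmp_path / "in.a3m") in args
        assert args[args.index("--num-recycle") + 1] == "1"
        assert args[args.index("--max-msa") + 1] == "32:64"
        assert args[args.index("--num-models") + 1] == "1"
        assert args[args.index("--random-seed") + 1] == "5"

    def test_pure_function_of_inputs(self, tmp_path):
        cfg = PredictorConfig()
        a = build_predictor_command(tmp_path / "m.a3m", cfg)
        b = build_predictor_command(tmp_path / "m.a3m", cfg)
        assert a == b

    def test_recycle_floor_enforced(self):
        with pytest.raises(ValueError):
            PredictorConfig(n_recycles=0)


class TestDockingCommand:
    def box(self):
        return DockingBox(center=np.array([1.0, 2.0, 3.0]))

    def test_engine_settings_match_defaults(self):
        cfg = DockerConfig(box=self.box())
        args = build_docking_command("rec.pdbqt", ["a.pdbqt"], cfg)
        assert args[args.index("--scoring") + 1] == "vina"
        assert args[args.index("--search_mode") + 1] == "balance"
        assert args[args.index("--seed") + 1] == "1"
        for axis in "xyz":
            assert args[args.index(f"--size_{axis}") + 1] == "20"

    def test_all_ligands_present_exactly_once(self):
        cfg = DockerConfig(box=self.box())
        ligands = [f"l{i}.pdbqt" for i in range(7)]
        args = build_docking_command("rec.pdbqt", ligands, cfg)
        for l in ligands:
            assert args.count(l) == 1

    def test_empty_ligand_list_raises(self):
        with pytest.raises(ValueError):
            build_docking_command("rec.pdbqt", [], DockerConfig(box=self.box()))

    def test_builders_never_execute(self):
        runner = RecordingRunner()
        cfg = DockerConfig(box=self.box())
        build_docking_command("rec.pdbqt", ["a.pdbqt"], cfg)
        assert runner.calls == []  # building is pure; running is explicit
        runner.run(["echo", "hi"])
        assert runner.calls == [["echo", "hi"]]


class TestScoreParsing:
    def test_vina_remark_line(self, tmp_path):
        p = tmp_path / "out.pdbqt"
        p.write_text("MODEL 1\nREMARK VINA RESULT:    -9.31  0.000  0.000\nENDMDL\n")
        assert parse_docking_score(p) == pytest.approx(-9.31)

    def test_log_table_row(self, tmp_path):
        p = tmp_path / "log.txt"
        p.write_text("mode |  affinity\n-----+----------\n   1    -7.25   0.000\n")
        assert parse_docking_score(p) == pytest.approx(-7.25)

    def test_missing_file_or_score_is_failed(self, tmp_path):
        assert parse_docking_score(tmp_path / "nope.txt") == FAILED
        p = tmp_path / "empty.txt"
        p.write_text("no poses found\n")
        assert parse_docking_score(p) == FAILED


class TestMockPredict:
    def test_bit_identical_reproducibility(self, msa):
        m = mask_of([0] * 12)
        a = mock_predict(msa, m, seed=3)
        b = mock_predict(msa, m, seed=3)
        assert np.array_equal(a.plddt, b.plddt)
        for (_, _, x), (_, _, y) in zip(a.residues, b.residues):
            assert np.array_equal(x["CA"], y["CA"])

    def test_hamming_one_masks_differ_geometrically(self, msa):
        base = [0] * 12
        s0 = mock_predict(msa, mask_of(base), seed=0)
        for flip in range(12):
            bits = list(base)
            bits[flip] = 1
            s1 = mock_predict(msa, mask_of(bits), seed=0)
            d = max(
                np.linalg.norm(x["CA"] - y["CA"])
                for (_, _, x), (_, _, y) in zip(s0.residues, s1.residues)
            )
            assert d > 0

    def test_failure_fraction_controls_acceptance(self, msa):
        m = mask_of([1, 0] * 6)
        always = mock_predict(msa, m, seed=1, failure_fraction=0.0)
        never = mock_predict(msa, m, seed=1, failure_fraction=1.0)
        assert accept_structure(always)
        assert not accept_structure(never)


class TestMockDock:
    def library(self, n_active=20, n_inactive=480):
        return [
            LigandRecord(f"a{i}", "C", label="active") for i in range(n_active)
        ] + [
            LigandRecord(f"d{i}", "C", label="inactive") for i in range(n_inactive)
        ]

    def structure(self, msa, bits):
        return mock_predict(msa, mask_of(bits), seed=0)

    def test_null_effect_gives_half_auc(self, msa):
        oracle = PlantedLandscape(hidden_bits=np.ones(12, int), delta=0.0)
        lib = self.library()
        aucs = [
            roc_auc(
                mock_dock(self.structure(msa, [1] * 12), lib, oracle, np.random.default_rng(s)),
                lib,
            )
            for s in range(10)
        ]
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_optimal_mask_with_strong_signal_separates(self, msa):
        oracle = PlantedLandscape(hidden_bits=np.ones(12, int), delta=3.0, sigma=0.5)
        lib = self.library()
        result = mock_dock(self.structure(msa, [1] * 12), lib, oracle, np.random.default_rng(0))
        assert roc_auc(result, lib) > 0.95

    def test_vanishing_noise_reaches_perfect_auc(self, msa):
        oracle = PlantedLandscape(hidden_bits=np.ones(12, int), delta=1.0, sigma=1e-9)
        lib = self.library()
        result = mock_dock(self.structure(msa, [1] * 12), lib, oracle, np.random.default_rng(0))
        assert roc_auc(result, lib) == pytest.approx(1.0)

    def test_empirical_auc_matches_closed_form_on_similarity_grid(self, msa):
        """Monte-Carlo AUC vs Φ((μi − μa + δ·sim)/(σ√2)) within 3σ at each grid point."""
        length = 12
        oracle = PlantedLandscape(hidden_bits=np.ones(length, int), delta=1.16, sigma=0.5)
        lib = self.library(n_active=30, n_inactive=1500)
        n_rep = 20
        for sim in (0.0, 0.25, 0.5, 0.75, 1.0):
            k = round(sim * length)
            bits = [1] * k + [0] * (length - k)
            expected = oracle.expected_auc(oracle.similarity(mask_of(bits)))
            aucs = [
                roc_auc(
                    mock_dock(self.structure(msa, bits), lib, oracle, np.random.default_rng(100 + r)),
                    lib,
                )
                for r in range(n_rep)
            ]
            mc_sigma = np.std(aucs, ddof=1) / np.sqrt(n_rep)
            assert abs(np.mean(aucs) - expected) < 3 * max(mc_sigma, 1e-3)

    def test_expected_auc_strictly_increasing_in_similarity(self):
        oracle = PlantedLandscape(hidden_bits=np.ones(10, int))
        grid = [oracle.expected_auc(s) for s in np.linspace(0, 1, 11)]
        assert all(x < y for x, y in zip(grid, grid[1:]))
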