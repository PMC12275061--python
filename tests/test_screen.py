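import numpy as np
import pytest

from alascreen.screen import (
    FAILED,
    LabellingError,
    LigandRecord,
    ScreeningResult,
    SplitError,
    SplitSpec,
    UndefinedAUCError,
    cluster_split_3fold,
    fingerprints,
    label_by_ic50,
    read_ligand_table,
    roc_auc,
    sample_fixed_sets,
    tanimoto,
    write_ligand_table,
)
from alascreen.synth import FixtureSpec, make_toy_library


def lib(labels):
    return [
        LigandRecord(f"L{i}", "C", label=("active" if l else "inactive"))
        for i, l in enumerate(labels)
    ]


def result(scores):
    return ScreeningResult("s", {f"L{i}": s for i, s in enumerate(scores)})


class TestLabelling:
    @pytest.mark.parametrize(
        "ic50,expected",
        [(9.9, "active"), (10.0, "inactive"), (0.1, "active"), (5000.0, "inactive")],
    )
    def test_strict_10nM_threshold(self, ic50, expected):
        (r,) = label_by_ic50([LigandRecord("x", "C", ic50_nM=ic50)])
        assert r.label == expected

    def test_elementwise_over_mixed_values(self):
        values = [1.0, 9.99, 10.0, 10.01, 250.0]
        out = label_by_ic50(
            [LigandRecord(f"x{i}", "C", ic50_nM=v) for i, v in enumerate(values)]
        )
        assert [r.label for r in out] == [
            "active" if v < 10 else "inactive" for v in values
        ]

    def test_missing_ic50_and_label_raises(self):
        with pytest.raises(LabellingError):
            label_by_ic50([LigandRecord("x", "C")])


class TestRocAuc:
    def test_interleaved_ranking_is_three_quarters(self):
        # actives at -9 and -7, inactives at -8 and -6: 3 of 4 pairs concordant
        library = lib([1, 1, 0, 0])
        r = result([-9, -7, -8, -6])
        assert roc_auc(r, library) == pytest.approx(0.75)

    def test_perfect_separation(self):
        library = lib([1, 1, 0, 0, 0])
        r = result([-9, -8.5, -5, -4, -3])
        assert roc_auc(r, library) == 1.0

    def test_full_tie_gives_half(self):
        library = lib([1, 0, 1, 0])
        r = result([-5, -5, -5, -5])
        assert roc_auc(r, library) == pytest.approx(0.5)

    def test_failed_ligands_rank_strictly_last(self):
        # the failed active loses every pair; the docked active wins all
        library = lib([1, 1, 0, 0])
        r = result([-9, FAILED, -8, -6])
        # pairs: (a0 beats both) + (a1 loses both) = 2/4
        assert roc_auc(r, library) == pytest.approx(0.5)

    def test_failed_ties_among_themselves(self):
        library = lib([1, 0])
        r = result([FAILED, FAILED])
        assert roc_auc(r, library) == pytest.approx(0.5)

    def test_single_class_raises(self):
        with pytest.raises(UndefinedAUCError):
            roc_auc(result([-5, -4]), lib([1, 1]))

    def test_negated_ranking_complements(self, rng):
        for _ in range(10):
            labels = rng.integers(0, 2, size=20)
            if labels.min() == labels.max():
                continue
            scores = rng.normal(size=20)  # continuous: ties a.s. absent
            library = lib(labels)
            fwd = roc_auc(result(scores), library)
            rev = roc_auc(result(-scores), library)
            assert fwd == pytest.approx(1.0 - rev, abs=1e-12)


class TestTanimoto:
    def test_identical_nonempty_is_one(self):
        fp = np.array([1, 0, 1, 1], bool)
        assert tanimoto(fp, fp) == 1.0

    def test_disjoint_is_zero(self):
        assert tanimoto(np.array([1, 0, 0]), np.array([0, 1, 1])) == 0.0

    def test_hand_counted_overlap(self):
        a = np.zeros(8, bool)
        b = np.zeros(8, bool)
        a[[1, 2, 3]] = True
        b[[2, 3, 4]] = True
        assert tanimoto(a, b) == pytest.approx(0.5)

    def test_empty_union_defined_as_one(self):
        z = np.zeros(4, bool)
        assert tanimoto(z, z) == 1.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            tanimoto(np.zeros(4, bool), np.zeros(5, bool))


@pytest.fixture(scope="module")
def small_library():
    gen = np.random.default_rng(3)
    return make_toy_library(FixtureSpec(n_actives=12, decoy_ratio=4, n_site_residues=10), gen)


class TestClusterSplit:
    def test_no_similar_pair_straddles_explore_and_test(self, small_library):
        folds = cluster_split_3fold(small_library, seed=0, distance_cutoff=0.4)
        fps = fingerprints(small_library)
        index = {r.ligand_id: i for i, r in enumerate(small_library)}
        for explore, test in folds:
            for e in explore:
                for t in test:
                    sim = tanimoto(fps[index[e.ligand_id]], fps[index[t.ligand_id]])
                    assert sim <= 0.6 + 1e-12  # distance > cutoff across the split

    def test_test_folds_cover_library_and_are_disjoint_from_explore(self, small_library):
        folds = cluster_split_3fold(small_library, seed=0)
        covered = set()
        for explore, test in folds:
            ids_e = {r.ligand_id for r in explore}
            ids_t = {r.ligand_id for r in test}
            assert not ids_e & ids_t
            covered |= ids_t
        assert covered == {r.ligand_id for r in small_library}

    def test_explore_fraction_near_two_thirds(self, small_library):
        folds = cluster_split_3fold(small_library, seed=0)
        for explore, _ in folds:
            frac = len(explore) / len(small_library)
            assert 0.45 < frac < 0.85  # cluster granularity around 2/3

    def test_reproducible_under_seed(self, small_library):
        a = cluster_split_3fold(small_library, seed=5)
        b = cluster_split_3fold(small_library, seed=5)
        for (ea, ta), (eb, tb) in zip(a, b):
            assert [r.ligand_id for r in ea] == [r.ligand_id for r in eb]
            assert [r.ligand_id for r in ta] == [r.ligand_id for r in tb]


@pytest.fixture(scope="module")
def big_library():
    gen = np.random.default_rng(9)
    return make_toy_library(FixtureSpec(n_actives=100, decoy_ratio=50, n_site_residues=10), gen)


class TestFixedSets:
    def test_middle_spec_sizes(self, big_library):
        sets = sample_fixed_sets(big_library, SplitSpec(scheme="middle"), seed=1)
        for explore, test in sets:
            assert sum(r.label == "active" for r in explore) == 30
            assert sum(r.label == "inactive" for r in explore) == 1500
            assert len(explore) + len(test) == len(big_library)

    def test_small_spec_sizes(self, big_library):
        sets = sample_fixed_sets(big_library, SplitSpec(scheme="small"), seed=1)
        for explore, _ in sets:
            assert sum(r.label == "active" for r in explore) == 10
            assert sum(r.label == "inactive" for r in explore) == 500

    def test_exploration_sets_pairwise_disjoint(self, big_library):
        sets = sample_fixed_sets(big_library, SplitSpec(scheme="small"), seed=2)
        ids = [{r.ligand_id for r in explore} for explore, _ in sets]
        assert not (ids[0] & ids[1]) and not (ids[0] & ids[2]) and not (ids[1] & ids[2])

    def test_deficit_raises_with_named_shortfall(self, small_library):
        with pytest.raises(SplitError, match="active"):
            sample_fixed_sets(small_library, SplitSpec(scheme="middle"), seed=0)


class TestLigandTableIO:
    def test_round_trip(self, tmp_path, small_library):
        path = tmp_path / "lib.csv"
        write_ligand_table(small_library, path)
        back = read_ligand_table(path)
        assert [r.ligand_id for r in back] == [r.ligand_id for r in small_library]
        assert [r.label for r in back] == [r.label for r in small_library]
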