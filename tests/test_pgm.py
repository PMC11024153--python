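import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pgm_transfer import (
    ComparabilityError,
    ConfigurationError,
    ModelConfig,
    NumericError,
    PGMConfig,
    PrincipalGradient,
    TaskSpec,
    TransferabilityMap,
    build_map,
    extractor_gradient,
    featurize,
    pgm_distance,
    principal_gradient,
    rank_sources,
)
from pgm_transfer.model import init_model, make_batch
from pgm_transfer.pgm import restart_gradient
from pgm_transfer.synthetic import SyntheticTaskSpec, generate_task_family


def _pg(vector, h="h"):
    return PrincipalGradient(np.asarray(vector, float), 1, h, "d", "classification")


def brute_force_distance(vs, vt):
    """Independent re-implementation with explicit loops."""
    num = 0.0
    ns = 0.0
    nt = 0.0
    for a, b in zip(vs, vt):
        num += (b - a) ** 2
        ns += a * a
        nt += b * b
    return math.sqrt(num) / (math.sqrt(ns) * math.sqrt(nt))


class TestPGMDistance:
    def test_identical_vectors_give_zero(self):
        assert pgm_distance(_pg([1.0, 2.0]), _pg([1.0, 2.0])) == 0.0

    def test_hand_computed_unit_vectors(self):
        assert pgm_distance(_pg([1, 0]), _pg([0, 1])) == pytest.approx(math.sqrt(2), abs=1e-8)

    def test_hand_computed_scaled_vectors(self):
        # 2*sqrt(2)/4: doubling both vectors halves the distance
        assert pgm_distance(_pg([2, 0]), _pg([0, 2])) == pytest.approx(0.70710678, abs=1e-8)

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(2, 30)
            vs, vt = rng.normal(size=n), rng.normal(size=n)
            assert pgm_distance(_pg(vs), _pg(vt)) == pytest.approx(
                brute_force_distance(vs, vt), abs=1e-12, rel=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_symmetry_exact_and_scaling_law(self, seed):
        rng = np.random.default_rng(seed)
        vs, vt = rng.normal(size=10), rng.normal(size=10)
        d = pgm_distance(_pg(vs), _pg(vt))
        assert d == pgm_distance(_pg(vt), _pg(vs))
        for c in (0.5, 3.0, 117.0):
            dc = pgm_distance(_pg(c * vs), _pg(c * vt))
            assert dc == pytest.approx(d / c, rel=1e-10)

    def test_degenerate_norm_raises(self):
        with pytest.raises(NumericError):
            pgm_distance(_pg([0.0, 0.0]), _pg([1.0, 0.0]))

    def test_mismatched_config_hash_raises(self):
        with pytest.raises(ComparabilityError):
            pgm_distance(_pg([1.0], h="a"), _pg([1.0], h="b"))

    def test_mismatched_length_raises(self):
        with pytest.raises(ComparabilityError):
            pgm_distance(_pg([1.0, 0.0]), _pg([1.0, 0.0, 0.0]))


class TestPrincipalGradient:
    def test_single_restart_single_batch_equals_plain_gradient(
            self, tiny_classification_dataset, bag_config):
        records, task = tiny_classification_dataset
        pc = PGMConfig(n_restarts=1, base_seed=4, batch_size=64)
        pg = principal_gradient(records, task, bag_config, pc, dataset_name="x")
        from dataclasses import replace

        state = init_model(replace(bag_config, predictor_out=1, init_seed=4))
        graphs = [featurize(r) for r in records]
        labels = np.stack([r.labels for r in records])
        observed = np.stack([r.observed for r in records])
        g = extractor_gradient(state, make_batch(graphs, labels, observed), task)
        assert np.allclose(pg.vector, g, atol=1e-12)

    def test_deterministic_across_runs(self, tiny_classification_dataset, bag_config):
        records, task = tiny_classification_dataset
        pc = PGMConfig(n_restarts=2, base_seed=0, batch_size=4)
        a = principal_gradient(records, task, bag_config, pc)
        b = principal_gradient(records, task, bag_config, pc)
        assert np.array_equal(a.vector, b.vector)

    @pytest.mark.parametrize("mode", ["same_init", "random_init"])
    def test_decomposes_into_mean_of_single_restarts(
            self, mode, tiny_classification_dataset, bag_config):
        records, task = tiny_classification_dataset
        pc = PGMConfig(n_restarts=3, restart_mode=mode, base_seed=1, batch_size=4)
        pg = principal_gradient(records, task, bag_config, pc, dataset_name="x")
        singles = [
            restart_gradient(records, task, bag_config, pc, restart=k, dataset_name="x")
            for k in range(3)
        ]
        assert np.array_equal(pg.vector, np.mean(singles, axis=0))
        assert pg.n_restarts == 3

    def test_vector_length_invariant_to_predictor_width(
            self, tiny_classification_dataset, bag_config):
        from pgm_transfer.data_io import MoleculeRecord

        records, task1 = tiny_classification_dataset
        pc = PGMConfig(n_restarts=1, base_seed=0)
        pg1 = principal_gradient(records, task1, bag_config, pc)
        recs5 = [
            MoleculeRecord(r.smiles, np.tile(r.labels, 5), np.tile(r.observed, 5))
            for r in records
        ]
        task5 = TaskSpec("classification", 5, "t5")
        pg5 = principal_gradient(recs5, task5, bag_config, pc)
        assert pg1.vector.shape == pg5.vector.shape

    def test_save_load_roundtrip(self, tmp_path, tiny_classification_dataset, bag_config):
        records, task = tiny_classification_dataset
        pg = principal_gradient(records, task, bag_config, PGMConfig(n_restarts=1))
        pg.save(tmp_path / "pg")
        back = PrincipalGradient.load(tmp_path / "pg")
        assert np.array_equal(pg.vector, back.vector)
        assert back.config_hash == pg.config_hash


def _small_family(seed, rel=(1.0, 0.0)):
    base = SyntheticTaskSpec(n_molecules=120, n_subtasks=4, seed=seed)
    return generate_task_family(base, list(rel), seed=seed)


@pytest.fixture(scope="module")
def family_map():
    datasets, _ = _small_family(0, rel=(0.8, 0.4, 0.1))
    mc = ModelConfig(hidden_width=8, encoder_depth=2)
    pc = PGMConfig(n_restarts=2, batch_size=32)
    return build_map(datasets, mc, pc)


class TestBuildMap:
    def test_symmetric_zero_diagonal_positive_offdiag(self, family_map):
        d = family_map.distances
        assert np.array_equal(d, d.T)
        assert np.all(np.diag(d) == 0.0)
        off = d[~np.eye(len(d), dtype=bool)]
        assert np.all(off > 0)

    def test_number_of_distinct_computed_distances(self, family_map):
        d = family_map.distances
        k = len(family_map.names)
        upper = d[np.triu_indices(k, 1)]
        assert len(set(upper.tolist())) == k * (k - 1) // 2

    def test_identical_dataset_same_name_gives_zero_distance(
            self, tiny_classification_dataset, bag_config):
        records, task = tiny_classification_dataset
        pc = PGMConfig(n_restarts=2)
        a = principal_gradient(records, task, bag_config, pc, dataset_name="same")
        b = principal_gradient(records, task, bag_config, pc, dataset_name="same")
        assert pgm_distance(a, b) == 0.0

    def test_clone_task_closer_than_independent_task(self):
        """Relabeled clone of the base sits closer than an unrelated task
        in a majority of generator seeds."""
        mc = ModelConfig(hidden_width=8, encoder_depth=2)
        pc = PGMConfig(n_restarts=3, batch_size=32)
        wins = 0
        for seed in range(10):
            datasets, _ = _small_family(seed)
            tmap = build_map(datasets, mc, pc)
            wins += tmap.distance("base", "rel1.00") < tmap.distance("base", "rel0.00")
        assert wins > 5

    def test_duplicate_names_rejected(self, tiny_classification_dataset, bag_config):
        records, task = tiny_classification_dataset
        with pytest.raises(ConfigurationError):
            build_map([("a", records, task), ("a", records, task)],
                      bag_config, PGMConfig(n_restarts=1))


class TestRankSources:
    def _map(self, names, mat):
        return TransferabilityMap(names=names, distances=np.asarray(mat, float))

    def test_ascending_order(self):
        tmap = self._map(["A", "B", "T"],
                         [[0, 0.7, 0.2], [0.7, 0, 0.5], [0.2, 0.5, 0]])
        assert rank_sources(tmap, "T") == [("A", 0.2), ("B", 0.5)]

    def test_tie_broken_alphabetically(self):
        tmap = self._map(["B", "A", "T"],
                         [[0, 0.9, 0.3], [0.9, 0, 0.3], [0.3, 0.3, 0]])
        assert [n for n, _ in rank_sources(tmap, "T")] == ["A", "B"]

    def test_head_is_argmin_of_target_row(self):
        rng = np.random.default_rng(3)
        n = 6
        m = rng.uniform(0.1, 1, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        names = [f"d{i}" for i in range(n)]
        tmap = self._map(names, m)
        best, d = rank_sources(tmap, "d2")[0]
        row = {names[j]: m[2, j] for j in range(n) if j != 2}
        assert d == min(row.values()) and row[best] == d

    def test_unknown_target_raises(self):
        tmap = self._map(["A", "B"], [[0, 1], [1, 0]])
        with pytest.raises(ConfigurationError):
            rank_sources(tmap, "Z")
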