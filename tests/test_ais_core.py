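import math

import numpy as np
import pytest

from aisclf import (
    AISConfig,
    AISModel,
    Antibody,
    MemoryCell,
    affinity,
    classify_ais,
    clone_count,
    fit_ais,
    generate_blobs,
    hormone_concentration,
    initialize_population,
    mutate,
    normalize_minmax,
    predict_ais,
)
from aisclf.ais_core import _hormone_from_cells
from aisclf.data_model import FeatureTable


def make_model(cells, config):
    return AISModel(
        memory_cells=cells,
        hormone=_hormone_from_cells(cells, config),
        normalization=None,
        config=config,
        iteration_trace=[0.0],
    )


class TestAffinity:
    def test_zero_distance_gives_one(self):
        x = np.array([0.3, 0.7])
        assert affinity(x, x) == 1.0

    def test_unit_distance_gives_half(self):
        assert affinity(np.array([0.0]), np.array([1.0])) == 0.5

    def test_matches_independent_distance_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a, b = rng.random(4), rng.random(4)
            # explicit coordinate-wise distance, no linalg
            dist = math.sqrt(sum((ai - bi) ** 2 for ai, bi in zip(a, b)))
            assert abs(affinity(a, b) - 1.0 / (1.0 + dist)) < 1e-12

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            affinity(np.zeros(2), np.zeros(3))


class TestCloneCount:
    def test_full_affinity_gives_clonal_rate(self):
        assert clone_count(1.0, 10) == 10

    def test_low_affinity_floors_at_one(self):
        assert clone_count(0.04, 10) == 1

    def test_rounding_grid(self):
        """round-half-away-from-zero on the grid 0.05 .. 1.00."""
        for i in range(1, 21):
            aff = 0.05 * i
            expected = max(1, int(math.floor(10 * aff + 0.5)))
            assert clone_count(aff, 10) == expected

    def test_monotone_in_affinity(self):
        affs = np.linspace(0.01, 1.0, 100)
        counts = [clone_count(a, 10) for a in affs]
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestMutate:
    def test_perfect_affinity_means_no_mutation(self):
        ab = Antibody(np.array([0.2, 0.8]), 0, 1.0)
        out = mutate(ab, AISConfig(), np.random.default_rng(0))
        np.testing.assert_array_equal(out, ab.vector)

    def test_mutation_sd_scales_with_affinity(self):
        """sigma = mutation_scale * (1 - affinity): at affinity 0.5 and
        scale 0.2, per-coordinate SD of mutants of an interior point is
        0.1 within 3%."""
        ab = Antibody(np.full(3, 0.5), 0, 0.5)
        rng = np.random.default_rng(1)
        cfg = AISConfig(mutation_scale=0.2)
        mutants = np.array([mutate(ab, cfg, rng) for _ in range(10_000)])
        sds = mutants.std(axis=0)
        assert np.all(np.abs(sds - 0.1) < 0.003)

    def test_corner_mutants_stay_in_cube(self):
        ab = Antibody(np.zeros(4), 0, 0.1)
        rng = np.random.default_rng(2)
        for _ in range(200):
            out = mutate(ab, AISConfig(), rng)
            assert out.min() >= 0 and out.max() <= 1


class TestInitializePopulation:
    def _table(self, X, y):
        d = X.shape[1]
        return FeatureTable(X, [f"f{i}" for i in range(d)], ["continuous"] * d, y)

    def test_identical_points_single_centroid(self):
        X = np.vstack([np.full((10, 2), 0.4), np.full((10, 2), 0.9)])
        y = np.array([0] * 10 + [1] * 10)
        abs_, _ = initialize_population(self._table(X, y), AISConfig(seed=0))
        class0 = [ab for ab in abs_ if ab.class_id == 0]
        assert len(class0) == 1
        np.testing.assert_allclose(class0[0].vector, [0.4, 0.4])

    def test_centroids_recover_blob_means(self):
        """Each class is itself two well-separated blobs; seeding k-means
        must place centroids near the true blob means."""
        rng = np.random.default_rng(3)
        means = {0: [(0.1, 0.1), (0.1, 0.9)], 1: [(0.9, 0.1), (0.9, 0.9)]}
        X, y = [], []
        for c, mus in means.items():
            for mu in mus:
                X.append(np.clip(rng.normal(mu, 0.02, size=(100, 2)), 0, 1))
                y += [c] * 100
        X = np.vstack(X)
        abs_, _ = initialize_population(
            self._table(X, np.array(y)), AISConfig(n_best=2, seed=4)
        )
        for c, mus in means.items():
            centroids = np.array([ab.vector for ab in abs_ if ab.class_id == c])
            for mu in mus:
                assert np.min(np.linalg.norm(centroids - mu, axis=1)) < 0.05

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        X = rng.random((60, 3))
        y = np.array([0, 1] * 30)
        t = self._table(X, y)
        a, _ = initialize_population(t, AISConfig(seed=6))
        b, _ = initialize_population(t, AISConfig(seed=6))
        for ab1, ab2 in zip(a, b):
            np.testing.assert_array_equal(ab1.vector, ab2.vector)


class TestFitAIS:
    def test_point_classes_are_fixed_points(self):
        X = np.vstack([np.full((20, 3), 0.1), np.full((20, 3), 0.9)])
        y = np.array([0] * 20 + [1] * 20)
        table = FeatureTable(X, list("abc"), ["continuous"] * 3, y)
        model = fit_ais(table, AISConfig(seed=0))
        for mc in model.memory_cells:
            target = 0.1 if mc.class_id == 0 else 0.9
            np.testing.assert_allclose(mc.vector, target, atol=1e-6)
        # displacement settles after the first rounds
        trace = model.iteration_trace
        assert all(b <= a + 1e-12 for a, b in zip(trace[2:], trace[3:]))

    def test_separable_blobs_high_training_accuracy(self, separable_blobs):
        table, normalized, _ = separable_blobs
        model = fit_ais(normalized, AISConfig(seed=1))
        pred, _ = predict_ais(model, normalized.values)
        assert (pred == table.labels).mean() >= 0.99

    def test_deterministic_given_seed(self, separable_blobs):
        _, normalized, _ = separable_blobs
        m1 = fit_ais(normalized, AISConfig(seed=2))
        m2 = fit_ais(normalized, AISConfig(seed=2))
        np.testing.assert_array_equal(m1.mc_matrix, m2.mc_matrix)
        assert m1.iteration_trace == m2.iteration_trace

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).random((10, 2))
        table = FeatureTable(X, ["a", "b"], ["continuous"] * 2, np.zeros(10, dtype=int))
        with pytest.raises(ValueError):
            fit_ais(table, AISConfig())

    def test_affinity_never_decreases(self, separable_blobs):
        """Clonal replacement keeps a mutant only on improvement, so every
        antibody slot's affinity is monotone non-decreasing."""
        _, normalized, _ = separable_blobs
        model = fit_ais(normalized, AISConfig(seed=3))
        trace = np.vstack(model.affinity_trace)
        assert np.all(np.diff(trace, axis=0) >= -1e-15)

    def test_zero_mutation_reduces_to_kmeans(self):
        """With mutation_scale = 0 clonal selection cannot move antibodies:
        the memory cells are exactly the per-class k-means seeds, and
        nearest-cell classification agrees with the k-means oracle."""
        table = generate_blobs(k=2, n_per_cluster=150, separation=8, dims=4, seed=7)
        normalized, _ = normalize_minmax(table)
        cfg = AISConfig(mutation_scale=0.0, seed=8)
        model = fit_ais(normalized, cfg)
        abs_, _ = initialize_population(normalized, cfg)
        np.testing.assert_array_equal(
            model.mc_matrix, np.vstack([ab.vector for ab in abs_])
        )
        pred, _ = predict_ais(model, normalized.values)
        assert (pred == table.labels).mean() >= 0.99

    def test_row_permutation_barely_moves_accuracy(self, separable_blobs):
        table, normalized, _ = separable_blobs
        base = fit_ais(normalized, AISConfig(seed=4))
        acc_base = (predict_ais(base, normalized.values)[0] == table.labels).mean()
        perm = np.random.default_rng(5).permutation(table.n_samples)
        shuffled = normalized.select_rows(perm)
        model = fit_ais(shuffled, AISConfig(seed=4))
        acc_perm = (predict_ais(model, normalized.values)[0] == table.labels).mean()
        assert abs(acc_base - acc_perm) < 0.01


class TestHormoneField:
    def test_probabilities_sum_to_one_everywhere(self, separable_blobs):
        _, normalized, _ = separable_blobs
        model = fit_ais(normalized, AISConfig(seed=0))
        queries = np.random.default_rng(1).random((1000, normalized.n_features))
        probs = model.hormone.probabilities_batch(queries)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert probs.min() >= 0

    def test_on_cell_far_rival(self):
        cfg = AISConfig()
        cells = [MemoryCell(np.array([0.1, 0.1]), 0), MemoryCell(np.array([0.9, 0.9]), 1)]
        model = make_model(cells, cfg)
        p = hormone_concentration(model, np.array([0.1, 0.1]))
        assert p[0] >= 1 - 1e-9  # rival ~11 bandwidths away

    def test_equidistant_symmetry(self):
        cfg = AISConfig()
        cells = [MemoryCell(np.array([0.4, 0.5]), 0), MemoryCell(np.array([0.6, 0.5]), 1)]
        model = make_model(cells, cfg)
        p = hormone_concentration(model, np.array([0.5, 0.5]))
        np.testing.assert_allclose(p, [0.5, 0.5], atol=1e-12)

    def test_matches_bruteforce_kernel_sum(self, separable_blobs):
        _, normalized, _ = separable_blobs
        model = fit_ais(normalized, AISConfig(seed=2))
        rng = np.random.default_rng(3)
        bw = model.config.radius_of_influence
        for _ in range(50):
            x = rng.random(normalized.n_features)
            raw = {0: 0.0, 1: 0.0}
            for mc in model.memory_cells:
                d2 = float(((x - mc.vector) ** 2).sum())
                raw[mc.class_id] += math.exp(-d2 / (2 * bw * bw))
            expected = np.array([raw[0], raw[1]]) / (raw[0] + raw[1])
            np.testing.assert_allclose(
                hormone_concentration(model, x), expected, atol=1e-10
            )


class TestClassify:
    def test_agreement_branch(self):
        cfg = AISConfig()
        cells = [MemoryCell(np.array([0.2, 0.2]), 0), MemoryCell(np.array([0.8, 0.8]), 1)]
        model = make_model(cells, cfg)
        cls, score = classify_ais(model, np.array([0.2, 0.2]))
        assert cls == 0 and score >= 0.5

    def test_burring_conflict_goes_to_nearest_cell(self):
        """Hormone slightly favors class 1 (two cells vs one) but the
        query sits within the burring radius of the class-0 cell and the
        hormone gap is below epsilon: the nearest memory cell decides."""
        cfg = AISConfig(burring_epsilon=0.3, burring_radius=0.1)
        cells = [
            MemoryCell(np.array([0.40]), 0),
            MemoryCell(np.array([0.56]), 1),
            MemoryCell(np.array([0.60]), 1),
        ]
        model = make_model(cells, cfg)
        x = np.array([0.48])
        probs = hormone_concentration(model, x)
        assert probs[1] > probs[0]  # decisions genuinely conflict
        assert probs[1] - probs[0] < cfg.burring_epsilon
        cls, _ = classify_ais(model, x)
        assert cls == 0

    def test_large_gap_goes_to_hormone(self):
        """Same conflict geometry but the hormone gap exceeds epsilon:
        the strongest concentration decides against the nearest cell."""
        cfg = AISConfig(burring_epsilon=0.1, burring_radius=0.1)
        cells = [
            MemoryCell(np.array([0.47]), 0),
            MemoryCell(np.array([0.50]), 1),
            MemoryCell(np.array([0.52]), 1),
        ]
        model = make_model(cells, cfg)
        x = np.array([0.46])
        probs = hormone_concentration(model, x)
        assert probs[1] - probs[0] > cfg.burring_epsilon
        # nearest cell is class 0 ...
        assert abs(x[0] - 0.47) < abs(x[0] - 0.50)
        cls, score = classify_ais(model, x)
        assert cls == 1
        assert score == pytest.approx(probs[1])


class TestSerialization:
    def test_json_round_trip(self, separable_blobs, tmp_path):
        _, normalized, params = separable_blobs
        model = fit_ais(normalized, AISConfig(seed=9))
        model.normalization = params
        path = tmp_path / "model.json"
        model.to_json(path)
        back = AISModel.from_json(path)
        np.testing.assert_allclose(back.mc_matrix, model.mc_matrix)
        queries = np.random.default_rng(0).random((20, normalized.n_features))
        np.testing.assert_array_equal(
            predict_ais(back, queries)[0], predict_ais(model, queries)[0]
        )
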