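"""PSO wrapper: update equations, cost function, reproducibility contracts."""

import numpy as np
import pytest

from mmpso.data import TabularDataset
from mmpso.swarm import (
    FitnessConfig,
    Particle,
    PSOSubsetSelector,
    SwarmConfig,
    decode_subset,
    fitness_cost,
    knn_error,
    make_fold_assignment,
    run_pso,
    update_position,
    update_velocity,
)
from mmpso.synthetic import PlantSpec, make_planted_dataset


class _FixedRng:
    """Stand-in generator returning a constant for every uniform draw."""

    def __init__(self, value):
        self.value = value

    def random(self, d):
        return np.full(d, self.value)


class TestDecode:
    @pytest.mark.parametrize(
        "position, expected",
        [
            ([0.0, 0.0, 0.0], []),
            ([1.0, 1.0], [0, 1]),
            ([0.2, 0.7, 0.5], [1]),  # threshold comparison is strict
        ],
    )
    def test_decoding(self, position, expected):
        assert decode_subset(np.array(position), 0.5).tolist() == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            decode_subset(np.array([0.1, np.nan]))


class TestUpdateEquations:
    def test_zero_random_terms_leave_inertia_only(self):
        p = Particle(np.array([0.3]), np.array([1.0]), np.array([0.5]), 0.0)
        v = update_velocity(p, np.array([0.7]), SwarmConfig(omega=0.9), _FixedRng(0.0))
        assert v == pytest.approx([0.9], abs=1e-15)

    def test_converged_particle_stays(self):
        x = np.array([0.4, 0.6])
        p = Particle(x, np.zeros(2), x.copy(), 0.0)
        v = update_velocity(p, x.copy(), SwarmConfig(), _FixedRng(0.37))
        assert v == pytest.approx([0.0, 0.0], abs=1e-15)
        assert update_position(p, v) == pytest.approx(x, abs=1e-15)

    def test_scalar_substitution(self):
        # omega*v + c1*r1*(pb-x) + c2*r2*(gb-x) = 0.9 + 0.2 + 0.4 = 1.5
        p = Particle(np.array([0.0]), np.array([1.0]), np.array([0.2]), 0.0)
        v = update_velocity(p, np.array([0.4]), SwarmConfig(omega=0.9, c1=2, c2=2), _FixedRng(0.5))
        assert v == pytest.approx([1.5], abs=1e-12)

    def test_velocity_clamped(self):
        p = Particle(np.array([0.0]), np.array([10.0]), np.array([1.0]), 0.0)
        v = update_velocity(p, np.array([1.0]), SwarmConfig(omega=1.0, v_max=4.0), _FixedRng(1.0))
        assert v == pytest.approx([4.0])

    @pytest.mark.parametrize(
        "x, v, expected", [(0.3, 0.2, 0.5), (0.9, 0.5, 1.0), (0.1, -0.5, 0.0), (0.7, 0.0, 0.7)]
    )
    def test_position_update_and_clamp(self, x, v, expected):
        p = Particle(np.array([x]), np.array([0.0]), np.array([x]), 0.0)
        assert update_position(p, np.array([v])) == pytest.approx([expected], abs=1e-15)

    def test_bounds_preserved_under_random_iteration(self, rng):
        # the only mutation paths in the search are these two updates
        cfg = SwarmConfig(v_max=2.0)
        pos = rng.random(10)
        vel = rng.uniform(-1, 1, 10)
        for _ in range(50):
            p = Particle(pos, vel, rng.random(10), 0.0)
            vel = update_velocity(p, rng.random(10), cfg, rng)
            pos = update_position(p, vel)
            assert (np.abs(vel) <= cfg.v_max).all()
            assert ((0.0 <= pos) & (pos <= 1.0)).all()


class TestKnnError:
    def test_separable_blobs_have_zero_error(self, blobs):
        folds = make_fold_assignment(blobs.y, 5, seed=0)
        assert knn_error(blobs, [0, 1], FitnessConfig(), folds) == 0.0

    def test_permuted_labels_near_chance(self, blobs, rng):
        errs = []
        for s in range(10):
            y = np.random.default_rng(s).permutation(blobs.y)
            ds = TabularDataset(X=blobs.X, y=y)
            folds = make_fold_assignment(y, 5, seed=s)
            errs.append(knn_error(ds, [0, 1], FitnessConfig(), folds))
        # binomial chance level: 0.5 +- 3 sigma with n=100 draws per run
        assert abs(np.mean(errs) - 0.5) < 3 * 0.05

    def test_one_nn_matches_hand_trace(self):
        # 8 points on a line; folds = first/second half; 1-NN by |distance|
        X = np.array([[0.0], [1.0], [2.0], [3.0], [10.0], [11.0], [12.0], [13.0]])
        y = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        ds = TabularDataset(X=X, y=y)
        folds = [
            (np.array([4, 5, 6, 7]), np.array([0, 1, 2, 3])),
            (np.array([0, 1, 2, 3]), np.array([4, 5, 6, 7])),
        ]
        # fold 1: train {10,11:0, 12,13:1} scaled; tests 0..3 all nearest 10 -> class 0
        # => errors at the two class-1 test points; rate 0.5. fold 2 symmetric.
        got = knn_error(ds, [0], FitnessConfig(knn_k=1, folds=2), folds)
        assert got == pytest.approx(0.5, abs=1e-12)

    def test_small_training_fold_rejected(self, blobs):
        folds = [(np.arange(3), np.arange(3, 100))]
        with pytest.raises(ValueError, match="knn_k"):
            knn_error(blobs, [0], FitnessConfig(knn_k=5), folds)


class TestFitnessCost:
    def test_empty_subset_costs_alpha(self, blobs):
        folds = make_fold_assignment(blobs.y, 5, seed=0)
        cost, err = fitness_cost(np.zeros(4), blobs, FitnessConfig(), folds)
        assert err == 1.0
        assert cost == pytest.approx(0.95, abs=1e-12)

    def test_direct_substitution(self, blobs):
        # prime the cache so V_error = 0.2 for the decoded subset
        position = np.array([0.9, 0.1])
        cache = {decode_subset(position).tobytes(): 0.2}
        cfg = FitnessConfig(alpha=0.95, beta=0.05, n_all=100)
        cost, err = fitness_cost(position, blobs, cfg, [], _cache=cache)
        assert err == 0.2
        assert cost == pytest.approx(0.95 * 0.2 + 0.05 * (1 / 100), abs=1e-12)

    def test_worst_case_full_subset_costs_one(self, blobs):
        position = np.ones(10)
        cache = {decode_subset(position).tobytes(): 1.0}
        cost, _ = fitness_cost(position, blobs, FitnessConfig(n_all=10), [], _cache=cache)
        assert cost == pytest.approx(1.0, abs=1e-12)

    def test_alpha_beta_must_sum_to_one(self):
        with pytest.raises(ValueError, match="equal 1"):
            FitnessConfig(alpha=0.9, beta=0.05)


@pytest.fixture(scope="module")
def planted30():
    ds, truth = make_planted_dataset(
        PlantSpec(n_samples=120, n_informative=3, n_noise=27, class_sep=3.0, seed=9)
    )
    return ds, truth


class TestRunPso:
    def test_single_motionless_particle(self, blobs):
        cfg = SwarmConfig(population=1, iterations=1, c1=0.0, c2=0.0, omega=0.0, seed=4)
        res = run_pso(blobs, cfg, FitnessConfig())
        # replicate the seeded initialization: gbest is the initial decoding
        rng = np.random.default_rng(4)
        init = rng.random((1, blobs.n_features))[0]
        assert res.selected == decode_subset(init, 0.5).tolist()
        assert len(res.trace) == 1

    def test_same_seed_bit_identical(self, planted30):
        ds, _ = planted30
        cfg = SwarmConfig(population=10, iterations=5, seed=21)
        a = run_pso(ds, cfg, FitnessConfig())
        b = run_pso(ds, cfg, FitnessConfig())
        assert a == b

    def test_trace_non_increasing_and_decomposition(self, planted30):
        ds, _ = planted30
        res = run_pso(ds, SwarmConfig(population=15, iterations=10, seed=1), FitnessConfig())
        assert all(b <= a + 1e-15 for a, b in zip(res.trace, res.trace[1:]))
        expected = 0.95 * res.error_component + 0.05 * len(res.selected) / ds.n_features
        assert res.cost == pytest.approx(expected, abs=1e-12)

    def test_pure_error_minimization_finds_separating_feature(self):
        rng = np.random.default_rng(3)
        n = 60
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 5))
        X[:, 2] = y * 10.0 + rng.normal(size=n) * 0.1  # perfect separator
        ds = TabularDataset(X=X, y=y)
        res = run_pso(
            ds,
            SwarmConfig(population=20, iterations=10, seed=0),
            FitnessConfig(alpha=1.0, beta=0.0),
        )
        assert res.error_component == 0.0

    def test_degenerate_dataset_rejected(self):
        ds = TabularDataset(X=np.random.default_rng(0).random((10, 3)), y=np.zeros(10, dtype=int))
        with pytest.raises(ValueError, match="2 classes"):
            run_pso(ds, SwarmConfig(population=2, iterations=1))

    def test_selector_estimator_surface(self, planted30):
        ds, truth = planted30
        sel = PSOSubsetSelector(population=15, iterations=8, random_state=0).fit(ds.X, ds.y)
        assert sel.support_.sum() == len(sel.result_.selected)
        assert sel.transform(ds.X).shape[1] == sel.support_.sum()
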