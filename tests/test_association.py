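"""Mutual information and MIC: closed forms, oracle agreement, calibration."""

import math

import numpy as np
import pytest

from mmpso.association import (
    AssociationConfig,
    association_to_label,
    characteristic_matrix,
    mic,
    mutual_info_discrete,
    pairwise_association,
)
from mmpso.data import TabularDataset


def plug_in_mi(x, y):
    """Independent oracle: direct summation over observed joint cells."""
    x, y = np.asarray(x), np.asarray(y)
    n = len(x)
    total = 0.0
    for xv in np.unique(x):
        for yv in np.unique(y):
            pxy = np.mean((x == xv) & (y == yv))
            if pxy > 0:
                total += pxy * math.log2(pxy / (np.mean(x == xv) * np.mean(y == yv)))
    return total


class TestMutualInfo:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([0, 1, 0, 1], [0, 1, 0, 1], 1.0),  # identical balanced binary: 1 bit
            ([0, 0, 1, 1], [0, 1, 0, 1], 0.0),  # joint factorizes exactly
        ],
    )
    def test_closed_forms(self, x, y, expected):
        assert mutual_info_discrete(x, y) == pytest.approx(expected, abs=1e-12)

    def test_matches_direct_summation_on_2x2_counts(self):
        # counts {(0,0):2, (0,1):1, (1,0):1, (1,1):2}
        x = [0, 0, 0, 1, 1, 1]
        y = [0, 0, 1, 0, 1, 1]
        assert mutual_info_discrete(x, y) == pytest.approx(plug_in_mi(x, y), abs=1e-12)

    def test_entropy_identity_and_symmetry(self, rng):
        for _ in range(100):
            n = rng.integers(5, 60)
            x = rng.integers(0, 4, n)
            y = rng.integers(0, 3, n)
            got = mutual_info_discrete(x, y)
            hx = plug_in_mi(x, x)
            hy = plug_in_mi(y, y)
            hxy = plug_in_mi(
                np.ravel_multi_index((x, y), (4, 3)), np.ravel_multi_index((x, y), (4, 3))
            )
            assert got == pytest.approx(hx + hy - hxy, abs=1e-12)
            assert got == pytest.approx(mutual_info_discrete(y, x), abs=1e-12)
            assert -1e-12 <= got <= min(hx, hy) + 1e-12

    def test_input_errors(self):
        with pytest.raises(ValueError, match="length mismatch"):
            mutual_info_discrete([0, 1], [0])
        with pytest.raises(ValueError, match="empty"):
            mutual_info_discrete([], [])


class TestCharacteristicMatrix:
    def test_monotone_bijection_has_unit_2x2_entry(self):
        x = np.arange(1.0, 17.0)
        cm = characteristic_matrix(x, x)
        assert cm.entries[(2, 2)] == pytest.approx(1.0, abs=1e-12)
        assert all(0.0 <= v <= 1.0 for v in cm.entries.values())

    def test_constant_input_flagged_all_zero(self):
        x = np.arange(16.0)
        cm = characteristic_matrix(x, np.full(16, 3.0))
        assert cm.constant_input
        assert set(cm.entries.values()) == {0.0}

    def test_too_small_sample_names_minimum(self):
        with pytest.raises(ValueError, match="minimum n is 11"):
            characteristic_matrix(np.arange(10.0), np.arange(10.0))

    def test_admissible_grid_bounds(self):
        cm = characteristic_matrix(np.arange(20.0), np.arange(20.0))
        B = AssociationConfig().grid_budget(20)
        for i, j in cm.entries:
            assert i >= 2 and j >= 2 and i * j <= B


class TestMic:
    def test_perfect_dependence(self, rng):
        x = rng.normal(size=20)
        assert mic(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_constant_partner_is_zero(self, rng):
        x = rng.normal(size=20)
        assert mic(x, np.zeros(20)) == 0.0

    def test_approx_equals_exhaustive_small_n(self, rng):
        exact_cfg = AssociationConfig(mode="exhaustive")
        for rep in range(60):
            n = int(rng.integers(11, 13))
            x, y = rng.random(n), rng.random(n)
            assert mic(x, y) == pytest.approx(mic(x, y, exact_cfg), abs=1e-12)

    def test_symmetry_exhaustive(self, rng):
        cfg = AssociationConfig(mode="exhaustive")
        for _ in range(10):
            x, y = rng.random(11), rng.random(11)
            assert mic(x, y, cfg) == pytest.approx(mic(y, x, cfg), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        # grids depend only on ranks, so a strictly monotone axis map is a no-op
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        assert mic(x, y) == pytest.approx(mic(np.exp(x), y), abs=1e-12)
        assert mic(x, x**3 + 5.0) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("kind", ["linear", "quadratic", "sine"])
    def test_noiseless_functional_relationships(self, kind, rng):
        from mmpso.synthetic import make_functional_pair

        x, y = make_functional_pair(kind, n=1000, noise_sd=0.0, seed=5)
        assert mic(x, y) >= 0.99


class TestAssociationToLabel:
    def test_perfectly_separated_classes(self):
        x = np.concatenate([np.linspace(0, 1, 10), np.linspace(5, 6, 10)])
        y = np.repeat([0, 1], 10)
        assert association_to_label(x, y) == pytest.approx(1.0, abs=1e-12)

    def test_constant_feature(self):
        y = np.repeat([0, 1], 10)
        assert association_to_label(np.zeros(20), y) == 0.0

    def test_single_class_warns_and_returns_zero(self, rng):
        with pytest.warns(UserWarning, match="single class"):
            assert association_to_label(rng.random(20), np.zeros(20, dtype=int)) == 0.0

    def test_signal_beats_noise_across_seeds(self):
        from mmpso.synthetic import PlantSpec, make_planted_dataset

        wins = 0
        seeds = 40
        for s in range(seeds):
            ds, truth = make_planted_dataset(
                PlantSpec(n_samples=100, n_informative=1, n_noise=1, class_sep=3.0, seed=s)
            )
            a = association_to_label(ds.X[:, truth["informative"][0]], ds.y)
            b = association_to_label(ds.X[:, truth["noise"][0]], ds.y)
            wins += a > b
        assert wins / seeds >= 0.95


class TestPairwiseAssociation:
    def test_workers_do_not_change_result(self, planted_small):
        ds, _ = planted_small
        t1 = pairwise_association(ds, workers=1)
        t4 = pairwise_association(ds, workers=4)
        assert (t1.to_numpy() == t4.to_numpy()).all()

    def test_diagonal_and_per_pair_agreement(self, planted_small):
        ds, _ = planted_small
        table = pairwise_association(ds, targets=[0, 2, 5])
        assert np.allclose(np.diag(table.iloc[:, :3]), 1.0)
        names = list(table.index)
        for a in range(3):
            for b in range(a + 1, 3):
                direct = mic(
                    ds.X[:, ds.feature_names.index(names[a])],
                    ds.X[:, ds.feature_names.index(names[b])],
                )
                assert table.iloc[a, b] == pytest.approx(direct, abs=1e-12)
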