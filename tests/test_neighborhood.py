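"""Neighbor statistics, constrained permutation test, integration, classes."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

import histoplex as hp
from histoplex.neighborhood import NeighborhoodConfig, _pair_counts

from conftest import brute_force_statistic, make_cells, random_cells


class TestCountNeighbors:
    def test_pair_within_radius(self):
        cells = make_cells([(0, 0), (10, 0)], ["A", "B"])
        stat = hp.count_neighbors(cells, 50)
        assert stat.at["A", "B"] == 1.0
        assert stat.at["B", "A"] == 1.0

    def test_pair_outside_radius(self):
        cells = make_cells([(0, 0), (60, 0)], ["A", "B"])
        stat = hp.count_neighbors(cells, 50)
        assert stat.at["A", "B"] == 0.0

    def test_self_excluded(self):
        cells = make_cells([(0, 0)], ["A"])
        assert hp.count_neighbors(cells, 50).at["A", "A"] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        cells = random_cells(rng, int(rng.integers(10, 200)))
        fast = hp.count_neighbors(cells, 50)
        slow = brute_force_statistic(cells, 50)
        pd.testing.assert_frame_equal(fast, slow)

    def test_radius_monotonicity(self):
        rng = np.random.default_rng(9)
        cells = random_cells(rng, 120)
        prev = None
        for r in (20, 40, 60, 90):
            stat = hp.count_neighbors(cells, r)
            if prev is not None:
                assert (stat.to_numpy() >= prev.to_numpy() - 1e-12).all()
            prev = stat

    def test_empty_region_raises(self):
        with pytest.raises(ValueError, match="empty"):
            hp.count_neighbors(make_cells(np.empty((0, 2)), []), 50)


class TestPermutationTest:
    def test_single_type_all_p_one(self):
        rng = np.random.default_rng(0)
        cells = random_cells(rng, 40, types=("Tcy",))
        res = hp.permutation_test(
            cells, NeighborhoodConfig(n_permutations=50, fixed_phenotypes=frozenset())
        )
        assert (res.p_attraction.to_numpy() == 1.0).all()

    def test_fixed_pair_convention(self):
        rng = np.random.default_rng(1)
        cells = random_cells(
            rng, 120, types=("HLADRpos_mel", "HLADRneg_mel", "Tcy")
        )
        res = hp.permutation_test(cells, NeighborhoodConfig(n_permutations=50))
        assert res.p_attraction.at["HLADRpos_mel", "HLADRneg_mel"] == 1.0
        assert res.p_attraction.at["HLADRneg_mel", "HLADRpos_mel"] == 1.0
        # fixed-vs-movable pairs still get a real p-value
        assert res.p_attraction.at["HLADRpos_mel", "Tcy"] <= 1.0

    def test_fixed_melanoma_not_randomized(self):
        """Melanoma labels keep their positions: a melanoma-only region is
        permutation-invariant even against a movable type placed far away."""
        xy = [(0, 0), (5, 5), (10, 0), (400, 400), (405, 405), (410, 400)]
        phen = ["HLADRneg_mel"] * 3 + ["Tcy"] * 3
        res = hp.permutation_test(
            make_cells(xy, phen), NeighborhoodConfig(n_permutations=99)
        )
        # nothing can move, so every permutation reproduces the observation
        assert res.p_attraction.at["Tcy", "Tcy"] == 1.0
        assert res.p_attraction.at["HLADRneg_mel", "Tcy"] == 1.0

    def test_unconstrained_equals_standard_permutation_oracle(self):
        """With no fixed phenotypes the constrained test reduces to the
        textbook label-permutation test (same seed, brute-force recount)."""
        rng = np.random.default_rng(5)
        cells = random_cells(rng, 60)
        cfg = NeighborhoodConfig(n_permutations=99, fixed_phenotypes=frozenset(),
                                 seed=123)
        res = hp.permutation_test(cells, cfg)

        labels = cells["phenotype"].to_numpy(object)
        types = sorted(set(labels))
        codes = pd.Categorical(labels, categories=types).codes.astype(np.int64)
        xy = cells[["x_px", "y_px"]].to_numpy(float)
        pairs = cKDTree(xy).query_pairs(cfg.radius_px, output_type="ndarray")
        obs = _pair_counts(pairs, codes, len(types))
        oracle_rng = np.random.default_rng(123)
        ge = np.zeros_like(obs)
        for _ in range(99):
            perm = codes[oracle_rng.permutation(len(codes))]
            ge += _pair_counts(pairs, perm, len(types)) >= obs
        expected = (1.0 + ge) / 100.0
        np.testing.assert_array_equal(res.p_attraction.to_numpy(), expected)

    def test_relabeling_symmetry(self):
        rng = np.random.default_rng(7)
        cells = random_cells(rng, 80, types=("A", "B", "C"))
        cfg = NeighborhoodConfig(n_permutations=60, fixed_phenotypes=frozenset(),
                                 seed=4)
        res = hp.permutation_test(cells, cfg)
        swapped = cells.copy()
        swapped["phenotype"] = swapped["phenotype"].map(
            {"A": "B", "B": "A", "C": "C"}
        )
        res2 = hp.permutation_test(swapped, cfg)
        perm = {"A": "B", "B": "A", "C": "C"}
        for a in "ABC":
            for b in "ABC":
                assert res.p_attraction.at[a, b] == res2.p_attraction.at[
                    perm[a], perm[b]
                ]

    def test_config_validation(self):
        with pytest.raises(ValueError, match="fixed and excluded"):
            NeighborhoodConfig(
                fixed_phenotypes=frozenset({"x"}),
                excluded_phenotypes=frozenset({"x"}),
            ).validate()
        with pytest.raises(ValueError, match="radius"):
            NeighborhoodConfig(radius_px=0).validate()

    def test_excluded_phenotypes_dropped(self):
        rng = np.random.default_rng(2)
        cells = random_cells(rng, 60, types=("Tcy", "Stroma", "other"))
        res = hp.permutation_test(cells, NeighborhoodConfig(n_permutations=20))
        assert set(res.statistic.index) == {"Tcy"}

    def test_summary_and_edges(self):
        rng = np.random.default_rng(3)
        cells = random_cells(rng, 80)
        res = hp.permutation_test(
            cells, NeighborhoodConfig(n_permutations=30, fixed_phenotypes=frozenset())
        )
        text = res.summary()
        assert "permutations:      30" in text
        edges = res.edges()
        assert set(edges["interaction"]) <= {"strong", "moderate"}


class TestClassify:
    @pytest.mark.parametrize(
        "p,expected", [(0.03, "strong"), (0.07, "moderate"), (0.5, "none"),
                       (0.05, "moderate"), (0.1, "none"), (1.0, "none")]
    )
    def test_thresholds(self, p, expected):
        assert hp.classify_interaction(p) == expected

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_out_of_range_raises(self, p):
        with pytest.raises(ValueError):
            hp.classify_interaction(p)


class TestIntegrateSamples:
    def _result(self, p, n_a, n_b):
        types = ["A", "B"]
        mat = pd.DataFrame([[1.0, p], [p, 1.0]], index=types, columns=types)
        counts = pd.Series({"A": n_a, "B": n_b})
        w = np.log10(np.sqrt(np.outer(counts, counts).astype(float)))
        return hp.NeighborhoodResults(
            statistic=mat * 0, p_attraction=mat, p_avoidance=mat,
            classes=mat.astype(str), counts=counts,
            weights=pd.DataFrame(w, index=types, columns=types),
            config=NeighborhoodConfig(), sample_id="s",
        )

    def test_single_sample_identity(self):
        r = self._result(0.2, 100, 100)
        out = hp.integrate_samples([r])
        assert out.at["A", "B"] == pytest.approx(0.2)

    def test_equal_weights_arithmetic_mean(self):
        out = hp.integrate_samples(
            [self._result(0.2, 50, 50), self._result(0.4, 50, 50)]
        )
        assert out.at["A", "B"] == pytest.approx(0.3)

    def test_weight_closed_form(self):
        r = self._result(0.2, 100, 100)
        assert r.weights.at["A", "B"] == pytest.approx(2.0)

    def test_zero_weight_samples_excluded(self):
        # n_a = n_b = 1 gives weight log10(1) = 0 -> excluded
        out = hp.integrate_samples(
            [self._result(0.9, 1, 1), self._result(0.2, 100, 100)]
        )
        assert out.at["A", "B"] == pytest.approx(0.2)

    def test_all_zero_weight_is_missing(self):
        out = hp.integrate_samples([self._result(0.9, 1, 1)])
        assert np.isnan(out.at["A", "B"])

    def test_no_samples_raises(self):
        with pytest.raises(ValueError, match="no samples"):
            hp.integrate_samples([])
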