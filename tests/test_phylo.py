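"""Tree building, split support, and the star/clock hypothesis tests."""

import numpy as np
import pytest

from cnevol.distance import DistanceMatrix, distance_matrix, phase_patient
from cnevol.phylo import (
    bh_adjust,
    build_tree,
    clock_test,
    split_support,
    star_topology_test,
)
from cnevol.profiles import PatientDataset

from conftest import make_profile


def _tip_depths(tree, exclude="diploid"):
    out = {}
    for tip in tree.tips():
        if tip.name == exclude:
            continue
        out[tip.name] = tree.distance(tip)
    return out


class TestBuildTree:
    def test_three_point_additivity(self):
        # d(A,B)=2, d(A,dip)=3, d(B,dip)=3 solves to A:1, B:1, diploid:2
        dm = DistanceMatrix(
            ("A", "B", "diploid"), np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        )
        tree = build_tree(dm)
        depths = _tip_depths(tree)
        assert depths == {"A": 3.0, "B": 3.0}
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == lengths["B"] == 1.0

    def test_two_samples_cherry(self):
        dm = DistanceMatrix(("A", "diploid"), np.array([[0, 5], [5, 0]], dtype=float))
        tree = build_tree(dm)
        assert {t.name for t in tree.tips()} == {"A", "diploid"}
        assert _tip_depths(tree)["A"] == 5.0

    def test_additive_exactness_four_taxa(self):
        # tree ((A:1,B:2):3,(C:4,diploid:5)) -> additive distances
        d = np.array(
            [
                [0, 3, 8, 9],
                [3, 0, 9, 10],
                [8, 9, 0, 9],
                [9, 10, 9, 0],
            ],
            dtype=float,
        )
        dm = DistanceMatrix(("A", "B", "C", "diploid"), d)
        tree = build_tree(dm)
        # recovered pairwise path lengths must match the input exactly
        tips = {t.name: t for t in tree.tips()}
        for i, x in enumerate(dm.ids):
            for j, y in enumerate(dm.ids):
                if i < j:
                    assert tips[x].distance(tips[y]) == pytest.approx(d[i, j])

    def test_deterministic(self, simulated_patient):
        ds, _ = simulated_patient
        dm = distance_matrix(phase_patient(ds, exhaustive_threshold=8))
        assert str(build_tree(dm)) == str(build_tree(dm))

    def test_nonfinite_rejected(self):
        dm = DistanceMatrix(("A", "diploid"), np.zeros((2, 2)))
        bad = DistanceMatrix(("A", "B", "diploid"), np.zeros((3, 3)))
        object.__setattr__(bad, "values", np.array([[0, 1, np.inf]] * 3))
        with pytest.raises(ValueError):
            build_tree(bad)


class TestSplitSupport:
    def _strong_patient(self):
        # two clades with many concordant segments: one dominant split
        a = [3] * 10 + [1] * 10
        b = [1] * 10 + [3] * 10
        profiles = [
            make_profile("A1", a, [1] * 20),
            make_profile("A2", a, [1] * 20),
            make_profile("B1", b, [1] * 20),
            make_profile("B2", b, [1] * 20),
        ]
        return PatientDataset("P", profiles)

    def test_high_signal_supports_are_one(self):
        phased = phase_patient(self._strong_patient(), exhaustive_threshold=0)
        support = split_support(phased, n_replicates=30, seed=1)
        assert support
        assert all(v == 1.0 for v in support.values())

    def test_zero_replicates_is_error(self):
        phased = phase_patient(self._strong_patient(), exhaustive_threshold=0)
        with pytest.raises(ValueError):
            split_support(phased, n_replicates=0)

    def test_seed_reproducible(self):
        phased = phase_patient(self._strong_patient(), exhaustive_threshold=0)
        s1 = split_support(phased, n_replicates=20, seed=7)
        s2 = split_support(phased, n_replicates=20, seed=7)
        assert s1 == s2

    def test_too_few_leaves_empty(self, two_sample_patient):
        phased = phase_patient(two_sample_patient)
        assert split_support(phased, n_replicates=10, seed=0) == {}


class TestStarTest:
    def test_exact_star_fits_perfectly(self):
        b = np.array([3.0, 4.0, 5.0, 2.0])
        d = b[:, None] + b[None, :]
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(("A", "B", "C", "diploid"), d)
        res = star_topology_test(dm)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert res.df == 2

    def test_strongly_branched_rejected(self):
        # two clades of three, internal edge of 30 events
        within, between = 4.0, 34.0
        n = 6
        d = np.full((n, n), between)
        for i in range(3):
            for j in range(3):
                d[i, j] = d[i + 3, j + 3] = within if i != j else 0.0
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(("A", "B", "C", "D", "E", "diploid"), d)
        res = star_topology_test(dm)
        assert res.p < 0.05

    def test_untestable_below_four_taxa(self):
        dm = DistanceMatrix(("A", "B", "diploid"), np.ones((3, 3)) - np.eye(3))
        assert not star_topology_test(dm).testable

    def test_type_i_error_bounded(self):
        """On noisy star matrices the rejection rate stays moderate."""
        rej = 0
        n_rep = 200
        for s in range(n_rep):
            rng = np.random.default_rng(s)
            b = rng.integers(10, 30, size=6).astype(float)
            d = b[:, None] + b[None, :] + rng.integers(-2, 3, size=(6, 6))
            d = np.triu(d, 1)
            d = d + d.T
            dm = DistanceMatrix(tuple("ABCDE") + ("diploid",), d)
            if star_topology_test(dm).p < 0.05:
                rej += 1
        assert rej / n_rep <= 0.15


class TestClockTest:
    def _tree_from_depths(self, depths):
        # star tree over the given root-to-leaf depths plus a diploid at root
        ids = [f"L{i}" for i in range(len(depths))] + ["diploid"]
        d = np.zeros((len(ids), len(ids)))
        for i, x in enumerate(depths):
            d[i, -1] = d[-1, i] = x
            for j, y in enumerate(depths):
                if i != j:
                    d[i, j] = x + y
        return build_tree(DistanceMatrix(tuple(ids), d))

    def test_ultrametric_is_clocklike(self):
        res = clock_test(self._tree_from_depths([10, 10, 10, 10]))
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)

    def test_inflated_leaf_rejected(self):
        res = clock_test(self._tree_from_depths([50, 10, 10, 10]))
        assert res.p < 0.05

    def test_p_decreases_with_inflation(self):
        ps = [clock_test(self._tree_from_depths([x, 10, 10, 10])).p for x in (10, 20, 40)]
        assert ps[0] > ps[1] > ps[2]

    def test_deterministic(self):
        t = self._tree_from_depths([30, 10, 10, 10])
        assert clock_test(t) == clock_test(t)

    def test_zero_tree_untestable(self):
        res = clock_test(self._tree_from_depths([0, 0, 0]))
        assert not res.testable


class TestBHAdjust:
    def test_step_up_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert bh_adjust([0.2]) == [0.2]
        assert bh_adjust([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_monotone_never_decreases(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=20)
        adj = bh_adjust(list(p))
        assert all(a >= x for a, x in zip(adj, p))
        order = np.argsort(p)
        adj_sorted = np.asarray(adj)[order]
        assert all(np.diff(adj_sorted) >= -1e-12)

    def test_nan_passthrough_and_validation(self):
        out = bh_adjust([0.01, None, 0.04])
        assert np.isnan(out[1])
        with pytest.raises(ValueError):
            bh_adjust([1.5])
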