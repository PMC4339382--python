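"""Minimum event distance: oracle equivalence, symmetrization, phasing."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnevol.distance import (
    INFEASIBLE,
    distance_matrix,
    med_asym,
    med_oracle,
    med_symmetric,
    phase_patient,
)
from cnevol.profiles import PatientDataset, SampleRecord

from conftest import make_profile


class TestMedAsym:
    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ([2, 2, 2], [2, 2, 2], 0),
            ([2, 2, 2], [3, 3, 2], 1),  # one amplification run
            ([2, 3, 2], [3, 2, 3], 3),  # gains cannot bridge the loss
            ([2, 0, 2], [3, 0, 3], 1),  # lost segment is transparent
            ([3], [1], 2),
            ([1, 1, 2, 3], [2, 0, 2, 2], 2),  # overshoot a deletion, repay by amp
        ],
    )
    def test_known_values(self, u, v, expected):
        assert med_asym(u, v) == expected

    def test_regaining_lost_segment_is_infeasible(self):
        assert med_asym([0, 2], [1, 2]) == INFEASIBLE

    def test_validation(self):
        with pytest.raises(ValueError):
            med_asym([1, 2], [1])
        with pytest.raises(ValueError):
            med_asym([-1], [0])

    def test_agrees_with_bfs_oracle(self):
        """Exhaustive BFS over event sequences is the ground truth."""
        rng = np.random.default_rng(2024)
        tested = 0
        while tested < 1000:
            n = int(rng.integers(1, 5))
            u = rng.integers(0, 4, n)
            v = rng.integers(0, 4, n)
            d = med_asym(u, v)
            if d == INFEASIBLE:
                continue
            try:
                oracle = med_oracle(u, v, max_depth=9)
            except RuntimeError:
                continue
            assert d == oracle, f"u={u}, v={v}: {d} != oracle {oracle}"
            tested += 1

    def test_closed_form_when_no_zeros(self):
        """Away from zero, the distance is the two-sided skyline count."""
        rng = np.random.default_rng(7)
        for _ in range(300):
            n = int(rng.integers(1, 6))
            u = rng.integers(1, 4, n)
            v = rng.integers(1, 4, n)
            delta = v - u
            p = np.maximum(delta, 0)
            m = np.maximum(-delta, 0)
            skyline = (
                p[0] + np.maximum(np.diff(p), 0).sum() + m[0] + np.maximum(np.diff(m), 0).sum()
            )
            assert med_asym(u, v) == skyline

    @given(st.lists(st.integers(0, 3), min_size=1, max_size=5))
    @settings(deadline=None, derandomize=True)
    def test_zero_iff_identical(self, u):
        assert med_asym(u, u) == 0
        v = list(u)
        v[0] += 1
        if u[0] > 0:
            assert med_asym(u, v) > 0


class TestMedSymmetric:
    def test_forced_direction(self):
        assert med_symmetric([2], [0]) == 2

    def test_doubly_infeasible_routes_through_ancestor(self):
        # both directions lose a segment the other keeps; ancestor [2, 2]
        assert med_symmetric([0, 2], [2, 0]) == 4

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(1, 5))
            u = rng.integers(0, 4, n)
            v = rng.integers(0, 4, n)
            assert med_symmetric(u, v) == med_symmetric(v, u)


class TestPhasing:
    def test_no_heterozygous_segments_is_identity(self):
        p1 = make_profile("S1", [2, 2], [2, 2])
        p2 = make_profile("S2", [3, 3], [3, 3])
        ds = PatientDataset("P", [p1, p2])
        phased = phase_patient(ds)
        assert phased.flips == (False, False)
        assert [p.cn_a for p in phased.profiles] == [(2, 2), (3, 3)]

    def test_multiset_preserved_per_segment(self, simulated_patient):
        ds, _ = simulated_patient
        phased = phase_patient(ds, exhaustive_threshold=8)
        for orig, new in zip(ds.profiles, phased.profiles):
            for s in range(ds.n_segments):
                assert {orig.cn_a[s], orig.cn_b[s]} == {new.cn_a[s], new.cn_b[s]}

    def test_exhaustive_picks_cheaper_assignment(self):
        # Two samples share a gained haplotype across two segments: keeping
        # the gains on one haplotype costs one 2-segment amplification;
        # crossing them costs two.
        p1 = make_profile("S1", [3, 3], [1, 1])
        p2 = make_profile("S2", [3, 3], [1, 1])
        ds = PatientDataset("P", [p1, p2])
        phased = phase_patient(ds, exhaustive_threshold=12)
        a1 = phased.profiles[0].cn_a
        assert a1 in [(3, 3), (1, 1)]  # uncrossed assignment
        crossed_cost = None
        from cnevol.distance import _phasing_cost

        crossed_cost = _phasing_cost(ds, [False, True])
        assert phased.total_cost < crossed_cost

    def test_heuristic_near_exhaustive(self):
        """Greedy + hill climbing matches the exhaustive optimum >= 90%."""
        from cnevol.simulate import SimulationConfig, simulate_patient

        equal = 0
        n_trials = 200
        for s in range(n_trials):
            rng = np.random.default_rng(5000 + s)
            cfg = SimulationConfig(
                samples_per_patient=3, n_segments=8, het_fraction=0.6, events_per_branch=3
            )
            ds, _ = simulate_patient(cfg, rng=rng)
            ex = phase_patient(ds, exhaustive_threshold=12)
            he = phase_patient(ds, exhaustive_threshold=0)
            assert he.total_cost >= ex.total_cost - 1e-9
            equal += abs(he.total_cost - ex.total_cost) < 1e-9
        assert equal >= 0.9 * n_trials


class TestDistanceMatrix:
    def test_single_sample_matrix(self):
        ds = PatientDataset("P", [make_profile("S1", [2, 2], [1, 1])])
        dm = distance_matrix(phase_patient(ds))
        assert dm.ids == ("S1", "diploid")
        assert dm.values[0, 0] == 0
        # one amplification run turns (1,1)x2 into (2,2)x(1,1)
        assert dm.values[0, 1] == 1

    def test_diploid_column_is_divergence_from_normal(self, simulated_patient):
        ds, _ = simulated_patient
        phased = phase_patient(ds, exhaustive_threshold=8)
        dm = distance_matrix(phased)
        n_seg = ds.n_segments
        ones = np.ones(n_seg, dtype=np.int64)
        for i, p in enumerate(phased.profiles):
            direct = med_symmetric(p.cn_a, ones) + med_symmetric(p.cn_b, ones)
            assert dm.values[i, -1] == direct

    def test_bounded_by_simulated_events(self, simulated_patient):
        """On the true haplotypes, MED is a minimum and cannot exceed the
        simulated event count separating a pair (estimated phasing may)."""
        from cnevol.simulate import apply_events

        ds, truth = simulated_patient
        # replay the truth to recover each leaf's actual haplotypes
        nodes = {"root": (np.array(truth.founder_a), np.array(truth.founder_b))}
        pending = dict(truth.branch_events)
        while pending:
            for node, events in list(pending.items()):
                parent = truth.parent[node]
                if parent in nodes:
                    nodes[node] = apply_events(*nodes[parent], events)
                    del pending[node]
        leaves = ds.sample_ids
        for x, y in itertools.combinations(leaves, 2):
            d = med_symmetric(nodes[x][0], nodes[y][0]) + med_symmetric(nodes[x][1], nodes[y][1])
            assert d <= truth.pair_events(x, y) + 1e-9

    def test_permutation_equivariant(self, two_sample_patient):
        phased = phase_patient(two_sample_patient)
        dm = distance_matrix(phased)
        ds_rev = PatientDataset(
            "P1",
            list(reversed(two_sample_patient.profiles)),
            list(reversed(two_sample_patient.records)),
        )
        dm_rev = distance_matrix(phase_patient(ds_rev))
        assert dm.values[0, 1] == dm_rev.values[0, 1]
        assert dm.values[0, -1] == dm_rev.values[1, -1]
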