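"""Spatio-temporal cluster formation and permutation inference."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from gazebeta.cluster import (
    Cluster,
    PermutationNull,
    aggregate_windows,
    cluster_permutation_test,
    cluster_pvalues,
    form_clusters,
    persistence_filter,
    pointwise_tmap,
)
from gazebeta.montage import MONTAGE_19, AdjacencyGraph, default_adjacency


def tiny_graph():
    """Three electrodes: E1–E2 adjacent, E3 isolated."""
    return AdjacencyGraph({"E1": ("E2",)}, ("E1", "E2", "E3"))


def make_cluster(extents, direction=1, mass=None):
    els, samples = [], []
    names = list(extents)
    for i, name in enumerate(names):
        for s, e in extents[name]:
            idx = np.arange(int(round(s * 1000)), int(round(e * 1000)))
            els.append(np.full(idx.size, i))
            samples.append(idx)
    els = np.concatenate(els)
    samples = np.concatenate(samples)
    runs = max(
        max(int(round((e - s) * 1000)) for s, e in ivs) for ivs in extents.values()
    )
    return Cluster(
        electrodes=els,
        samples=samples,
        mass=mass if mass is not None else direction * float(els.size),
        direction=direction,
        extents=extents,
        max_run_s=runs / 1000.0,
        p=0.01,
    )


class TestMontage:
    def test_adjacency_is_symmetric_and_irreflexive(self, graph):
        for a in graph.montage:
            assert a not in graph.neighbors(a)
            for b in graph.neighbors(a):
                assert a in graph.neighbors(b)

    def test_every_montage_electrode_present(self, graph):
        assert set(graph.montage) == set(MONTAGE_19)
        for e in graph.montage:
            assert len(graph.neighbors(e)) > 0

    def test_cp5_neighborhood(self, graph):
        assert graph.neighbors("CP5") == frozenset({"FC5", "CP1", "P7", "P3"})


class TestFormation:
    def test_empty_mask_gives_no_clusters(self):
        t = np.zeros((3, 100))
        p = np.ones((3, 100))
        assert form_clusters(t, p, tiny_graph()) == []

    def test_single_run_mass_arithmetic(self):
        """A 25-ms run with t = 3 at each millisecond has mass 75."""
        t = np.zeros((3, 100))
        p = np.ones((3, 100))
        t[0, 10:35] = 3.0
        p[0, 10:35] = 0.01
        clusters = form_clusters(t, p, tiny_graph())
        assert len(clusters) == 1
        c = clusters[0]
        assert c.mass == pytest.approx(75.0)
        assert c.direction == 1
        assert c.extents == {"E1": [(0.010, 0.035)]}
        assert c.max_run_s == pytest.approx(0.025)

    def test_adjacent_electrodes_with_overlapping_runs_merge(self):
        t = np.zeros((3, 100))
        p = np.ones((3, 100))
        t[0, 10:30] = 2.0
        t[1, 25:45] = 2.0
        p[t > 0] = 0.01
        clusters = form_clusters(t, p, tiny_graph())
        assert len(clusters) == 1
        assert set(clusters[0].extents) == {"E1", "E2"}

    def test_non_adjacent_electrodes_stay_separate(self):
        t = np.zeros((3, 100))
        p = np.ones((3, 100))
        t[0, 10:30] = 2.0
        t[2, 10:30] = 2.0  # E3 has no neighbors
        p[t > 0] = 0.01
        clusters = form_clusters(t, p, tiny_graph())
        assert len(clusters) == 2

    def test_opposite_signs_never_merge(self):
        t = np.zeros((3, 100))
        p = np.ones((3, 100))
        t[0, 10:20] = 2.0
        t[0, 20:30] = -2.0
        p[np.abs(t) > 0] = 0.01
        clusters = form_clusters(t, p, tiny_graph())
        assert sorted(c.direction for c in clusters) == [-1, 1]


class TestPValues:
    def test_mass_below_every_null_max(self):
        c = make_cluster({"E1": [(0.01, 0.03)]}, mass=1.0)
        null = PermutationNull(10, 0, np.full(10, 50.0))
        cluster_pvalues([c], null)
        assert c.p == pytest.approx(1.0)

    def test_mass_above_every_null_max(self):
        c = make_cluster({"E1": [(0.01, 0.03)]}, mass=99.0)
        null = PermutationNull(999, 0, np.zeros(999))
        cluster_pvalues([c], null)
        assert c.p == pytest.approx(1.0 / 1000.0)


class TestPersistence:
    def test_exactly_10ms_removed_11ms_kept(self):
        c10 = make_cluster({"E1": [(0.020, 0.030)]})
        c11 = make_cluster({"E1": [(0.020, 0.031)]})
        out = persistence_filter([c10, c11])
        assert out == [c11]

    def test_empty_list(self):
        assert persistence_filter([]) == []

    def test_subset_preserved_in_order(self):
        cs = [
            make_cluster({"E1": [(0.0, 0.050)]}),
            make_cluster({"E2": [(0.1, 0.105)]}),
            make_cluster({"E3": [(0.2, 0.280)]}),
        ]
        assert persistence_filter(cs) == [cs[0], cs[2]]

    def test_multi_electrode_cluster_judged_by_single_electrode_runs(self):
        # total footprint is long but no single electrode exceeds 10 ms
        c = make_cluster({"E1": [(0.0, 0.008)], "E2": [(0.007, 0.015)]})
        assert persistence_filter([c]) == []


class TestWindows:
    def test_single_cluster_is_its_own_window(self, graph):
        c = make_cluster({"CP5": [(0.554, 0.579)]})
        ws = aggregate_windows([c], graph)
        assert len(ws) == 1
        assert ws[0].start_s == pytest.approx(0.554)
        assert ws[0].end_s == pytest.approx(0.579)
        assert ws[0].electrodes == ("CP5",)

    def test_parietal_premotor_intervals_integrate_to_one_window(self, graph):
        """Consecutive/adjacent significant intervals over CP2, P4, CP5 and
        FC1 merge into a single 0.554–0.619 s representative window."""
        cs = [
            make_cluster({"CP2": [(0.554, 0.576)]}),
            make_cluster({"CP2": [(0.589, 0.607)]}),
            make_cluster({"P4": [(0.567, 0.579)]}),
            make_cluster({"P4": [(0.602, 0.619)]}),
            make_cluster({"CP5": [(0.554, 0.579)]}),
            make_cluster({"FC1": [(0.603, 0.615)]}),
        ]
        ws = aggregate_windows(cs, graph)
        assert len(ws) == 1
        w = ws[0]
        assert w.start_s == pytest.approx(0.554)
        assert w.end_s == pytest.approx(0.619)
        assert set(w.electrodes) == {"CP2", "CP5", "FC1", "P4"}

    def test_distant_intervals_stay_separate(self, graph):
        cs = [
            make_cluster({"O2": [(0.890, 0.941)]}),
            make_cluster({"O2": [(1.814, 1.862)]}),
        ]
        ws = aggregate_windows(cs, graph)
        assert len(ws) == 2

    def test_opposite_directions_never_merge(self, graph):
        cs = [
            make_cluster({"CP2": [(0.554, 0.576)]}, direction=1),
            make_cluster({"CP2": [(0.580, 0.600)]}, direction=-1, mass=-20.0),
        ]
        assert len(aggregate_windows(cs, graph)) == 2


class TestPointwise:
    def test_identical_constant_envelopes_give_zero_t(self):
        env = np.ones((4, 2, 30))
        pw = pointwise_tmap(env[:2], env[2:], n_perm=20, seed=0)
        np.testing.assert_allclose(pw.t_obs, 0.0)

    def test_exact_p_matches_brute_force_enumeration(self, rng):
        """4 vs 3 participants: exact permutation p at every point equals
        enumeration over all 35 label assignments."""
        env_a = rng.standard_normal((4, 3, 12))
        env_b = rng.standard_normal((3, 3, 12)) + 0.5
        pw = pointwise_tmap(env_a, env_b, exact=True)
        assert pw.n_perm == 35
        X = np.concatenate([env_a, env_b]).reshape(7, -1)
        for j in range(X.shape[1]):
            t_obs = sps.ttest_ind(X[:4, j], X[4:, j], equal_var=True).statistic
            count = 0
            for combo in itertools.combinations(range(7), 4):
                sel = np.zeros(7, dtype=bool)
                sel[list(combo)] = True
                t_perm = sps.ttest_ind(X[sel, j], X[~sel, j], equal_var=True).statistic
                count += abs(t_perm) >= abs(t_obs) - 1e-10
            assert pw.p_obs.ravel()[j] == pytest.approx(count / 35, abs=1.0 / 35)

    def test_null_pointwise_p_approximately_uniform(self, rng):
        env_a = rng.standard_normal((6, 4, 200))
        env_b = rng.standard_normal((11, 4, 200))
        pw = pointwise_tmap(env_a, env_b, n_perm=400, seed=1)
        frac = (pw.p_obs < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_group_size_below_two_raises(self, rng):
        with pytest.raises(ValueError):
            pointwise_tmap(
                rng.standard_normal((1, 2, 10)), rng.standard_normal((5, 2, 10))
            )


class TestEndToEnd:
    def test_seed_determinism(self, rng):
        env_a = rng.standard_normal((4, 3, 60))
        env_b = rng.standard_normal((4, 3, 60))
        g = AdjacencyGraph({"E1": ("E2",), "E2": ("E3",)}, ("E1", "E2", "E3"))
        a1 = cluster_permutation_test(env_a, env_b, g, n_perm=100, seed=7)
        a2 = cluster_permutation_test(env_a, env_b, g, n_perm=100, seed=7)
        np.testing.assert_array_equal(a1.null.max_mass, a2.null.max_mass)
        np.testing.assert_array_equal(a1.p_obs, a2.p_obs)
        assert [c.p for c in a1.clusters] == [c.p for c in a2.clusters]

    def test_group_order_flips_mass_sign(self, rng):
        env_a = rng.standard_normal((4, 3, 60))
        env_b = rng.standard_normal((4, 3, 60)) + 0.3
        g = AdjacencyGraph({"E1": ("E2",)}, ("E1", "E2", "E3"))
        a1 = cluster_permutation_test(env_a, env_b, g, exact=True)
        a2 = cluster_permutation_test(env_b, env_a, g, exact=True)
        m1 = sorted(round(c.mass, 4) for c in a1.clusters)
        m2 = sorted(round(-c.mass, 4) for c in a2.clusters)
        assert m1 == m2

    def test_cluster_p_within_valid_range(self, rng):
        env_a = rng.standard_normal((4, 3, 60))
        env_b = rng.standard_normal((4, 3, 60)) + 1.0
        g = AdjacencyGraph({"E1": ("E2",)}, ("E1", "E2", "E3"))
        an = cluster_permutation_test(env_a, env_b, g, n_perm=99, seed=3)
        for c in an.clusters:
            assert 1.0 / 100.0 <= c.p <= 1.0
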