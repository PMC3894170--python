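"""Divergence estimators, NJ trees and the window bootstrap."""

import numpy as np
import pytest

from canid_popgen.demography import DemographicModel, Population
from canid_popgen.divergence import (
    DistanceMatrix,
    distance_matrix,
    nj_tree,
    pairwise_divergence,
    split_time_moment_estimator,
    tree_bipartitions,
    window_bootstrap_support,
)
from canid_popgen.errors import EmptyOverlapError, InvalidParameterError
from canid_popgen.simulate import simulate_dataset
from conftest import make_locus_set


def dm_from_values(values, samples):
    values = np.asarray(values, dtype=float)
    return DistanceMatrix(
        samples,
        values,
        window_mismatch=values[None] * 1000.0,
        window_called=np.full((1, len(samples), len(samples)), 1000.0),
    )


class TestPairwiseDivergence:
    @pytest.mark.parametrize(
        "ga, gb, allpairs, conservative",
        [
            (0, 0, 0.0, 0.0),  # AA vs AA
            (0, 1, 0.5, 0.0),  # AA vs AT
            (0, 2, 1.0, 1.0),  # AA vs TT
            (1, 1, 0.5, 0.0),  # AT vs AT
            (1, 2, 0.5, 0.0),  # AT vs TT
        ],
    )
    def test_single_site_scores(self, ga, gb, allpairs, conservative):
        assert pairwise_divergence([ga], [gb], 1, "allpairs") == allpairs
        assert pairwise_divergence([ga], [gb], 1, "conservative") == conservative

    def test_allpairs_dominates_conservative(self):
        rng = np.random.default_rng(0)
        ga = rng.integers(0, 3, 500)
        gb = rng.integers(0, 3, 500)
        ap = pairwise_divergence(ga, gb, 1000, "allpairs")
        cons = pairwise_divergence(ga, gb, 1000, "conservative")
        assert ap >= cons

    def test_missing_sites_dropped_from_both_terms(self):
        # one informative mismatch over one effective called site
        assert pairwise_divergence([0, -1], [2, 2], 2, "conservative") == 1.0

    def test_empty_overlap(self):
        with pytest.raises(EmptyOverlapError):
            pairwise_divergence([-1], [2], 1, "allpairs")


class TestDistanceMatrix:
    def test_identical_samples_give_zero_matrix(self):
        data = make_locus_set([(1, 1, 1), (2, 2, 2)], ["a", "b", "c"])
        dm = distance_matrix(data, mode="conservative")
        np.testing.assert_array_equal(dm.values, np.zeros((3, 3)))

    def test_hand_computed_toy_matrix(self):
        # 10 sites, 4 samples, length 10 -> divergence = mismatches / 10
        sites = [
            (0, 0, 2, 2),
            (0, 2, 2, 0),
            (2, 2, 0, 0),
            (0, 0, 0, 2),
            (2, 0, 0, 0),
            (0, 1, 2, 1),
            (1, 1, 0, 2),
            (0, 0, 2, 0),
            (2, 2, 2, 0),
            (0, 2, 0, 2),
        ]
        data = make_locus_set(sites, ["a", "b", "c", "d"], length=10)
        dm = distance_matrix(data, mode="conservative")
        # by hand: count sites where the pair shares no allele
        expected = np.zeros((4, 4))
        for s in sites:
            for i in range(4):
                for j in range(4):
                    if {s[i], s[j]} == {0, 2}:
                        expected[i, j] += 0.1
        np.testing.assert_allclose(dm.values, expected)

    def test_window_partials_reconstruct_totals(self, fig5a_dataset):
        dm = distance_matrix(fig5a_dataset, loci_per_window=10)
        total = dm.window_mismatch.sum(axis=0) / np.maximum(
            dm.window_called.sum(axis=0), 1
        )
        np.fill_diagonal(total, 0)
        np.testing.assert_allclose(total, dm.values)

    def test_wolves_closer_to_each_other_than_to_dogs(self, fig5a_dataset):
        dm = distance_matrix(fig5a_dataset, mode="conservative")
        df = dm.as_dataframe()
        wolf_pairs = [("CRW", "CHW"), ("CRW", "ISW"), ("CHW", "ISW")]
        dog_wolf = [(d, w) for d in ("BOX", "BSJ", "DNG")
                    for w in ("CRW", "CHW", "ISW")]
        mean_ww = np.mean([df.loc[a, b] for a, b in wolf_pairs])
        mean_dw = np.mean([df.loc[a, b] for a, b in dog_wolf])
        assert mean_ww < mean_dw


class TestNJTree:
    def test_additive_matrix_recovered_exactly(self):
        # tree ((a:1,b:2):1,(c:3,d:4)); pairwise path lengths are additive
        values = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(dm_from_values(values, ["a", "b", "c", "d"]))
        assert tree_bipartitions(tree.tree) == {("c", "d")}
        # branch lengths reproduce the input distances
        t = tree.tree
        for x, y, d in [("a", "b", 3), ("a", "c", 5), ("c", "d", 7)]:
            assert t.find(x).distance(t.find(y)) == pytest.approx(d)

    def test_three_taxa_star(self):
        values = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = nj_tree(dm_from_values(values, ["a", "b", "c"]))
        t = tree.tree
        assert t.find("a").distance(t.find("b")) == pytest.approx(2)
        assert t.find("a").distance(t.find("c")) == pytest.approx(3)
        assert t.find("b").distance(t.find("c")) == pytest.approx(5)

    def test_tied_matrix_is_deterministic(self):
        values = np.ones((4, 4)) - np.eye(4)
        trees = {
            nj_tree(dm_from_values(values, list("abcd"))).newick()
            for _ in range(5)
        }
        assert len(trees) == 1

    def test_nonfinite_rejected(self):
        values = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]])
        with pytest.raises(InvalidParameterError):
            nj_tree(dm_from_values(values, list("abc")))

    def test_expected_divergence_matrix_recovers_model_topology(self, fig5a_nomig):
        # analytic E[dxy] = 2 mu E[T2], with E[T2] integrated over the
        # chain of ancestral epochs (coalescence can spill past a short
        # ancestor into deeper, larger populations); NJ on these exact
        # expectations must return the model tree
        m = fig5a_nomig
        mu = m.mutation_rate
        leaves = sorted(m.leaves)

        def ancestor_of(a, b):
            pa = set()
            p = m.populations[a]
            while p.parent is not None:
                pa.add(p.parent)
                p = m.populations[p.parent]
            p = m.populations[b]
            while p.parent is not None:
                if p.parent in pa:
                    return m.populations[p.parent]
                p = m.populations[p.parent]
            raise AssertionError("no common ancestor")

        def expected_pair_t2(anc):
            # E[T2] = start + integral of survival over ancestor chain
            total, surv, p = anc.start_gen, 1.0, anc
            while True:
                ne = p.ne_at(p.start_gen)
                rate = 1.0 / (2.0 * ne)
                if p.parent is None:
                    total += surv / rate
                    return total
                duration = p.end_gen - p.start_gen
                total += surv * (1.0 - np.exp(-rate * duration)) / rate
                surv *= np.exp(-rate * duration)
                p = m.populations[p.parent]

        n = len(leaves)
        values = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                anc = ancestor_of(leaves[i], leaves[j])
                values[i, j] = values[j, i] = 2 * mu * expected_pair_t2(anc)
        tree = nj_tree(dm_from_values(values, leaves))
        # canonical sides exclude the reference taxon BOX, so the dog clade
        # and the (BOX,BSJ) pair appear as their wolf/jackal complements
        assert tree_bipartitions(tree.tree) == {
            ("CHW", "ISW"),  # wolf-internal pair
            ("CHW", "CRW", "ISW"),  # wolf clade
            ("CHW", "CRW", "GLJ", "ISW"),  # complement of the dog clade
            ("CHW", "CRW", "DNG", "GLJ", "ISW"),  # complement of (BOX, BSJ)
        }


class TestWindowBootstrap:
    def test_single_window_gives_full_support(self):
        values = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = window_bootstrap_support(dm_from_values(values, list("abcd")),
                                        n_reps=10, seed=1)
        assert set(tree.supports.values()) == {100.0}

    def test_seed_reproducibility_and_window_order_invariance(self, fig5a_dataset):
        dm = distance_matrix(fig5a_dataset, loci_per_window=10)
        t1 = window_bootstrap_support(dm, n_reps=30, seed=9)
        t2 = window_bootstrap_support(dm, n_reps=30, seed=9)
        assert t1.supports == t2.supports
        # permuting windows redraws different window identities, but edges
        # supported in every replicate stay saturated
        perm = np.random.default_rng(0).permutation(dm.n_windows)
        dm_perm = DistanceMatrix(
            dm.samples, dm.values, dm.window_mismatch[perm], dm.window_called[perm]
        )
        t3 = window_bootstrap_support(dm_perm, n_reps=30, seed=9)
        saturated = {p for p, v in t1.supports.items() if v == 100.0}
        assert saturated
        assert all(t3.supports[p] == 100.0 for p in saturated)

    def test_label_swap_invariance(self, fig5a_dataset):
        dm = distance_matrix(fig5a_dataset, loci_per_window=10)
        swapped = ["CHW" if s == "CRW" else "CRW" if s == "CHW" else s
                   for s in dm.samples]
        dm_sw = DistanceMatrix(swapped, dm.values, dm.window_mismatch,
                               dm.window_called)
        t1 = window_bootstrap_support(dm, n_reps=20, seed=5)
        t2 = window_bootstrap_support(dm_sw, n_reps=20, seed=5)
        relabel = {"CRW": "CHW", "CHW": "CRW"}
        remapped = {
            tuple(sorted(relabel.get(x, x) for x in part)): v
            for part, v in t1.supports.items()
        }
        assert remapped == t2.supports


class TestSplitTimeEstimator:
    def test_equal_rates_give_zero(self):
        assert split_time_moment_estimator(4e-4, 4e-4, 4e-4, 1e-8) == (0.0, False)

    def test_arithmetic(self):
        t, clamped = split_time_moment_estimator(5e-4, 4e-4, 4e-4, 1e-8, 3.0)
        assert t == pytest.approx(15_000)
        assert not clamped

    def test_negative_clamped(self):
        t, clamped = split_time_moment_estimator(1e-4, 4e-4, 4e-4, 1e-8)
        assert t == 0.0 and clamped

    def test_recovers_split_time_from_simulations(self):
        # two populations split 5000 generations ago, Ne 10,000 everywhere
        t_split, ne, mu = 5000.0, 10_000.0, 1e-8
        pops = {
            "A": Population("A", "anc", ne, 0.0, t_split),
            "B": Population("B", "anc", ne, 0.0, t_split),
            "anc": Population("anc", None, ne, t_split),
        }
        m = DemographicModel(pops, [])
        estimates = []
        for rep in range(30):
            data = simulate_dataset(m, 500, 1000, mu=mu, seed=1000 + rep)
            called = 500 * 1000
            _, g = data.stacked()
            dxy = pairwise_divergence(g[:, 0], g[:, 1], called, "allpairs")
            het_a = (g[:, 0] == 1).sum() / called
            het_b = (g[:, 1] == 1).sum() / called
            t_est, _ = split_time_moment_estimator(dxy, het_a, het_b, mu,
                                                   gen_time=1.0)
            estimates.append(t_est)
        assert np.mean(estimates) == pytest.approx(t_split, rel=0.10)
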