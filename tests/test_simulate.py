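"""Structured-coalescent simulator against closed forms and msprime."""

import numpy as np
import pytest

from canid_popgen.demography import (
    DemographicModel,
    MigrationBand,
    PiecewiseNeTrajectory,
    Population,
)
from canid_popgen.errors import InfiniteSitesError, InvalidParameterError, ModelError
from canid_popgen.simulate import (
    simulate_dataset,
    simulate_depth_track,
    simulate_genealogy,
    simulate_trajectory_genome,
)


def expected_t2(epochs):
    """Independent oracle: E[T2] under piecewise-constant Ne.

    ``epochs`` is a list of (duration_generations, Ne); the last duration
    may be inf.  Integrates P(T > t) epoch by epoch in closed form.
    """
    total, surv = 0.0, 1.0
    for duration, ne in epochs:
        rate = 1.0 / (2.0 * ne)
        if np.isinf(duration):
            total += surv / rate
            break
        total += surv * (1.0 - np.exp(-rate * duration)) / rate
        surv *= np.exp(-rate * duration)
    return total


def single_pop(ne, name="p"):
    return DemographicModel({name: Population(name, None, ne)}, [])


def split_model(split_gen, ne_leaf, ne_anc, bands=()):
    pops = {
        "A": Population("A", "anc", ne_leaf, 0.0, split_gen),
        "B": Population("B", "anc", ne_leaf, 0.0, split_gen),
        "anc": Population("anc", None, ne_anc, split_gen),
    }
    return DemographicModel(pops, list(bands))


class TestGenealogy:
    def test_mean_tmrca_constant_ne(self):
        # E[T2] = 2N for two lineages in one constant population
        n = 5000.0
        tm = np.array(
            [simulate_genealogy(single_pop(n), ["p"], (1, i)).tmrca
             for i in range(10_000)]
        )
        se = tm.std() / np.sqrt(len(tm))
        assert abs(tm.mean() - 2 * n) < 3 * se

    def test_no_coalescence_before_split_without_migration(self):
        m = split_model(2000.0, 1000.0, 1000.0)
        for i in range(300):
            g = simulate_genealogy(m, ["A", "B"], (2, i))
            internal = g.times[g.n_leaves:]
            cross = [
                t for t, pop in zip(internal, g.node_pop[g.n_leaves:])
                if pop == "anc"
            ]
            # lineages sampled in different populations meet only in 'anc'
            assert g.tmrca >= 2000.0
            assert all(t >= 2000.0 for t in cross)

    def test_fig5a_wolf_tmrca_matches_epoch_integration(self, fig5a_nomig):
        m = fig5a_nomig
        g = m.generation_time
        epochs = [
            (13_400 / g, 10_000.0),
            ((14_900 - 13_400) / g, 12_600.0),
            ((398_000 - 14_900) / g, 45_000.0),
            (np.inf, 45_000.0),
        ]
        expect = expected_t2(epochs)
        tm = np.array(
            [simulate_genealogy(m, ["CRW"], (3, i)).tmrca for i in range(30_000)]
        )
        assert tm.mean() == pytest.approx(expect, rel=0.02)

    def test_nonleaf_sample_rejected(self, fig5a_nomig):
        with pytest.raises(ModelError):
            simulate_genealogy(fig5a_nomig, ["ancDW"], 1)

    def test_migration_allows_pre_split_coalescence(self):
        m = split_model(50_000.0, 1000.0, 1000.0,
                        bands=[MigrationBand("A", "B", 5.0)])
        tm = [simulate_genealogy(m, ["A", "B"], (4, i)).tmrca for i in range(200)]
        assert min(tm) < 50_000.0


class TestDataset:
    def test_heterozygosity_matches_theta(self):
        # theta = 4*Ne*mu per site for a single constant population
        ne, mu, n_loci, L = 10_000.0, 1e-8, 20_000, 1000
        data = simulate_dataset(single_pop(ne), n_loci, L, mu=mu, seed=5)
        het_per_locus = np.array(
            [(loc.genotypes[:, 0] == 1).sum() for loc in data.loci], dtype=float
        )
        rate = het_per_locus.sum() / (n_loci * L)
        se = het_per_locus.std() / np.sqrt(n_loci) / L
        assert abs(rate - 4 * ne * mu) < 3 * se

    def test_divergence_matches_closed_form(self):
        # E[dxy] = 2 mu (T + 2 Ne_anc) for a clean split
        t_split, ne, mu, n_loci, L = 5000.0, 10_000.0, 1e-8, 10_000, 1000
        m = split_model(t_split, ne, ne)
        data = simulate_dataset(m, n_loci, L, mu=mu, seed=6)
        # mean of the 4 allele comparisons per site, averaged over sites
        per_locus = np.empty(n_loci)
        for i, loc in enumerate(data.loci):
            ga = loc.genotypes[:, 0].astype(float)
            gb = loc.genotypes[:, 1].astype(float)
            per_locus[i] = ((ga * (2 - gb) + gb * (2 - ga)) / 4.0).sum()
        dxy = per_locus.sum() / (n_loci * L)
        se = per_locus.std() / np.sqrt(n_loci) / L
        assert abs(dxy - 2 * mu * (t_split + 2 * ne)) < 3 * se

    def test_zero_mutation_rate_gives_no_sites(self):
        data = simulate_dataset(single_pop(1000.0), 50, 1000, mu=0.0, seed=7)
        assert data.n_sites == 0

    def test_same_seed_reproduces_exactly(self, fig5a_nomig):
        a = simulate_dataset(fig5a_nomig, 30, 1000, seed=11)
        b = simulate_dataset(fig5a_nomig, 30, 1000, seed=11)
        for la, lb in zip(a.loci, b.loci):
            np.testing.assert_array_equal(la.positions, lb.positions)
            np.testing.assert_array_equal(la.genotypes, lb.genotypes)

    def test_per_locus_streams_are_subset_stable(self, fig5a_nomig):
        # locus i is identical whether or not other loci are simulated
        big = simulate_dataset(fig5a_nomig, 20, 1000, seed=12)
        small = simulate_dataset(fig5a_nomig, 5, 1000, seed=12)
        for i in range(5):
            np.testing.assert_array_equal(
                big.loci[i].genotypes, small.loci[i].genotypes
            )

    def test_symmetric_model_sharing_is_symmetric(self):
        # label swap in a symmetric two-population model leaves the joint
        # site-frequency summary unchanged in expectation
        m = split_model(2000.0, 5000.0, 5000.0)
        data = simulate_dataset(m, 4000, 1000, mu=1e-8, seed=13)
        _, g = data.stacked()
        private_a = ((g[:, 0] > 0) & (g[:, 1] == 0)).sum()
        private_b = ((g[:, 1] > 0) & (g[:, 0] == 0)).sum()
        total = private_a + private_b
        assert abs(private_a - private_b) < 3 * np.sqrt(total)

    def test_infinite_sites_violation(self):
        with pytest.raises(InfiniteSitesError):
            simulate_dataset(single_pop(1e7), 1, 10, mu=1e-2, seed=1)

    def test_invalid_sizes(self):
        with pytest.raises(InvalidParameterError):
            simulate_dataset(single_pop(100.0), 0, 1000)


class TestTrajectoryGenome:
    def test_constant_trajectory_equals_constant_model(self):
        traj = PiecewiseNeTrajectory((), (5000.0,))
        a = simulate_trajectory_genome(traj, 30, 1000, mu=1e-8, seed=21)
        b = simulate_dataset(single_pop(5000.0, name="pop0"), 30, 1000,
                             mu=1e-8, seed=21, samples=["pop0"])
        for la, lb in zip(a.loci, b.loci):
            np.testing.assert_array_equal(la.genotypes, lb.genotypes)

    def test_step_trajectory_bounds_heterozygosity(self):
        # recent bottleneck: het strictly between 4*Ne_recent*mu and
        # 4*Ne_ancient*mu
        mu = 1e-8
        traj = PiecewiseNeTrajectory((1000.0,), (1000.0, 30_000.0))
        data = simulate_trajectory_genome(traj, 10_000, 1000, mu=mu, seed=22)
        het = sum((loc.genotypes[:, 0] == 1).sum() for loc in data.loci) / 1e7
        assert 4 * 1000 * mu < het < 4 * 30_000 * mu

    def test_two_epoch_tmrca_matches_closed_form(self):
        traj = PiecewiseNeTrajectory((2000.0,), (1000.0, 20_000.0))
        pop = Population("p", None, traj)
        m = DemographicModel({"p": pop}, [])
        expect = expected_t2([(2000.0, 1000.0), (np.inf, 20_000.0)])
        tm = np.array(
            [simulate_genealogy(m, ["p"], (23, i)).tmrca for i in range(10_000)]
        )
        se = tm.std() / np.sqrt(len(tm))
        assert abs(tm.mean() - expect) < 3 * se


class TestMsprimeCrossCheck:
    def test_fig5a_wolf_tmrca_agrees_with_msprime(self, fig5a_nomig):
        msprime = pytest.importorskip("msprime")
        m = fig5a_nomig
        dem = msprime.Demography()
        for name, p in m.populations.items():
            dem.add_population(name=name, initial_size=p.ne)
        for parent, kids in m.children.items():
            dem.add_population_split(
                time=m.populations[parent].start_gen, derived=kids,
                ancestral=parent,
            )
        dem.sort_events()
        reps = msprime.sim_ancestry(
            samples={"CRW": 1}, demography=dem, num_replicates=10_000,
            random_seed=31, ploidy=2,
        )
        ms = np.array([ts.max_root_time for ts in reps])
        ours = np.array(
            [simulate_genealogy(m, ["CRW"], (32, i)).tmrca for i in range(10_000)]
        )
        pooled_se = np.sqrt(ms.var() / len(ms) + ours.var() / len(ours))
        assert abs(ms.mean() - ours.mean()) < 3 * pooled_se


class TestDepthTrack:
    def test_diploid_mean(self):
        profile = np.full(50_000, 2)
        track = simulate_depth_track(profile, 15.0, seed=41)
        se = track.depth.std() / np.sqrt(len(track.depth))
        assert abs(track.depth.mean() - 30.0) < 3 * se

    def test_zero_copy_region_is_empty(self):
        profile = np.concatenate([np.full(1000, 2), np.zeros(1000, int)])
        track = simulate_depth_track(profile, 15.0, seed=42)
        assert np.all(track.depth[1000:] == 0)

    def test_high_copy_window_mean(self):
        profile = np.full(10_000, 29)
        track = simulate_depth_track(profile, 15.0, seed=43)
        se = track.depth.std() / np.sqrt(len(track.depth))
        assert abs(track.depth.mean() - 435.0) < 3 * se

    def test_empty_profile_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_depth_track(np.array([]), 15.0)
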