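"""Structured-coalescent simulation of unlinked neutral loci.

The simulator runs the coalescent backwards in time on a
:class:`~canid_popgen.demography.DemographicModel`: within each epoch
(between population splits, Ne breakpoints and migration-band endpoints)
lineages in a population of diploid size ``Ne`` coalesce pairwise at rate
``1/(2*Ne)`` per pair per generation, and migrate along active bands at
the band's per-generation rate; at a split time the daughter populations'
lineages merge into the parent.  Waiting times are exponential with rates
updated at epoch boundaries (continuous-time exact simulation, no
discrete generations).

Mutations are dropped on the resulting genealogy as a Poisson process
with rate ``mu * L * total_branch_length`` under the infinite-sites
model: each mutation occupies a distinct position within the locus and
defines the derived allele.  There is no intra-locus recombination, no
sequencing-error model and no selection.

Random-number streams are per locus (derived from ``(seed, locus
index)``) so any subset of loci reproduces exactly regardless of how the
work is split up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demography import DemographicModel, PiecewiseNeTrajectory, Population
from .errors import InfiniteSitesError, InvalidParameterError, ModelError
from .loci import Locus, LocusSet

__all__ = [
    "Genealogy",
    "simulate_genealogy",
    "simulate_dataset",
    "simulate_trajectory_genome",
    "simulate_depth_track",
]


@dataclass
class Genealogy:
    """A coalescent tree over 2 lineages per sampled diploid.

    Leaves are nodes ``0 .. 2k-1``; leaf ``2i`` and ``2i+1`` are the two
    chromosomes of the diploid sampled from ``samples[i]``.  ``parent``
    is -1 at the grand MRCA.  Times are generations before present.
    """

    samples: list[str]
    times: np.ndarray  # (n_nodes,) float
    parent: np.ndarray  # (n_nodes,) int, -1 for the root
    node_pop: list[str]  # population in which each node was created

    @property
    def n_leaves(self) -> int:
        return 2 * len(self.samples)

    @property
    def tmrca(self) -> float:
        return float(self.times.max())

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 at the root)."""
        bl = np.zeros(len(self.times))
        has_parent = self.parent >= 0
        bl[has_parent] = self.times[self.parent[has_parent]] - self.times[has_parent]
        return bl

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def descendant_leaves(self) -> np.ndarray:
        """(n_nodes, n_leaves) boolean matrix of leaves below each node."""
        n_nodes = len(self.times)
        nl = self.n_leaves
        desc = np.zeros((n_nodes, nl), dtype=bool)
        desc[np.arange(nl), np.arange(nl)] = True
        for node in np.argsort(self.times, kind="stable"):
            p = self.parent[node]
            if p >= 0:
                desc[p] |= desc[node]
        return desc


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_genealogy(
    model: DemographicModel, samples: list[str], seed
) -> Genealogy:
    """Simulate one genealogy for one diploid (2 lineages) per named leaf.

    ``samples`` lists leaf population names; duplicates are allowed (two
    diploids from one population).  ``seed`` is an int, a seed sequence
    or a ``numpy.random.Generator``.
    """
    rng = _as_rng(seed)
    leaf_names = set(model.leaves)
    for s in samples:
        if s not in leaf_names:
            raise ModelError(f"sampled population {s!r} is not a leaf of the model")

    n_lin = 2 * len(samples)
    times = [0.0] * n_lin
    parents = [-1] * n_lin
    node_pop: list[str] = []
    lineage_pop: dict[int, str] = {}
    for i, s in enumerate(samples):
        lineage_pop[2 * i] = s
        lineage_pop[2 * i + 1] = s
        node_pop.extend([s, s])

    pops = model.populations
    boundaries = model.epoch_boundaries()
    # backward-time band view: forward source->target means a lineage now in
    # `target` jumps into `source` looking backwards
    bands = []
    for b in model.migration_bands:
        lo, hi = model.band_interval(b)
        bands.append((b.target, b.source, model.band_rate(b), lo, hi))

    t = 0.0
    bi = 0
    next_node = n_lin
    while len(lineage_pop) > 1:
        counts: dict[str, int] = {}
        for pop in lineage_pop.values():
            counts[pop] = counts.get(pop, 0) + 1
        events: list[tuple[float, str, object]] = []
        for pop in sorted(counts):
            k = counts[pop]
            if k >= 2:
                ne = pops[pop].ne_at(t)
                events.append((k * (k - 1) / 2.0 / (2.0 * ne), "coal", pop))
        for frm, to, m, lo, hi in bands:
            if lo <= t < hi and counts.get(frm, 0) > 0:
                events.append((counts[frm] * m, "mig", (frm, to)))
        total_rate = sum(e[0] for e in events)
        next_boundary = boundaries[bi] if bi < len(boundaries) else np.inf

        if total_rate > 0:
            dt = rng.exponential(1.0 / total_rate)
        else:
            dt = np.inf
        if t + dt >= next_boundary:
            if not np.isfinite(next_boundary):
                raise ModelError(
                    "lineages cannot reach a common ancestor; the model tree "
                    "is malformed"
                )
            # advance to the boundary: merge populations ending there
            t = next_boundary
            bi += 1
            for lid, pop in list(lineage_pop.items()):
                while pops[pop].end_gen <= t:
                    pop = pops[pop].parent  # type: ignore[assignment]
                lineage_pop[lid] = pop
            continue

        t += dt
        u = rng.random() * total_rate
        acc = 0.0
        chosen = events[-1]
        for ev in events:
            acc += ev[0]
            if u < acc:
                chosen = ev
                break
        if chosen[1] == "coal":
            pop = chosen[2]
            ids = sorted(l for l, p in lineage_pop.items() if p == pop)
            pair = rng.choice(len(ids), size=2, replace=False)
            a, b_ = ids[pair[0]], ids[pair[1]]
            times.append(t)
            parents.append(-1)
            node_pop.append(pop)  # type: ignore[arg-type]
            parents[a] = next_node
            parents[b_] = next_node
            del lineage_pop[a], lineage_pop[b_]
            lineage_pop[next_node] = pop  # type: ignore[assignment]
            next_node += 1
        else:
            frm, to = chosen[2]  # type: ignore[misc]
            ids = sorted(l for l, p in lineage_pop.items() if p == frm)
            lid = ids[rng.integers(len(ids))]
            lineage_pop[lid] = to

    return Genealogy(
        list(samples),
        np.asarray(times),
        np.asarray(parents, dtype=np.int64),
        node_pop,
    )


def _mutate_locus(
    gen: Genealogy, mu: float, length: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Drop infinite-sites mutations; return (positions, genotype matrix)."""
    bl = gen.branch_lengths()
    total = float(bl.sum())
    expected = mu * length * total
    if expected > length:
        raise InfiniteSitesError(
            f"expected {expected:.1f} mutations exceed the {length} bp locus; "
            "lower the mutation rate or shorten the tree"
        )
    n_mut = int(rng.poisson(expected))
    n_mut = min(n_mut, length)  # cannot exceed available distinct sites
    n_samp = len(gen.samples)
    if n_mut == 0:
        return (
            np.empty(0, dtype=np.int64),
            np.empty((0, n_samp), dtype=np.int8),
        )
    positions = np.sort(rng.choice(length, size=n_mut, replace=False))
    branch = rng.choice(len(bl), size=n_mut, p=bl / total)
    desc = gen.descendant_leaves()
    derived = desc[branch]  # (n_mut, n_leaves)
    genotypes = (
        derived[:, 0::2].astype(np.int8) + derived[:, 1::2].astype(np.int8)
    )
    return positions, genotypes


def simulate_dataset(
    model: DemographicModel,
    n_loci: int,
    locus_length: int,
    mu: float | None = None,
    seed: int = 0,
    samples: list[str] | None = None,
) -> LocusSet:
    """Simulate a :class:`LocusSet` of unlinked loci under the model.

    One diploid is sampled per population in ``samples`` (default: all
    leaves in sorted order).  Each locus gets its own genealogy and its
    own RNG stream derived from ``(seed, locus index)``.
    """
    if n_loci <= 0:
        raise InvalidParameterError("n_loci must be > 0")
    if locus_length <= 0:
        raise InvalidParameterError("locus_length must be > 0")
    if mu is None:
        mu = model.mutation_rate
    if samples is None:
        samples = sorted(model.leaves)

    loci = []
    for i in range(n_loci):
        rng = np.random.default_rng((int(seed), i))
        gen = simulate_genealogy(model, samples, rng)
        positions, genotypes = _mutate_locus(gen, mu, locus_length, rng)
        loci.append(Locus(f"locus_{i}", locus_length, positions, genotypes))
    return LocusSet(list(samples), loci)


def simulate_trajectory_genome(
    trajectory: PiecewiseNeTrajectory,
    n_loci: int,
    locus_length: int,
    mu: float = 1e-8,
    seed: int = 0,
) -> LocusSet:
    """Single-diploid genome under a piecewise-constant Ne history.

    Single-population special case of :func:`simulate_dataset`; a
    constant trajectory reproduces the constant-Ne result on the same
    seed and stream.
    """
    pop = Population("pop0", None, trajectory)
    model = DemographicModel({"pop0": pop}, [], name="trajectory")
    return simulate_dataset(model, n_loci, locus_length, mu=mu, seed=seed,
                            samples=["pop0"])


def simulate_depth_track(
    copy_profile: np.ndarray,
    haploid_mean_depth: float,
    window: int = 1000,
    seed: int = 0,
    control_length: int = 20000,
    contig: str = "target",
):
    """Poisson read-depth track for a locus with known per-base copy number.

    Per-base depth ~ Poisson(copy * haploid_mean_depth).  Also simulates
    a diploid (copy 2) control region of ``control_length`` bases whose
    mean depth serves as the normalization constant downstream.  Returns
    a :class:`~canid_popgen.cnv.DepthTrack`.
    """
    from .cnv import DepthTrack  # local import to avoid a cycle

    copy_profile = np.asarray(copy_profile)
    if copy_profile.size == 0:
        raise InvalidParameterError("copy_profile must be non-empty")
    if np.any(copy_profile < 0):
        raise InvalidParameterError("copy numbers must be >= 0")
    if haploid_mean_depth <= 0:
        raise InvalidParameterError("haploid_mean_depth must be > 0")
    rng = _as_rng(seed)
    depth = rng.poisson(copy_profile * haploid_mean_depth).astype(np.float64)
    control = rng.poisson(
        2.0 * haploid_mean_depth, size=control_length
    ).astype(np.float64)
    return DepthTrack(
        contig=contig,
        depth=depth,
        control_mean=float(control.mean()),
        window=window,
    )
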