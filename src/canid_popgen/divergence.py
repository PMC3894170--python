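"""Diploid pairwise divergence, neighbor-joining trees and window bootstrap.

Two per-site divergence estimators between diploid individuals are
implemented side by side:

* ``conservative`` — a site counts 1 only when the two genotypes share
  no allele (e.g. AA vs TT), else 0.  Robust to genotyping noise in
  heterozygotes.
* ``allpairs`` — the mean of the four inter-individual allele
  comparisons, (1/4) * sum 1[x_i != y_j]; AA vs AT contributes 1/2.

The genome-wide value is (sum of per-site mismatch scores) / (called
sites).  Per-window partial sums are retained so a tree's bootstrap
support can be computed by resampling windows with replacement until the
resampled genome has at least as many called sites as the original, then
rebuilding the matrix as (sum mismatches)/(sum called) — recomputed from
pooled partials, not averaged window ratios, to avoid weighting bias
from uneven window coverage.

NJ itself is delegated to scikit-bio (canonical Q-criterion
agglomeration, negative branch lengths clamped to zero).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio
from skbio.tree import TreeNode, nj

from .errors import EmptyOverlapError, InvalidParameterError
from .loci import LocusSet

__all__ = [
    "DistanceMatrix",
    "SupportTree",
    "pairwise_divergence",
    "distance_matrix",
    "nj_tree",
    "window_bootstrap_support",
    "split_time_moment_estimator",
]


def _mismatch_scores(ga: np.ndarray, gb: np.ndarray, mode: str) -> np.ndarray:
    """Per-site mismatch score between two derived-allele-count tracks."""
    if mode == "allpairs":
        return (ga * (2 - gb) + gb * (2 - ga)) / 4.0
    if mode == "conservative":
        return (((ga == 0) & (gb == 2)) | ((ga == 2) & (gb == 0))).astype(float)
    raise InvalidParameterError(f"unknown divergence mode {mode!r}")


def pairwise_divergence(
    ga: np.ndarray,
    gb: np.ndarray,
    called_sites: float,
    mode: str = "conservative",
) -> float:
    """Mean per-site divergence between two diploid genotype tracks.

    ``ga``/``gb`` hold derived-allele counts at the variant sites of a
    shared called-site set of total size ``called_sites`` (invariant
    sites contribute zero mismatches but are part of the denominator).
    Sites missing in either individual are excluded from both numerator
    and denominator.
    """
    ga = np.asarray(ga, dtype=np.int16)
    gb = np.asarray(gb, dtype=np.int16)
    missing = (ga < 0) | (gb < 0)
    effective_called = called_sites - int(missing.sum())
    if effective_called <= 0:
        raise EmptyOverlapError("no overlapping called sites between the tracks")
    scores = _mismatch_scores(ga[~missing], gb[~missing], mode)
    return float(scores.sum()) / effective_called


@dataclass
class DistanceMatrix:
    """Symmetric per-site divergence matrix with per-window partial sums.

    ``window_mismatch[w]`` and ``window_called[w]`` are (n, n) matrices
    of mismatch scores and called-site counts in window ``w``; summing
    over windows and dividing reproduces ``values`` exactly.
    """

    samples: list[str]
    values: np.ndarray  # (n, n) float
    window_mismatch: np.ndarray  # (W, n, n)
    window_called: np.ndarray  # (W, n, n)

    @property
    def n_windows(self) -> int:
        return len(self.window_mismatch)

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.samples)


def distance_matrix(
    data: LocusSet,
    mode: str = "conservative",
    loci_per_window: int = 10,
) -> DistanceMatrix:
    """All-pairs divergence with per-window partials for the bootstrap.

    Windows are contiguous runs of ``loci_per_window`` whole loci.
    """
    n = data.n_samples
    if n < 3:
        raise InvalidParameterError("need at least 3 samples")
    locus_idx, g = data.stacked()
    g = g.astype(np.int16)
    n_windows = max(1, -(-data.n_loci // loci_per_window))
    window_of_site = locus_idx // loci_per_window
    window_of_locus = np.arange(data.n_loci) // loci_per_window

    mism = np.zeros((n_windows, n, n))
    called = np.zeros((n_windows, n, n))
    # called sites per window per pair: min of the two samples' called counts
    # per locus (identical under full calling; missing-site handling below)
    locus_called = data.called  # (n_loci, n_samples)
    for i in range(n):
        for j in range(i + 1, n):
            missing = (g[:, i] < 0) | (g[:, j] < 0)
            scores = np.where(
                missing, 0.0, _mismatch_scores(g[:, i], g[:, j], mode)
            )
            mism[:, i, j] = np.bincount(
                window_of_site, weights=scores, minlength=n_windows
            )
            pair_called = np.minimum(locus_called[:, i], locus_called[:, j]).astype(
                float
            )
            called_w = np.bincount(
                window_of_locus, weights=pair_called, minlength=n_windows
            )
            called_w -= np.bincount(
                window_of_site, weights=missing.astype(float), minlength=n_windows
            )
            called[:, i, j] = called_w
            mism[:, j, i] = mism[:, i, j]
            called[:, j, i] = called[:, i, j]

    total_called = called.sum(axis=0)
    np.fill_diagonal(total_called, 1.0)  # avoid 0/0 on the diagonal
    off = ~np.eye(n, dtype=bool)
    if np.any(total_called[off] <= 0):
        raise EmptyOverlapError("some sample pair shares no called sites")
    values = mism.sum(axis=0) / total_called
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(list(data.samples), values, mism, called)


@dataclass
class SupportTree:
    """Unrooted NJ topology with branch lengths and bootstrap supports.

    ``supports`` maps each internal-edge bipartition (canonicalized as
    the sorted tuple of leaf names on the side *not* containing the
    reference taxon) to percent support in [0, 100].
    """

    tree: TreeNode
    supports: dict[tuple[str, ...], float] = field(default_factory=dict)
    negative_branches_clamped: int = 0

    def bipartitions(self) -> set[tuple[str, ...]]:
        return tree_bipartitions(self.tree)

    def newick(self) -> str:
        """Newick string with supports as internal node labels."""
        t = self.tree.copy()
        if self.supports:
            for node in t.non_tips():
                tips = tuple(sorted(x.name for x in node.tips()))
                key = _canonical_bipartition(
                    tips, tuple(sorted(x.name for x in t.tips()))
                )
                if key in self.supports:
                    node.name = f"{self.supports[key]:g}"
        buf = _io.StringIO()
        t.write(buf, format="newick")
        return buf.getvalue().strip()


def _canonical_bipartition(
    side: tuple[str, ...], all_names: tuple[str, ...]
) -> tuple[str, ...]:
    ref = all_names[0]  # deterministic reference taxon
    side_set = set(side)
    if ref in side_set:
        side_set = set(all_names) - side_set
    return tuple(sorted(side_set))


def tree_bipartitions(tree: TreeNode) -> set[tuple[str, ...]]:
    """Non-trivial bipartitions induced by a tree's internal edges."""
    all_names = tuple(sorted(t.name for t in tree.tips()))
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = tuple(sorted(t.name for t in node.tips()))
        if 1 < len(side) < len(all_names) - 1:
            parts.add(_canonical_bipartition(side, all_names))
    return parts


def _skbio_dm(values: np.ndarray, samples: list[str]) -> skbio.DistanceMatrix:
    # enforce exact symmetry against floating-point asymmetry
    sym = (values + values.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    return skbio.DistanceMatrix(sym, ids=samples)


def nj_tree(matrix: DistanceMatrix) -> SupportTree:
    """Canonical neighbor joining; negative branch lengths clamped to 0."""
    if not np.all(np.isfinite(matrix.values)):
        raise InvalidParameterError("distance matrix contains non-finite entries")
    tree = nj(_skbio_dm(matrix.values, matrix.samples))
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    return SupportTree(tree=tree, negative_branches_clamped=clamped)


def window_bootstrap_support(
    matrix: DistanceMatrix, n_reps: int = 100, seed: int = 0
) -> SupportTree:
    """Window-resampling bootstrap supports for the NJ tree.

    Each replicate draws windows with replacement until the cumulative
    called-site count reaches the original total, rebuilds the distance
    matrix from pooled window partials and reruns NJ; support for each
    original internal edge is the percentage of replicates whose tree
    contains the same bipartition.  Resampling is genome-global: one
    window sequence per replicate, applied to all pairs.
    """
    base = nj_tree(matrix)
    original_parts = tree_bipartitions(base.tree)
    n_windows = matrix.n_windows
    if n_windows < 2:
        # degenerate: every replicate is the original genome
        base.supports = {p: 100.0 for p in original_parts}
        return base

    rng = np.random.default_rng(seed)
    # per-window called-site size (pair-averaged; identical across pairs
    # when all samples share one called-site set)
    off = ~np.eye(len(matrix.samples), dtype=bool)
    win_sizes = matrix.window_called[:, off].mean(axis=1)
    target = win_sizes.sum()

    hits = {p: 0 for p in original_parts}
    for _ in range(n_reps):
        drawn: list[int] = []
        cum = 0.0
        while cum < target:
            w = int(rng.integers(n_windows))
            drawn.append(w)
            cum += win_sizes[w]
        counts = np.bincount(drawn, minlength=n_windows).astype(float)
        mism = np.tensordot(counts, matrix.window_mismatch, axes=(0, 0))
        called = np.tensordot(counts, matrix.window_called, axes=(0, 0))
        np.fill_diagonal(called, 1.0)
        values = mism / called
        np.fill_diagonal(values, 0.0)
        rep_tree = nj(_skbio_dm(values, matrix.samples))
        rep_parts = tree_bipartitions(rep_tree)
        for p in original_parts:
            if p in rep_parts:
                hits[p] += 1
    base.supports = {p: 100.0 * h / n_reps for p, h in hits.items()}
    return base


def split_time_moment_estimator(
    dxy: float,
    het_a: float,
    het_b: float,
    mu: float,
    gen_time: float = 3.0,
) -> tuple[float, bool]:
    """Net-divergence moment estimate of a split time, in years.

    T = (dxy - (het_a + het_b)/2) / (2 mu) * gen_time; the mean
    heterozygosity proxies ancestral diversity 2*mu*2*Ne_anc.  Negative
    estimates are clamped to 0; the second return value flags clamping.
    """
    if mu <= 0:
        raise InvalidParameterError("mu must be > 0")
    if dxy < 0:
        raise InvalidParameterError("dxy must be >= 0")
    t_gen = (dxy - (het_a + het_b) / 2.0) / (2.0 * mu)
    if t_gen < 0:
        return (0.0, True)
    return (t_gen * gen_time, False)
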