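"""ABBA/BABA/BBAA site-pattern statistics for diploid quartets.

For an ordered quartet (P1, P2, P3, O) a biallelic site qualifies when
the two alleles (A and B) are each present in exactly two of the four
individuals and no individual carries both (i.e. all four are
homozygous, two of each allele).  The label records which individual
shares an allele with the outgroup:

* ``BBAA`` — P1, P2 share one allele vs P3, O (concordant with the
  assumed species tree);
* ``ABBA`` — P2, P3 vs P1, O;
* ``BABA`` — P1, P3 vs P2, O.

Under incomplete lineage sorting alone ABBA and BABA are equally likely,
so the D statistic D = (nABBA - nBABA)/(nABBA + nBABA) is centred on
zero; post-divergence gene flow between P3 and one of P1/P2 skews it.
Significance comes from a delete-one block jackknife over contiguous
runs of whole loci.

Two counting modes are kept side by side: *strict* presence counts (the
default for configuration frequencies) and *frequency-weighted* counts
(per-individual derived-allele frequencies in {0, 1/2, 1}, the default
for D because it uses heterozygous sites instead of discarding them).
The letter convention above is fixed and unit-tested; it is a classic
source of sign errors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    InsufficientBlocksError,
    LabelingError,
    ShapeError,
    UndefinedStatisticError,
)
from .loci import LocusSet

__all__ = [
    "QuartetSpec",
    "SitePatternTable",
    "presence_partition",
    "count_patterns",
    "d_statistic",
    "jackknife_z",
    "enumerate_quartets",
    "model_fit_error",
    "pattern_frequency_table",
    "dstat_results_table",
]

CONFIGS = ("ABBA", "BABA", "BBAA")


@dataclass(frozen=True)
class QuartetSpec:
    """Ordered quartet (P1, P2, P3, outgroup) of distinct sample names."""

    p1: str
    p2: str
    p3: str
    outgroup: str

    def __post_init__(self):
        if len({self.p1, self.p2, self.p3, self.outgroup}) != 4:
            raise ShapeError("quartet samples must be four distinct names")

    @property
    def names(self) -> tuple[str, str, str, str]:
        return (self.p1, self.p2, self.p3, self.outgroup)

    def __str__(self) -> str:  # row key in result tables
        return f"({self.p1},{self.p2};{self.p3}|{self.outgroup})"


@dataclass
class SitePatternTable:
    """ABBA/BABA/BBAA tallies with per-block partials for the jackknife.

    ``n_*`` are strict presence counts; ``w_*`` frequency-weighted counts
    (equal to the strict counts when no weighted tally was computed, so
    hand-built tables behave the same in both modes).  ``block_*`` arrays
    hold per-block (ABBA, BABA) partial sums.
    """

    quartet: QuartetSpec | None
    n_abba: float
    n_baba: float
    n_bbaa: float
    w_abba: float = None  # type: ignore[assignment]
    w_baba: float = None  # type: ignore[assignment]
    block_counts: np.ndarray = None  # type: ignore[assignment]  # (B, 2) strict
    block_weights: np.ndarray = None  # type: ignore[assignment]  # (B, 2) weighted
    n_sites_excluded: int = 0

    def __post_init__(self):
        if self.w_abba is None:
            self.w_abba = float(self.n_abba)
        if self.w_baba is None:
            self.w_baba = float(self.n_baba)
        if self.block_counts is None:
            self.block_counts = np.array([[self.n_abba, self.n_baba]], dtype=float)
        if self.block_weights is None:
            self.block_weights = np.array([[self.w_abba, self.w_baba]], dtype=float)

    @property
    def n_qualifying(self) -> float:
        return self.n_abba + self.n_baba + self.n_bbaa

    @property
    def frequencies(self) -> dict[str, float]:
        """Strict configuration frequencies conditional on qualifying sites."""
        total = self.n_qualifying
        if total == 0:
            return {c: 0.0 for c in CONFIGS}
        return {
            "ABBA": self.n_abba / total,
            "BABA": self.n_baba / total,
            "BBAA": self.n_bbaa / total,
        }


def presence_partition(genotypes) -> str:
    """Classify one site's quartet genotypes as ABBA/BABA/BBAA/other.

    ``genotypes`` holds derived-allele counts (0/1/2) for (P1, P2, P3, O).
    An allele is present in an individual iff it carries >= 1 copy; a
    label is assigned only when the presence pattern splits the quartet
    2/2 with no individual carrying both alleles.
    """
    g = np.asarray(genotypes)
    if g.shape != (4,):
        raise ShapeError("expected genotypes for exactly four individuals")
    if np.any(g == 1) or np.any(g < 0):
        return "other"  # heterozygote carries both alleles; missing excluded
    d = g == 2
    if d.sum() != 2:
        return "other"
    if d[0] == d[3]:
        return "ABBA"
    if d[1] == d[3]:
        return "BABA"
    return "BBAA"


def _classify_strict(g: np.ndarray) -> np.ndarray:
    """Vectorized strict classification; codes 0=other, 1=ABBA, 2=BABA, 3=BBAA."""
    hom = (g == 0) | (g == 2)
    valid = hom.all(axis=1) & ((g == 2).sum(axis=1) == 2)
    d = g == 2
    code = np.zeros(len(g), dtype=np.int8)
    abba = valid & (d[:, 0] == d[:, 3])
    baba = valid & ~abba & (d[:, 1] == d[:, 3])
    bbaa = valid & ~abba & ~baba
    code[abba], code[baba], code[bbaa] = 1, 2, 3
    return code


def _weights(g: np.ndarray) -> np.ndarray:
    """Frequency-weighted (ABBA, BABA) contributions per site.

    Derived-allele frequencies per individual are p = g/2; both allele
    polarities contribute, so the weights are polarity-symmetric.
    """
    p = g / 2.0
    q = 1.0 - p
    abba = q[:, 0] * p[:, 1] * p[:, 2] * q[:, 3] + p[:, 0] * q[:, 1] * q[:, 2] * p[:, 3]
    baba = p[:, 0] * q[:, 1] * p[:, 2] * q[:, 3] + q[:, 0] * p[:, 1] * q[:, 2] * p[:, 3]
    return np.column_stack([abba, baba])


def count_patterns(
    quartet: QuartetSpec, data: LocusSet, block_loci: int = 200
) -> SitePatternTable:
    """Tally site patterns for a quartet across all loci.

    Sites with a missing genotype in any quartet member are excluded for
    this quartet only.  Jackknife blocks are contiguous runs of
    ``block_loci`` whole loci.
    """
    cols = [data.sample_index(n) for n in quartet.names]
    locus_idx, g_all = data.stacked()
    g = g_all[:, cols].astype(np.int16)
    keep = (g >= 0).all(axis=1)
    n_excluded = int((~keep).sum())
    g = g[keep]
    locus_idx = locus_idx[keep]

    code = _classify_strict(g)
    w = _weights(g)

    n_blocks = max(1, -(-data.n_loci // block_loci))
    block_of_site = locus_idx // block_loci
    block_counts = np.zeros((n_blocks, 2))
    block_weights = np.zeros((n_blocks, 2))
    for j, c in enumerate((1, 2)):
        block_counts[:, j] = np.bincount(
            block_of_site, weights=(code == c).astype(float), minlength=n_blocks
        )
    block_weights[:, 0] = np.bincount(block_of_site, weights=w[:, 0], minlength=n_blocks)
    block_weights[:, 1] = np.bincount(block_of_site, weights=w[:, 1], minlength=n_blocks)

    return SitePatternTable(
        quartet=quartet,
        n_abba=float((code == 1).sum()),
        n_baba=float((code == 2).sum()),
        n_bbaa=float((code == 3).sum()),
        w_abba=float(w[:, 0].sum()),
        w_baba=float(w[:, 1].sum()),
        block_counts=block_counts,
        block_weights=block_weights,
        n_sites_excluded=n_excluded,
    )


def _mode_totals(table: SitePatternTable, mode: str) -> tuple[float, float, np.ndarray]:
    if mode == "strict":
        return table.n_abba, table.n_baba, table.block_counts
    if mode == "weighted":
        return table.w_abba, table.w_baba, table.block_weights
    raise ShapeError(f"unknown counting mode {mode!r}")


def d_statistic(table: SitePatternTable, mode: str = "weighted") -> float:
    """D = (nABBA - nBABA) / (nABBA + nBABA), in [-1, 1]."""
    abba, baba, _ = _mode_totals(table, mode)
    denom = abba + baba
    if denom == 0:
        raise UndefinedStatisticError("no ABBA or BABA sites; D is undefined")
    return (abba - baba) / denom


@dataclass(frozen=True)
class JackknifeResult:
    d: float
    se: float
    z: float
    n_blocks: int

    @property
    def significant(self) -> bool:
        return abs(self.z) >= 3.0


def jackknife_z(
    table: SitePatternTable, mode: str = "weighted", min_blocks: int = 20
) -> JackknifeResult:
    """Delete-one-block jackknife Z score for D.

    Blocks with no ABBA/BABA signal are dropped; at least ``min_blocks``
    non-empty blocks are required.  SE = 0 (identical leave-one-out
    values) raises :class:`UndefinedStatisticError`.
    """
    abba, baba, blocks = _mode_totals(table, mode)
    nonempty = blocks[blocks.sum(axis=1) > 0]
    n = len(nonempty)
    if n < min_blocks:
        raise InsufficientBlocksError(
            f"{n} non-empty blocks < required {min_blocks}"
        )
    d_full = d_statistic(table, mode)
    rest = np.array([abba, baba]) - nonempty  # (B, 2) leave-one-out totals
    d_j = (rest[:, 0] - rest[:, 1]) / (rest[:, 0] + rest[:, 1])
    se = float(np.sqrt((n - 1) / n * ((d_j - d_j.mean()) ** 2).sum()))
    if se == 0:
        raise UndefinedStatisticError("jackknife variance is zero; Z undefined")
    return JackknifeResult(d=d_full, se=se, z=d_full / se, n_blocks=n)


def enumerate_quartets(
    ingroup: list[str],
    outgroup: str,
    mode: str = "all",
    labels: dict[str, str] | None = None,
) -> list[QuartetSpec]:
    """Enumerate quartets over an ingroup with a fixed outgroup.

    ``mode='all'``: every 3-subset of the ingroup, in deterministic
    (input) order — C(n, 3) quartets.  ``mode='dog_wolf_test'``: only
    quartets where P3 is a dog and (P1, P2) are wolves, or vice versa;
    requires ``labels`` mapping each ingroup name to 'dog' or 'wolf'.
    """
    if len(ingroup) < 3:
        raise ShapeError("need at least 3 ingroup samples")
    if mode == "all":
        return [
            QuartetSpec(a, b, c, outgroup)
            for a, b, c in itertools.combinations(ingroup, 3)
        ]
    if mode == "dog_wolf_test":
        if labels is None or any(s not in labels for s in ingroup):
            raise LabelingError("dog_wolf_test mode requires dog/wolf labels "
                                "for every ingroup sample")
        dogs = [s for s in ingroup if labels[s] == "dog"]
        wolves = [s for s in ingroup if labels[s] == "wolf"]
        quartets = []
        for p3 in dogs:
            for p1, p2 in itertools.combinations(wolves, 2):
                quartets.append(QuartetSpec(p1, p2, p3, outgroup))
        for p3 in wolves:
            for p1, p2 in itertools.combinations(dogs, 2):
                quartets.append(QuartetSpec(p1, p2, p3, outgroup))
        return quartets
    raise ShapeError(f"unknown mode {mode!r}")


def pattern_frequency_table(
    data: LocusSet,
    quartets: list[QuartetSpec],
    block_loci: int = 200,
) -> pd.DataFrame:
    """Strict configuration frequencies per quartet (rows) x config (cols)."""
    rows = {}
    for q in quartets:
        table = count_patterns(q, data, block_loci=block_loci)
        rows[str(q)] = table.frequencies
    return pd.DataFrame.from_dict(rows, orient="index")[list(CONFIGS)]


def model_fit_error(
    observed: pd.DataFrame,
    simulated: pd.DataFrame,
    flag_threshold: float = 0.015,
) -> tuple[float, list[tuple[str, str]]]:
    """Absolute-error fit score between two configuration-frequency tables.

    score = sum over quartets and configurations of |f_sim - f_obs|
    (raw sum, no per-quartet normalization).  Cells whose absolute
    difference exceeds ``flag_threshold`` (default 1.5%) are flagged.
    """
    if set(observed.index) != set(simulated.index) or set(observed.columns) != set(
        simulated.columns
    ):
        raise ShapeError("observed and simulated tables must share quartets "
                         "and configuration labels")
    sim = simulated.loc[observed.index, observed.columns]
    diff = (sim - observed).abs()
    score = float(diff.to_numpy().sum())
    flags = [
        (str(q), str(c))
        for q in diff.index
        for c in diff.columns
        if diff.loc[q, c] > flag_threshold
    ]
    return score, flags


def dstat_results_table(
    data: LocusSet,
    quartets: list[QuartetSpec],
    block_loci: int = 200,
    mode: str = "weighted",
) -> pd.DataFrame:
    """One row per quartet: counts, frequencies, D, Z and significance."""
    rows = []
    for q in quartets:
        t = count_patterns(q, data, block_loci=block_loci)
        freqs = t.frequencies
        row = {
            "quartet": str(q),
            "n_abba": t.n_abba,
            "n_baba": t.n_baba,
            "n_bbaa": t.n_bbaa,
            "f_abba": freqs["ABBA"],
            "f_baba": freqs["BABA"],
            "f_bbaa": freqs["BBAA"],
        }
        try:
            jk = jackknife_z(t, mode=mode)
            row.update(D=jk.d, Z=jk.z, SE=jk.se, significant=jk.significant)
        except (InsufficientBlocksError, UndefinedStatisticError):
            try:
                row.update(D=d_statistic(t, mode=mode))
            except UndefinedStatisticError:
                row.update(D=np.nan)
            row.update(Z=np.nan, SE=np.nan, significant=False)
        rows.append(row)
    return pd.DataFrame(rows).set_index("quartet")
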