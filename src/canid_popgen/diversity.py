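"""Heterozygosity tracks, dog/wolf site-sharing classes and ROH masking.

Per-site heterozygosity (the fraction of called sites at which a diploid
carries two different alleles) is the classic long-term estimator of
4*Ne*mu.  Windowed tracks support box-plot style summaries and the
detection of runs of homozygosity (ROH) — long stretches of depressed
heterozygosity caused by recent inbreeding, which are masked before
interpreting genome-wide rates as ancestral diversity.

Variant sites segregating among dogs and wolves are classified into
four disjoint, exhaustive categories: shared (segregating in both
groups), private to wolves, private to dogs (segregating in exactly one
group, the other monomorphic), and fixed differences (each group
monomorphic for a different allele).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, UndefinedStatisticError
from .loci import LocusSet

__all__ = [
    "HetTrack",
    "SharingSummary",
    "windowed_heterozygosity",
    "genome_heterozygosity",
    "classify_variant_sites",
    "roh_mask",
]

SHARING_CATEGORIES = ("shared", "private_wolves", "private_dogs", "fixed")


@dataclass
class HetTrack:
    """Windowed heterozygosity for one diploid genome.

    ``windows`` has columns start, end (bp, 0-based half-open), het
    (heterozygous-site count), called (called-site count) and rate
    (het/called, NaN where called == 0).
    """

    sample: str
    windows: pd.DataFrame
    genome_het: int
    genome_called: int

    @property
    def genome_rate(self) -> float:
        if self.genome_called == 0:
            raise UndefinedStatisticError("no called sites")
        return self.genome_het / self.genome_called

    def summary(self, min_called_fraction: float = 0.5) -> pd.Series:
        """Box-plot quartiles over windows with enough called sites.

        Windows with fewer than ``min_called_fraction`` of their span
        called are excluded (edge-window noise guard).
        """
        w = self.windows
        span = w["end"] - w["start"]
        ok = w["called"] >= min_called_fraction * span
        return w.loc[ok, "rate"].describe()


def windowed_heterozygosity(
    data: LocusSet, sample: str, window_size: int = 100_000
) -> HetTrack:
    """Heterozygosity in ``window_size``-bp windows over concatenated loci.

    Loci are laid end to end on a single genome coordinate axis (locus i
    occupies [sum of previous lengths, +length)).  Windows with zero
    called sites get a missing (NaN) rate, not zero.
    """
    col = data.sample_index(sample)
    lengths = np.array([loc.length for loc in data.loci], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    genome_len = int(offsets[-1])
    if genome_len == 0:
        raise InvalidParameterError("empty locus set")
    n_windows = -(-genome_len // window_size)

    het = np.zeros(n_windows, dtype=np.int64)
    called = np.zeros(n_windows, dtype=np.float64)
    for i, loc in enumerate(data.loci):
        g = loc.genotypes[:, col]
        het_pos = offsets[i] + loc.positions[g == 1]
        if len(het_pos):
            het += np.bincount(het_pos // window_size, minlength=n_windows)
        # spread the locus' called sites across the windows it overlaps
        start, end = offsets[i], offsets[i + 1]
        frac = data.called[i, col] / loc.length
        for w in range(start // window_size, (end - 1) // window_size + 1):
            overlap = min(end, (w + 1) * window_size) - max(start, w * window_size)
            called[w] += overlap * frac

    windows = pd.DataFrame(
        {
            "start": np.arange(n_windows) * window_size,
            "end": np.minimum((np.arange(n_windows) + 1) * window_size, genome_len),
            "het": het,
            "called": called,
        }
    )
    windows["rate"] = np.where(
        windows["called"] > 0, windows["het"] / windows["called"], np.nan
    )
    return HetTrack(
        sample=sample,
        windows=windows,
        genome_het=int(het.sum()),
        genome_called=int(round(called.sum())),
    )


def genome_heterozygosity(data: LocusSet, sample: str) -> float:
    """Genome-wide heterozygous fraction for one sample."""
    col = data.sample_index(sample)
    het = sum(int((loc.genotypes[:, col] == 1).sum()) for loc in data.loci)
    called = int(data.called[:, col].sum())
    if called == 0:
        raise UndefinedStatisticError("no called sites")
    return het / called


@dataclass
class SharingSummary:
    """Counts and percentages of dog/wolf variant-sharing categories."""

    counts: dict[str, int]
    n_excluded_missing: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            return {c: 0.0 for c in SHARING_CATEGORIES}
        return {c: 100.0 * self.counts[c] / total for c in SHARING_CATEGORIES}

    def as_dataframe(self) -> pd.DataFrame:
        pct = self.percentages
        return pd.DataFrame(
            {
                "category": list(SHARING_CATEGORIES),
                "count": [self.counts[c] for c in SHARING_CATEGORIES],
                "percent": [pct[c] for c in SHARING_CATEGORIES],
            }
        ).set_index("category")


def classify_variant_sites(
    data: LocusSet, dogs: list[str], wolves: list[str]
) -> SharingSummary:
    """Classify biallelic sites by segregation in the dog and wolf groups.

    Sites with missing genotypes in any group member are excluded (their
    count is reported).  A site monomorphic in both groups for the same
    allele (variant only elsewhere, e.g. in the outgroup) is not counted.
    """
    if not dogs or not wolves:
        raise InvalidParameterError("both groups must be non-empty")
    dog_idx = [data.sample_index(s) for s in dogs]
    wolf_idx = [data.sample_index(s) for s in wolves]
    _, g = data.stacked()
    gd = g[:, dog_idx].astype(np.int16)
    gw = g[:, wolf_idx].astype(np.int16)
    keep = (gd >= 0).all(axis=1) & (gw >= 0).all(axis=1)
    n_excluded = int((~keep).sum())
    gd, gw = gd[keep], gw[keep]

    def _state(gg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(segregating, monomorphic-allele 0/1) per site for one group."""
        tot = gg.sum(axis=1)
        seg = (tot > 0) & (tot < 2 * gg.shape[1])
        mono_allele = (tot == 2 * gg.shape[1]).astype(np.int8)  # valid if not seg
        return seg, mono_allele

    dog_seg, dog_allele = _state(gd)
    wolf_seg, wolf_allele = _state(gw)

    shared = dog_seg & wolf_seg
    private_dogs = dog_seg & ~wolf_seg
    private_wolves = wolf_seg & ~dog_seg
    fixed = ~dog_seg & ~wolf_seg & (dog_allele != wolf_allele)
    counts = {
        "shared": int(shared.sum()),
        "private_dogs": int(private_dogs.sum()),
        "private_wolves": int(private_wolves.sum()),
        "fixed": int(fixed.sum()),
    }
    return SharingSummary(counts=counts, n_excluded_missing=n_excluded)


def roh_mask(
    het_track: HetTrack,
    rate_threshold: float = 0.1,
    min_length: int = 1_000_000,
) -> tuple[list[tuple[int, int]], float]:
    """Mask runs of homozygosity and report the masked-genome rate.

    A ROH is a maximal run of consecutive windows whose rate is below
    ``rate_threshold`` times the genome mean, of total span at least
    ``min_length`` bp.  Returns 0-based half-open intervals plus the
    heterozygosity recomputed outside the mask.  Windows with missing
    rates break runs.
    """
    mean_rate = het_track.genome_rate
    if mean_rate == 0:
        raise UndefinedStatisticError("genome mean heterozygosity is zero")
    w = het_track.windows
    below = (w["rate"] < rate_threshold * mean_rate).fillna(False).to_numpy()

    intervals: list[tuple[int, int]] = []
    run_start = None
    for i, b in enumerate(below):
        if b and run_start is None:
            run_start = i
        elif not b and run_start is not None:
            intervals.append((run_start, i))
            run_start = None
    if run_start is not None:
        intervals.append((run_start, len(below)))

    starts = w["start"].to_numpy()
    ends = w["end"].to_numpy()
    mask = [
        (int(starts[a]), int(ends[b - 1]))
        for a, b in intervals
        if ends[b - 1] - starts[a] >= min_length
    ]
    masked_windows = np.zeros(len(w), dtype=bool)
    for a, b in intervals:
        if ends[b - 1] - starts[a] >= min_length:
            masked_windows[a:b] = True
    kept = ~masked_windows
    called = w["called"].to_numpy()[kept].sum()
    het = w["het"].to_numpy()[kept].sum()
    masked_rate = het / called if called > 0 else float("nan")
    return mask, masked_rate
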