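"""In-memory containers for unlinked neutral loci.

A :class:`LocusSet` holds many independent loci, each a biallelic site
table over the same diploid samples (one diploid per population).
Genotypes are derived-allele counts in {0, 1, 2} with -1 for missing;
derived polarity is known by construction in simulated data and taken
from the ancestral-allele convention (REF = ancestral) when read from
VCF.  Sites within a locus share one genealogy; loci are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SampleLookupError

__all__ = ["Locus", "LocusSet"]


@dataclass
class Locus:
    """One locus: sorted variant positions and a site-by-sample genotype table."""

    id: str
    length: int
    positions: np.ndarray  # (n_sites,) int64, 0-based within the locus
    genotypes: np.ndarray  # (n_sites, n_samples) int8; derived count, -1 missing

    @property
    def n_sites(self) -> int:
        return len(self.positions)


@dataclass
class LocusSet:
    """Unlinked biallelic loci over a fixed diploid sample panel."""

    samples: list[str]
    loci: list[Locus]
    #: called sites per (locus, sample); defaults to the locus length.
    called: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.called is None:
            self.called = np.array(
                [[loc.length] * len(self.samples) for loc in self.loci], dtype=np.int64
            )
        else:
            self.called = np.asarray(self.called, dtype=np.int64)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return sum(loc.n_sites for loc in self.loci)

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise SampleLookupError(f"sample {name!r} not in {self.samples}") from None

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """All sites stacked: (locus index per site, genotype matrix).

        Returns ``(locus_idx, G)`` with ``locus_idx`` of shape (n_sites,)
        and ``G`` of shape (n_sites, n_samples).
        """
        if not self.loci:
            return (np.empty(0, dtype=np.int64), np.empty((0, self.n_samples), np.int8))
        locus_idx = np.concatenate(
            [np.full(loc.n_sites, i, dtype=np.int64) for i, loc in enumerate(self.loci)]
        )
        g = np.concatenate([loc.genotypes for loc in self.loci], axis=0)
        return locus_idx, g

    def subset_samples(self, names: list[str]) -> "LocusSet":
        idx = [self.sample_index(n) for n in names]
        loci = [
            Locus(loc.id, loc.length, loc.positions, loc.genotypes[:, idx])
            for loc in self.loci
        ]
        return LocusSet(list(names), loci, self.called[:, idx])
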