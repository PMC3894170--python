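import numpy as np
import pytest

from canid_popgen import bundled_model, simulate_dataset
from canid_popgen.loci import Locus, LocusSet

DOGS = ["BOX", "BSJ", "DNG"]
WOLVES = ["CRW", "CHW", "ISW"]
OUTGROUP = "GLJ"


@pytest.fixture(scope="session")
def fig5a():
    return bundled_model("fig5a")


@pytest.fixture(scope="session")
def fig5a_nomig(fig5a):
    return fig5a.without_migration()


@pytest.fixture(scope="session")
def fig5a_dataset(fig5a_nomig):
    """A moderately sized no-migration dataset over all seven genomes."""
    return simulate_dataset(fig5a_nomig, n_loci=4000, locus_length=1000, seed=42)


def make_locus_set(genotype_rows, samples, length=1000, locus_of_site=None):
    """Build a LocusSet from a list of per-site genotype tuples.

    ``locus_of_site`` assigns sites to loci (default: all in one locus).
    """
    g = np.asarray(genotype_rows, dtype=np.int8)
    if locus_of_site is None:
        locus_of_site = [0] * len(g)
    locus_of_site = np.asarray(locus_of_site)
    loci = []
    for lid in range(locus_of_site.max() + 1):
        rows = g[locus_of_site == lid]
        positions = np.arange(len(rows), dtype=np.int64)
        loci.append(Locus(f"locus_{lid}", length, positions, rows))
    return LocusSet(list(samples), loci)
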