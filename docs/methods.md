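# Methods

## Demographic model representation

A model is a rooted population tree. Each population occupies a time
interval `[start, end)` in generations before present (leaves start at
0; an internal population starts at the split where its children merge
into it, looking backwards) and carries one diploid effective size —
a constant, or a piecewise-constant trajectory on a single branch.
Internal populations may have one child (a pure size-change event) or
two (a divergence). Split times must strictly increase rootward.

Migration bands are directed forward-in-time channels `source →
target`. Each carries a *total* rate `m_tot`, interpreted as the
expected number of migration events per lineage over the interval in
which both populations coexist, so the per-generation per-lineage rate
is `m = m_tot / duration` and the probability that a lineage migrates
at least once is `1 − exp(−m_tot)`. This is the standard coalescent
convention; where a source reports only a total rate, this is the
reading we adopt. Backwards in time a lineage currently in `target`
jumps into `source` — the simulator reverses bands internally.

Model files store times in years and sizes in individuals; everything
internal is generations, converted once at the I/O boundary through the
generation time (default 3 years). Reporting conventions: times to
0.1 ky, fold changes to one decimal, rates to two significant figures.

### The bundled `fig5a` model and its placeholders

Split times (12.1/12.8/13.3/13.4/14.9/398 kya), ancestral sizes
(45,000 / 12,600 / 2,000) and the calibration constants are
inference-backed. Four quantities are visible only in a figure and are
therefore *placeholders*, marked as user-settable in the file:

* terminal-branch Ne — wolves 10,000 each (low end of the recent
  single-genome estimates, 10,000–17,000), Basenji 1,800 and Dingo 900
  (recent single-genome estimates: 1,640–1,980 and 704–1,042), Boxer
  1,500 (a breed of comparable recent size), jackal 20,000;
* the wolf-internal split order and its 13.3 kya time (the two wolf
  divergences cluster tightly at ~13.4 kya; a 100-year offset imposes
  the strict ordering the tree structure requires);
* band total rates (0.03–0.05), consistent with "nearly all total
  rates below 10%";
* the `regional` and `isw_source` alternative topologies carry the few
  published band rates (e.g. Basenji→Boxer m_tot = 1.24) and
  placeholder times documented in the files.

These values were fixed when the models were written and are treated as
the study conditions; they are not tuning knobs.

## Simulator

Exact continuous-time structured coalescent: within each epoch
(delimited by splits, Ne breakpoints and band endpoints) total event
rates are constant — coalescence at `k(k−1)/2 · 1/(2Ne)` per
population, migration at `k·m` per active band — so waiting times are
exponential; crossing an epoch boundary re-merges lineage sets and
refreshes rates. No discrete generations, no intra-locus recombination,
no selection, no sequencing error. Mutations are Poisson with rate
`μ·L·total_branch_length` under infinite sites within each locus
(an error is raised if the expectation exceeds the locus length).
CpG heterogeneity is not simulated; it enters only as the rate
correction in the calibration layer, mirroring the upstream filtering
of CpG sites.

Determinism contract: locus `i` uses the RNG stream seeded by
`(seed, i)`, so any subset of loci reproduces exactly regardless of how
a run is partitioned. The same seed gives byte-identical output files.

What the generator emulates: genotype matrices at many unlinked 1-kb
neutral loci, one diploid per population, with known ancestral/derived
polarity and complete calling. What it does not emulate: genotyping
error, missing data patterns, linkage between loci, recombination
within loci, reference bias, or CpG mutation-rate heterogeneity.
Passing tests therefore validate the statistical machinery and the
model's internal consistency — not robustness to the artefacts of real
sequencing pipelines.

## Statistics

**Site patterns.** A site qualifies for a quartet (P1,P2,P3,O) in
strict mode when all four individuals are homozygous and each allele is
carried by exactly two of them; the label records who shares with the
outgroup (BBAA: P1,P2 vs P3,O; ABBA: P2,P3 vs P1,O; BABA: P1,P3 vs
P2,O). Frequency-weighted mode uses per-individual derived-allele
frequencies in {0, ½, 1} with both polarities contributing, so
heterozygous sites inform instead of being discarded. Strict mode is
the default for configuration frequencies (it matches the definition of
the published frequency tables); weighted mode is the default for D
and its jackknife. The model-fit score is the raw sum of
|f_sim − f_obs| over quartets and configurations; a per-quartet
normalization would rescale but not reorder the three bundled models,
and the 1.5% flag threshold applies per cell.

**Jackknife.** Delete-one-block over contiguous runs of whole loci
(default 200 loci per block; for real coordinates 5-Mb windows are the
analogous choice). At least 20 non-empty blocks are required; zero
jackknife variance raises rather than reporting an infinite Z.

**Divergence.** Two per-site estimators: *conservative* (a site counts
1 only if the two genotypes share no allele) and *all-mismatches* (mean
of the four inter-allele comparisons, expectation 2μE[T2]). Distances
are (Σ mismatches)/(Σ called sites), never means of window ratios.
A known limitation, discovered while validating tree recovery: the
conservative estimator's expectation depends on each individual's
heterozygosity (a high-het individual is rarely opposite-homozygous),
which shortens outgroup distances to high-diversity lineages by an
amount (~5×10⁻⁴ here) that dwarfs the short wolf-clade internal edge
(~2×10⁻⁵). Under this model the conservative NJ tree therefore places
the jackal inside the wolf clade at any data scale, while the
all-mismatches estimator, being linear in coalescence time, recovers
the generating topology. Trees intended for topology inference should
use `mode="allpairs"`; the conservative mode is retained for
robustness comparisons.

**Bootstrap.** One window sequence per replicate (genome-global
resampling), drawing windows with replacement until the resampled
called-site total reaches the original, then rebuilding the matrix from
pooled window partials and rerunning NJ. Support is the percentage of
replicates containing each original internal bipartition. NJ itself is
scikit-bio's canonical implementation; negative branch lengths are
clamped to zero and flagged.

**Sharing classes.** "Private" means segregating in exactly one group
with the other group monomorphic; "fixed" requires opposite
monomorphism. These four categories are disjoint and exhaustive over
sites variant within the two groups; sites variant only in the
outgroup are not counted.

**ROH masking.** Maximal runs of consecutive windows with rate below
0.1× the genome mean and span ≥ 1 Mb. Both parameters are defaults
surfaced in the API, chosen as conventional values; windows with no
called sites break runs rather than extending them.

**Copy number.** Per-base copy = 2 × (1-kb sliding-mean smoothed
depth) / (mean depth of known-diploid control regions); discrete calls
round half-up, fractional means are first-class. No GC correction.
qPCR copies = calibrator × efficiency^(−ΔΔCt), efficiency in (1, 2],
defaults 2 and a diploid calibrator — standard ΔΔCt assumptions.

## Numerical and design choices

* Coordinates: VCF 1-based; BED half-open 0-based; internal 0-based.
  Conversion only at file boundaries, covered by round-trip tests.
* NJ determinism: fixed input order plus scikit-bio's deterministic
  agglomeration; exact ties reproduce across runs.
* Bipartitions are canonicalized as the leaf set on the side away from
  a fixed reference taxon (the alphabetically first sample).
* Negative moment estimates of split times clamp to zero with a flag.
* The calibration layer validates μ > 0, g > 0, 0 ≤ CpG fraction < 1,
  ordered intervals; degenerate inputs raise typed errors rather than
  returning NaN.

## Problem sizes used by the distributional tests

Chosen to keep the whole suite in a few minutes on one core while
leaving each check's acceptance band at its stated value: closed-form
simulator checks at 10,000–20,000 replicates/loci (3-SE bands);
D-statistic null calibration at 12 replicate datasets × 18 dog-wolf
quartets × 4,000 loci (≥95% of tests with |Z| < 3); clade-support
bootstrap at 250,000 loci in 500 windows of 500 loci — the 500-kb
window analogue — with 100 replicates (dog and wolf clade edges at
100%); model-fit ranking with 4,000 observed and 3,000 simulated loci
per model; split-time recovery over 30 replicate datasets of 500 loci
(within 10%); CNV call recovery at 100 seeded replicates per true copy
number (≥99% correct). The wolf heterozygosity check simulates one
diploid wolf at 20,000 × 1-kb loci and asserts the genome rate falls in
the observed wolf range 1.2–1.6×10⁻³.

## Known limitations

* The simulator is quadratic-free but single-threaded Python; hundreds
  of thousands of loci take a couple of minutes.
* The exact published forms of the conservative/all-mismatches
  divergence estimators, the ROH rule and the model-fit normalization
  live in supplements unavailable here; the implementations follow the
  printed verbal definitions, and where a choice was open it is
  documented above.
* Real-data ingestion is limited to biallelic-SNV VCFs and BED tracks;
  there is no alignment, genotyping, or duplication-discovery stage.
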