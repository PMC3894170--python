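# Single-wolf-source alternative model: the dog clade diverges most
# recently from the Israeli wolf lineage, shortly (<200 y) after the wolf
# populations diverged from each other, producing a star-like wolf/dog
# divergence.  Dog-internal structure matches fig5a (12.8 / 12.1 kya).
#
# PLACEHOLDERS (figure-only): terminal Ne as in fig5a; dog-from-ISW split
# at 13.25 kya (between the wolf splits and within 200 y of them); branch
# Ne for the ISW+dog ancestor 12,600.
name: isw_source
generation_time: 3.0
mutation_rate: 1.0e-8
populations:
  - {name: BOX, parent: ancBB, ne: 1500}
  - {name: BSJ, parent: ancBB, ne: 1800}
  - {name: ancBB, parent: ancDOG, ne: 2000, split_years: 12100}
  - {name: DNG, parent: ancDOG, ne: 900}
  - {name: ancDOG, parent: ISWDOG, ne: 2000, split_years: 12800}
  - {name: ISW, parent: ISWDOG, ne: 10000}
  - {name: ISWDOG, parent: ancWLF1, ne: 12600, split_years: 13250}
  - {name: CHW, parent: ancWLF1, ne: 10000}
  - {name: ancWLF1, parent: ancWLF, ne: 12600, split_years: 13300}
  - {name: CRW, parent: ancWLF, ne: 10000}
  - {name: ancWLF, parent: ancDW, ne: 12600, split_years: 13400}
  - {name: ancDW, parent: root, ne: 45000, split_years: 14900}
  - {name: GLJ, parent: root, ne: 20000}
  - {name: root, parent: null, ne: 45000, split_years: 398000}
migration_bands: []
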