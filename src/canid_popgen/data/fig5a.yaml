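# Dog/wolf reciprocal-monophyly demographic model: dogs (Boxer BOX,
# Basenji BSJ, Dingo DNG) and wolves (Israeli ISW, Croatian CRW, Chinese
# CHW) as sister monophyletic clades, golden jackal GLJ outgroup.
#
# Printed, inference-backed values: split times 12.1 / 12.8 / 13.4 / 14.9 /
# 398 kya; ancestral Ne 45,000 (dog+wolf ancestor), 2,000 (dog ancestor),
# 12,600 (wolf ancestor); generation time 3 y; filtered-site mutation rate
# 1e-8 per generation.
#
# PLACEHOLDERS (figure-only, user-settable): terminal-branch Ne values are
# not printed; defaults follow single-genome PSMC-style recent estimates
# (wolves 10,000 each; Basenji 1,800; Dingo 900; Boxer 1,500; jackal
# 20,000).  The wolf-internal split (ancWLF1, 13.3 kya) orders the two
# tightly clustered wolf divergences (~13.4 kya).  Band m_tot values are
# figure-only; defaults are small (total rates below 10%) and user-settable.
name: fig5a
generation_time: 3.0
mutation_rate: 1.0e-8
populations:
  - {name: BOX, parent: ancBB, ne: 1500}
  - {name: BSJ, parent: ancBB, ne: 1800}
  - {name: ancBB, parent: ancDOG, ne: 2000, split_years: 12100}
  - {name: DNG, parent: ancDOG, ne: 900}
  - {name: ancDOG, parent: ancDW, ne: 2000, split_years: 12800}
  - {name: ISW, parent: ancWLF1, ne: 10000}
  - {name: CHW, parent: ancWLF1, ne: 10000}
  - {name: ancWLF1, parent: ancWLF, ne: 12600, split_years: 13300}
  - {name: CRW, parent: ancWLF, ne: 10000}
  - {name: ancWLF, parent: ancDW, ne: 12600, split_years: 13400}
  - {name: ancDW, parent: root, ne: 45000, split_years: 14900}
  - {name: GLJ, parent: root, ne: 20000}
  - {name: root, parent: null, ne: 45000, split_years: 398000}
migration_bands:
  - {source: ISW, target: BSJ, m_tot: 0.05}
  - {source: BSJ, target: ISW, m_tot: 0.05}
  - {source: CHW, target: DNG, m_tot: 0.03}
  - {source: DNG, target: CHW, m_tot: 0.04}
  - {source: GLJ, target: ISW, m_tot: 0.05}
  - {source: ISW, target: GLJ, m_tot: 0.05}
  - {source: GLJ, target: ancDW, m_tot: 0.05}
  - {source: ancDW, target: GLJ, m_tot: 0.05}
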