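# Regional-domestication alternative model: each dog lineage originates
# from the wolf of its own geographic region (Boxer from Croatian wolf,
# Basenji from Israeli wolf, Dingo from Chinese wolf), so there is no dog
# clade.  Regional ancestors: EUR (BOX+CRW), MEA (BSJ+ISW), EAS (DNG+CHW),
# with topology (EUR, (MEA, EAS)).
#
# Printed values: ingroup root Ne 45,000 at 14.9 kya; jackal split 398 kya;
# migration bands between dog lineages and between wolf lineages carry the
# printed posterior-mean total rates (Basenji->Boxer 1.24, Basenji->Dingo
# 0.47, Croatian->Israeli 0.33, Croatian->Chinese 0.33).
# PLACEHOLDERS (figure-only): terminal Ne as in fig5a; pairwise dog-wolf
# split times (12 kya) and regional-ancestor merge times (13.4 kya MEA+EAS);
# regional-ancestor Ne 12,600.
name: regional
generation_time: 3.0
mutation_rate: 1.0e-8
populations:
  - {name: BOX, parent: EUR, ne: 1500}
  - {name: CRW, parent: EUR, ne: 10000}
  - {name: EUR, parent: ancDW, ne: 12600, split_years: 12000}
  - {name: BSJ, parent: MEA, ne: 1800}
  - {name: ISW, parent: MEA, ne: 10000}
  - {name: MEA, parent: MEAEAS, ne: 12600, split_years: 12100}
  - {name: DNG, parent: EAS, ne: 900}
  - {name: CHW, parent: EAS, ne: 10000}
  - {name: EAS, parent: MEAEAS, ne: 12600, split_years: 12200}
  - {name: MEAEAS, parent: ancDW, ne: 12600, split_years: 13400}
  - {name: ancDW, parent: root, ne: 45000, split_years: 14900}
  - {name: GLJ, parent: root, ne: 20000}
  - {name: root, parent: null, ne: 45000, split_years: 398000}
migration_bands:
  - {source: BSJ, target: BOX, m_tot: 1.24}
  - {source: BSJ, target: DNG, m_tot: 0.47}
  - {source: CRW, target: ISW, m_tot: 0.33}
  - {source: CRW, target: CHW, m_tot: 0.33}
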