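"""Segregation of the SAG stop-loss genotype in the 80-dog Basenji survey.

Cross-tabulates the published genotype survey (wild-type T vs mutant C)
against ophthalmoscopic phenotype, collapses to the recessive-model 2x2
(affected/normal x homozygous-mutant/other) and tests it with a
two-sided Fisher exact test.  Discordant dogs are enumerated: the two
affected dogs without the mutant genotype (phenocopies — likely a second
PRA locus or misdiagnosis) and the one normal homozygote (non-penetrant
at 6.4 years, an age where onset may simply not have occurred yet).
"""

from rohmap.survey import basenji_sag_survey, segregation_report

table = basenji_sag_survey()
print("phenotype x genotype counts (hom_ref / het / hom_alt):")
print(table.counts.to_string())

rep = segregation_report(table)
a, b, c, d = rep.table2x2
print(f"\nrecessive-model 2x2: affected {a}/{b}, normal {c}/{d}")
print(f"Fisher two-sided p = {rep.fisher_p:.3g}")
print(f"odds ratio = {rep.odds_ratio:.1f}"
      + (" (Haldane-corrected)" if rep.haldane_corrected else ""))
print(f"phenocopies (affected, not hom_alt): {len(rep.phenocopies)}")
print(f"non-penetrant carriers (normal, hom_alt): {len(rep.non_penetrant)}")
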