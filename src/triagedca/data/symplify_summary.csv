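# Published diagnostic-accuracy summary for the SYMPLIFY study
# (ISRCTN10226380): prospective UK cohort of symptomatic adults referred from
# primary care for urgent suspected-cancer investigation, tested with the
# Galleri multicancer detection assay (GRAIL, LLC).  Each value below is a
# number printed in the study's public reports; every unprinted quantity is
# left blank (unavailable) rather than imputed.
#
# overall row provenance:
#   n_total 5461        — participants reaching diagnostic resolution at 9 months
#   prevalence 6.7      — % with a confirmed cancer diagnosis
#   sensitivity 66.3    — % of cancers with a positive cancer-signal call
#   specificity 98.4    — % of non-cancers with a negative call
# lung row provenance:
#   prevalence 29.8     — highest pathway prevalence
#   sensitivity 70.8
# gynecologic row provenance:
#   prevalence 3.7      — lowest pathway prevalence
#   sensitivity 49.1    — lowest pathway sensitivity
# upper_gi row provenance:
#   sensitivity 80.4    — highest pathway sensitivity
# Pathway-level N, D, P, PPV and NPV were not printed; pathway specificities
# were reported only as "above 96%" and are therefore left blank.
# All proportions below are percentages.
pathway,n_total,n_cancer,prevalence,n_positive,sensitivity,specificity,ppv,npv
overall,5461,,6.7,,66.3,98.4,,
lung,,,29.8,,70.8,,,
gynecologic,,,3.7,,49.1,,,
upper_gi,,,,,80.4,,,
lower_gi,,,,,,,,
rdc,,,,,,,,
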