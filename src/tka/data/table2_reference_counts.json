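{
  "_comment": "Curated headline totals recorded alongside this cohort fixture (n=103, 73 altered + 30 alteration-free patients). The assessment report recomputes each quantity from the per-patient rows and flags any that disagree; three recorded totals are known to be internally inconsistent with the row-level listing (patients_with_mutation, patients_any_extended, genes_with_putative_oncogenic).",
  "n_patients": 103,
  "n_patients_with_rnaseq": 71,
  "patients_any_full": 73,
  "patients_any_achievable": 48,
  "patients_any_extended": 49,
  "patients_putative_full": 34,
  "patients_putative_achievable": 26,
  "patients_putative_extended": 30,
  "patients_with_mutation": 56,
  "patients_with_amplification": 17,
  "patients_with_overexpression": 17,
  "patients_with_fusion": 1,
  "genes_with_any_alteration": 40,
  "genes_with_putative_oncogenic": 22,
  "genes_with_amplification": 15,
  "oncogenic_mutations": 5
}
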