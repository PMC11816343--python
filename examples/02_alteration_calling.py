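"""Call alterations from tiny hand-made molecular tables.

Shows each calling rule in isolation: the strict copy-number > 5
amplification surrogate, the Q3 + 1.5×IQR overexpression fence, the
impact/oncogenicity mutation screen, and fusion attribution to catalog
partners.
"""

import numpy as np

import tka

catalog = tka.load_packaged_catalog()
sets = catalog.gene_sets()

# Amplification: strictly greater than 5 copies counts.
cnvs = [
    tka.CnvRecord("P1", "PDGFRA", 6.2),
    tka.CnvRecord("P2", "PDGFRA", 5.0),  # boundary: not amplified
    tka.CnvRecord("P3", "KIT", 2.1),
]
for ev in tka.call_amplifications(cnvs):
    print(f"amplification: {ev.patient_id} {ev.gene} ({ev.detail})")

# Overexpression: one extreme log2CPM value among five samples.
expr = tka.ExpressionMatrix.from_arrays(
    ["FRK"], ["P1", "P2", "P3", "P4", "P5"],
    np.array([[1.0, 2.0, 3.0, 4.0, 100.0]]),
)
for ev in tka.call_overexpression(expr):
    print(f"overexpression: {ev.patient_id} {ev.gene} ({ev.detail})")
# With Q1=2 and Q3=4 the fence is 4 + 1.5*2 = 7, so only the 100 is called.

# Mutation screening: benign dropped, VUS kept but not oncogenic.
muts = [
    tka.MutationRecord("P1", "BRAF", "MODERATE", "oncogenic", "p.V600E"),
    tka.MutationRecord("P1", "KDR", "MODERATE", "vus"),
    tka.MutationRecord("P2", "DDR1", "HIGH", "benign"),
]
for ev in tka.screen_mutations(muts):
    print(f"mutation: {ev.patient_id} {ev.gene} oncogenic={ev.oncogenic}")

# Fusions: credited to the catalog partner(s) only.
fusions = [tka.FusionRecord("P3", "ABL1", "SZRD1", "ABL1::SZRD1")]
for ev in tka.collect_fusions(fusions, sets):
    print(f"fusion: {ev.patient_id} {ev.gene} ({ev.detail})")
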