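"""Load the packaged drug-target catalog and inspect its nested gene sets.

The catalog lists 46 protein-kinase genes with preclinical evidence of
regorafenib inhibition; 18 are inhibited at clinically achievable drug
concentrations and 19 act in angiogenesis pathways. The 23-gene set is the
18 plus the 5 angiogenesis genes outside them.
"""

import tka

catalog = tka.load_packaged_catalog()
sets = catalog.gene_sets()

print(f"catalog genes:            {len(catalog)}")
print(f"clinically achievable:    {len(sets.achievable_set)}")
print(f"angiogenesis genes:       {len(sets.angiogenesis_set)}")
print(f"extended (18 + 5 angio):  {len(sets.extended_set)}")
print(f"achievable ∩ angiogenesis: {len(sets.achievable_set & sets.angiogenesis_set)}")
print(f"the extra five: {sorted(sets.extended_set - sets.achievable_set)}")

# Symbol normalization: older or alternative kinase names resolve to HUGO.
for alias in ("VEGFR2", "TIE2", "CSFR1"):
    print(f"alias {alias!r} -> {catalog.normalize(alias)}")

# Affinity-based inhibition calls at the 100 nM threshold.
for symbol in ("FGFR1", "TEK", "SLK"):
    gene = catalog[symbol]
    status = tka.classify_inhibition_status(gene)
    print(f"{symbol}: min affinity {gene.min_affinity()} nM -> {status}")
# FGFR1 (202 nM) and TEK (311 nM) sit above the threshold, so on affinity
# evidence alone they are not inhibited; most genes lack numbers entirely.
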