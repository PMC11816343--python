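# Methods

## Problem and model

Given a cohort of tumors with processed molecular tables and a drug-target
catalog, the package answers one question per patient and gene set: does
this tumor carry at least one alteration — and at least one *putative
oncogenic* alteration — in a gene the drug can plausibly inhibit? The
aggregate of those verdicts is the drug's target-presence profile in the
cohort.

The alteration model is deliberately permissive: any of four molecular
mechanisms (mutation, gene amplification, gene overexpression, gene
fusion) is accepted as potential evidence of target relevance, on the
grounds that each can change the abundance or activity of the encoded
kinase. Methylation and histone-level regulation are out of scope. The
"putative oncogenic" restriction then narrows mutations to curated
oncogenic/likely-oncogenic calls while keeping all amplification,
overexpression and fusion events — the asymmetry reflects that the latter
three are intrinsically rare, large-effect findings while most somatic
point mutations are variants of uncertain significance.

## Calling rules and their parameters

| parameter | default | units | role |
|---|---|---|---|
| `amplification_threshold` | 5 | copies | strict lower bound (CN > 5) accepted as an amplification surrogate for gene-level NGS copy-number estimates; fractional values allowed |
| `iqr_multiplier` | 1.5 | — | upper Tukey fence Q3 + k·IQR on log2CPM, per gene across all samples in the matrix |
| `min_samples_for_outlier_test` | 4 | samples | refuse outlier calling below this cohort size (quartiles of fewer points are not meaningful) |
| `inhibition_threshold_nM` | 100 | nM | pooled K_D/IC50 ≤ threshold ⇒ target classified inhibited |

Quantiles use linear interpolation between order statistics (type 7,
numpy's default). No convention is canonical for the fence rule; type 7 is
what most scientific software computes by default, the choice is recorded
in the report's `config` section, and the packaged-cohort results do not
depend on it (the fixture's outliers are far from the fence). The fence is
one-sided by design: only overexpression is treated as drug-relevant.

Affinity evidence pools dissociation constants and half-maximal inhibitory
concentrations into a single nM scale, ignoring their biochemical
difference; the minimum across measurements and compounds (parent drug or
active metabolites) decides the inhibition status. `inhibition_confirmed`
is an independent curated flag — confirmation comes from external assay
review, not from the numeric threshold — which is why FGFR1 (202 nM) can
be simultaneously `not_inhibited` by threshold and curated as confirmed.

Mutation screening assumes input tables are already somatic, annotated
with impact (HIGH/MODERATE retained) and an oncogenicity class from a
ClinGen/CGC/VICC-style classification; the package consumes the class, it
never computes one.

## Gene sets and verdict semantics

The catalog induces four sets: full (46), clinically achievable (18),
angiogenesis (19), and extended (23 = 18 ∪ (19 \ 18)). Verdicts are
set-based per patient: several events in one gene count once for presence.
Gene-level summaries count events per record instead, so two distinct
mutations in one gene contribute 2 to that gene's total but 1 to any
patient verdict. Because the assessment sets nest, verdicts are monotone
in the set — enforced as an invariant and fuzz-tested.

Cohort denominators come from the manifest (every enrolled patient,
including alteration-free ones and those without RNA-seq), not from the
subset with events. Percentages are reported to one decimal with
round-half-away-from-zero; an empty cohort reports percentages as
undefined (`None`), never 0. Acceptance-style checks anchor on integer
counts, since rounded percentages are ambiguous at the 0.1% level
(17/103 is 16.50485…%).

## Packaged cohort fixture

The fixture transcribes a curated 103-patient glioblastoma cohort: 73
per-patient alteration rows (printed as `GENE mut|amp|over` conjunctions
and one `ABL1::SZRD1 fusion`), 30 alteration-free patients, and stored
yes/no target verdicts for all three sets. Patient identifiers (P001…)
are synthetic; the rows carry none, so the mapping is conventional and
affects no aggregate. RNA-seq availability (71/103) is assigned to the 17
patients with printed overexpression events plus the lowest-numbered
remainder. Mutation classes come from printed annotations (`(VUS-NMD)`)
or, failing that, from whether the mutation reappears in the row's
putative-oncogenic column (then `oncogenic`, else `vus`).

Because the rows print event kinds but not the underlying numbers, the
raw mode back-generates numeric tables consistent with the events: copy
number 6 for amplified (patient, gene) pairs and explicit 2.0 background
rows; an expression baseline that is a per-gene random permutation of an
even grid on [4.5, 5.5] log2CPM with planted outliers at 13.0. The grid
guarantees the fence stays in ≈[5.9, 6.1] — strictly above every baseline
value and far below every planted one — so raw-mode calling reproduces the
event-mode verdicts exactly, by construction, for any jitter seed.

Curated headline totals ship alongside the fixture. Three of them are
internally inconsistent with a recount of the per-patient rows (patients
with ≥1 mutation: recorded 56 vs recounted 58; 23-gene-set any-alteration
count: recorded 49 vs 53; genes with ≥1 putative oncogenic alteration:
recorded 22 vs 23). The report recomputes, compares and flags these in
`consistency_flags`; they are deliberately excluded from the reproduced
headline statistics.

## Simulator

The generator emulates the data *shapes* the pipeline consumes, not tumor
biology: independent Bernoulli plantings per gene and patient for
mutations (default p = 0.018), amplifications (0.006) and fusions
(2×10⁻⁴); an oncogenicity-class mixture that is heavily VUS-weighted
(oncogenic + likely oncogenic = 6%) with a small benign mass to exercise
the exclusion path; Gaussian per-gene log2CPM (mean 5, sd 1) with planted
outliers at mean + 8; amplification copy numbers uniform on [6, 20] —
strictly above the calling threshold; fusions pairing a catalog gene with
a synthetic out-of-catalog partner; and an RNA-seq coverage fraction
(default 71/103) selecting which patients get expression columns. Defaults
were set once to reproduce, in expectation, the order of magnitude of the
reference cohort (tens of mutations, a handful of amplifications per
46-gene screen of ~100 patients).

One root seed spawns per-table substreams in a fixed order
(mutation, CNV, expression, fusion, manifest), so extending the generator
with a new table cannot perturb existing draws; identical configs and
seeds are byte-reproducible.

What the simulator does **not** model: inter-gene and inter-modality
correlation, clonal structure, allele fractions, per-gene expression
scale differences, and — most relevantly for testing — the fact that a
Gaussian sample has a nonzero probability (~0.7% per value) of exceeding
its own cohort's Tukey fence. Passing recovery tests therefore show that
the pipeline faithfully recovers what was planted under independence;
they do not validate the calling rules against real tumor data, where
expression is heavy-tailed and alterations co-occur.

That intrinsic false-positive rate also dictates a design choice: the
closed-form expectation 1 − Π(1 − p_g) deliberately ignores fence
false-positives, so the parameter-recovery test runs a WES-only
configuration (RNA-seq coverage 0) where the expectation is exact.
Expression recovery is checked separately: with outliers planted ≥ 6 sd
above baseline at ≤ 5% rate, recall must be ≥ 95% and the false-positive
rate ≤ 1% (consistent with the Gaussian fence-exceedance probability).

## Numerical and degenerate-input choices

* Duplicate CNV records for one (patient, gene) collapse to the maximum
  copy number before thresholding.
* Event unification collapses exact duplicates — same (patient, gene,
  kind, detail) — and sorts rows lexicographically, making every summary
  byte-deterministic under input permutation.
* A constant expression vector has IQR 0 and fence = Q3; no value exceeds
  it, so nothing is called.
* Symbol matching is case-insensitive and whitespace-trimmed, with an
  alias map for legacy kinase names (VEGFR2→KDR, TIE2→TEK, CSFR1→CSF1R,
  …); unknown symbols in mutation/CNV/expression tables are hard errors,
  while unknown fusion partners pass through as labels only.
* Problem sizes in the test suite (cohorts of 50–200 patients, 20 seeds
  for recovery, ≤ 46 genes) keep the whole suite in a few seconds while
  leaving binomial intervals tight enough to detect calling biases of a
  few percent.

## Known limitations

* The CN > 5 amplification surrogate was established for one gene family
  on NGS data and may not transfer to every kinase; there is no
  orthogonal (e.g. FISH) validation path in the package.
* The fence rule conflates biological overexpression with cohort-relative
  extremeness; in small RNA-seq subsets the fence is noisy.
* Affinity pooling across K_D/IC50 and across assay sources is a
  simplification; the catalog format accepts fuller per-compound tables
  for users who have them.
* Pharmacokinetics — most importantly whether the drug reaches the tumor
  compartment at inhibitory concentrations — is explicitly outside the
  model: target presence is a necessary, not sufficient, condition for
  drug benefit.
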