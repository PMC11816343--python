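"""Synthetic tumor-cohort generator with planted, recorded ground truth.

The simulator emulates the statistical shape of the data the pipeline
consumes — a WES cohort (every patient has a mutation/CNV table) of which
a configurable fraction also has RNA-seq — without any read-level realism:

* per gene and patient, independent Bernoulli draws decide whether a
  mutation, an amplification, or a fusion is planted;
* planted mutation oncogenicity classes are sampled from a configurable
  mixture (heavily VUS-weighted by default, matching the observed rarity
  of oncogenic calls: 5 of 87 in the reference cohort shape);
* expression is Gaussian per gene on the log2CPM scale; planted outliers
  sit at baseline mean + ``outlier_shift``;
* planted amplification copy numbers are drawn uniformly on a support
  strictly above the calling threshold;
* fusions pair a catalog gene with a synthetic out-of-catalog partner.

Every planted event is recorded in a :class:`SimulatedTruth`, together
with per-gene-set presence verdicts derived from the plantings by the same
nesting rules the pipeline applies — so recovery is checkable exactly.

One global seed feeds per-table substreams (spawned in a fixed order from
a :class:`numpy.random.SeedSequence`), so adding a table to the generator
does not perturb the draws of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .calling import (
    ONCOGENIC_CLASSES,
    ONCOGENICITY_CLASSES,
    AlterationEvent,
    CnvRecord,
    ExpressionMatrix,
    FusionRecord,
    MutationRecord,
)
from .catalog import GeneSetCatalog, TargetCatalog
from .errors import ValidationError
from .io import ManifestEntry

#: Default oncogenicity-class mixture: overwhelmingly VUS, a sliver of
#: oncogenic/likely-oncogenic, and some benign mass so the exclusion path
#: is exercised.
DEFAULT_ONCOGENICITY_MIXTURE: dict[str, float] = {
    "oncogenic": 0.03,
    "likely_oncogenic": 0.03,
    "vus": 0.78,
    "vus_nmd": 0.06,
    "likely_benign": 0.05,
    "benign": 0.05,
}

#: Mutation impact mixture; inputs are modeled as already impact-screened
#: upstream, so only HIGH/MODERATE appear by default.
DEFAULT_IMPACT_MIXTURE: dict[str, float] = {"HIGH": 0.15, "MODERATE": 0.85}


@dataclass(frozen=True)
class GeneRates:
    """Per-gene, per-patient planting probabilities."""

    p_mutation: float = 0.018
    p_amplification: float = 0.006
    p_fusion: float = 0.0002

    def __post_init__(self) -> None:
        for name in ("p_mutation", "p_amplification", "p_fusion"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class ExpressionModel:
    """Gaussian log2CPM baseline with planted additive outliers."""

    baseline_mean: float = 5.0
    baseline_sd: float = 1.0
    outlier_rate: float = 0.006
    outlier_shift: float = 8.0

    def __post_init__(self) -> None:
        if self.baseline_sd <= 0:
            raise ValidationError("baseline_sd must be positive")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValidationError("outlier_rate must be in [0, 1]")
        if self.outlier_shift <= 0:
            raise ValidationError("outlier_shift must be positive")


@dataclass(frozen=True)
class CopyNumberModel:
    """Diploid baseline with amplified genes drawn above the threshold."""

    baseline: float = 2.0
    gain_low: float = 6.0
    gain_high: float = 20.0

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ValidationError("baseline copy number must be ≥ 0")
        if not 0 < self.gain_low <= self.gain_high:
            raise ValidationError("need 0 < gain_low ≤ gain_high")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters.

    Defaults emulate the reference cohort shape: 103 patients with WES, a
    ~69% RNA-seq coverage fraction, and sparse per-gene alteration rates
    (≈0.018 mutation, ≈0.006 amplification, ≈0.0002 fusion per
    gene-patient) that reproduce, in expectation, tens of mutations and a
    handful of amplifications per 46-gene screen.
    """

    n_patients: int = 103
    genes: tuple[str, ...] = ()  # empty = use the whole catalog
    rates: Mapping[str, GeneRates] | GeneRates = GeneRates()
    oncogenicity_mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ONCOGENICITY_MIXTURE)
    )
    impact_mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IMPACT_MIXTURE)
    )
    expression: ExpressionModel = ExpressionModel()
    copy_number: CopyNumberModel = CopyNumberModel()
    rnaseq_coverage_fraction: float = 71 / 103
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be ≥ 1")
        if not 0.0 <= self.rnaseq_coverage_fraction <= 1.0:
            raise ValidationError("rnaseq_coverage_fraction must be in [0, 1]")
        total = sum(self.oncogenicity_mixture.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValidationError(
                f"oncogenicity_mixture must sum to 1, got {total}"
            )
        unknown = set(self.oncogenicity_mixture) - set(ONCOGENICITY_CLASSES)
        if unknown:
            raise ValidationError(f"unknown oncogenicity classes: {sorted(unknown)}")
        if not math.isclose(sum(self.impact_mixture.values()), 1.0, abs_tol=1e-9):
            raise ValidationError("impact_mixture must sum to 1")

    def rates_for(self, gene: str) -> GeneRates:
        if isinstance(self.rates, GeneRates):
            return self.rates
        return self.rates.get(gene, GeneRates())

    def oncogenic_class_probability(self) -> float:
        """P(a planted mutation is oncogenic/likely oncogenic)."""
        return sum(
            p for cls, p in self.oncogenicity_mixture.items()
            if cls in ONCOGENIC_CLASSES
        )

    def per_gene_oncogenic_probability(
        self, gene: str, with_expression: bool = False
    ) -> float:
        """P(≥1 planted putative-oncogenic event in ``gene`` for a patient),
        under independence of the event kinds."""
        r = self.rates_for(gene)
        p_not = (
            (1 - r.p_amplification)
            * (1 - r.p_fusion)
            * (1 - r.p_mutation * self.oncogenic_class_probability())
        )
        if with_expression:
            p_not *= 1 - self.expression.outlier_rate
        return 1.0 - p_not


@dataclass(frozen=True)
class SimulatedTruth:
    """Planted events plus the presence verdicts they imply."""

    events: tuple[AlterationEvent, ...]
    verdicts: Mapping[str, Mapping[str, bool]]  # patient -> set name -> bool

    def planted(self, kind: str) -> list[AlterationEvent]:
        return [e for e in self.events if e.kind == kind]


@dataclass(frozen=True)
class SimulatedCohort:
    mutations: tuple[MutationRecord, ...]
    cnvs: tuple[CnvRecord, ...]
    expression: ExpressionMatrix | None
    fusions: tuple[FusionRecord, ...]
    manifest: tuple[ManifestEntry, ...]
    truth: SimulatedTruth


def expected_target_fraction(
    per_gene_probabilities: Mapping[str, float], gene_set: Iterable[str]
) -> float:
    """Closed-form P(≥1 qualifying alteration in the set) under per-gene
    independence: 1 − Π_{g ∈ set} (1 − p_g). Genes absent from the
    probability map contribute p=0."""
    prob_none = 1.0
    for gene in set(gene_set):
        prob_none *= 1.0 - per_gene_probabilities.get(gene, 0.0)
    return 1.0 - prob_none


def _sample_mixture(rng: np.random.Generator, mixture: Mapping[str, float], n: int):
    keys = sorted(mixture)
    probs = np.array([mixture[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return [keys[i] for i in rng.choice(len(keys), size=n, p=probs)]


def simulate_cohort(
    config: SimulationConfig, catalog: TargetCatalog
) -> SimulatedCohort:
    """Generate one cohort: four input tables, a manifest, and the planted
    truth. Deterministic given ``config.seed``."""
    genes = list(config.genes) if config.genes else sorted(catalog.symbols)
    unknown = set(genes) - set(catalog.symbols)
    if unknown:
        raise ValidationError(f"simulated genes not in catalog: {sorted(unknown)}")

    root = np.random.SeedSequence(config.seed)
    # fixed spawn order: mutation, cnv, expression, fusion, manifest
    streams = [np.random.default_rng(s) for s in root.spawn(5)]
    rng_mut, rng_cnv, rng_expr, rng_fus, rng_man = streams

    patients = [f"S{i:04d}" for i in range(1, config.n_patients + 1)]

    n_rnaseq = round(config.rnaseq_coverage_fraction * config.n_patients)
    with_rnaseq = set(
        rng_man.choice(patients, size=n_rnaseq, replace=False)
    ) if n_rnaseq else set()
    manifest = tuple(
        ManifestEntry(p, has_wes=True, has_rnaseq=p in with_rnaseq)
        for p in patients
    )

    truth_events: list[AlterationEvent] = []

    # mutations
    mutations: list[MutationRecord] = []
    for gene in genes:
        p = config.rates_for(gene).p_mutation
        if p == 0:
            continue
        hits = np.nonzero(rng_mut.random(config.n_patients) < p)[0]
        classes = _sample_mixture(rng_mut, config.oncogenicity_mixture, len(hits))
        impacts = _sample_mixture(rng_mut, config.impact_mixture, len(hits))
        for idx, cls, impact in zip(hits, classes, impacts):
            mutations.append(
                MutationRecord(
                    patient_id=patients[idx],
                    gene=gene,
                    impact=impact,
                    oncogenicity=cls,
                )
            )
            truth_events.append(
                AlterationEvent(
                    patient_id=patients[idx],
                    gene=gene,
                    kind="mutation",
                    oncogenic=cls in ONCOGENIC_CLASSES,
                    detail=cls,
                )
            )

    # copy numbers: baseline rows everywhere, gains where planted
    cnvs: list[CnvRecord] = []
    cn_model = config.copy_number
    for gene in genes:
        p = config.rates_for(gene).p_amplification
        amped = rng_cnv.random(config.n_patients) < p if p else np.zeros(
            config.n_patients, dtype=bool
        )
        gains = rng_cnv.uniform(cn_model.gain_low, cn_model.gain_high,
                                int(amped.sum()))
        gi = 0
        for idx, patient in enumerate(patients):
            if amped[idx]:
                cn = float(gains[gi]); gi += 1
                truth_events.append(
                    AlterationEvent(
                        patient_id=patient,
                        gene=gene,
                        kind="amplification",
                        detail=f"copy_number={cn:g}",
                    )
                )
            else:
                cn = cn_model.baseline
            cnvs.append(CnvRecord(patient_id=patient, gene=gene, copy_number=cn))

    # expression for the RNA-seq subset
    expression = None
    samples = [p for p in patients if p in with_rnaseq]
    if samples:
        em = config.expression
        values = rng_expr.normal(
            em.baseline_mean, em.baseline_sd, size=(len(genes), len(samples))
        )
        planted = rng_expr.random((len(genes), len(samples))) < em.outlier_rate
        values[planted] = em.baseline_mean + em.outlier_shift
        for i, j in zip(*np.nonzero(planted)):
            truth_events.append(
                AlterationEvent(
                    patient_id=samples[j],
                    gene=genes[i],
                    kind="overexpression",
                    detail=f"log2cpm={values[i, j]:g}",
                )
            )
        expression = ExpressionMatrix.from_arrays(genes, samples, values)

    # fusions: catalog gene :: synthetic out-of-catalog partner
    fusions: list[FusionRecord] = []
    for gene in genes:
        p = config.rates_for(gene).p_fusion
        if p == 0:
            continue
        hits = np.nonzero(rng_fus.random(config.n_patients) < p)[0]
        for k, idx in enumerate(hits):
            label = f"{gene}::PARTNER{k + 1}"
            fusions.append(
                FusionRecord(
                    patient_id=patients[idx],
                    gene_5prime=gene,
                    gene_3prime=f"PARTNER{k + 1}",
                    label=label,
                )
            )
            truth_events.append(
                AlterationEvent(
                    patient_id=patients[idx],
                    gene=gene,
                    kind="fusion",
                    detail=label,
                )
            )

    truth_events.sort()
    verdicts = _truth_verdicts(truth_events, patients, catalog.gene_sets())
    return SimulatedCohort(
        mutations=tuple(mutations),
        cnvs=tuple(cnvs),
        expression=expression,
        fusions=tuple(fusions),
        manifest=manifest,
        truth=SimulatedTruth(events=tuple(truth_events), verdicts=verdicts),
    )


def _truth_verdicts(
    events: Sequence[AlterationEvent],
    patients: Sequence[str],
    sets: GeneSetCatalog,
) -> dict[str, dict[str, bool]]:
    onco_genes: dict[str, set[str]] = {p: set() for p in patients}
    for ev in events:
        if ev.oncogenic:
            onco_genes[ev.patient_id].add(ev.gene)
    return {
        p: {
            name: not onco_genes[p].isdisjoint(members)
            for name, members in sets.named().items()
        }
        for p in patients
    }
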