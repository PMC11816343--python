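"""Alteration calling: turn processed molecular tables into unified events.

Four independent calling rules, mirroring common practice in bulk
tumor-profiling studies of modest cohort size:

* **Amplification** — a per-gene copy-number estimate strictly greater than
  a threshold (default 5) is accepted as a surrogate for gene amplification.
* **Overexpression** — within each gene, a sample's log2CPM value is an
  outlier when it exceeds the Tukey upper fence Q3 + 1.5 × IQR computed
  across all samples in the matrix. Under-expression is never flagged.
* **Mutation screening** — input mutations are already impact-annotated;
  only HIGH/MODERATE impact records are kept, benign/likely-benign classes
  are dropped entirely, and the surviving records are flagged oncogenic iff
  their curated class is oncogenic or likely_oncogenic.
* **Fusions** — a fusion is credited to every catalog gene among its two
  partners; non-catalog partners survive only in the event detail.

Amplifications, overexpression calls and fusions always count as putative
oncogenic events; mutations only when their class says so.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import GeneSetCatalog
from .errors import TooFewSamplesError, ValidationError

IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")
ONCOGENICITY_CLASSES = (
    "oncogenic",
    "likely_oncogenic",
    "vus",
    "vus_nmd",
    "likely_benign",
    "benign",
)
ONCOGENIC_CLASSES = frozenset({"oncogenic", "likely_oncogenic"})
BENIGN_CLASSES = frozenset({"benign", "likely_benign"})
SCREENED_IMPACTS = frozenset({"HIGH", "MODERATE"})
EVENT_KINDS = ("mutation", "amplification", "overexpression", "fusion")


@dataclass(frozen=True, order=True)
class MutationRecord:
    patient_id: str
    gene: str
    impact: str
    oncogenicity: str
    hgvs: str | None = None

    def __post_init__(self) -> None:
        if not self.patient_id or not self.gene:
            raise ValidationError("mutation record needs patient_id and gene")
        if self.impact not in IMPACTS:
            raise ValidationError(
                f"unknown impact {self.impact!r}; allowed: {IMPACTS}"
            )
        if self.oncogenicity not in ONCOGENICITY_CLASSES:
            raise ValidationError(
                f"unknown oncogenicity class {self.oncogenicity!r}; "
                f"allowed: {ONCOGENICITY_CLASSES}"
            )


@dataclass(frozen=True, order=True)
class CnvRecord:
    patient_id: str
    gene: str
    copy_number: float

    def __post_init__(self) -> None:
        if not self.patient_id or not self.gene:
            raise ValidationError("CNV record needs patient_id and gene")
        if self.copy_number < 0:
            raise ValidationError(
                f"copy number must be ≥ 0, got {self.copy_number} "
                f"({self.patient_id}/{self.gene})"
            )


@dataclass(frozen=True, order=True)
class FusionRecord:
    patient_id: str
    gene_5prime: str
    gene_3prime: str
    label: str = ""

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValidationError("fusion record needs patient_id")
        if not (self.gene_5prime or self.gene_3prime):
            raise ValidationError("fusion record needs at least one partner gene")

    @property
    def display_label(self) -> str:
        return self.label or f"{self.gene_5prime}::{self.gene_3prime}"


class ExpressionMatrix:
    """A gene × sample grid of log2CPM values.

    Thin wrapper over a pandas DataFrame (genes as the index, patient ids as
    columns) enforcing uniqueness and finiteness.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            raise ValidationError("expression matrix has duplicate gene rows")
        if frame.columns.has_duplicates:
            raise ValidationError("expression matrix has duplicate sample columns")
        values = frame.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise ValidationError("expression matrix contains non-finite values")
        self.frame = frame.astype(float)

    @classmethod
    def from_arrays(
        cls,
        genes: Sequence[str],
        samples: Sequence[str],
        values: np.ndarray,
    ) -> "ExpressionMatrix":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(genes), len(samples)):
            raise ValidationError(
                f"expression grid shape {values.shape} does not match "
                f"{len(genes)} genes × {len(samples)} samples"
            )
        return cls(pd.DataFrame(values, index=list(genes), columns=list(samples)))

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def samples(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_samples(self) -> int:
        return self.frame.shape[1]


@dataclass(frozen=True)
class AnalysisConfig:
    """Calling thresholds.

    amplification_threshold is a *strict* lower bound on the copy number;
    iqr_multiplier scales the interquartile range in the upper outlier
    fence; min_samples_for_outlier_test guards against meaningless quartiles
    on tiny cohorts.
    """

    amplification_threshold: float = 5.0
    iqr_multiplier: float = 1.5
    min_samples_for_outlier_test: int = 4

    def __post_init__(self) -> None:
        if self.amplification_threshold <= 0:
            raise ValidationError("amplification_threshold must be positive")
        if self.iqr_multiplier <= 0:
            raise ValidationError("iqr_multiplier must be positive")
        if self.min_samples_for_outlier_test < 1:
            raise ValidationError("min_samples_for_outlier_test must be ≥ 1")


@dataclass(frozen=True, order=True)
class AlterationEvent:
    """A unified called alteration for one (patient, gene)."""

    patient_id: str
    gene: str
    kind: str
    oncogenic: bool = True
    detail: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if self.kind != "mutation" and not self.oncogenic:
            raise ValidationError(
                f"{self.kind} events are always putative oncogenic"
            )


def call_amplifications(
    cnvs: Iterable[CnvRecord], config: AnalysisConfig = AnalysisConfig()
) -> list[AlterationEvent]:
    """One amplification event per (patient, gene) whose copy number is
    strictly above the threshold; duplicate records collapse to the maximum
    copy number. Output order is (patient, gene)-sorted."""
    best: dict[tuple[str, str], float] = {}
    for rec in cnvs:
        if rec.copy_number > config.amplification_threshold:
            key = (rec.patient_id, rec.gene)
            if rec.copy_number > best.get(key, float("-inf")):
                best[key] = rec.copy_number
    return [
        AlterationEvent(
            patient_id=p,
            gene=g,
            kind="amplification",
            oncogenic=True,
            detail=f"copy_number={best[(p, g)]:g}",
        )
        for p, g in sorted(best)
    ]


def overexpression_fences(
    expr: ExpressionMatrix, config: AnalysisConfig = AnalysisConfig()
) -> pd.DataFrame:
    """Per-gene Q1, Q3 and the upper outlier fence Q3 + k × IQR.

    Quartiles use linear interpolation between order statistics (numpy's
    default, quantile type 7)."""
    values = expr.frame.to_numpy(dtype=float)
    q1 = np.quantile(values, 0.25, axis=1)
    q3 = np.quantile(values, 0.75, axis=1)
    fence = q3 + config.iqr_multiplier * (q3 - q1)
    return pd.DataFrame(
        {"q1": q1, "q3": q3, "fence": fence}, index=expr.frame.index
    )


def call_overexpression(
    expr: ExpressionMatrix, config: AnalysisConfig = AnalysisConfig()
) -> list[AlterationEvent]:
    """Flag, per gene, every sample whose log2CPM exceeds the Tukey upper
    fence computed across all samples in the matrix. One-sided: low values
    are never events."""
    if expr.n_samples < config.min_samples_for_outlier_test:
        raise TooFewSamplesError(
            f"outlier detection needs ≥ {config.min_samples_for_outlier_test} "
            f"samples, got {expr.n_samples}"
        )
    fences = overexpression_fences(expr, config)
    events: list[AlterationEvent] = []
    samples = expr.samples
    values = expr.frame.to_numpy(dtype=float)
    for i, gene in enumerate(expr.genes):
        over = np.nonzero(values[i] > fences["fence"].iloc[i])[0]
        for j in over:
            events.append(
                AlterationEvent(
                    patient_id=samples[j],
                    gene=gene,
                    kind="overexpression",
                    oncogenic=True,
                    detail=f"log2cpm={values[i, j]:g};fence={fences['fence'].iloc[i]:g}",
                )
            )
    events.sort()
    return events


def screen_mutations(muts: Iterable[MutationRecord]) -> list[AlterationEvent]:
    """Keep HIGH/MODERATE-impact, non-benign mutations; the event is
    putative oncogenic iff the curated class is oncogenic/likely_oncogenic."""
    events = []
    for rec in muts:
        if rec.impact not in SCREENED_IMPACTS:
            continue
        if rec.oncogenicity in BENIGN_CLASSES:
            continue
        detail = rec.oncogenicity + (f";{rec.hgvs}" if rec.hgvs else "")
        events.append(
            AlterationEvent(
                patient_id=rec.patient_id,
                gene=rec.gene,
                kind="mutation",
                oncogenic=rec.oncogenicity in ONCOGENIC_CLASSES,
                detail=detail,
            )
        )
    events.sort()
    return events


def collect_fusions(
    fusions: Iterable[FusionRecord], sets: GeneSetCatalog
) -> list[AlterationEvent]:
    """Credit each fusion to every catalog gene among its partners; a
    catalog::catalog fusion yields two events, a fusion with no catalog
    partner yields none."""
    events = []
    for rec in fusions:
        partners = [g for g in (rec.gene_5prime, rec.gene_3prime) if g]
        for gene in dict.fromkeys(partners):  # de-dupe, keep order
            if gene in sets.full_set:
                events.append(
                    AlterationEvent(
                        patient_id=rec.patient_id,
                        gene=gene,
                        kind="fusion",
                        oncogenic=True,
                        detail=rec.display_label,
                    )
                )
    events.sort()
    return events


def unify_alterations(
    *event_lists: Iterable[AlterationEvent],
) -> pd.DataFrame:
    """Merge event lists into one deterministic per-patient table.

    Exact duplicates — same (patient, gene, kind, detail) — collapse to one
    row; distinct mutations in the same gene (different detail) are kept so
    gene-level totals count them individually, while patient-level presence
    logic downstream is set-based anyway. Rows are sorted by
    (patient, gene, kind, detail)."""
    seen: dict[tuple[str, str, str, str], AlterationEvent] = {}
    for events in event_lists:
        for ev in events:
            seen.setdefault((ev.patient_id, ev.gene, ev.kind, ev.detail), ev)
    rows = [seen[k] for k in sorted(seen)]
    return pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in rows],
            "gene": [e.gene for e in rows],
            "kind": [e.kind for e in rows],
            "oncogenic": [e.oncogenic for e in rows],
            "detail": [e.detail for e in rows],
        }
    )


def events_from_frame(frame: pd.DataFrame) -> list[AlterationEvent]:
    """Inverse of :func:`unify_alterations` for a unified event table."""
    return [
        AlterationEvent(
            patient_id=row.patient_id,
            gene=row.gene,
            kind=row.kind,
            oncogenic=bool(row.oncogenic),
            detail=row.detail,
        )
        for row in frame.itertuples(index=False)
    ]
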