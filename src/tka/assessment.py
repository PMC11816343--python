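"""Per-patient target-presence verdicts and cohort/gene-level summaries.

A patient *has the target* under a gene set S when at least one called
alteration falls in a gene of S. Two verdict flavours are tracked per set:

* ``any_alteration`` — any event at all (benign mutations never reach this
  stage; they are dropped during screening);
* ``putative_oncogenic`` — at least one event whose ``oncogenic`` flag is
  set (all amplifications/overexpression/fusions, plus oncogenic or
  likely-oncogenic mutations).

Because the assessment sets nest (achievable ⊆ extended ⊆ full), verdicts
are monotone: a yes under the 18-gene set implies a yes under the 23- and
46-gene sets.

Percentages are over the manifest size — every enrolled patient, including
alteration-free ones and those without expression data — reported to one
decimal, rounding halves away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .calling import EVENT_KINDS, AlterationEvent, events_from_frame
from .catalog import (
    CatalogConfig,
    GeneSetCatalog,
    TargetCatalog,
    classify_inhibition_status,
)
from .errors import ManifestMismatchError

SET_NAMES = ("full", "achievable", "extended")


def percentage(count: int, denominator: int) -> float | None:
    """100 × count / denominator to one decimal, half away from zero;
    ``None`` (an explicit undefined marker) for an empty denominator."""
    if denominator == 0:
        return None
    raw = Decimal(100 * count) / Decimal(denominator)
    return float(raw.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Verdict:
    any_alteration: bool
    putative_oncogenic: bool

    def __post_init__(self) -> None:
        if self.putative_oncogenic and not self.any_alteration:
            raise ValueError("putative_oncogenic implies any_alteration")


@dataclass(frozen=True)
class PatientProfile:
    patient_id: str
    events: tuple[AlterationEvent, ...]
    has_expression_data: bool
    verdicts: Mapping[str, Verdict]

    @property
    def altered_genes(self) -> frozenset[str]:
        return frozenset(e.gene for e in self.events)

    @property
    def putative_target_genes(self) -> frozenset[str]:
        return frozenset(e.gene for e in self.events if e.oncogenic)


@dataclass(frozen=True)
class GeneSummary:
    gene: str
    n_mutations: int = 0
    n_amplifications: int = 0
    n_overexpressions: int = 0
    n_fusions: int = 0
    n_oncogenic: int = 0

    @property
    def n_any(self) -> int:
        return (
            self.n_mutations
            + self.n_amplifications
            + self.n_overexpressions
            + self.n_fusions
        )


@dataclass(frozen=True)
class CohortSummary:
    n_patients: int
    per_set: Mapping[str, Mapping[str, int | float | None]]
    modality_counts: Mapping[str, int]

    def as_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "per_set": {k: dict(v) for k, v in self.per_set.items()},
            "modality_counts": dict(self.modality_counts),
        }


def _as_events(events) -> list[AlterationEvent]:
    if isinstance(events, pd.DataFrame):
        return events_from_frame(events)
    return list(events)


def build_patient_profiles(
    events,
    manifest: Sequence,
    sets: GeneSetCatalog,
) -> list[PatientProfile]:
    """One profile per manifest patient (alteration-free patients included),
    with any/putative verdicts for the three assessment sets.

    ``manifest`` entries need ``patient_id`` and ``has_rnaseq`` attributes
    (see :class:`tka.io.ManifestEntry`). An event whose patient is not in
    the manifest raises :class:`ManifestMismatchError`.
    """
    event_list = _as_events(events)
    roster = {m.patient_id: m for m in manifest}
    if len(roster) != len(manifest):
        raise ManifestMismatchError("manifest patient_ids are not unique")
    by_patient: dict[str, list[AlterationEvent]] = {p: [] for p in roster}
    for ev in event_list:
        if ev.patient_id not in roster:
            raise ManifestMismatchError(
                f"event references patient {ev.patient_id!r} absent from manifest"
            )
        by_patient[ev.patient_id].append(ev)

    named_sets = sets.named()
    profiles = []
    for patient_id in roster:
        evs = tuple(sorted(by_patient[patient_id]))
        genes_any = {e.gene for e in evs}
        genes_onco = {e.gene for e in evs if e.oncogenic}
        verdicts = {
            name: Verdict(
                any_alteration=not genes_any.isdisjoint(members),
                putative_oncogenic=not genes_onco.isdisjoint(members),
            )
            for name, members in named_sets.items()
        }
        profiles.append(
            PatientProfile(
                patient_id=patient_id,
                events=evs,
                has_expression_data=bool(getattr(roster[patient_id], "has_rnaseq", False)),
                verdicts=verdicts,
            )
        )
    return profiles


def summarize_cohort(profiles: Sequence[PatientProfile]) -> CohortSummary:
    """Patient-presence counts per gene set plus per-modality patient counts.

    An empty cohort yields zero counts with percentages marked undefined
    (``None``), never 0.0.
    """
    n = len(profiles)
    per_set = {}
    for name in SET_NAMES:
        n_any = sum(1 for p in profiles if p.verdicts[name].any_alteration)
        n_onco = sum(1 for p in profiles if p.verdicts[name].putative_oncogenic)
        per_set[name] = {
            "n_any": n_any,
            "pct_any": percentage(n_any, n),
            "n_oncogenic": n_onco,
            "pct_oncogenic": percentage(n_onco, n),
        }
    modality = {}
    for kind in EVENT_KINDS:
        modality[f"n_with_{kind}"] = sum(
            1 for p in profiles if any(e.kind == kind for e in p.events)
        )
    return CohortSummary(n_patients=n, per_set=per_set, modality_counts=modality)


def summarize_genes(events, sets: GeneSetCatalog) -> pd.DataFrame:
    """Event counts per catalog gene (zero-filled), one row per gene.

    Columns: n_mutations, n_amplifications, n_overexpressions, n_fusions,
    n_any, n_oncogenic. ``n_any`` counts every event; ``n_oncogenic`` only
    events flagged oncogenic. Gene-absent events are ignored (events are
    expected to be catalog-normalized upstream)."""
    event_list = _as_events(events)
    genes = sorted(sets.full_set)
    counts = {
        g: {"n_mutations": 0, "n_amplifications": 0, "n_overexpressions": 0,
            "n_fusions": 0, "n_oncogenic": 0}
        for g in genes
    }
    kind_column = {
        "mutation": "n_mutations",
        "amplification": "n_amplifications",
        "overexpression": "n_overexpressions",
        "fusion": "n_fusions",
    }
    for ev in event_list:
        if ev.gene not in counts:
            continue
        counts[ev.gene][kind_column[ev.kind]] += 1
        if ev.oncogenic:
            counts[ev.gene]["n_oncogenic"] += 1
    frame = pd.DataFrame.from_dict(counts, orient="index")
    frame.index.name = "gene"
    frame["n_any"] = (
        frame["n_mutations"]
        + frame["n_amplifications"]
        + frame["n_overexpressions"]
        + frame["n_fusions"]
    )
    return frame[
        ["n_mutations", "n_amplifications", "n_overexpressions", "n_fusions",
         "n_any", "n_oncogenic"]
    ]


def gene_level_stats(gene_summaries: pd.DataFrame) -> dict:
    """Distinct-gene tallies over a :func:`summarize_genes` table."""
    n_genes = len(gene_summaries)
    n_altered = int((gene_summaries["n_any"] > 0).sum())
    n_amplified = int((gene_summaries["n_amplifications"] > 0).sum())
    n_putative = int((gene_summaries["n_oncogenic"] > 0).sum())
    return {
        "n_genes": n_genes,
        "n_genes_with_any_alteration": n_altered,
        "n_genes_without_alteration": n_genes - n_altered,
        "n_genes_with_amplification": n_amplified,
        "pct_genes_with_amplification": percentage(n_amplified, n_genes),
        "n_genes_with_putative_oncogenic": n_putative,
    }


@dataclass(frozen=True)
class TargetPartition:
    confirmed_target_genes: frozenset[str]
    unconfirmed_target_genes: frozenset[str]
    unconfirmed_only: bool


def partition_effective_targets(
    profile: PatientProfile, not_confirmed: frozenset[str] | Iterable[str]
) -> TargetPartition:
    """Split a patient's putative-oncogenic target genes into those with
    confirmed drug inhibition and those without; ``unconfirmed_only`` is
    true iff the patient has putative targets and every one of them lies in
    the not-confirmed set."""
    not_confirmed = frozenset(not_confirmed)
    putative = profile.putative_target_genes
    unconfirmed = putative & not_confirmed
    confirmed = putative - not_confirmed
    return TargetPartition(
        confirmed_target_genes=confirmed,
        unconfirmed_target_genes=unconfirmed,
        unconfirmed_only=bool(putative) and not confirmed,
    )


def compare_alterations_to_affinity(
    gene_summaries: pd.DataFrame,
    catalog: TargetCatalog,
    config: CatalogConfig = CatalogConfig(),
) -> pd.DataFrame:
    """Per-gene table joining alteration counts with affinity evidence —
    the data behind an alterations-vs-minimal-inhibitory-concentration
    plot. Columns: n_any, n_oncogenic, min_affinity_nM (NaN when absent),
    inhibition_status, clinically_achievable, angiogenesis."""
    rows = []
    for gene in catalog:
        summary = (
            gene_summaries.loc[gene.symbol]
            if gene.symbol in gene_summaries.index
            else None
        )
        rows.append(
            {
                "gene": gene.symbol,
                "n_any": int(summary["n_any"]) if summary is not None else 0,
                "n_oncogenic": int(summary["n_oncogenic"]) if summary is not None else 0,
                "min_affinity_nM": gene.min_affinity(),
                "inhibition_status": classify_inhibition_status(gene, config),
                "clinically_achievable": gene.clinically_achievable,
                "angiogenesis": gene.angiogenesis,
            }
        )
    return pd.DataFrame(rows).set_index("gene").sort_index()
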