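"""End-to-end orchestration: normalize → call → assess → report."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from .assessment import (
    CohortSummary,
    PatientProfile,
    build_patient_profiles,
    summarize_cohort,
    summarize_genes,
)
from .calling import (
    AnalysisConfig,
    CnvRecord,
    ExpressionMatrix,
    FusionRecord,
    MutationRecord,
    call_amplifications,
    call_overexpression,
    collect_fusions,
    screen_mutations,
    unify_alterations,
)
from .catalog import CatalogConfig, TargetCatalog
from .io import ManifestEntry
from .report import build_report


@dataclass(frozen=True)
class AssessmentResult:
    profiles: tuple[PatientProfile, ...]
    cohort_summary: CohortSummary
    gene_summaries: pd.DataFrame
    events: pd.DataFrame
    report: dict


def normalize_inputs(
    catalog: TargetCatalog,
    mutations: Sequence[MutationRecord] = (),
    cnvs: Sequence[CnvRecord] = (),
    expression: ExpressionMatrix | None = None,
    fusions: Sequence[FusionRecord] = (),
):
    """Rewrite every gene symbol to its canonical catalog form.

    Mutation/CNV/expression genes must resolve (unknown symbols raise
    :class:`tka.errors.SymbolNotInCatalogError`); fusion partners are
    normalized only when they are catalog genes, since out-of-catalog
    partners are legitimate."""
    mutations = [replace(m, gene=catalog.normalize(m.gene)) for m in mutations]
    cnvs = [replace(c, gene=catalog.normalize(c.gene)) for c in cnvs]
    if expression is not None:
        frame = expression.frame.copy()
        frame.index = [catalog.normalize(g) for g in frame.index]
        expression = ExpressionMatrix(frame)

    def _maybe(symbol: str) -> str:
        return catalog.normalize(symbol) if catalog.aliases.known(symbol) else symbol

    fusions = [
        replace(f, gene_5prime=_maybe(f.gene_5prime), gene_3prime=_maybe(f.gene_3prime))
        for f in fusions
    ]
    return mutations, cnvs, expression, fusions


def assess_cohort(
    catalog: TargetCatalog,
    manifest: Sequence[ManifestEntry],
    mutations: Sequence[MutationRecord] = (),
    cnvs: Sequence[CnvRecord] = (),
    expression: ExpressionMatrix | None = None,
    fusions: Sequence[FusionRecord] = (),
    analysis_config: AnalysisConfig = AnalysisConfig(),
    catalog_config: CatalogConfig = CatalogConfig(),
    reference_counts: dict | None = None,
) -> AssessmentResult:
    """Run the four calling rules on raw tables, then the assessment."""
    mutations, cnvs, expression, fusions = normalize_inputs(
        catalog, mutations, cnvs, expression, fusions
    )
    sets = catalog.gene_sets()
    event_lists = [
        screen_mutations(mutations),
        call_amplifications(cnvs, analysis_config),
        collect_fusions(fusions, sets),
    ]
    if expression is not None and expression.n_samples:
        event_lists.append(call_overexpression(expression, analysis_config))
    events = unify_alterations(*event_lists)
    return assess_events(
        catalog,
        manifest,
        events,
        analysis_config=analysis_config,
        catalog_config=catalog_config,
        reference_counts=reference_counts,
    )


def assess_events(
    catalog: TargetCatalog,
    manifest: Sequence[ManifestEntry],
    events,
    analysis_config: AnalysisConfig = AnalysisConfig(),
    catalog_config: CatalogConfig = CatalogConfig(),
    reference_counts: dict | None = None,
) -> AssessmentResult:
    """Assessment stage only, for pre-called event tables (event-mode
    fixtures, simulator truth, or external callers)."""
    if not isinstance(events, pd.DataFrame):
        events = unify_alterations(events)
    sets = catalog.gene_sets()
    profiles = build_patient_profiles(events, manifest, sets)
    cohort = summarize_cohort(profiles)
    genes = summarize_genes(events, sets)
    report = build_report(
        profiles,
        cohort,
        genes,
        catalog,
        analysis_config=analysis_config,
        catalog_config=catalog_config,
        reference_counts=reference_counts,
    )
    return AssessmentResult(
        profiles=tuple(profiles),
        cohort_summary=cohort,
        gene_summaries=genes,
        events=events,
        report=report,
    )
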