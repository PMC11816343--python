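"""Assemble the JSON assessment report and its TSV exports.

The report is one self-contained dict with sections ``config``,
``gene_sets``, ``gene_summaries``, ``patient_profiles``,
``cohort_summary``, ``gene_level_stats``, ``affinity_comparison`` and —
when curated reference totals are supplied — ``consistency_flags``
comparing each recomputed headline total against its recorded value and
marking disagreements instead of forcing them to match.

TSV exports mirror the per-patient verdict layout (one row per patient,
alterations as ``GENE kind`` conjunctions) and the cohort summary (counts
and percentages per gene set).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .assessment import (
    CohortSummary,
    PatientProfile,
    compare_alterations_to_affinity,
    gene_level_stats,
)
from .calling import AnalysisConfig
from .catalog import CatalogConfig, TargetCatalog

_KIND_ABBREV = {
    "mutation": "mut",
    "amplification": "amp",
    "overexpression": "over",
    "fusion": "fusion",
}


def _conjunction(events, oncogenic_only: bool = False) -> str:
    parts = []
    for e in events:
        if oncogenic_only and not e.oncogenic:
            continue
        if e.kind == "fusion":
            parts.append(f"{e.detail or e.gene} fusion")
        else:
            parts.append(f"{e.gene} {_KIND_ABBREV[e.kind]}")
    return " and ".join(parts) if parts else "-"


def build_report(
    profiles: Sequence[PatientProfile],
    cohort: CohortSummary,
    gene_summaries: pd.DataFrame,
    catalog: TargetCatalog,
    analysis_config: AnalysisConfig = AnalysisConfig(),
    catalog_config: CatalogConfig = CatalogConfig(),
    reference_counts: Mapping[str, int] | None = None,
) -> dict:
    sets = catalog.gene_sets()
    stats = gene_level_stats(gene_summaries)
    n_onco_mut = int(
        sum(
            1
            for p in profiles
            for e in p.events
            if e.kind == "mutation" and e.oncogenic
        )
    )
    report = {
        "config": {
            "amplification_threshold": analysis_config.amplification_threshold,
            "amplification_comparison": "strictly_greater",
            "iqr_multiplier": analysis_config.iqr_multiplier,
            "quantile_convention": "linear interpolation (type 7)",
            "min_samples_for_outlier_test": analysis_config.min_samples_for_outlier_test,
            "inhibition_threshold_nM": catalog_config.inhibition_threshold_nM,
        },
        "gene_sets": {
            name: sorted(members) for name, members in sets.named().items()
        } | {"angiogenesis": sorted(sets.angiogenesis_set)},
        "gene_summaries": {
            gene: {k: int(v) for k, v in row.items()}
            for gene, row in gene_summaries.to_dict(orient="index").items()
        },
        "gene_level_stats": stats | {"n_oncogenic_mutations": n_onco_mut},
        "patient_profiles": [
            {
                "patient_id": p.patient_id,
                "has_expression_data": p.has_expression_data,
                "alterations": _conjunction(p.events),
                "n_alterations": len(p.events),
                "putative_oncogenic_alterations": _conjunction(
                    p.events, oncogenic_only=True
                ),
                "verdicts": {
                    name: {
                        "any_alteration": v.any_alteration,
                        "putative_oncogenic": v.putative_oncogenic,
                    }
                    for name, v in p.verdicts.items()
                },
            }
            for p in profiles
        ],
        "cohort_summary": cohort.as_dict(),
        "affinity_comparison": [
            {
                k: (None if isinstance(v, float) and pd.isna(v) else v)
                for k, v in record.items()
            }
            for record in (
                compare_alterations_to_affinity(
                    gene_summaries, catalog, catalog_config
                )
                .reset_index()
                .to_dict(orient="records")
            )
        ],
    }
    if reference_counts is not None:
        report["consistency_flags"] = consistency_flags(
            report, profiles, reference_counts
        )
    return report


def consistency_flags(
    report: dict,
    profiles: Sequence[PatientProfile],
    reference_counts: Mapping[str, int],
) -> list[dict]:
    """Compare recomputed headline totals against curated recorded totals.

    Each flag carries the recorded value, the recomputation from the
    per-patient rows, and a ``consistent`` boolean; disagreements are
    surfaced, never reconciled.
    """
    cohort = report["cohort_summary"]
    stats = report["gene_level_stats"]
    recomputed = {
        "n_patients": cohort["n_patients"],
        "n_patients_with_rnaseq": sum(1 for p in profiles if p.has_expression_data),
        "patients_any_full": cohort["per_set"]["full"]["n_any"],
        "patients_any_achievable": cohort["per_set"]["achievable"]["n_any"],
        "patients_any_extended": cohort["per_set"]["extended"]["n_any"],
        "patients_putative_full": cohort["per_set"]["full"]["n_oncogenic"],
        "patients_putative_achievable": cohort["per_set"]["achievable"]["n_oncogenic"],
        "patients_putative_extended": cohort["per_set"]["extended"]["n_oncogenic"],
        "patients_with_mutation": cohort["modality_counts"]["n_with_mutation"],
        "patients_with_amplification": cohort["modality_counts"]["n_with_amplification"],
        "patients_with_overexpression": cohort["modality_counts"]["n_with_overexpression"],
        "patients_with_fusion": cohort["modality_counts"]["n_with_fusion"],
        "genes_with_any_alteration": stats["n_genes_with_any_alteration"],
        "genes_with_putative_oncogenic": stats["n_genes_with_putative_oncogenic"],
        "genes_with_amplification": stats["n_genes_with_amplification"],
        "oncogenic_mutations": stats["n_oncogenic_mutations"],
    }
    flags = []
    for key, recorded in reference_counts.items():
        if key not in recomputed:
            continue
        flags.append(
            {
                "quantity": key,
                "recorded": recorded,
                "recomputed": recomputed[key],
                "consistent": recorded == recomputed[key],
            }
        )
    return flags


def write_report(report: dict, out_dir: str | Path) -> dict[str, Path]:
    """Write ``report.json`` plus per-patient and cohort-summary TSVs.

    Output is byte-stable for identical inputs (sorted keys, LF endings).
    Returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["report"] = out / "report.json"
    paths["report"].write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )

    lines = [
        "patient_id\talterations\tn_alterations\tputative_oncogenic_alterations"
        "\ttarget_full\ttarget_achievable\ttarget_extended"
    ]
    for p in report["patient_profiles"]:
        v = p["verdicts"]
        lines.append(
            "\t".join(
                [
                    p["patient_id"],
                    p["alterations"],
                    str(p["n_alterations"]),
                    p["putative_oncogenic_alterations"],
                ]
                + [
                    "yes" if v[name]["putative_oncogenic"] else "no"
                    for name in ("full", "achievable", "extended")
                ]
            )
        )
    paths["patients"] = out / "patient_verdicts.tsv"
    paths["patients"].write_text("\n".join(lines) + "\n", encoding="utf-8")

    cohort = report["cohort_summary"]
    rows = ["metric\tfull\tachievable\textended"]
    for metric in ("n_any", "pct_any", "n_oncogenic", "pct_oncogenic"):
        cells = [
            str(cohort["per_set"][name][metric])
            for name in ("full", "achievable", "extended")
        ]
        rows.append("\t".join([metric] + cells))
    paths["summary"] = out / "cohort_summary.tsv"
    paths["summary"].write_text("\n".join(rows) + "\n", encoding="utf-8")
    return paths
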