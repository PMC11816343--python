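"""Readers and writers for the minimal TSV dialects the pipeline consumes.

All files are UTF-8, tab-separated, LF-terminated, with fixed column
orders so diffs are byte-stable:

* mutations:  ``patient_id  gene  impact  oncogenicity  hgvs`` (extra
  columns ignored; hgvs may be blank)
* CNVs:       ``patient_id  gene  copy_number``
* expression: first column ``gene``, one column per patient_id, log2CPM
* fusions:    ``patient_id  gene_5prime  gene_3prime  label``
* manifest:   ``patient_id  has_wes  has_rnaseq``
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .calling import CnvRecord, ExpressionMatrix, FusionRecord, MutationRecord
from .errors import ParseError, ValidationError


@dataclass(frozen=True)
class ManifestEntry:
    patient_id: str
    has_wes: bool = True
    has_rnaseq: bool = False

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValidationError("manifest entry needs a patient_id")


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: file is empty") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return frame


def read_mutations(path: str | Path) -> list[MutationRecord]:
    frame = _read_tsv(path, ["patient_id", "gene", "impact", "oncogenicity"])
    return [
        MutationRecord(
            patient_id=r.patient_id,
            gene=r.gene,
            impact=r.impact,
            oncogenicity=r.oncogenicity,
            hgvs=(getattr(r, "hgvs", "") or None),
        )
        for r in frame.itertuples(index=False)
    ]


def write_mutations(records: Sequence[MutationRecord], path: str | Path) -> None:
    lines = ["patient_id\tgene\timpact\toncogenicity\thgvs"]
    for r in records:
        lines.append(f"{r.patient_id}\t{r.gene}\t{r.impact}\t{r.oncogenicity}\t{r.hgvs or ''}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_cnvs(path: str | Path) -> list[CnvRecord]:
    frame = _read_tsv(path, ["patient_id", "gene", "copy_number"])
    records = []
    for r in frame.itertuples(index=False):
        try:
            cn = float(r.copy_number)
        except ValueError as exc:
            raise ParseError(
                f"{path}: bad copy_number {r.copy_number!r} for "
                f"{r.patient_id}/{r.gene}"
            ) from exc
        records.append(CnvRecord(patient_id=r.patient_id, gene=r.gene, copy_number=cn))
    return records


def write_cnvs(records: Sequence[CnvRecord], path: str | Path) -> None:
    lines = ["patient_id\tgene\tcopy_number"]
    for r in records:
        lines.append(f"{r.patient_id}\t{r.gene}\t{r.copy_number:g}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_expression(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if frame.index.name != "gene":
        raise ParseError(f"{path}: first column must be named 'gene'")
    return ExpressionMatrix(frame)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    frame = expr.frame.copy()
    frame.index.name = "gene"
    # repr-round-trip float formatting keeps read(write(x)) exact
    frame.to_csv(path, sep="\t", float_format="%.17g", lineterminator="\n")


def read_fusions(path: str | Path) -> list[FusionRecord]:
    frame = _read_tsv(path, ["patient_id", "gene_5prime", "gene_3prime"])
    return [
        FusionRecord(
            patient_id=r.patient_id,
            gene_5prime=r.gene_5prime,
            gene_3prime=r.gene_3prime,
            label=getattr(r, "label", ""),
        )
        for r in frame.itertuples(index=False)
    ]


def write_fusions(records: Sequence[FusionRecord], path: str | Path) -> None:
    lines = ["patient_id\tgene_5prime\tgene_3prime\tlabel"]
    for r in records:
        lines.append(f"{r.patient_id}\t{r.gene_5prime}\t{r.gene_3prime}\t{r.label}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _parse_bool(text: str, path: Path) -> bool:
    t = str(text).strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no"):
        return False
    raise ParseError(f"{path}: cannot parse boolean {text!r}")


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    path = Path(path)
    frame = _read_tsv(path, ["patient_id", "has_wes", "has_rnaseq"])
    entries = [
        ManifestEntry(
            patient_id=r.patient_id,
            has_wes=_parse_bool(r.has_wes, path),
            has_rnaseq=_parse_bool(r.has_rnaseq, path),
        )
        for r in frame.itertuples(index=False)
    ]
    ids = [e.patient_id for e in entries]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate patient_ids in manifest")
    return entries


def write_manifest(entries: Sequence[ManifestEntry], path: str | Path) -> None:
    lines = ["patient_id\thas_wes\thas_rnaseq"]
    for e in entries:
        lines.append(
            f"{e.patient_id}\t{str(e.has_wes).lower()}\t{str(e.has_rnaseq).lower()}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
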