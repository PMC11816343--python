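"""Drug-target catalog: genes, affinity evidence, and nested gene sets.

The catalog models the target spectrum of a multikinase inhibitor
(regorafenib in the packaged data): 46 protein-kinase genes with preclinical
affinity/inhibition evidence, of which 18 are inhibited at clinically
achievable drug concentrations and 19 sit in angiogenesis-related pathways.
The union of the 18 with the angiogenesis genes outside it yields the
23-gene "extended" set. Those three nested sets, plus the full 46, drive
every per-patient target-presence verdict downstream.

Affinity evidence mixes dissociation constants (K_D) and half-maximal
inhibitory concentrations (IC50), both in nM. The two are pooled and
compared against a single threshold (default 100 nM): the minimum value
observed for a gene, across measurement kinds and compounds (parent drug or
its active metabolites M-2/M-5), decides inhibited vs not_inhibited; genes
without any numeric value are `unknown`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .errors import CatalogError, SymbolNotInCatalogError

AFFINITY_KINDS = ("KD", "IC50")
COMPOUNDS = ("parent", "M2", "M5")
INHIBITION_STATUSES = ("confirmed", "not_confirmed", "unknown")

#: Alias -> canonical HUGO symbol. Collected from the catalog's "previous
#: term" and UniProt columns plus spellings seen in per-patient tables
#: (e.g. "CSFR1"). Matching is case-insensitive; canonical symbols resolve
#: to themselves implicitly.
DEFAULT_ALIASES: dict[str, str] = {
    "CDK11": "CDK19",
    "ECK": "EPHA2",
    "VEGFR1": "FLT1",
    "VEGFR2": "KDR",
    "VEGFR3": "FLT4",
    "FRK/PTK5": "FRK",
    "PTK5": "FRK",
    "MEK5": "MAP2K5",
    "YSK4": "MAP3K19",
    "M3K19": "MAP3K19",
    "ZAK": "MAP3K20",
    "TAK1": "MAP3K7",
    "M4K4": "MAP4K4",
    "P38-BETA": "MAPK11",
    "P38-BETA/SAPK2": "MAPK11",
    "SAPK2": "MAPK11",
    "P38-ALPHA": "MAPK14",
    "MK14": "MAPK14",
    "ERK8": "MAPK15",
    "MK15": "MAPK15",
    "JNK2": "MAPK9",
    "TRKA": "NTRK1",
    "TRKC": "NTRK3",
    "PGFRA": "PDGFRA",
    "PGFRB": "PDGFRB",
    "LOK": "STK10",
    "TIE2": "TEK",
    "TIE-2": "TEK",
    "TNI3K": "TNNI3K",
    "CSFR1": "CSF1R",
}


@dataclass(frozen=True)
class AffinityMeasurement:
    """One K_D or IC50 measurement, in nM; ``value`` may be absent."""

    kind: str
    value: float | None
    compound: str = "parent"
    source: str = ""

    def __post_init__(self) -> None:
        if self.kind not in AFFINITY_KINDS:
            raise CatalogError(
                f"affinity kind must be one of {AFFINITY_KINDS}, got {self.kind!r}"
            )
        if self.compound not in COMPOUNDS:
            raise CatalogError(
                f"compound must be one of {COMPOUNDS}, got {self.compound!r}"
            )
        if self.value is not None and not self.value > 0:
            raise CatalogError(f"affinity value must be > 0 nM, got {self.value}")


@dataclass(frozen=True)
class TargetGene:
    """A catalog gene with its affinity evidence and curated flags."""

    symbol: str
    protein_name: str = ""
    affinities: tuple[AffinityMeasurement, ...] = ()
    clinically_achievable: bool = False
    angiogenesis: bool = False
    inhibition_confirmed: str = "unknown"

    def __post_init__(self) -> None:
        if not self.symbol or not self.symbol.strip():
            raise CatalogError("gene symbol must be non-empty")
        if self.symbol != self.symbol.strip().upper():
            raise CatalogError(
                f"gene symbol must be upper-case and trimmed: {self.symbol!r}"
            )
        if self.inhibition_confirmed not in INHIBITION_STATUSES:
            raise CatalogError(
                f"inhibition_confirmed must be one of {INHIBITION_STATUSES}, "
                f"got {self.inhibition_confirmed!r}"
            )

    def min_affinity(self) -> float | None:
        """Minimum present affinity value across kinds and compounds (nM)."""
        values = [m.value for m in self.affinities if m.value is not None]
        return min(values) if values else None


@dataclass(frozen=True)
class GeneSetCatalog:
    """The nested gene sets a target-presence verdict is computed against.

    full_set ⊇ extended_set ⊇ achievable_set, and angiogenesis_set ⊆
    full_set; extended_set is the achievable set plus the angiogenesis
    genes outside it.
    """

    full_set: frozenset[str]
    achievable_set: frozenset[str]
    angiogenesis_set: frozenset[str]
    extended_set: frozenset[str]

    def __post_init__(self) -> None:
        if not self.achievable_set <= self.extended_set <= self.full_set:
            raise CatalogError("gene sets must nest: achievable ⊆ extended ⊆ full")
        if not self.angiogenesis_set <= self.full_set:
            raise CatalogError("angiogenesis_set must be a subset of full_set")
        expected = self.achievable_set | (self.angiogenesis_set - self.achievable_set)
        if self.extended_set != expected:
            raise CatalogError(
                "extended_set must equal achievable_set ∪ "
                "(angiogenesis_set \\ achievable_set)"
            )

    def named(self) -> dict[str, frozenset[str]]:
        """The three assessment sets keyed by their conventional names."""
        return {
            "full": self.full_set,
            "achievable": self.achievable_set,
            "extended": self.extended_set,
        }


class AliasMap:
    """Case-insensitive mapping from alias symbols to canonical HUGO symbols.

    Canonical symbols implicitly map to themselves. Every alias value must
    be a canonical member.
    """

    def __init__(self, canonical: Iterable[str], aliases: Mapping[str, str] = ()):
        self._canonical = {s.upper() for s in canonical}
        self._aliases: dict[str, str] = {}
        for alias, target in dict(aliases).items():
            target_u = target.strip().upper()
            if target_u not in self._canonical:
                raise CatalogError(
                    f"alias {alias!r} maps to {target!r}, not a canonical symbol"
                )
            self._aliases[alias.strip().upper()] = target_u

    @property
    def canonical(self) -> frozenset[str]:
        return frozenset(self._canonical)

    def resolve(self, symbol: str) -> str:
        """Canonical symbol for ``symbol``; raises if unknown."""
        key = symbol.strip().upper()
        if not key:
            raise SymbolNotInCatalogError(symbol)
        if key in self._canonical:
            return key
        if key in self._aliases:
            return self._aliases[key]
        raise SymbolNotInCatalogError(symbol)

    def known(self, symbol: str) -> bool:
        try:
            self.resolve(symbol)
            return True
        except SymbolNotInCatalogError:
            return False


@dataclass(frozen=True)
class CatalogConfig:
    """Inhibition-call configuration: a gene is a positive target when its
    minimum pooled K_D/IC50 is ≤ ``inhibition_threshold_nM``."""

    inhibition_threshold_nM: float = 100.0

    def __post_init__(self) -> None:
        if not self.inhibition_threshold_nM > 0:
            raise CatalogError("inhibition threshold must be strictly positive")


@dataclass(frozen=True)
class TargetCatalog:
    """A validated set of target genes plus the derived nested gene sets."""

    genes: tuple[TargetGene, ...]
    aliases: AliasMap = field(compare=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        symbols = [g.symbol for g in self.genes]
        dupes = {s for s in symbols if symbols.count(s) > 1}
        if dupes:
            raise CatalogError(f"duplicate gene symbols in catalog: {sorted(dupes)}")
        if not self.genes:
            raise CatalogError("catalog contains no genes")
        if self.aliases is None:
            known = {a: c for a, c in DEFAULT_ALIASES.items() if c in set(symbols)}
            object.__setattr__(self, "aliases", AliasMap(symbols, known))

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, symbol: str) -> TargetGene:
        for g in self.genes:
            if g.symbol == symbol:
                return g
        raise SymbolNotInCatalogError(symbol)

    @property
    def symbols(self) -> frozenset[str]:
        return frozenset(g.symbol for g in self.genes)

    def gene_sets(self) -> GeneSetCatalog:
        return build_gene_sets(self.genes)

    def normalize(self, symbol: str) -> str:
        return normalize_gene_symbol(symbol, self.aliases)

    def not_confirmed_set(self) -> frozenset[str]:
        """Genes whose inhibition later assays failed to confirm."""
        return frozenset(
            g.symbol for g in self.genes if g.inhibition_confirmed == "not_confirmed"
        )


def normalize_gene_symbol(symbol: str, aliases: AliasMap) -> str:
    """Resolve ``symbol`` (case-insensitive, trimmed) to its canonical HUGO
    symbol, following the alias map; unknown symbols raise
    :class:`SymbolNotInCatalogError` naming the offending text."""
    return aliases.resolve(symbol)


def build_gene_sets(genes: Iterable[TargetGene]) -> GeneSetCatalog:
    """Derive the nested full/achievable/angiogenesis/extended sets from
    per-gene flags. The extended set is the clinically-achievable set plus
    every angiogenesis gene not already in it."""
    genes = list(genes)
    full = frozenset(g.symbol for g in genes)
    achievable = frozenset(g.symbol for g in genes if g.clinically_achievable)
    angio = frozenset(g.symbol for g in genes if g.angiogenesis)
    extended = achievable | (angio - achievable)
    return GeneSetCatalog(full, achievable, angio, extended)


def classify_inhibition_status(
    gene: TargetGene, config: CatalogConfig = CatalogConfig()
) -> str:
    """``inhibited`` iff the minimum pooled affinity value is ≤ threshold;
    ``unknown`` when no measurement carries a value."""
    lowest = gene.min_affinity()
    if lowest is None:
        return "unknown"
    return "inhibited" if lowest <= config.inhibition_threshold_nM else "not_inhibited"


_CATALOG_COLUMNS = (
    "symbol",
    "protein_name",
    "clinically_achievable",
    "angiogenesis",
    "inhibition_confirmed",
    "kd_nM",
    "ic50_nM",
)


def _parse_bool(text: str, where: str) -> bool:
    t = text.strip().lower()
    if t in ("true", "yes", "1"):
        return True
    if t in ("false", "no", "0", ""):
        return False
    raise CatalogError(f"{where}: cannot parse boolean {text!r}")


def _parse_affinity(text: str, kind: str, where: str) -> AffinityMeasurement | None:
    t = text.strip()
    if not t:
        return None
    try:
        value = float(t)
    except ValueError as exc:
        raise CatalogError(f"{where}: bad {kind} value {text!r}") from exc
    return AffinityMeasurement(kind=kind, value=value)


def _gene_from_fields(fields: Mapping[str, str], where: str) -> TargetGene:
    affinities = []
    for column, kind in (("kd_nM", "KD"), ("ic50_nM", "IC50")):
        m = _parse_affinity(fields.get(column, ""), kind, where)
        if m is not None:
            affinities.append(m)
    status = fields.get("inhibition_confirmed", "unknown").strip() or "unknown"
    try:
        return TargetGene(
            symbol=fields["symbol"].strip().upper(),
            protein_name=fields.get("protein_name", "").strip(),
            affinities=tuple(affinities),
            clinically_achievable=_parse_bool(
                fields.get("clinically_achievable", ""), where
            ),
            angiogenesis=_parse_bool(fields.get("angiogenesis", ""), where),
            inhibition_confirmed=status,
        )
    except CatalogError as exc:
        raise CatalogError(f"{where}: {exc}") from exc


def load_catalog(path: str | Path) -> TargetCatalog:
    """Load a target catalog from TSV (documented header) or JSON.

    TSV columns: ``symbol protein_name clinically_achievable angiogenesis
    inhibition_confirmed kd_nM ic50_nM`` (affinity columns may be blank).
    JSON: a list of objects with the same field names.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise CatalogError(f"{path}: catalog file is empty")
    if path.suffix.lower() == ".json":
        records = json.loads(text)
        if not isinstance(records, list) or not records:
            raise CatalogError(f"{path}: JSON catalog must be a non-empty list")
        genes = [
            _gene_from_fields(
                {k: str(v) if v is not None else "" for k, v in rec.items()},
                f"{path}: record {i}",
            )
            for i, rec in enumerate(records)
        ]
        return TargetCatalog(tuple(genes))

    lines = text.splitlines()
    header = lines[0].rstrip("\n").split("\t")
    missing = [c for c in ("symbol",) if c not in header]
    if missing:
        raise CatalogError(f"{path}: header missing columns {missing}; got {header}")
    genes = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) > len(header):
            raise CatalogError(
                f"{path}:{lineno}: expected ≤{len(header)} columns, got {len(cells)}"
            )
        cells += [""] * (len(header) - len(cells))  # trailing blanks may be omitted
        genes.append(_gene_from_fields(dict(zip(header, cells)), f"{path}:{lineno}"))
    if not genes:
        raise CatalogError(f"{path}: catalog has a header but no gene rows")
    return TargetCatalog(tuple(genes))


def load_packaged_catalog() -> TargetCatalog:
    """The packaged 46-gene regorafenib target catalog."""
    with resources.as_file(
        resources.files("tka.data").joinpath("table1_catalog.tsv")
    ) as p:
        return load_catalog(p)
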