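"""Domain types and ingestion for non-synonymous SNV audit.

A variant is one observed single-nucleotide change (multi-allelic positions
are separate records sharing a site key). Genomic sites are classified into
four mutually exclusive groups from the clinical-significance terms of all
variants observed at the site:

* ``pathogenic`` — pathogenic evidence at the site, no benign evidence;
* ``benign``     — benign evidence, no pathogenic evidence;
* ``both``       — evidence of both kinds (different alleles, typically);
* ``other``      — neither kind of evidence.

Independently, HGMD-style class codes flag disease-causing mutations (DM).
Prediction tools contribute rank scores in [0, 1] (a raw score transformed
to its quantile rank over a reference collection); a score above the tool's
cutoff is a pathogenic call.

Coordinates are 1-based and fully closed (VCF convention). Ancestral-allele
calls carry an explicit confidence; 1000 Genomes-style strings encode
confidence by case (uppercase = high) and are mapped on ingestion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TOOLS",
    "SITE_GROUPS",
    "HGMD_CLASSES",
    "HGMD_DISEASE_CLASSES",
    "DEFAULT_TERM_MAP",
    "NUCLEOTIDES",
    "AncestralCall",
    "VariantRecord",
    "ToolScorePanel",
    "ConservationScores",
    "SiteAnnotation",
    "ParsedVariant",
    "ParseResult",
    "RowError",
    "ConfigurationError",
    "parse_variant_table",
    "write_variant_table",
    "classify_site",
    "annotate_sites",
    "call_tool",
    "flag_back_mutation",
]

#: The fixed panel of 12 prediction tools whose rank scores are audited.
TOOLS: tuple[str, ...] = (
    "SIFT",
    "PROVEAN",
    "MutationTaster",
    "FATHMM-MKL",
    "FATHMM-XF",
    "FATHMM",
    "MetaSVM",
    "MetaLR",
    "PolyPhen-2",
    "MutationAssessor",
    "CADD",
    "DANN",
)

SITE_GROUPS: tuple[str, ...] = ("pathogenic", "benign", "both", "other")

#: HGMD class vocabulary. DM = disease-causing mutation; DM? = questioned;
#: DP = disease-associated polymorphism; DFP = DP with functional evidence;
#: FP = in vitro/in vivo functional polymorphism; none = unannotated.
HGMD_CLASSES: tuple[str, ...] = ("DM", "DM?", "DP", "DFP", "FP", "none")

#: The disease-relevant subset (everything but "none").
HGMD_DISEASE_CLASSES: frozenset[str] = frozenset({"DM", "DM?", "DP", "DFP", "FP"})

NUCLEOTIDES: tuple[str, ...] = ("A", "C", "G", "T")

CONSERVATION_CLADES: tuple[str, ...] = ("vertebrate", "mammal", "primate")

#: Default mapping of ClinVar-style terms to evidence classes. Terms absent
#: from the map are treated as "neither" (with a logged warning).
DEFAULT_TERM_MAP: dict[str, str] = {
    "Pathogenic": "pathogenic",
    "Likely pathogenic": "pathogenic",
    "Pathogenic/Likely pathogenic": "pathogenic",
    "Benign": "benign",
    "Likely benign": "benign",
    "Benign/Likely benign": "benign",
    "Uncertain significance": "neither",
    "risk factor": "neither",
    "Association": "neither",
    "association": "neither",
    "Protective": "neither",
    "protective": "neither",
    "drug response": "neither",
    "not provided": "neither",
    "other": "neither",
}


class ConfigurationError(ValueError):
    """A configuration problem (missing column, unknown tool, bad cutoff)."""


@dataclass(frozen=True)
class AncestralCall:
    """An inferred ancestral allele with its call confidence."""

    allele: str
    confidence: str  # "high" or "low"

    def __post_init__(self) -> None:
        if self.allele not in NUCLEOTIDES:
            raise ValueError(f"ancestral allele {self.allele!r} is not a nucleotide")
        if self.confidence not in ("high", "low"):
            raise ValueError(f"confidence must be 'high' or 'low', got {self.confidence!r}")

    @classmethod
    def from_string(cls, text: str) -> "AncestralCall | None":
        """Parse a 1000G-style call: uppercase = high confidence, lowercase = low."""
        text = text.strip()
        if not text or text in (".", "-", "N", "n"):
            return None
        if text.upper() not in NUCLEOTIDES:
            return None
        return cls(text.upper(), "high" if text.isupper() else "low")


@dataclass(frozen=True)
class VariantRecord:
    """One observed non-synonymous SNV."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    hgvs: str = ""
    clinvar_terms: tuple[str, ...] = ()
    hgmd_class: str = "none"
    ancestral: AncestralCall | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in NUCLEOTIDES:
            raise ValueError(f"ref {self.ref!r} is not a nucleotide")
        if self.alt not in NUCLEOTIDES:
            raise ValueError(f"alt {self.alt!r} is not a nucleotide")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.hgmd_class not in HGMD_CLASSES:
            raise ValueError(f"unknown HGMD class {self.hgmd_class!r}")

    @property
    def site_key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass(frozen=True)
class ToolScorePanel:
    """Rank scores in [0, 1] for the 12-tool panel; absent tools are missing."""

    scores: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tool, score in self.scores.items():
            if tool not in TOOLS:
                raise ValueError(f"unknown tool {tool!r}")
            if not (0.0 <= score <= 1.0):
                raise ValueError(f"{tool} rank score {score} outside [0, 1]")

    def get(self, tool: str) -> float | None:
        return self.scores.get(tool)


@dataclass(frozen=True)
class ConservationScores:
    """Per-clade phastCons (in [0,1]) and phyloP (unbounded) scores.

    phyloP sign encodes direction: positive = conservation, negative =
    acceleration. Missing clades are simply absent from the mappings.
    """

    phastcons: Mapping[str, float] = field(default_factory=dict)
    phylop: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for clade, value in self.phastcons.items():
            if clade not in CONSERVATION_CLADES:
                raise ValueError(f"unknown clade {clade!r}")
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"phastCons[{clade}] = {value} outside [0, 1]")
        for clade in self.phylop:
            if clade not in CONSERVATION_CLADES:
                raise ValueError(f"unknown clade {clade!r}")


@dataclass(frozen=True)
class SiteAnnotation:
    """A genomic site with its four-group class, DM flag and conservation."""

    chrom: str
    pos: int
    group: str
    is_dm: bool = False
    conservation: ConservationScores = field(default_factory=ConservationScores)

    def __post_init__(self) -> None:
        if self.group not in SITE_GROUPS:
            raise ValueError(f"site group must be one of {SITE_GROUPS}, got {self.group!r}")


@dataclass(frozen=True)
class ParsedVariant:
    """One parsed row: the variant, its score panel and site-level extras."""

    record: VariantRecord
    scores: ToolScorePanel = field(default_factory=ToolScorePanel)
    conservation: ConservationScores = field(default_factory=ConservationScores)
    nondegenerate: bool | None = None


@dataclass(frozen=True)
class RowError:
    row_index: int  # 0-based data-row index
    message: str


@dataclass
class ParseResult:
    variants: list[ParsedVariant]
    errors: list[RowError]

    def raise_on_errors(self) -> "ParseResult":
        if self.errors:
            head = "; ".join(f"row {e.row_index}: {e.message}" for e in self.errors[:5])
            raise ValueError(f"{len(self.errors)} malformed rows ({head} ...)")
        return self


_MANDATORY_COLUMNS = ("chrom", "pos", "ref", "alt", "gene")
_MISSING_TOKENS = ("", ".", "-", "NA", "nan")

_PHASTCONS_COLUMNS = {c: f"phastcons_{c}" for c in CONSERVATION_CLADES}
_PHYLOP_COLUMNS = {c: f"phylop_{c}" for c in CONSERVATION_CLADES}


def _is_missing(token: object) -> bool:
    return token is None or (isinstance(token, float) and pd.isna(token)) or str(token).strip() in _MISSING_TOKENS


def _parse_terms(token: object) -> tuple[str, ...]:
    if _is_missing(token):
        return ()
    return tuple(t.strip() for t in str(token).split(";") if t.strip())


def parse_variant_table(
    path: str | Path,
    *,
    normalize_chrom: bool = False,
) -> ParseResult:
    """Read a tab-separated variant table into typed records.

    The table must carry ``chrom, pos, ref, alt, gene`` and may carry
    ``hgvs, clinvar, hgmd_class, ancestral, nondegenerate``, per-clade
    conservation columns (``phastcons_vertebrate`` ...), and one column per
    tool named exactly as in :data:`TOOLS`. Missing values are ``.`` or
    empty. Rows with unparseable coordinates, malformed alleles, or rank
    scores outside [0, 1] are collected as :class:`RowError` (reported, not
    silently dropped).

    Parameters
    ----------
    path : the TSV file.
    normalize_chrom : strip a leading ``chr`` from chromosome names.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"variant table lacks mandatory column(s): {', '.join(missing)}")

    tool_columns = [t for t in TOOLS if t in df.columns]
    variants: list[ParsedVariant] = []
    errors: list[RowError] = []

    for i, row in enumerate(df.itertuples(index=False)):
        row_map = dict(zip(df.columns, row))
        try:
            pos = int(str(row_map["pos"]))
        except ValueError:
            errors.append(RowError(i, f"unparseable coordinate {row_map['pos']!r}"))
            continue
        chrom = str(row_map["chrom"]).strip()
        if normalize_chrom and chrom.lower().startswith("chr"):
            chrom = chrom[3:]
        try:
            record = VariantRecord(
                chrom=chrom,
                pos=pos,
                ref=str(row_map["ref"]).strip().upper(),
                alt=str(row_map["alt"]).strip().upper(),
                gene=str(row_map["gene"]).strip(),
                hgvs="" if _is_missing(row_map.get("hgvs")) else str(row_map["hgvs"]).strip(),
                clinvar_terms=_parse_terms(row_map.get("clinvar")),
                hgmd_class=(
                    "none"
                    if _is_missing(row_map.get("hgmd_class"))
                    else str(row_map["hgmd_class"]).strip()
                ),
                ancestral=AncestralCall.from_string(str(row_map.get("ancestral", "."))),
            )
            scores: dict[str, float] = {}
            for tool in tool_columns:
                token = row_map[tool]
                if _is_missing(token):
                    continue
                scores[tool] = float(token)
            panel = ToolScorePanel(scores)
            phastcons: dict[str, float] = {}
            phylop: dict[str, float] = {}
            for clade, col in _PHASTCONS_COLUMNS.items():
                if col in row_map and not _is_missing(row_map[col]):
                    phastcons[clade] = float(row_map[col])
            for clade, col in _PHYLOP_COLUMNS.items():
                if col in row_map and not _is_missing(row_map[col]):
                    phylop[clade] = float(row_map[col])
            conservation = ConservationScores(phastcons, phylop)
            nondeg_token = row_map.get("nondegenerate")
            nondegenerate = None if _is_missing(nondeg_token) else str(nondeg_token).strip() in ("1", "true", "True")
        except ValueError as exc:
            errors.append(RowError(i, str(exc)))
            continue
        variants.append(ParsedVariant(record, panel, conservation, nondegenerate))

    return ParseResult(variants, errors)


def write_variant_table(variants: Iterable[ParsedVariant], path: str | Path) -> None:
    """Write parsed variants back to the TSV schema read by :func:`parse_variant_table`."""
    rows = []
    for pv in variants:
        r = pv.record
        anc = "."
        if r.ancestral is not None:
            anc = r.ancestral.allele if r.ancestral.confidence == "high" else r.ancestral.allele.lower()
        row: dict[str, object] = {
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "gene": r.gene,
            "hgvs": r.hgvs or ".",
            "clinvar": ";".join(r.clinvar_terms) or ".",
            "hgmd_class": r.hgmd_class if r.hgmd_class != "none" else ".",
            "ancestral": anc,
            "nondegenerate": "." if pv.nondegenerate is None else int(pv.nondegenerate),
        }
        for clade, col in _PHASTCONS_COLUMNS.items():
            value = pv.conservation.phastcons.get(clade)
            row[col] = "." if value is None else repr(value)
        for clade, col in _PHYLOP_COLUMNS.items():
            value = pv.conservation.phylop.get(clade)
            row[col] = "." if value is None else repr(value)
        for tool in TOOLS:
            score = pv.scores.get(tool)
            row[tool] = "." if score is None else repr(score)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def classify_site(
    records_at_site: Sequence[VariantRecord],
    term_map: Mapping[str, str] | None = None,
) -> str:
    """Assign the four-group class to a site from its variants' ClinVar terms.

    ``pathogenic`` if at least one pathogenic-evidence term and no benign
    evidence across all records at the site; ``benign`` symmetrically;
    ``both`` with evidence of each kind; ``other`` with neither. Terms not
    in the map are logged and treated as no evidence. Order-invariant.
    """
    if not records_at_site:
        raise ValueError("classify_site requires at least one record")
    term_map = DEFAULT_TERM_MAP if term_map is None else term_map
    has_pathogenic = False
    has_benign = False
    for record in records_at_site:
        for term in record.clinvar_terms:
            evidence = term_map.get(term)
            if evidence is None:
                logger.warning("unknown clinical-significance term %r treated as neither", term)
                evidence = "neither"
            if evidence == "pathogenic":
                has_pathogenic = True
            elif evidence == "benign":
                has_benign = True
    if has_pathogenic and has_benign:
        return "both"
    if has_pathogenic:
        return "pathogenic"
    if has_benign:
        return "benign"
    return "other"


def annotate_sites(
    variants: Sequence[ParsedVariant],
    term_map: Mapping[str, str] | None = None,
) -> dict[tuple[str, int], SiteAnnotation]:
    """Group variants by site and build :class:`SiteAnnotation` for each.

    The DM flag is set when any variant at the site carries HGMD class
    ``DM``; conservation is taken from the first record at the site (per
    site it is a property of the position, so records agree by schema).
    """
    by_site: dict[tuple[str, int], list[ParsedVariant]] = {}
    for pv in variants:
        by_site.setdefault(pv.record.site_key, []).append(pv)
    annotations: dict[tuple[str, int], SiteAnnotation] = {}
    for key, group_variants in by_site.items():
        group = classify_site([pv.record for pv in group_variants], term_map)
        is_dm = any(pv.record.hgmd_class == "DM" for pv in group_variants)
        annotations[key] = SiteAnnotation(
            chrom=key[0],
            pos=key[1],
            group=group,
            is_dm=is_dm,
            conservation=group_variants[0].conservation,
        )
    return annotations


def call_tool(
    score: float | None,
    tool: str,
    thresholds: Mapping[str, float] | None = None,
) -> str:
    """Binarize a rank score: pathogenic iff strictly above the tool's cutoff.

    All cutoffs default to 0.5 on the rank-score scale and may be overridden
    per tool. A missing score propagates as ``"missing"``.
    """
    if tool not in TOOLS:
        raise ConfigurationError(f"unknown tool {tool!r}")
    if score is None:
        return "missing"
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"rank score {score} outside [0, 1]")
    cutoff = 0.5 if thresholds is None else thresholds.get(tool, 0.5)
    if not (0.0 <= cutoff <= 1.0):
        raise ConfigurationError(f"cutoff {cutoff} for {tool} outside [0, 1]")
    return "pathogenic" if score > cutoff else "benign"


def flag_back_mutation(v: VariantRecord, *, require_high_confidence: bool = True) -> bool:
    """True iff the variant restores the inferred ancestral nucleotide.

    Requires an ancestral call whose allele equals the alternative allele
    and differs from the reference (the reference is the derived state).
    Low-confidence calls count only when ``require_high_confidence`` is off;
    an absent call is never a back mutation.
    """
    anc = v.ancestral
    if anc is None:
        return False
    if require_high_confidence and anc.confidence != "high":
        return False
    return v.alt == anc.allele and v.ref != anc.allele


def normalize_variant(v: VariantRecord, *, strip_chr: bool = True) -> VariantRecord:
    """Return a copy with the chromosome name normalized (``chr`` prefix removed)."""
    chrom = v.chrom[3:] if strip_chr and v.chrom.lower().startswith("chr") else v.chrom
    return replace(v, chrom=chrom)
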