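"""Conservation-stratified analysis of prediction errors and back mutations.

Prediction tools lean heavily on evolutionary conservation, so their errors
are not uniform: benign variants at highly conserved positions attract
false-positive calls, and pathogenic variants at weakly conserved positions
attract false negatives. This module quantifies that excess with a Pearson
chi-squared test of the error group against the background of all annotated
positions of the same truth class, stratified at a phastCons cutoff
(default 0.5, vertebrate clade).

It also reports pathogenic "back mutations" — variants whose alternative
allele restores the inferred ancestral nucleotide yet carry pathogenic
annotation — a reminder that the derived allele can be the healthy state.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import pearson_chi2_2x2
from .variant_model import (
    DEFAULT_TERM_MAP,
    HGMD_DISEASE_CLASSES,
    ParsedVariant,
    ParseResult,
    flag_back_mutation,
    parse_variant_table,
)

__all__ = [
    "EnrichmentTest",
    "bin_conservation",
    "significance_stars",
    "error_conservation_profile",
    "conservation_error_table",
    "phylop_sign_summary",
    "back_mutation_report",
    "load_back_mutation_catalog",
]


@dataclass(frozen=True)
class EnrichmentTest:
    """A 2x2 enrichment of an error group against its background."""

    group_count: int
    group_total: int
    background_count: int
    background_total: int
    chi2: float
    p: float
    stars: str

    def __post_init__(self) -> None:
        if self.group_count > self.group_total or self.background_count > self.background_total:
            raise ValueError("counts cannot exceed totals")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must be a probability")

    @property
    def proportion_group(self) -> float | None:
        return self.group_count / self.group_total if self.group_total else None

    @property
    def proportion_background(self) -> float | None:
        return self.background_count / self.background_total if self.background_total else None


def bin_conservation(score: float | None, cutoff: float = 0.5) -> str | None:
    """Bin a phastCons score as "high" (>= cutoff) or "low"; missing propagates."""
    if not (0.0 < cutoff < 1.0):
        raise ValueError(f"cutoff must lie in (0, 1), got {cutoff}")
    if score is None or (isinstance(score, float) and np.isnan(score)):
        return None
    return "high" if score >= cutoff else "low"


def significance_stars(p: float) -> str:
    """Star code for a p-value: * p<0.05, ** p<1e-5, *** p<1e-10."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if p < 1e-10:
        return "***"
    if p < 1e-5:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def error_conservation_profile(
    calls: Sequence[str | None],
    labels: Sequence[str],
    conservation: Sequence[float | None],
    direction: str,
    *,
    cutoff: float = 0.5,
) -> EnrichmentTest | None:
    """Conservation enrichment of one tool's errors (one bar of the profile).

    ``direction="FP-at-high"``: among benign-labeled variants, the error
    group is those falsely called pathogenic; counted is high conservation.
    ``direction="FN-at-low"``: among pathogenic-labeled variants, the group
    is those falsely called benign; counted is low conservation. The
    background is all positions of the same truth class (error group
    included), so a group that coincides with its background gives chi2 = 0
    and p = 1 exactly. Positions with missing conservation are excluded
    from group and background alike. Returns None when the error group is
    empty.
    """
    if direction not in ("FP-at-high", "FN-at-low"):
        raise ValueError(f"unknown direction {direction!r}")
    if not (len(calls) == len(labels) == len(conservation)):
        raise ValueError("calls, labels and conservation must align")
    truth_class = "benign" if direction == "FP-at-high" else "pathogenic"
    error_call = "pathogenic" if direction == "FP-at-high" else "benign"
    counted_bin = "high" if direction == "FP-at-high" else "low"

    group_count = group_total = bg_count = bg_total = 0
    for call, label, cons in zip(calls, labels, conservation):
        if label != truth_class:
            continue
        conservation_bin = bin_conservation(cons, cutoff)
        if conservation_bin is None:
            continue
        bg_total += 1
        if conservation_bin == counted_bin:
            bg_count += 1
        if call == error_call:
            group_total += 1
            if conservation_bin == counted_bin:
                group_count += 1

    if group_total == 0:
        return None
    chi2, p = pearson_chi2_2x2(
        [
            [group_count, group_total - group_count],
            [bg_count, bg_total - bg_count],
        ]
    )
    return EnrichmentTest(
        group_count=group_count,
        group_total=group_total,
        background_count=bg_count,
        background_total=bg_total,
        chi2=chi2,
        p=p,
        stars=significance_stars(p),
    )


def conservation_error_table(
    calls_by_tool: Mapping[str, Sequence[str | None]],
    labels_by_arm: Mapping[str, Sequence[str]],
    conservation: Sequence[float | None],
    *,
    cutoff: float = 0.5,
) -> pd.DataFrame:
    """Per-tool enrichment table across analysis arms.

    ``labels_by_arm`` maps an arm name (e.g. "clinvar", "hgmd_dm") to truth
    labels over the same variant vector; FP-at-high is computed on benign
    labels and FN-at-low on pathogenic labels for every (tool, arm) pair.
    Empty error groups appear as rows with missing statistics, so nothing
    is silently dropped.
    """
    rows = []
    for arm, labels in labels_by_arm.items():
        for tool, calls in calls_by_tool.items():
            for direction in ("FP-at-high", "FN-at-low"):
                test = error_conservation_profile(
                    calls, labels, conservation, direction, cutoff=cutoff
                )
                row: dict[str, object] = {"arm": arm, "tool": tool, "direction": direction}
                if test is None:
                    row.update(
                        group_count=0, group_total=0, proportion_group=np.nan,
                        background_count=np.nan, background_total=np.nan,
                        proportion_background=np.nan, chi2=np.nan, p=np.nan, stars="",
                    )
                else:
                    row.update(
                        group_count=test.group_count,
                        group_total=test.group_total,
                        proportion_group=test.proportion_group,
                        background_count=test.background_count,
                        background_total=test.background_total,
                        proportion_background=test.proportion_background,
                        chi2=test.chi2,
                        p=test.p,
                        stars=test.stars,
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def phylop_sign_summary(
    variants: Sequence[ParsedVariant],
    groups: Mapping[tuple[str, int], str],
) -> pd.DataFrame:
    """Descriptive per-clade phyloP summary by site group.

    Counts positive (conserved) and negative (accelerated) scores and
    reports location/scale per clade and group; no hypothesis test is
    attached to these panels.
    """
    rows = []
    for pv in variants:
        group = groups.get(pv.record.site_key)
        if group is None:
            continue
        for clade, value in pv.conservation.phylop.items():
            rows.append({"group": group, "clade": clade, "phylop": value})
    if not rows:
        return pd.DataFrame(
            columns=["group", "clade", "n", "n_positive", "n_negative", "mean", "median", "sd"]
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["group", "clade"])["phylop"]
        .agg(
            n="size",
            n_positive=lambda s: int((s > 0).sum()),
            n_negative=lambda s: int((s < 0).sum()),
            mean="mean",
            median="median",
            sd="std",
        )
        .reset_index()
    )
    return out


def back_mutation_report(
    variants: Iterable[ParsedVariant],
    *,
    term_map: Mapping[str, str] | None = None,
    hgmd_classes: frozenset[str] | set[str] = HGMD_DISEASE_CLASSES,
    require_high_confidence: bool = True,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Tabulate pathogenic variants that revert to the ancestral allele.

    A variant qualifies when it is a back mutation (alt restores the
    ancestral call) and is assigned pathogenic by either annotation source:
    any ClinVar pathogenic-evidence term on the record (co-occurring benign
    terms do not disqualify), or an HGMD class in ``hgmd_classes`` (default:
    every disease-relevant class; pass ``{"DM"}`` to restrict).

    Returns the per-variant table and a summary with ``n_variants`` and
    ``n_genes`` (unique gene symbols).
    """
    term_map = DEFAULT_TERM_MAP if term_map is None else term_map
    rows = []
    for pv in variants:
        r = pv.record
        if not flag_back_mutation(r, require_high_confidence=require_high_confidence):
            continue
        clinvar_pathogenic = any(term_map.get(t) == "pathogenic" for t in r.clinvar_terms)
        hgmd_hit = r.hgmd_class in hgmd_classes
        if not (clinvar_pathogenic or hgmd_hit):
            continue
        rows.append(
            {
                "gene": r.gene,
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "hgvs": r.hgvs,
                "clinvar": ";".join(r.clinvar_terms),
                "hgmd_class": r.hgmd_class,
                "ancestral": r.ancestral.allele if r.ancestral else "",
                "clinvar_pathogenic": clinvar_pathogenic,
                "hgmd_hit": hgmd_hit,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene", "chrom", "pos", "ref", "alt", "hgvs", "clinvar",
            "hgmd_class", "ancestral", "clinvar_pathogenic", "hgmd_hit",
        ],
    )
    summary = {"n_variants": len(table), "n_genes": int(table["gene"].nunique())}
    return table, summary


def load_back_mutation_catalog() -> ParseResult:
    """Load the bundled catalog of pathogenic derived-to-ancestral mutations.

    The catalog lists 35 non-synonymous variants (33 genes) whose
    alternative allele restores the high-confidence ancestral state yet
    which carry pathogenic annotation from ClinVar and/or an HGMD disease
    class. Gene symbols, transcript HGVS strings, alleles and annotations
    are the published values; genomic coordinates are synthetic placeholders
    (the catalog is keyed by gene and transcript change, not position).
    """
    ref = resources.files("snvaudit.data").joinpath("pathogenic_back_mutations.tsv")
    with resources.as_file(ref) as path:
        return parse_variant_table(path)
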