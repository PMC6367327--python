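"""Gene-level characterization of disease susceptibility.

Pathogenic variants are not spread uniformly over genes. This module
aggregates variants per gene and relates pathogenic burden to gene-level
properties: polymorphic-site rate per kilobase of exon, expression
abundance (maximum over tissues) and tissue specificity (information
content), and ranked protein-protein interaction (PPI) degree. Gene groups
defined by pathogenic-site counts are compared on these properties with
two-sample Kolmogorov-Smirnov tests on their empirical distributions.

Susceptibility classes:

* **disease-sensitive** — more than 30% of the gene's annotated variant
  sites are pathogenic;
* **disease-tolerant** — no pathogenic or DM annotation at all despite more
  than fifty polymorphic sites;
* **other** — everything else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .stats import ks_test, pearson_correlation
from .variant_model import ParsedVariant, annotate_sites

__all__ = [
    "ExpressionProfile",
    "GeneSummary",
    "snv_rate",
    "classify_susceptibility",
    "expression_max",
    "tissue_specificity",
    "ranked_degree",
    "ecdf_compare",
    "group_by_pathogenic_count",
    "build_gene_summaries",
    "gene_group_comparisons",
    "length_rate_correlation",
]


@dataclass(frozen=True)
class ExpressionProfile:
    """Non-negative expression abundances over a panel of tissues (53 by default)."""

    values: tuple[float, ...]
    tissues: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.tissues and len(self.tissues) != len(self.values):
            raise ValueError("tissue names must align with values")
        if any(v < 0 for v in self.values):
            raise ValueError("expression abundances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class GeneSummary:
    """Per-gene aggregation used throughout the gene-level analyses."""

    gene: str
    exon_length_bp: int
    n_polymorphic: int = 0
    n_pathogenic_sites: int = 0
    n_dm_sites: int = 0
    n_annotated_sites: int = 0
    expression: ExpressionProfile | None = None
    ppi_degree: int | None = None

    def __post_init__(self) -> None:
        if self.exon_length_bp < 1:
            raise ValueError("exon_length_bp must be >= 1")
        for name in ("n_polymorphic", "n_pathogenic_sites", "n_dm_sites", "n_annotated_sites"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def snv_rate(g: GeneSummary) -> float:
    """Polymorphic-site occurrence rate per kilobase of exon."""
    return 1000.0 * g.n_polymorphic / g.exon_length_bp


def classify_susceptibility(
    g: GeneSummary,
    *,
    sens_prop: float = 0.30,
    tol_min_poly: int = 50,
) -> str:
    """Classify a gene as disease_sensitive / disease_tolerant / other.

    Disease-sensitive: strictly more than ``sens_prop`` of the gene's
    annotated variant sites (ClinVar + HGMD union) are pathogenic/DM.
    Disease-tolerant: zero pathogenic and zero DM sites with strictly more
    than ``tol_min_poly`` polymorphic sites. A zero annotated-site
    denominator leaves the proportion undefined and the gene "other".
    """
    if g.n_annotated_sites > 0:
        # pathogenic burden: sites pathogenic by either source, capped by annotated
        burden = min(max(g.n_pathogenic_sites, g.n_dm_sites), g.n_annotated_sites)
        if burden / g.n_annotated_sites > sens_prop:
            return "disease_sensitive"
    if g.n_pathogenic_sites == 0 and g.n_dm_sites == 0 and g.n_polymorphic > tol_min_poly:
        return "disease_tolerant"
    return "other"


def expression_max(e: ExpressionProfile) -> float | None:
    """Maximum abundance over tissues; None for an empty profile."""
    if e.n == 0:
        return None
    return max(e.values)


def tissue_specificity(e: ExpressionProfile) -> float | None:
    """Information content of the expression profile, in [0, log2 n].

    With p_i the share of total abundance in tissue i, the score is
    ``log2(n) + sum_i p_i * log2(p_i)`` (p log p taken as 0 at p = 0):
    0 for perfectly uniform expression, log2(n) for single-tissue
    expression. None when the total abundance is 0.
    """
    total = sum(e.values)
    if total <= 0 or e.n == 0:
        return None
    acc = 0.0
    for v in e.values:
        p = v / total
        if p > 0:
            acc += p * math.log2(p)
    return math.log2(e.n) + acc


def ranked_degree(degrees: Mapping[str, int | None]) -> dict[str, float | None]:
    """Rank fraction in (0, 1] of each gene's PPI degree over the universe.

    Ascending ranks with mean rank for ties, divided by the number of genes
    with a degree; genes with a missing degree get None and do not affect
    the ranking. Order-preserving: a higher degree never gets a lower rank.
    """
    genes = [g for g, d in degrees.items() if d is not None]
    if not genes:
        raise ValueError("no gene has a degree")
    values = np.array([degrees[g] for g in genes], dtype=float)
    ranks = rankdata(values, method="average") / len(genes)
    out: dict[str, float | None] = {g: None for g in degrees}
    out.update(dict(zip(genes, ranks.tolist())))
    return out


def ecdf_compare(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float] | None:
    """Two-sample two-sided KS comparison of empirical distributions.

    Returns (D, p); None when either group is empty after dropping NaNs.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        return None
    return ks_test(a, b)


def group_by_pathogenic_count(
    counts: Mapping[str, int],
    cuts: Sequence[int] = (0, 20),
) -> dict[int, set[str]]:
    """Nested gene groups by strict pathogenic-site count thresholds.

    Returns {cut: genes with count > cut}; with the default cuts these are
    the "n > 0" and "n > 20" groups, and the latter is always a subset of
    the former.
    """
    return {cut: {g for g, n in counts.items() if n > cut} for cut in cuts}


def build_gene_summaries(
    variants: Sequence[ParsedVariant],
    gene_table: pd.DataFrame,
    expression: pd.DataFrame | None = None,
    degrees: Mapping[str, int] | None = None,
    term_map: Mapping[str, str] | None = None,
) -> dict[str, GeneSummary]:
    """Aggregate parsed variants and side tables into per-gene summaries.

    ``gene_table`` needs columns ``gene, exon_length_bp, n_polymorphic``;
    ``expression`` is a genes x tissues matrix indexed by gene symbol.
    Site counts come from the four-group site classification: a site counts
    as pathogenic when its group is "pathogenic"; DM sites carry the HGMD
    flag; annotated sites are those in any of pathogenic/benign/both or DM.
    """
    site_annotations = annotate_sites(variants, term_map)
    gene_of_site: dict[tuple[str, int], str] = {}
    for pv in variants:
        gene_of_site.setdefault(pv.record.site_key, pv.record.gene)

    per_gene: dict[str, dict[str, int]] = {}
    for key, ann in site_annotations.items():
        gene = gene_of_site[key]
        counts = per_gene.setdefault(
            gene, {"pathogenic": 0, "dm": 0, "annotated": 0}
        )
        if ann.group == "pathogenic":
            counts["pathogenic"] += 1
        if ann.is_dm:
            counts["dm"] += 1
        if ann.group in ("pathogenic", "benign", "both") or ann.is_dm:
            counts["annotated"] += 1

    summaries: dict[str, GeneSummary] = {}
    for row in gene_table.itertuples(index=False):
        gene = str(row.gene)
        counts = per_gene.get(gene, {"pathogenic": 0, "dm": 0, "annotated": 0})
        profile = None
        if expression is not None and gene in expression.index:
            profile = ExpressionProfile(
                values=tuple(float(v) for v in expression.loc[gene].to_numpy()),
                tissues=tuple(str(c) for c in expression.columns),
            )
        degree = None
        if degrees is not None and gene in degrees:
            degree = int(degrees[gene])
        summaries[gene] = GeneSummary(
            gene=gene,
            exon_length_bp=int(row.exon_length_bp),
            n_polymorphic=int(row.n_polymorphic),
            n_pathogenic_sites=counts["pathogenic"],
            n_dm_sites=counts["dm"],
            n_annotated_sites=counts["annotated"],
            expression=profile,
            ppi_degree=degree,
        )
    return summaries


def _metric_vector(
    summaries: Mapping[str, GeneSummary],
    genes: Sequence[str],
    metric: str,
    rank_fractions: Mapping[str, float | None],
) -> np.ndarray:
    out = []
    for g in genes:
        s = summaries[g]
        if metric == "expression_max":
            v = expression_max(s.expression) if s.expression else None
        elif metric == "tissue_specificity":
            v = tissue_specificity(s.expression) if s.expression else None
        elif metric == "ranked_degree":
            v = rank_fractions.get(g)
        else:
            raise ValueError(f"unknown metric {metric!r}")
        if v is not None:
            out.append(v)
    return np.asarray(out, dtype=float)


def gene_group_comparisons(
    summaries: Mapping[str, GeneSummary],
    *,
    arm: str = "clinvar",
    cuts: Sequence[int] = (0, 20),
) -> pd.DataFrame:
    """KS comparisons of gene groups against the all-gene universe.

    ``arm`` selects the pathogenic-site counter: "clinvar" uses
    n_pathogenic_sites, "hgmd" uses n_dm_sites. For each cut c the group is
    genes with count > c; each group is compared to all genes on expression
    maximum, tissue specificity, and ranked PPI degree, and nested groups
    are compared to each other.
    """
    if arm == "clinvar":
        counts = {g: s.n_pathogenic_sites for g, s in summaries.items()}
    elif arm == "hgmd":
        counts = {g: s.n_dm_sites for g, s in summaries.items()}
    else:
        raise ValueError(f"unknown arm {arm!r}")
    groups = group_by_pathogenic_count(counts, cuts)
    rank_fractions = ranked_degree({g: s.ppi_degree for g, s in summaries.items()})
    universe = list(summaries)

    comparisons: list[tuple[str, Sequence[str], str, Sequence[str]]] = []
    for cut in cuts:
        comparisons.append((f"n>{cut}", sorted(groups[cut]), "all", universe))
    if len(cuts) == 2 and cuts[0] < cuts[1]:
        comparisons.append(
            (f"n>{cuts[1]}", sorted(groups[cuts[1]]), f"n>{cuts[0]}", sorted(groups[cuts[0]]))
        )

    rows = []
    for metric in ("expression_max", "tissue_specificity", "ranked_degree"):
        for name_a, genes_a, name_b, genes_b in comparisons:
            a = _metric_vector(summaries, genes_a, metric, rank_fractions)
            b = _metric_vector(summaries, genes_b, metric, rank_fractions)
            res = ecdf_compare(a, b) if a.size and b.size else None
            rows.append(
                {
                    "arm": arm,
                    "metric": metric,
                    "group_a": name_a,
                    "group_b": name_b,
                    "n_a": int(a.size),
                    "n_b": int(b.size),
                    "median_a": float(np.median(a)) if a.size else np.nan,
                    "median_b": float(np.median(b)) if b.size else np.nan,
                    "D": np.nan if res is None else res[0],
                    "p": np.nan if res is None else res[1],
                }
            )
    return pd.DataFrame(rows)


def length_rate_correlation(summaries: Mapping[str, GeneSummary]) -> tuple[float, float] | None:
    """Pearson correlation of log exon length vs log polymorphic count.

    Genes with zero polymorphic sites are excluded (log undefined).
    """
    lengths = []
    counts = []
    for s in summaries.values():
        if s.n_polymorphic > 0:
            lengths.append(math.log10(s.exon_length_bp))
            counts.append(math.log10(s.n_polymorphic))
    return pearson_correlation(lengths, counts)
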