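"""Gene-level aggregation, susceptibility classes, expression and degree."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from snvaudit.gene_level import (
    ExpressionProfile,
    GeneSummary,
    build_gene_summaries,
    classify_susceptibility,
    ecdf_compare,
    expression_max,
    gene_group_comparisons,
    group_by_pathogenic_count,
    length_rate_correlation,
    ranked_degree,
    snv_rate,
    tissue_specificity,
)
from snvaudit.variant_model import ParsedVariant, VariantRecord


def _summary(**kwargs) -> GeneSummary:
    defaults = dict(gene="G", exon_length_bp=1000)
    defaults.update(kwargs)
    return GeneSummary(**defaults)


class TestSnvRate:
    @pytest.mark.parametrize(
        "n_poly, length, expected",
        [(30, 1000, 30.0), (0, 1000, 0.0), (45, 1500, 30.0)],
    )
    def test_rate_per_kb(self, n_poly, length, expected):
        g = _summary(n_polymorphic=n_poly, exon_length_bp=length)
        assert snv_rate(g) == pytest.approx(expected)


class TestSusceptibility:
    def test_high_pathogenic_proportion_is_sensitive(self):
        g = _summary(n_pathogenic_sites=40, n_annotated_sites=100)
        assert classify_susceptibility(g) == "disease_sensitive"

    def test_no_pathogenic_with_many_polymorphisms_is_tolerant(self):
        g = _summary(n_polymorphic=60)
        assert classify_susceptibility(g) == "disease_tolerant"

    def test_boundaries_are_strict(self):
        # exactly 30% is not "> 30%"; exactly 50 polymorphic is not "> 50"
        assert classify_susceptibility(
            _summary(n_pathogenic_sites=30, n_annotated_sites=100)
        ) == "other"
        assert classify_susceptibility(_summary(n_polymorphic=50)) == "other"

    def test_zero_denominator_is_other(self):
        assert classify_susceptibility(_summary()) == "other"

    def test_dm_sites_block_tolerance(self):
        g = _summary(n_dm_sites=1, n_polymorphic=100)
        assert classify_susceptibility(g) == "other"


class TestExpression:
    def test_max_abundance(self):
        assert expression_max(ExpressionProfile((1.0, 5.0, 3.0))) == 5.0
        assert expression_max(ExpressionProfile((0.0, 0.0))) == 0.0
        assert expression_max(ExpressionProfile((7.0,))) == 7.0

    def test_uniform_profile_has_zero_specificity(self):
        e = ExpressionProfile(tuple([2.5] * 53))
        assert tissue_specificity(e) == pytest.approx(0.0, abs=1e-12)

    def test_single_tissue_reaches_log2_n(self):
        values = [0.0] * 53
        values[17] = 9.0
        assert tissue_specificity(ExpressionProfile(tuple(values))) == pytest.approx(
            math.log2(53), abs=1e-12
        )

    def test_half_split_hand_value(self):
        # n = 4, p = (1/2, 1/2, 0, 0): log2(4) + 2 * (1/2 log2 1/2) = 2 - 1 = 1
        e = ExpressionProfile((3.0, 3.0, 0.0, 0.0))
        assert tissue_specificity(e) == pytest.approx(1.0, abs=1e-12)

    def test_specificity_bounded_by_log2_n(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(2, 20))
            e = ExpressionProfile(tuple(rng.random(n)))
            s = tissue_specificity(e)
            assert -1e-12 <= s <= math.log2(n) + 1e-12

    def test_zero_total_is_missing(self):
        assert tissue_specificity(ExpressionProfile((0.0, 0.0))) is None

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            ExpressionProfile((1.0, -0.5))


class TestRankedDegree:
    def test_strict_ordering(self):
        ranks = ranked_degree({"a": 1, "b": 2, "c": 3})
        assert ranks == pytest.approx({"a": 1 / 3, "b": 2 / 3, "c": 1.0})

    def test_tie_convention_mean_rank(self):
        n = 4
        ranks = ranked_degree({g: 7 for g in "abcd"})
        assert all(v == pytest.approx((n + 1) / (2 * n)) for v in ranks.values())

    def test_missing_degree_gets_missing_rank(self):
        ranks = ranked_degree({"a": 5, "b": None})
        assert ranks["b"] is None
        assert ranks["a"] == 1.0

    def test_order_preserving(self):
        rng = np.random.default_rng(9)
        degrees = {f"g{i}": int(d) for i, d in enumerate(rng.integers(0, 50, 30))}
        ranks = ranked_degree(degrees)
        for a in degrees:
            for b in degrees:
                if degrees[a] <= degrees[b]:
                    assert ranks[a] <= ranks[b] + 1e-12


class TestEcdfCompare:
    def test_identical_and_disjoint(self):
        assert ecdf_compare([1, 2, 3], [1, 2, 3])[0] == 0.0
        assert ecdf_compare([1, 2, 3], [10, 11, 12])[0] == 1.0

    def test_empty_group_missing(self):
        assert ecdf_compare([], [1.0]) is None


class TestGrouping:
    def test_strict_thresholds_and_nesting(self):
        counts = {"a": 21, "b": 20, "c": 0, "d": 5}
        groups = group_by_pathogenic_count(counts)
        assert groups[0] == {"a", "b", "d"}
        assert groups[20] == {"a"}
        assert groups[20] <= groups[0]


class TestAggregation:
    @pytest.fixture()
    def toy_inputs(self):
        def pv(pos, gene, terms=(), hgmd="none"):
            return ParsedVariant(
                record=VariantRecord(
                    chrom="1", pos=pos, ref="A", alt="G", gene=gene,
                    clinvar_terms=terms, hgmd_class=hgmd,
                )
            )

        variants = [
            pv(1, "GA", ("Pathogenic",)),
            pv(2, "GA", ("Pathogenic",)),
            pv(3, "GA", ("Benign",)),
            pv(4, "GB", (), "DM"),
            pv(5, "GB", ("Benign",)),
            pv(6, "GC"),
        ]
        gene_table = pd.DataFrame(
            {"gene": ["GA", "GB", "GC"], "exon_length_bp": [1000, 2000, 500],
             "n_polymorphic": [30, 80, 10]}
        )
        expression = pd.DataFrame(
            [[1.0, 9.0], [5.0, 5.0], [0.0, 2.0]],
            index=pd.Index(["GA", "GB", "GC"], name="gene"),
            columns=["t1", "t2"],
        )
        degrees = {"GA": 10, "GB": 2, "GC": 2}
        return variants, gene_table, expression, degrees

    def test_site_counts_per_gene(self, toy_inputs):
        variants, gene_table, expression, degrees = toy_inputs
        summaries = build_gene_summaries(variants, gene_table, expression, degrees)
        ga = summaries["GA"]
        assert (ga.n_pathogenic_sites, ga.n_dm_sites, ga.n_annotated_sites) == (2, 0, 3)
        gb = summaries["GB"]
        assert (gb.n_pathogenic_sites, gb.n_dm_sites, gb.n_annotated_sites) == (0, 1, 2)
        gc = summaries["GC"]
        assert gc.n_annotated_sites == 0
        assert summaries["GA"].expression.values == (1.0, 9.0)
        assert summaries["GB"].ppi_degree == 2

    def test_group_comparison_table_covers_every_metric(self, toy_inputs):
        variants, gene_table, expression, degrees = toy_inputs
        summaries = build_gene_summaries(variants, gene_table, expression, degrees)
        df = gene_group_comparisons(summaries, arm="clinvar")
        assert set(df["metric"]) == {"expression_max", "tissue_specificity", "ranked_degree"}
        # nothing silently omitted: every configured comparison has a row
        assert len(df) == 9

    def test_length_rate_correlation_on_planted_cohort(self, small_bundle):
        """Polymorphic counts scale with exon length, so the log-log
        correlation is strongly positive."""
        genes = small_bundle.genes
        gene_table = genes.rename(columns={})
        summaries = {
            row.gene: GeneSummary(
                gene=row.gene, exon_length_bp=int(row.exon_length_bp),
                n_polymorphic=int(row.n_polymorphic),
            )
            for row in gene_table.itertuples(index=False)
        }
        r, p = length_rate_correlation(summaries)
        assert r > 0.5
        assert p < 1e-6
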