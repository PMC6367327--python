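"""Domain types, table ingestion, site classification, calls, back mutations."""

from __future__ import annotations

import itertools

import pytest

from snvaudit.variant_model import (
    DEFAULT_TERM_MAP,
    TOOLS,
    AncestralCall,
    ConfigurationError,
    ConservationScores,
    ParsedVariant,
    SiteAnnotation,
    ToolScorePanel,
    VariantRecord,
    annotate_sites,
    call_tool,
    classify_site,
    flag_back_mutation,
    parse_variant_table,
    write_variant_table,
)

HEADER = "chrom\tpos\tref\talt\tgene\tclinvar\thgmd_class\tancestral\tSIFT\tCADD\n"


def _write(tmp_path, body, header=HEADER):
    path = tmp_path / "variants.tsv"
    path.write_text(header + body)
    return path


def _record(**kwargs) -> VariantRecord:
    defaults = dict(chrom="1", pos=100, ref="A", alt="G", gene="GENE1")
    defaults.update(kwargs)
    return VariantRecord(**defaults)


class TestParsing:
    def test_well_formed_rows_fully_populated(self, tmp_path):
        path = _write(
            tmp_path,
            "1\t100\tA\tG\tBRCA1\tPathogenic\tDM\tG\t0.9\t0.8\n"
            "2\t200\tC\tT\tTP53\tBenign;Likely benign\t.\tc\t0.1\t.\n"
            "X\t300\tG\tA\tDMD\t.\tDFP\t.\t.\t0.55\n",
        )
        result = parse_variant_table(path)
        assert not result.errors
        assert len(result.variants) == 3
        first = result.variants[0]
        assert first.record.gene == "BRCA1"
        assert first.record.clinvar_terms == ("Pathogenic",)
        assert first.record.hgmd_class == "DM"
        assert first.record.ancestral == AncestralCall("G", "high")
        assert first.scores.get("SIFT") == 0.9
        second = result.variants[1]
        assert second.record.clinvar_terms == ("Benign", "Likely benign")
        assert second.record.ancestral == AncestralCall("C", "low")
        assert second.scores.get("CADD") is None  # "." encodes missing
        assert result.variants[2].record.ancestral is None

    def test_out_of_range_rank_score_is_row_error(self, tmp_path):
        path = _write(tmp_path, "1\t100\tA\tG\tG1\t.\t.\t.\t1.2\t0.5\n")
        result = parse_variant_table(path)
        assert len(result.variants) == 0
        assert len(result.errors) == 1
        assert result.errors[0].row_index == 0
        assert "outside [0, 1]" in result.errors[0].message

    def test_malformed_rows_collected_not_dropped_silently(self, tmp_path):
        path = _write(
            tmp_path,
            "1\tabc\tA\tG\tG1\t.\t.\t.\t0.5\t0.5\n"   # bad coordinate
            "1\t100\tA\tA\tG1\t.\t.\t.\t0.5\t0.5\n"   # ref == alt
            "1\t200\tZ\tG\tG1\t.\t.\t.\t0.5\t0.5\n"   # bad allele
            "1\t300\tA\tG\tG1\t.\t.\t.\t0.5\t0.5\n",  # fine
        )
        result = parse_variant_table(path)
        assert len(result.variants) == 1
        assert [e.row_index for e in result.errors] == [0, 1, 2]
        with pytest.raises(ValueError):
            result.raise_on_errors()

    def test_missing_mandatory_column_is_configuration_error(self, tmp_path):
        path = _write(tmp_path, "1\t100\tA\tG\n", header="chrom\tpos\tref\talt\n")
        with pytest.raises(ConfigurationError, match="gene"):
            parse_variant_table(path)

    def test_chromosome_normalization_option(self, tmp_path):
        path = _write(tmp_path, "chr7\t100\tA\tG\tG1\t.\t.\t.\t.\t.\n")
        assert parse_variant_table(path).variants[0].record.chrom == "chr7"
        assert parse_variant_table(path, normalize_chrom=True).variants[0].record.chrom == "7"

    def test_round_trip_preserves_every_field(self, tmp_path):
        variants = [
            ParsedVariant(
                record=_record(
                    clinvar_terms=("Pathogenic", "risk factor"),
                    hgmd_class="DM?",
                    ancestral=AncestralCall("G", "low"),
                    hgvs="c.100A>G",
                ),
                scores=ToolScorePanel({"SIFT": 0.123456, "DANN": 1.0}),
                conservation=ConservationScores(
                    phastcons={"vertebrate": 0.75}, phylop={"mammal": -1.25}
                ),
                nondegenerate=True,
            ),
            ParsedVariant(record=_record(pos=222, ref="C", alt="T")),
        ]
        path = tmp_path / "rt.tsv"
        write_variant_table(variants, path)
        back = parse_variant_table(path)
        assert not back.errors
        assert back.variants == variants


class TestSiteClassification:
    @pytest.mark.parametrize(
        "terms, expected",
        [
            (("Pathogenic",), "pathogenic"),
            (("Benign",), "benign"),
            ((), "other"),
            (("Uncertain significance",), "other"),
            (("Likely pathogenic",), "pathogenic"),
        ],
    )
    def test_single_record_classes(self, terms, expected):
        assert classify_site([_record(clinvar_terms=terms)]) == expected

    def test_pathogenic_and_benign_alleles_make_both(self):
        records = [
            _record(alt="G", clinvar_terms=("Pathogenic",)),
            _record(alt="T", clinvar_terms=("Benign",)),
        ]
        assert classify_site(records) == "both"

    def test_unknown_term_treated_as_no_evidence(self, caplog):
        assert classify_site([_record(clinvar_terms=("weird-new-term",))]) == "other"

    def test_permutation_invariant_and_total(self):
        records = [
            _record(alt="G", clinvar_terms=("Pathogenic",)),
            _record(alt="T", clinvar_terms=("Benign",)),
            _record(alt="C", clinvar_terms=()),
        ]
        groups = {classify_site(list(p)) for p in itertools.permutations(records)}
        assert groups == {"both"}
        # totality/exclusivity: every subset maps to exactly one valid group
        for r in range(1, 4):
            for combo in itertools.combinations(records, r):
                assert classify_site(list(combo)) in ("pathogenic", "benign", "both", "other")

    def test_annotate_sites_groups_multiallelic_records(self):
        variants = [
            ParsedVariant(record=_record(alt="G", clinvar_terms=("Pathogenic",))),
            ParsedVariant(record=_record(alt="T", hgmd_class="DM")),
            ParsedVariant(record=_record(pos=999, clinvar_terms=("Benign",))),
        ]
        annotations = annotate_sites(variants)
        assert annotations[("1", 100)].group == "pathogenic"
        assert annotations[("1", 100)].is_dm
        assert annotations[("1", 999)].group == "benign"
        assert not annotations[("1", 999)].is_dm


class TestToolCalls:
    def test_above_cutoff_is_pathogenic(self):
        assert call_tool(0.51, "CADD") == "pathogenic"

    def test_boundary_is_benign_strict_inequality(self):
        assert call_tool(0.5, "DANN") == "benign"

    def test_missing_propagates(self):
        assert call_tool(None, "SIFT") == "missing"

    def test_unknown_tool_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            call_tool(0.9, "NotATool")

    def test_per_tool_threshold_override(self):
        assert call_tool(0.6, "SIFT", {"SIFT": 0.7}) == "benign"
        assert call_tool(0.6, "CADD", {"SIFT": 0.7}) == "pathogenic"

    def test_monotone_in_score(self):
        for tool in TOOLS:
            calls = [call_tool(s, tool) for s in (0.0, 0.25, 0.5, 0.75, 1.0)]
            # once pathogenic, raising the score never reverts to benign
            seen_pathogenic = False
            for c in calls:
                if c == "pathogenic":
                    seen_pathogenic = True
                assert not (seen_pathogenic and c == "benign")


class TestBackMutation:
    def test_alt_restoring_ancestral_is_back_mutation(self):
        v = _record(ref="G", alt="A", ancestral=AncestralCall("A", "high"))
        assert flag_back_mutation(v)

    def test_derived_direction_is_not(self):
        v = _record(ref="A", alt="G", ancestral=AncestralCall("A", "high"))
        assert not flag_back_mutation(v)

    def test_absent_ancestral_is_not(self):
        assert not flag_back_mutation(_record())

    def test_low_confidence_calls_from_case_convention(self, tmp_path):
        # 1000G-style: lowercase = low confidence; 5-variant hand fixture
        path = _write(
            tmp_path,
            "1\t1\tG\tA\tG1\t.\t.\ta\t.\t.\n"   # low-conf back mutation
            "1\t2\tG\tA\tG1\t.\t.\tA\t.\t.\n"   # high-conf back mutation
            "1\t3\tA\tG\tG1\t.\t.\tA\t.\t.\n"   # derived direction
            "1\t4\tG\tA\tG1\t.\t.\t.\t.\t.\n"   # no call
            "1\t5\tG\tA\tG1\t.\t.\tg\t.\t.\n",  # ancestral == ref (low)
        )
        records = [pv.record for pv in parse_variant_table(path).variants]
        strict = [flag_back_mutation(v, require_high_confidence=True) for v in records]
        lax = [flag_back_mutation(v, require_high_confidence=False) for v in records]
        assert strict == [False, True, False, False, False]
        assert lax == [True, True, False, False, False]


class TestInvariants:
    def test_variant_record_validation(self):
        with pytest.raises(ValueError):
            _record(pos=0)
        with pytest.raises(ValueError):
            _record(ref="G", alt="G")
        with pytest.raises(ValueError):
            _record(hgmd_class="XX")

    def test_score_panel_bounds(self):
        with pytest.raises(ValueError):
            ToolScorePanel({"SIFT": 1.5})
        with pytest.raises(ValueError):
            ToolScorePanel({"NotATool": 0.5})

    def test_site_annotation_closed_vocabulary(self):
        with pytest.raises(ValueError):
            SiteAnnotation(chrom="1", pos=1, group="unknown")

    def test_term_map_covers_published_annotation_vocabulary(self):
        for term in ("Pathogenic", "Likely pathogenic", "Benign", "Likely benign",
                     "risk factor", "Association", "Protective"):
            assert term in DEFAULT_TERM_MAP
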