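"""Four-allele quartet statistics: max, coefficient of variation, comparisons."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snvaudit.site_stats import (
    assemble_quartet,
    compare_groups,
    quartet_cv,
    quartet_max,
    quartet_table_stats,
    stat_conservation_correlation,
)

ALTS = {"C": 0.8, "G": 0.9, "T": 0.7}


class TestAssembly:
    def test_default_gives_reference_score_zero(self):
        q = assemble_quartet(ALTS, ref="A")
        assert q.scores == {"A": 0.0, "C": 0.8, "G": 0.9, "T": 0.7}

    def test_mean_of_alts_convention(self):
        q = assemble_quartet(ALTS, ref="A", ref_convention="mean-of-alts")
        assert q.scores["A"] == pytest.approx(0.8)

    def test_exclude_convention_keeps_three_scores(self):
        q = assemble_quartet(ALTS, ref="A", ref_convention="exclude-and-rescale")
        assert set(q.scores) == {"C", "G", "T"}

    def test_incomplete_alt_scores_yield_no_quartet(self):
        assert assemble_quartet({"C": 0.8, "G": 0.9}, ref="A") is None
        assert assemble_quartet({"C": 0.8, "G": 0.9, "T": None}, ref="A") is None

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            assemble_quartet(ALTS, ref="A", ref_convention="bogus")


class TestMax:
    def test_takes_the_maximum(self):
        assert quartet_max(assemble_quartet(ALTS, ref="A")) == 0.9

    def test_all_equal(self):
        q = assemble_quartet({"C": 0.5, "G": 0.5, "T": 0.5}, ref="A",
                             ref_convention="mean-of-alts")
        assert quartet_max(q) == 0.5

    def test_invariant_to_nucleotide_relabeling(self):
        values = [0.8, 0.9, 0.7]
        results = set()
        for perm in itertools.permutations(values):
            q = assemble_quartet(dict(zip("CGT", perm)), ref="A")
            results.add((quartet_max(q), round(quartet_cv(q), 12)))
        assert len(results) == 1


class TestCV:
    def test_zero_variance_gives_zero(self):
        q = assemble_quartet({"C": 0.5, "G": 0.5, "T": 0.5}, ref="A",
                             ref_convention="mean-of-alts")
        assert quartet_cv(q) == pytest.approx(0.0, abs=1e-12)

    def test_printed_formula_hand_value(self):
        """(0.2, 0.4, 0.6, 0.8): mu = 0.5, sigma = sqrt(0.2/3), CV ~ 0.516398."""
        from snvaudit.site_stats import ScoreQuartet

        q = ScoreQuartet(
            scores={"A": 0.2, "C": 0.4, "G": 0.6, "T": 0.8}, ref="A", tool="SIFT"
        )
        cv = quartet_cv(q)
        assert cv == pytest.approx(math.sqrt(0.2 / 3) / 0.5, abs=1e-9)
        assert cv == pytest.approx(0.516398, abs=1e-6)

    def test_zero_mean_is_undefined_not_an_exception(self):
        q = assemble_quartet({"C": 0.0, "G": 0.0, "T": 0.0}, ref="A")
        assert quartet_cv(q) is None

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
        st.floats(0.1, 1.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance_and_non_negativity(self, alts, c):
        scaled = {nt: min(1.0, s * c) for nt, s in zip("CGT", alts)}
        base = {nt: s * c for nt, s in zip("CGT", alts)}
        if any(v > 1 for v in base.values()):
            return
        q1 = assemble_quartet(dict(zip("CGT", alts)), ref="A",
                              ref_convention="exclude-and-rescale")
        q2 = assemble_quartet(base, ref="A", ref_convention="exclude-and-rescale")
        cv1, cv2 = quartet_cv(q1), quartet_cv(q2)
        assert cv1 >= 0
        assert cv2 == pytest.approx(cv1, rel=1e-9)  # CV = sigma/mu is scale-free

    def test_cv_zero_iff_all_scores_equal(self):
        q = assemble_quartet({"C": 0.5, "G": 0.5, "T": 0.6}, ref="A",
                             ref_convention="mean-of-alts")
        assert quartet_cv(q) > 0


class TestVectorizedTableStats:
    def test_matches_scalar_route(self):
        """The vectorized pipeline path equals assemble_quartet +
        quartet_max/quartet_cv site by site, for every convention."""
        rng = np.random.default_rng(21)
        rows = []
        for i in range(40):
            ref = "ACGT"[rng.integers(0, 4)]
            for tool in ("SIFT", "CADD"):
                for alt in [nt for nt in "ACGT" if nt != ref]:
                    rows.append(
                        {"chrom": "1", "pos": 100 + i, "ref": ref, "tool": tool,
                         "alt": alt, "score": float(rng.random())}
                    )
        long = pd.DataFrame(rows)
        for convention in ("zero", "mean-of-alts", "exclude-and-rescale"):
            table = quartet_table_stats(long, ref_convention=convention)
            assert len(table) == 80
            for row in table.itertuples(index=False):
                site = long[
                    (long["pos"] == row.pos) & (long["tool"] == row.tool)
                ]
                alt_scores = dict(zip(site["alt"], site["score"]))
                q = assemble_quartet(alt_scores, row.ref, row.tool, convention)
                assert row.max == pytest.approx(quartet_max(q), abs=1e-12)
                assert row.cv == pytest.approx(quartet_cv(q), abs=1e-12)

    def test_incomplete_sites_are_skipped(self):
        long = pd.DataFrame(
            [
                {"chrom": "1", "pos": 1, "ref": "A", "tool": "SIFT", "alt": "C", "score": 0.5},
                {"chrom": "1", "pos": 1, "ref": "A", "tool": "SIFT", "alt": "G", "score": 0.5},
            ]
        )
        assert len(quartet_table_stats(long)) == 0


class TestGroupComparison:
    def test_identical_samples_give_p_one(self):
        df = compare_groups({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert df.loc[0, "p"] == pytest.approx(1.0)

    def test_separated_samples_match_enumeration(self):
        df = compare_groups({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert df.loc[0, "p"] == pytest.approx(2 / 20, abs=1e-12)

    def test_empty_group_reported_missing(self):
        df = compare_groups({"a": [1.0], "b": []})
        assert np.isnan(df.loc[0, "p"])

    def test_planted_directions_on_synthetic_cohort(self, small_bundle):
        """Pathogenic-class quartets: maximum shifted up, CV shifted down."""
        stats = quartet_table_stats(small_bundle.quartets, ref_convention="zero")
        cadd = stats[stats["tool"] == "CADD"]
        groups_max = {
            g: cadd.loc[cadd["group"] == g, "max"].to_numpy()
            for g in ("pathogenic", "benign")
        }
        groups_cv = {
            g: cadd.loc[cadd["group"] == g, "cv"].dropna().to_numpy()
            for g in ("pathogenic", "benign")
        }
        p_max = compare_groups(groups_max).loc[0, "p"]
        p_cv = compare_groups(groups_cv).loc[0, "p"]
        assert p_max < 0.05
        assert p_cv < 0.05
        assert np.median(groups_max["pathogenic"]) > np.median(groups_max["benign"])
        assert np.median(groups_cv["pathogenic"]) < np.median(groups_cv["benign"])


class TestConservationCorrelation:
    def test_identity_and_anti_identity(self):
        v = [0.1, 0.5, 0.9, 0.3]
        assert stat_conservation_correlation(v, v)[0] == pytest.approx(1.0)
        assert stat_conservation_correlation(v, [-x for x in v])[0] == pytest.approx(-1.0)

    def test_fewer_than_three_pairs_missing(self):
        assert stat_conservation_correlation([1.0, 2.0], [1.0, 2.0]) is None

    def test_independent_draws_show_no_correlation(self):
        rng = np.random.default_rng(2)
        stat = rng.random(2000)
        cons = rng.random(2000)
        r, _ = stat_conservation_correlation(stat, cons)
        assert abs(r) < 0.1
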