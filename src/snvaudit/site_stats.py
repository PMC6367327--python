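"""Four-allele score statistics at non-degenerate sites.

At a non-degenerate codon position every nucleotide substitution changes
the amino acid, so a prediction tool implicitly assigns a score to each of
the four possible residents. Two per-site statistics summarize the quartet:

* the **maximum** score — how deleterious the worst change would be;
* the **coefficient of variation** CV = sigma/mu with mu the mean of the
  four scores and sigma the sample standard deviation (divisor 3) — a low
  CV marks a site intolerant to *any* change rather than to a specific one.

Only the three alternative alleles are ever scored by the tools; the score
attached to the reference allele is a convention (default 0: no change, no
predicted deleteriousness) and every downstream CV magnitude depends on it,
so alternative conventions are first-class and reports can be emitted under
each.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import pearson_correlation, rank_sum_test
from .variant_model import NUCLEOTIDES

__all__ = [
    "REF_CONVENTIONS",
    "ScoreQuartet",
    "assemble_quartet",
    "quartet_max",
    "quartet_cv",
    "compare_groups",
    "stat_conservation_correlation",
]

REF_CONVENTIONS = ("zero", "mean-of-alts", "exclude-and-rescale")


@dataclass(frozen=True)
class ScoreQuartet:
    """Scores for the four nucleotides at one non-degenerate site.

    Under the "exclude-and-rescale" convention the reference allele carries
    no score and statistics run over the three alternatives (mean over 3,
    standard-deviation divisor 2); under the other conventions all four
    scores participate (mean over 4, divisor 3, the printed formulas).
    """

    scores: Mapping[str, float]
    ref: str
    tool: str
    convention: str = "zero"

    def __post_init__(self) -> None:
        if self.ref not in NUCLEOTIDES:
            raise ValueError(f"ref {self.ref!r} is not a nucleotide")
        if self.convention not in REF_CONVENTIONS:
            raise ValueError(f"unknown ref convention {self.convention!r}")
        expected = 3 if self.convention == "exclude-and-rescale" else 4
        if len(self.scores) != expected:
            raise ValueError(f"expected {expected} scores, got {len(self.scores)}")
        for nt, s in self.scores.items():
            if nt not in NUCLEOTIDES:
                raise ValueError(f"{nt!r} is not a nucleotide")
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"score {s} for {nt} outside [0, 1]")

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(self.scores[nt] for nt in NUCLEOTIDES if nt in self.scores)


def assemble_quartet(
    alt_scores: Mapping[str, float],
    ref: str,
    tool: str = "",
    ref_convention: str = "zero",
) -> ScoreQuartet | None:
    """Build a quartet from the three alternative-allele scores.

    Returns None (quartet unavailable) when any of the three alternative
    scores is absent. The reference-allele score follows ``ref_convention``:
    0.0 by default, the mean of the alternatives, or excluded entirely.
    """
    if ref not in NUCLEOTIDES:
        raise ValueError(f"ref {ref!r} is not a nucleotide")
    alts = [nt for nt in NUCLEOTIDES if nt != ref]
    present = {nt: alt_scores[nt] for nt in alts if alt_scores.get(nt) is not None}
    if len(present) < 3:
        return None
    if ref_convention == "zero":
        scores = {**present, ref: 0.0}
    elif ref_convention == "mean-of-alts":
        scores = {**present, ref: sum(present.values()) / 3.0}
    elif ref_convention == "exclude-and-rescale":
        scores = present
    else:
        raise ValueError(f"unknown ref convention {ref_convention!r}")
    return ScoreQuartet(scores=scores, ref=ref, tool=tool, convention=ref_convention)


def quartet_max(q: ScoreQuartet) -> float:
    """Maximum of the per-nucleotide scores (invariant to relabeling)."""
    return max(q.values)


def quartet_cv(q: ScoreQuartet) -> float | None:
    """Coefficient of variation sigma/mu of the quartet scores.

    mu is the mean of the k scores and sigma the sample standard deviation
    with divisor k-1 (k = 4 except under "exclude-and-rescale", where k = 3).
    Undefined (None) when mu = 0. CV is non-negative, zero iff all scores
    are equal, and invariant to scaling all scores by a positive constant.
    """
    values = q.values
    k = len(values)
    mu = sum(values) / k
    if mu == 0.0:
        return None
    sigma = math.sqrt(sum((s - mu) ** 2 for s in values) / (k - 1))
    return sigma / mu


def quartet_table_stats(
    quartets: pd.DataFrame,
    ref_convention: str = "zero",
) -> pd.DataFrame:
    """Vectorized per-site, per-tool max and CV from a long quartet table.

    ``quartets`` has one row per (site, tool, alternative allele) with
    columns ``chrom, pos, ref, tool, alt, score`` and optionally ``group``
    and ``is_dm``. Sites with fewer than three alternative scores for a
    tool are skipped. Row-for-row equivalent to :func:`assemble_quartet` +
    :func:`quartet_max` / :func:`quartet_cv` (the scalar route is the
    oracle in tests); this path exists because per-site Python assembly is
    the pipeline bottleneck on cohort-sized tables.
    """
    if ref_convention not in REF_CONVENTIONS:
        raise ValueError(f"unknown ref convention {ref_convention!r}")
    df = quartets.copy()
    df["score"] = df["score"].astype(float)
    keys = ["chrom", "pos", "ref", "tool"]
    extra = [c for c in ("group", "is_dm") if c in df.columns]
    wide = df.pivot_table(
        index=keys + extra, columns="alt", values="score", aggfunc="first"
    ).reset_index()
    alt_cols = [c for c in NUCLEOTIDES if c in wide.columns]
    scores = wide.reindex(columns=list(NUCLEOTIDES)).to_numpy(dtype=float)
    ref_idx = np.array([NUCLEOTIDES.index(r) for r in wide["ref"]])
    rows = np.arange(len(wide))
    # a complete quartet has exactly the three non-ref scores present
    ref_is_nan = np.isnan(scores[rows, ref_idx])
    complete = (np.sum(~np.isnan(scores), axis=1) == 3) & ref_is_nan
    scores = scores[complete]
    ref_idx = ref_idx[complete]
    rows = np.arange(len(scores))
    if ref_convention == "zero":
        scores[rows, ref_idx] = 0.0
        k = 4
    elif ref_convention == "mean-of-alts":
        scores[rows, ref_idx] = np.nanmean(scores, axis=1)
        k = 4
    else:  # exclude-and-rescale
        k = 3
    mx = np.nanmax(scores, axis=1) if len(scores) else np.array([])
    mu = np.nansum(scores, axis=1) / k if len(scores) else np.array([])
    dev2 = np.nansum((scores - mu[:, None]) ** 2, axis=1) if len(scores) else np.array([])
    sigma = np.sqrt(dev2 / (k - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mu > 0, sigma / np.maximum(mu, 1e-300), np.nan)
    out = wide.loc[complete, keys + extra].reset_index(drop=True)
    out["max"] = mx
    out["cv"] = cv
    out["convention"] = ref_convention
    return out


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    *,
    min_size: int = 1,
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum p-values between site groups.

    Groups typically follow the five panels pathogenic / benign / both /
    other / DM. Each row carries the group medians so the direction of a
    difference is visible alongside its p-value. A pair with an empty (or
    under-sized) group is reported with a missing p rather than dropped.
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            a = np.asarray(values_by_group[ga], dtype=float)
            b = np.asarray(values_by_group[gb], dtype=float)
            a = a[~np.isnan(a)]
            b = b[~np.isnan(b)]
            row = {
                "group_a": ga,
                "group_b": gb,
                "n_a": a.size,
                "n_b": b.size,
                "median_a": float(np.median(a)) if a.size else np.nan,
                "median_b": float(np.median(b)) if b.size else np.nan,
            }
            if a.size < min_size or b.size < min_size or a.size == 0 or b.size == 0:
                row["p"] = np.nan
            else:
                _, row["p"] = rank_sum_test(a, b)
            rows.append(row)
    return pd.DataFrame(rows)


def stat_conservation_correlation(
    stat: Sequence[float],
    cons: Sequence[float],
) -> tuple[float, float] | None:
    """Pearson correlation between a per-site statistic (max or CV) and
    conservation, on complete pairs; None below 3 pairs."""
    return pearson_correlation(stat, cons)
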