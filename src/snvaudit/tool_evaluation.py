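"""Per-tool and combined-tool prediction evaluation.

Truth labels are restricted to pathogenic/benign (sites classified "both"
or "other" are excluded upstream). A tool subset classifies a variant only
when every member tool gives the same binary call (the all-agree rule);
otherwise the variant is a no-call, and no-calls stay in the sensitivity
and specificity denominators. That convention makes the trade-off visible:
adding tools can only shrink the called set, so sensitivity is
non-increasing and specificity non-decreasing along nested subsets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variant_model import TOOLS

__all__ = [
    "ConfusionTable",
    "Metrics",
    "CombinationResult",
    "confusion",
    "metrics",
    "pairwise_agreement",
    "combine_calls",
    "scan_combinations",
    "summarize_by_size",
]

_CALL_VALUES = ("pathogenic", "benign", "missing")


@dataclass(frozen=True)
class ConfusionTable:
    """Binary confusion counts with no-calls tracked per truth label."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    unclassified_pathogenic: int = 0
    unclassified_benign: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn", "unclassified_pathogenic", "unclassified_benign"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def unclassified(self) -> int:
        return self.unclassified_pathogenic + self.unclassified_benign

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn + self.unclassified


@dataclass(frozen=True)
class Metrics:
    """Sensitivity, specificity, accuracy; None where the denominator is 0.

    No-calls count against sensitivity/specificity: a pathogenic variant the
    subset leaves uncalled is a miss, not an exclusion. Accuracy is over all
    labeled variants.
    """

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None


@dataclass(frozen=True)
class CombinationResult:
    subset: frozenset[str]
    confusion: ConfusionTable
    metrics: Metrics

    @property
    def size(self) -> int:
        return len(self.subset)


def _check_labels(labels: Sequence[str]) -> None:
    bad = {x for x in labels if x not in ("pathogenic", "benign")}
    if bad:
        raise ValueError(f"labels must be pathogenic/benign, got {sorted(bad)}")


def confusion(calls: Sequence[str | None], labels: Sequence[str]) -> ConfusionTable:
    """Count the confusion table of binary calls against truth labels.

    ``calls`` entries are "pathogenic", "benign", or "missing"/None (counted
    as unclassified under the truth label). An empty input gives the
    all-zero table.
    """
    if len(calls) != len(labels):
        raise ValueError("calls and labels must align")
    _check_labels(labels)
    tp = fp = tn = fn = up = ub = 0
    for call, label in zip(calls, labels):
        if call is None or call == "missing":
            if label == "pathogenic":
                up += 1
            else:
                ub += 1
        elif call == "pathogenic":
            if label == "pathogenic":
                tp += 1
            else:
                fp += 1
        elif call == "benign":
            if label == "benign":
                tn += 1
            else:
                fn += 1
        else:
            raise ValueError(f"unknown call {call!r}")
    return ConfusionTable(tp, fp, tn, fn, up, ub)


def metrics(c: ConfusionTable) -> Metrics:
    """Sensitivity/specificity/accuracy from a confusion table.

    sensitivity = tp / (tp + fn + unclassified pathogenic)
    specificity = tn / (tn + fp + unclassified benign)
    accuracy    = (tp + tn) / all labeled
    Each is None when its denominator is zero.
    """
    sens_den = c.tp + c.fn + c.unclassified_pathogenic
    spec_den = c.tn + c.fp + c.unclassified_benign
    return Metrics(
        sensitivity=c.tp / sens_den if sens_den else None,
        specificity=c.tn / spec_den if spec_den else None,
        accuracy=(c.tp + c.tn) / c.total if c.total else None,
    )


def pairwise_agreement(calls_by_tool: Mapping[str, Sequence[str | None]]) -> pd.DataFrame:
    """Agreement fractions between tools over co-called variants.

    Entry (i, j) is the fraction of variants, among those where both tools
    give non-missing calls, with identical binary calls. The matrix is
    symmetric with unit diagonal; a pair with zero co-called variants is NaN.
    """
    tools = list(calls_by_tool)
    if len(tools) < 2:
        raise ValueError("pairwise agreement needs at least two tools")
    n = len(next(iter(calls_by_tool.values())))
    coded = {}
    for tool, calls in calls_by_tool.items():
        if len(calls) != n:
            raise ValueError("all call vectors must have the same length")
        coded[tool] = np.array(
            [-1 if (c is None or c == "missing") else int(c == "pathogenic") for c in calls]
        )
    out = pd.DataFrame(np.nan, index=tools, columns=tools, dtype=float)
    for i, ti in enumerate(tools):
        out.loc[ti, ti] = 1.0
        for tj in tools[i + 1 :]:
            both = (coded[ti] >= 0) & (coded[tj] >= 0)
            if both.sum() == 0:
                continue
            frac = float((coded[ti][both] == coded[tj][both]).mean())
            out.loc[ti, tj] = frac
            out.loc[tj, ti] = frac
    return out


def combine_calls(
    subset: Iterable[str],
    calls_by_tool: Mapping[str, Sequence[str | None]],
) -> list[str]:
    """Combined call under the all-agree rule.

    Pathogenic if every tool in the subset calls pathogenic; benign if every
    tool calls benign; otherwise (disagreement or any missing member score)
    a no-call, returned as "missing".
    """
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    vectors = [calls_by_tool[t] for t in subset]
    n = len(vectors[0])
    combined = []
    for i in range(n):
        votes = {v[i] for v in vectors}
        if votes == {"pathogenic"}:
            combined.append("pathogenic")
        elif votes == {"benign"}:
            combined.append("benign")
        else:
            combined.append("missing")
    return combined


def scan_combinations(
    tools: Sequence[str],
    calls_by_tool: Mapping[str, Sequence[str | None]],
    labels: Sequence[str],
    *,
    max_tools: int = 20,
    force: bool = False,
) -> list[CombinationResult]:
    """Evaluate every non-empty tool subset (2^k - 1 of them).

    The inner loop is vectorized (calls coded as integers; a subset's
    combined call is a reduction over its member rows) but is contract-
    equivalent to :func:`combine_calls` + :func:`confusion` per subset,
    which serves as the brute-force oracle in tests. Refuses k > 20 unless
    ``force`` is set.
    """
    tools = list(tools)
    if not tools:
        raise ValueError("tool set must be non-empty")
    if len(set(tools)) != len(tools):
        raise ValueError("tool set contains duplicates")
    if len(tools) > max_tools and not force:
        raise ValueError(f"refusing to scan 2^{len(tools)} - 1 subsets (force=True to override)")
    _check_labels(labels)
    n = len(labels)
    # code calls: 1 pathogenic, 0 benign, -1 missing
    coded = np.empty((len(tools), n), dtype=np.int8)
    for row, tool in enumerate(tools):
        calls = calls_by_tool[tool]
        if len(calls) != n:
            raise ValueError("call vectors and labels must align")
        coded[row] = [-1 if (c is None or c == "missing") else int(c == "pathogenic") for c in calls]
    is_path = np.array([lab == "pathogenic" for lab in labels])

    results: list[CombinationResult] = []
    for r in range(1, len(tools) + 1):
        for combo in itertools.combinations(range(len(tools)), r):
            sub = coded[list(combo)]
            all_path = (sub == 1).all(axis=0)
            all_benign = (sub == 0).all(axis=0)
            tp = int((all_path & is_path).sum())
            fp = int((all_path & ~is_path).sum())
            tn = int((all_benign & ~is_path).sum())
            fn = int((all_benign & is_path).sum())
            nocall = ~(all_path | all_benign)
            up = int((nocall & is_path).sum())
            ub = int((nocall & ~is_path).sum())
            table = ConfusionTable(tp, fp, tn, fn, up, ub)
            results.append(
                CombinationResult(
                    subset=frozenset(tools[i] for i in combo),
                    confusion=table,
                    metrics=metrics(table),
                )
            )
    return results


def summarize_by_size(results: Sequence[CombinationResult]) -> pd.DataFrame:
    """Mean and max sensitivity/specificity/accuracy per subset size."""
    if not results:
        raise ValueError("no combination results to summarize")
    rows = [
        {
            "size": r.size,
            "sensitivity": r.metrics.sensitivity,
            "specificity": r.metrics.specificity,
            "accuracy": r.metrics.accuracy,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    agg = df.groupby("size").agg(
        n_subsets=("sensitivity", "size"),
        mean_sensitivity=("sensitivity", "mean"),
        max_sensitivity=("sensitivity", "max"),
        mean_specificity=("specificity", "mean"),
        max_specificity=("specificity", "max"),
        mean_accuracy=("accuracy", "mean"),
        max_accuracy=("accuracy", "max"),
    )
    return agg.reset_index()


def results_to_frame(results: Sequence[CombinationResult]) -> pd.DataFrame:
    """Flatten combination results for TSV export (subset as sorted ;-joined names)."""
    rows = []
    for r in results:
        c = r.confusion
        rows.append(
            {
                "subset": ";".join(sorted(r.subset)),
                "size": r.size,
                "tp": c.tp,
                "fp": c.fp,
                "tn": c.tn,
                "fn": c.fn,
                "unclassified": c.unclassified,
                "sensitivity": r.metrics.sensitivity,
                "specificity": r.metrics.specificity,
                "accuracy": r.metrics.accuracy,
            }
        )
    return pd.DataFrame(rows)
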