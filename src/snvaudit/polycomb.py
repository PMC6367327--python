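"""Chromatin-state (PolyComb) overlap of variant sites across epigenomes.

PolyComb group proteins silence genes over broad domains, and chromHMM
segmentations of reference epigenomes label those domains as ReprPC
("repressed PolyComb") or ReprPCWk ("weak repressed PolyComb"). For each
variant site the statistic of interest is the fraction of epigenomes
(cell types) whose segmentation places the site in a given state — a site
silenced across many cell types sits in a regime where a coding change can
act through regulation rather than protein function.

BED intervals are 0-based half-open; variant positions are 1-based and
fully closed. The conversion is centralized here: a 1-based position ``p``
is covered by ``[start, end)`` iff ``start <= p - 1 < end``.

Because a segmentation's intervals are non-overlapping per chromosome,
the interval index is a pair of sorted start/end arrays queried by binary
search; lookups are verified against a linear interval-by-interval scan in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import rank_sum_test

__all__ = [
    "REPR_PC",
    "REPR_PC_WEAK",
    "EpigenomeStateTrack",
    "read_state_bed",
    "read_concatenated_bed",
    "site_in_state",
    "state_fraction",
    "state_fraction_table",
    "group_state_comparison",
]

REPR_PC = "ReprPC"
REPR_PC_WEAK = "ReprPCWk"


class _ChromIndex:
    """Sorted-interval index for one chromosome of one epigenome."""

    __slots__ = ("starts", "ends", "states")

    def __init__(self, starts: np.ndarray, ends: np.ndarray, states: np.ndarray):
        order = np.argsort(starts, kind="mergesort")
        self.starts = np.asarray(starts)[order]
        self.ends = np.asarray(ends)[order]
        self.states = np.asarray(states, dtype=object)[order]
        if (self.starts >= self.ends).any():
            raise ValueError("empty or inverted interval in state track")
        if (self.ends[:-1] > self.starts[1:]).any():
            raise ValueError("overlapping intervals in state track")

    def state_at(self, zero_based: int) -> str | None:
        i = int(np.searchsorted(self.starts, zero_based, side="right")) - 1
        if i >= 0 and self.ends[i] > zero_based:
            return str(self.states[i])
        return None

    def states_at(self, zero_based: np.ndarray) -> np.ndarray:
        """Vectorized lookup: state label per position, None where uncovered."""
        idx = np.searchsorted(self.starts, zero_based, side="right") - 1
        valid = idx >= 0
        idx_safe = np.where(valid, idx, 0)
        covered = valid & (self.ends[idx_safe] > zero_based)
        out = np.full(zero_based.shape, None, dtype=object)
        out[covered] = self.states[idx_safe[covered]]
        return out


@dataclass
class EpigenomeStateTrack:
    """One epigenome's chromatin-state segmentation.

    Intervals are non-overlapping per chromosome (each position carries at
    most one state); violations are rejected when the index is built.
    """

    epigenome: str
    _pending: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)
    _index: dict[str, _ChromIndex] = field(default_factory=dict)

    def add(self, chrom: str, start: int, end: int, state: str) -> None:
        if start >= end:
            raise ValueError(f"empty/inverted interval [{start}, {end}) on {chrom}")
        self._pending.setdefault(chrom, []).append((int(start), int(end), state))
        self._index.pop(chrom, None)

    def _chrom_index(self, chrom: str) -> _ChromIndex | None:
        if chrom in self._index:
            return self._index[chrom]
        pending = self._pending.get(chrom)
        if not pending:
            return None
        starts = np.array([p[0] for p in pending])
        ends = np.array([p[1] for p in pending])
        states = np.array([p[2] for p in pending], dtype=object)
        index = _ChromIndex(starts, ends, states)
        self._index[chrom] = index
        return index

    def set_intervals(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray, states: np.ndarray
    ) -> None:
        """Bulk-load one chromosome (replaces previously added intervals)."""
        self._pending.pop(chrom, None)
        self._index[chrom] = _ChromIndex(starts, ends, states)

    @property
    def chroms(self) -> set[str]:
        return set(self._pending) | set(self._index)

    def state_at(self, chrom: str, pos: int) -> str | None:
        """State label covering 1-based position ``pos``, or None."""
        index = self._chrom_index(chrom)
        if index is None:
            return None
        return index.state_at(pos - 1)

    def states_at(self, chrom: str, positions: Sequence[int]) -> np.ndarray:
        """Vectorized :meth:`state_at` over many 1-based positions."""
        positions = np.asarray(positions, dtype=int)
        index = self._chrom_index(chrom)
        if index is None:
            return np.full(positions.shape, None, dtype=object)
        return index.states_at(positions - 1)


def _track_from_frame(df: pd.DataFrame, epigenome: str) -> EpigenomeStateTrack:
    track = EpigenomeStateTrack(epigenome)
    for chrom, sub in df.groupby("chrom", sort=True, observed=True):
        track.set_intervals(
            str(chrom),
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            sub["state"].to_numpy(dtype=object),
        )
    return track


def read_state_bed(path: str | Path, epigenome: str | None = None) -> EpigenomeStateTrack:
    """Read one epigenome's BED file (chrom, start, end, state label)."""
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "state"],
        dtype={"chrom": str, "start": int, "end": int, "state": str},
        comment="#",
    )
    return _track_from_frame(df, epigenome or path.stem)


def read_concatenated_bed(path: str | Path) -> list[EpigenomeStateTrack]:
    """Read a concatenated BED with a 5th column naming the epigenome."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3, 4],
        names=["chrom", "start", "end", "state", "epigenome"],
        dtype={"chrom": str, "start": int, "end": int, "state": str, "epigenome": str},
        comment="#",
    )
    return [
        _track_from_frame(sub, str(name))
        for name, sub in df.groupby("epigenome", sort=True)
    ]


def site_in_state(
    site: tuple[str, int],
    track: EpigenomeStateTrack,
    states: str | Iterable[str],
) -> bool:
    """Whether the 1-based site lies in any of the given states in this track."""
    if isinstance(states, str):
        states = (states,)
    label = track.state_at(*site)
    return label is not None and label in set(states)


def state_fraction(
    site: tuple[str, int],
    tracks: Sequence[EpigenomeStateTrack],
    states: str | Iterable[str],
    *,
    covered_only: bool = False,
) -> float:
    """Fraction of epigenomes whose segmentation puts the site in the state(s).

    The denominator is all epigenomes supplied ("percentage of cell
    types"); epigenomes with no data at the site's chromosome count as
    not-in-state. With ``covered_only`` the denominator is restricted to
    epigenomes assigning any state at the site. ``states`` may be a single
    label or an iterable (the union event, e.g. ReprPC or ReprPCWk).
    """
    if not tracks:
        raise ValueError("need at least one epigenome track")
    if isinstance(states, str):
        states = (states,)
    wanted = set(states)
    hits = 0
    covered = 0
    for track in tracks:
        label = track.state_at(*site)
        if label is not None:
            covered += 1
            if label in wanted:
                hits += 1
    denominator = covered if covered_only else len(tracks)
    if denominator == 0:
        return 0.0
    return hits / denominator


def state_fraction_table(
    sites: Sequence[tuple[str, int]],
    tracks: Sequence[EpigenomeStateTrack],
    states: Mapping[str, str | tuple[str, ...]] | None = None,
    *,
    covered_only: bool = False,
) -> pd.DataFrame:
    """Per-site state fractions for several state definitions.

    ``states`` maps an output column name to a label or tuple of labels
    (union event); defaults to ReprPC, ReprPCWk and their union. Lookups
    run vectorized per track and chromosome; results agree with
    :func:`state_fraction` site by site.
    """
    if not tracks:
        raise ValueError("need at least one epigenome track")
    if states is None:
        states = {
            "ReprPC": REPR_PC,
            "ReprPCWk": REPR_PC_WEAK,
            "ReprPC_or_Wk": (REPR_PC, REPR_PC_WEAK),
        }
    chroms = np.array([s[0] for s in sites], dtype=object)
    positions = np.array([s[1] for s in sites], dtype=int)
    n = len(sites)
    counts = {name: np.zeros(n, dtype=int) for name in states}
    covered = np.zeros(n, dtype=int)
    for track in tracks:
        labels = np.full(n, None, dtype=object)
        for chrom in np.unique(chroms):
            mask = chroms == chrom
            labels[mask] = track.states_at(str(chrom), positions[mask])
        has_label = labels != None  # noqa: E711  (elementwise against object None)
        covered += has_label.astype(int)
        for name, wanted in states.items():
            wanted_set = {wanted} if isinstance(wanted, str) else set(wanted)
            counts[name] += np.isin(labels, list(wanted_set)).astype(int)
    denominator = covered if covered_only else np.full(n, len(tracks))
    out = {"chrom": chroms, "pos": positions}
    for name in states:
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(denominator > 0, counts[name] / np.maximum(denominator, 1), 0.0)
        out[name] = frac
    return pd.DataFrame(out)


def group_state_comparison(
    fractions_by_group: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests between groups of per-site
    state fractions (e.g. pathogenic vs benign sites, or FN vs TP sites of
    one tool), with group medians for direction. Empty groups yield missing
    p-values rather than being dropped.
    """
    groups = list(fractions_by_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            a = np.asarray(fractions_by_group[ga], dtype=float)
            b = np.asarray(fractions_by_group[gb], dtype=float)
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
            if a.size == 0 or b.size == 0:
                row["p"] = np.nan
            else:
                _, row["p"] = rank_sum_test(a, b)
            rows.append(row)
    return pd.DataFrame(rows)
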