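"""FPKM transformation, fold-change calling and transcriptome set overlaps.

Differential expression here is the pure fold-change rule used for RNAi
knockdown fat-body transcriptomes: within a per-replicate universe of the
most abundant transcripts, a transcript is "up" in a knockdown when
log2((FPKM_treatment + c) / (FPKM_control + c)) exceeds a strict threshold
(default +1, i.e. more than two-fold).  No count model or dispersion
estimation is involved.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


def compute_fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series | Mapping[str, float],
    library_sizes: pd.Series | Mapping[str, float],
) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM[t, s] = counts[t, s] / ((length_t / 1e3) * (library_size_s / 1e6)).
    """
    lengths = pd.Series(lengths).reindex(counts.index)
    library_sizes = pd.Series(library_sizes).reindex(counts.columns)
    if lengths.isna().any():
        raise ValueError("missing transcript lengths")
    if library_sizes.isna().any():
        raise ValueError("missing library sizes")
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    kb = lengths.to_numpy(dtype=float) / 1e3
    millions = library_sizes.to_numpy(dtype=float) / 1e6
    return counts.astype(float).div(kb, axis=0).div(millions, axis=1)


def select_top_abundant(
    fpkm: pd.DataFrame, treatment: str, control: str, n: int
) -> pd.Index:
    """The n transcripts with the largest FPKM(treatment) + FPKM(control).

    Deterministic under ties: a stable sort on abundance after a
    lexicographic sort on transcript ID.
    """
    for col in (treatment, control):
        if col not in fpkm.columns:
            raise KeyError(f"sample column {col!r} not in table")
    if n > len(fpkm):
        raise ValueError(f"requested top {n} of only {len(fpkm)} transcripts")
    abundance = (fpkm[treatment] + fpkm[control]).sort_index()
    ranked = abundance.sort_values(ascending=False, kind="mergesort")
    return ranked.index[:n]


def call_upregulated(
    fpkm: pd.DataFrame,
    treatment: str,
    control: str,
    log2_threshold: float = 1.0,
    pseudocount: float = 0.01,
    universe: Iterable[str] | None = None,
) -> tuple[set[str], pd.DataFrame]:
    """Transcripts with log2 fold change strictly above the threshold.

    Returns the up-set and a per-transcript call table (log2fc, is_up).  The
    pseudocount is added to numerator and denominator so zero-control
    transcripts are well defined; pass 0 to reproduce the bare ratio.
    """
    for col in (treatment, control):
        if col not in fpkm.columns:
            raise KeyError(f"sample column {col!r} not in table")
    sub = fpkm if universe is None else fpkm.loc[pd.Index(universe)]
    with np.errstate(divide="ignore"):
        log2fc = np.log2(
            (sub[treatment].to_numpy(dtype=float) + pseudocount)
            / (sub[control].to_numpy(dtype=float) + pseudocount)
        )
    calls = pd.DataFrame(
        {"log2fc": log2fc, "is_up": log2fc > log2_threshold}, index=sub.index
    )
    return set(calls.index[calls["is_up"]]), calls


def call_downregulated(
    fpkm: pd.DataFrame,
    treatment: str,
    control: str,
    log2_threshold: float = 1.0,
    pseudocount: float = 0.01,
    universe: Iterable[str] | None = None,
) -> tuple[set[str], pd.DataFrame]:
    """Symmetric down-call: log2 fold change strictly below -threshold."""
    up, calls = call_upregulated(
        fpkm, treatment, control, log2_threshold, pseudocount, universe
    )
    calls = calls.copy()
    calls["is_down"] = calls["log2fc"] < -log2_threshold
    return set(calls.index[calls["is_down"]]), calls


@dataclass(frozen=True)
class OverlapResult:
    """All intersection cardinalities of a labelled collection of gene sets."""

    sets: dict[str, frozenset]

    @property
    def labels(self) -> list[str]:
        return list(self.sets)

    def size(self, label: str) -> int:
        return len(self.sets[label])

    def intersection(self, *labels: str) -> frozenset:
        it = iter(labels)
        acc = set(self.sets[next(it)])
        for lab in it:
            acc &= self.sets[lab]
        return frozenset(acc)

    def intersection_size(self, *labels: str) -> int:
        return len(self.intersection(*labels))

    def percent(self, a: str, b: str) -> float:
        """|A ∩ B| / |A| × 100 (share of A also in B)."""
        if not self.sets[a]:
            raise ZeroDivisionError(f"set {a!r} is empty")
        return 100.0 * self.intersection_size(a, b) / self.size(a)

    def region_sizes(self) -> dict[frozenset, int]:
        """Exclusive Venn-region sizes keyed by the member label set."""
        universe = set().union(*self.sets.values())
        regions: dict[frozenset, int] = {}
        for r in range(1, len(self.sets) + 1):
            for combo in itertools.combinations(self.labels, r):
                inside = set(self.intersection(*combo))
                for other in self.sets:
                    if other not in combo:
                        inside -= self.sets[other]
                regions[frozenset(combo)] = len(inside)
        return regions

    def to_frame(self) -> pd.DataFrame:
        """Tidy table of every (non-exclusive) intersection size and percentage."""
        rows = []
        for r in range(1, len(self.sets) + 1):
            for combo in itertools.combinations(self.labels, r):
                rows.append(
                    {"region": "&".join(combo), "size": self.intersection_size(*combo)}
                )
        exclusive = self.region_sizes()
        for combo, size in exclusive.items():
            rows.append({"region": "only:" + "&".join(sorted(combo)), "size": size})
        return pd.DataFrame(rows)


def overlap_sets(sets: Mapping[str, Iterable[str]]) -> OverlapResult:
    """Build an OverlapResult from at least two labelled transcript sets."""
    if len(sets) < 2:
        raise ValueError("overlap analysis needs at least two sets")
    return OverlapResult({lab: frozenset(s) for lab, s in sets.items()})


def replicate_consensus(sets: Sequence[Iterable[str]]) -> set[str]:
    """Exact intersection of per-replicate up-sets."""
    sets = [set(s) for s in sets]
    if not sets:
        raise ValueError("consensus needs at least one set")
    return set.intersection(*sets)
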