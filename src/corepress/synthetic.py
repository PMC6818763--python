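"""Ground-truth synthetic data: expression tables, promoters, annotations.

Every downstream stage of the pipeline is testable without external
downloads because its inputs can be generated here with known truth:

* expression tables with planted >= 2-fold up-regulation in chosen
  treatment columns and a controlled overlap structure among treatments;
* upstream ("promoter") sequences with motifs planted at controlled
  positions, strands and pairwise distances over an i.i.d. background;
* single-label category annotations with a planted enriched category.

The generators are deterministic functions of ``rng_seed`` (independent
numpy streams per generator, spawned from the seed), so regeneration is
byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import reverse_complement, _validate_acgt

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SyntheticConfig:
    """Study conditions for the generators; defaults mirror the pipeline's use.

    ``planted_up_sets`` maps treatment label -> transcript IDs whose FPKM in
    that treatment is boosted by ``planted_log2fc`` (log2 units) over the
    control baseline.  ``noise_cv`` is the coefficient of variation of the
    multiplicative log-normal noise applied per treatment cell (the control
    column is the baseline draw itself).  ``plant_plan`` is a sequence of
    (gene, motif, strand, start) tuples written over the background
    sequence; minus-strand plants are written as the reverse complement.
    """

    rng_seed: int = 0
    # expression
    n_transcripts: int = 2000
    treatments: tuple[str, ...] = ("iLuc", "iMet", "iHairy", "iKr-h1")
    control: str = "iLuc"
    planted_up_sets: dict[str, frozenset] = field(default_factory=dict)
    planted_log2fc: float = 2.0
    baseline_log10_mean: float = 0.5
    baseline_log10_sigma: float = 0.6
    noise_cv: float = 0.1
    planted_min_fpkm: float = 0.0
    # promoters
    promoter_length: int = 5000
    promoter_ids: tuple[str, ...] = ()
    background_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    plant_plan: tuple[tuple[str, str, str, int], ...] = ()
    # annotation
    category_labels: tuple[str, ...] = tuple("OVTWPQCEFGHIDMNUZABK")
    enriched_category: str | None = None
    enrichment_ratio: float = 1.0
    enriched_gene_set: frozenset = frozenset()
    target_category_counts: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if abs(sum(self.background_freqs) - 1.0) > 1e-9:
            raise ValueError("background_freqs must sum to 1")
        if any(f < 0 for f in self.background_freqs):
            raise ValueError("background_freqs must be non-negative")
        if self.control not in self.treatments:
            raise ValueError("control label must be among the treatments")
        universe = set(self.transcript_ids())
        for label, ids in self.planted_up_sets.items():
            if label not in self.treatments:
                raise ValueError(f"planted treatment {label!r} not in treatments")
            if not set(ids) <= universe:
                raise ValueError(f"planted set for {label!r} outside transcript universe")
        for gene, motif, strand, start in self.plant_plan:
            _validate_acgt(motif, "planted motif")
            if strand not in ("+", "-"):
                raise ValueError(f"bad strand {strand!r} in plant plan")
            if not 0 <= start <= self.promoter_length - len(motif):
                raise ValueError(
                    f"plant of {motif!r} at {start} exceeds promoter bounds"
                )

    def transcript_ids(self) -> list[str]:
        return [f"T{i + 1:06d}" for i in range(self.n_transcripts)]

    def _stream(self, index: int) -> np.random.Generator:
        return np.random.default_rng([int(self.rng_seed), index])


@dataclass
class SyntheticTruth:
    """What was planted, recorded for downstream assertions."""

    up_sets_by_treatment: dict[str, set[str]] = field(default_factory=dict)
    planted_sites: list[tuple[str, str, str, int, int]] = field(default_factory=list)
    enriched_categories: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def gen_expression(config: SyntheticConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """FPKM table: control = baseline law, treatments = baseline x fold x noise.

    Planted transcripts in a treatment get the 2^planted_log2fc boost; all
    treatment cells carry multiplicative log-normal noise with CV
    ``noise_cv`` (mean 1).  ``planted_min_fpkm`` floors the baseline of
    planted transcripts so abundance filtering cannot drop them.
    """
    rng = config._stream(0)
    ids = config.transcript_ids()
    n = len(ids)
    baseline = 10.0 ** rng.normal(
        config.baseline_log10_mean, config.baseline_log10_sigma, size=n
    )
    if config.planted_min_fpkm > 0 and config.planted_up_sets:
        planted_union = set().union(*config.planted_up_sets.values())
        idx = [i for i, t in enumerate(ids) if t in planted_union]
        baseline[idx] = np.maximum(baseline[idx], config.planted_min_fpkm)

    if config.noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.noise_cv**2))
        mu = -(sigma**2) / 2.0  # unit-mean multiplicative noise
    columns: dict[str, np.ndarray] = {}
    id_pos = {t: i for i, t in enumerate(ids)}
    for treatment in config.treatments:
        if treatment == config.control:
            columns[treatment] = baseline.copy()
            continue
        values = baseline.copy()
        planted = config.planted_up_sets.get(treatment, frozenset())
        if planted:
            rows = [id_pos[t] for t in sorted(planted)]
            values[rows] *= 2.0**config.planted_log2fc
        if config.noise_cv > 0:
            values = values * rng.lognormal(mu, sigma, size=n)
        columns[treatment] = values
    table = pd.DataFrame(columns, index=pd.Index(ids, name="transcript_id"))
    truth = SyntheticTruth(
        up_sets_by_treatment={
            t: set(s) for t, s in config.planted_up_sets.items()
        }
    )
    return table, truth


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int, freqs) -> str:
    idx = rng.choice(4, size=length, p=list(freqs))
    return _BASES[idx].tobytes().decode("ascii")


def gen_promoters(config: SyntheticConfig) -> tuple[dict[str, str], SyntheticTruth]:
    """Upstream regions: i.i.d. background with motifs written over it.

    Later plants overwrite earlier ones; truth records the sites whose final
    sequence content still equals the planted motif (reverse complement for
    minus-strand plants).
    """
    rng = config._stream(1)
    gene_ids = list(config.promoter_ids) or sorted({g for g, *_ in config.plant_plan})
    promoters: dict[str, list[str]] = {
        g: list(_random_sequence(rng, config.promoter_length, config.background_freqs))
        for g in gene_ids
    }
    written: list[tuple[str, str, str, int, int, str]] = []
    for gene, motif, strand, start in config.plant_plan:
        if gene not in promoters:
            raise ValueError(f"plant for unknown promoter {gene!r}")
        content = motif.upper() if strand == "+" else reverse_complement(motif)
        promoters[gene][start : start + len(content)] = list(content)
        written.append((gene, motif.upper(), strand, start, start + len(content), content))
    sequences = {g: "".join(chars) for g, chars in promoters.items()}
    truth = SyntheticTruth()
    for gene, motif, strand, start, end, content in written:
        if sequences[gene][start:end] == content:  # survived later overwrites
            truth.planted_sites.append((gene, motif, strand, start, end))
    return sequences, truth


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def gen_annotation(config: SyntheticConfig) -> tuple[pd.Series, SyntheticTruth]:
    """Single-label category annotation with a planted enriched category.

    Two modes.  Exact mode (``target_category_counts`` set): genes of
    ``enriched_gene_set`` receive categories by the stated counts, all
    remaining genes cycle round-robin through the category alphabet, so the
    enrichment outcome is deterministic.  Ratio mode: every gene draws a
    category; genes in ``enriched_gene_set`` draw ``enriched_category`` with
    probability ratio/C instead of 1/C (error if ratio > C).
    """
    labels = list(config.category_labels)
    if not labels:
        raise ValueError("need at least one category label")
    rng = config._stream(2)
    ids = config.transcript_ids()
    target = sorted(set(config.enriched_gene_set))
    truth = SyntheticTruth()

    if config.target_category_counts is not None:
        counts = dict(config.target_category_counts)
        unknown = set(counts) - set(labels)
        if unknown:
            raise ValueError(f"counts for unknown categories: {sorted(unknown)}")
        if sum(counts.values()) > len(target):
            raise ValueError("target category counts exceed the target set size")
        assignment: dict[str, str] = {}
        cursor = 0
        for label, cnt in counts.items():
            for g in target[cursor : cursor + cnt]:
                assignment[g] = label
            cursor += cnt
        leftovers = [lab for lab in labels if lab not in counts] or labels
        for j, g in enumerate(target[cursor:]):
            assignment[g] = leftovers[j % len(leftovers)]
        rest = [g for g in ids if g not in assignment]
        for j, g in enumerate(rest):
            assignment[g] = labels[j % len(labels)]
        truth.enriched_categories = sorted(counts)
        annot = pd.Series({g: assignment[g] for g in ids})
        return annot, truth

    C = len(labels)
    base = np.full(C, 1.0 / C)
    if config.enriched_category is not None:
        if config.enriched_category not in labels:
            raise ValueError(f"{config.enriched_category!r} not in category alphabet")
        ratio = config.enrichment_ratio
        if ratio * (1.0 / C) > 1.0 + 1e-12:
            raise ValueError("enrichment ratio infeasible for this alphabet size")
        boosted = base.copy()
        e = labels.index(config.enriched_category)
        boosted[e] = ratio / C
        others = [i for i in range(C) if i != e]
        boosted[others] = (1.0 - boosted[e]) / (C - 1) if C > 1 else 0.0
        truth.enriched_categories = [config.enriched_category] if ratio > 1 else []
    else:
        boosted = base
    target_set = set(target)
    draws_base = rng.choice(C, size=len(ids), p=base)
    draws_boost = rng.choice(C, size=len(ids), p=boosted)
    values = [
        labels[draws_boost[i] if ids[i] in target_set else draws_base[i]]
        for i in range(len(ids))
    ]
    return pd.Series(values, index=pd.Index(ids)), truth


# ---------------------------------------------------------------------------
# Overlap planting: explicit three-way partition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThreeWayPlan:
    """Exclusive Venn-region sizes for sets A (Met), B (Hairy), C (Kr-h1)."""

    a_only: int
    b_only: int
    c_only: int
    ab: int
    ac: int
    bc: int
    abc: int

    def __post_init__(self) -> None:
        if min(
            self.a_only, self.b_only, self.c_only, self.ab, self.ac, self.bc, self.abc
        ) < 0:
            raise ValueError("Venn region sizes must be non-negative")

    def total(self) -> int:
        return self.a_only + self.b_only + self.c_only + self.ab + self.ac + self.bc + self.abc


def allocate_three_way(
    plan: ThreeWayPlan, ids: Sequence[str]
) -> tuple[dict[str, set[str]], dict[str, list[str]]]:
    """Assign IDs to Venn regions in order; returns (sets A/B/C, region ids).

    Region order: abc, ac, ab, bc, c_only, a_only, b_only — so the three-way
    core occupies the first IDs, which downstream fixtures reuse as the
    co-repressed cohort.
    """
    if plan.total() > len(ids):
        raise ValueError("not enough IDs for the requested overlap structure")
    order = ["abc", "ac", "ab", "bc", "c_only", "a_only", "b_only"]
    regions: dict[str, list[str]] = {}
    cursor = 0
    for name in order:
        size = getattr(plan, name)
        regions[name] = list(ids[cursor : cursor + size])
        cursor += size
    a = set(regions["abc"]) | set(regions["ab"]) | set(regions["ac"]) | set(regions["a_only"])
    b = set(regions["abc"]) | set(regions["ab"]) | set(regions["bc"]) | set(regions["b_only"])
    c = set(regions["abc"]) | set(regions["ac"]) | set(regions["bc"]) | set(regions["c_only"])
    return {"A": a, "B": b, "C": c}, regions
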