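"""KBS-HBS co-occurrence: per-gene nearest-pair distance and orientation.

For each upstream record the exact occurrences of the Kr-h1 binding-site
patterns (default the validated 9-mer TCTATTTAG) and the Hairy binding-site
E-box (default CACGTG) are located on both strands.  Genes carrying at
least one of each contribute a single nearest pair; distances are
start-to-start and "downstream" means closer to the TSS, i.e. the larger
coordinate within the upstream record.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .motifs import Probe, find_occurrences, reverse_complement, _validate_acgt

HBS_DOWNSTREAM = "HBS_downstream"
KBS_DOWNSTREAM = "KBS_downstream"
COINCIDENT = "coincident"

DEFAULT_KBS_PATTERNS = ("TCTATTTAG",)
DEFAULT_HBS_PATTERNS = ("CACGTG",)


@dataclass(frozen=True)
class Site:
    start: int
    end: int
    strand: str
    pattern: str


@dataclass
class SiteCatalog:
    """Per-gene located KBS and HBS occurrences plus record lengths."""

    kbs: dict[str, list[Site]]
    hbs: dict[str, list[Site]]
    record_lengths: dict[str, int]

    def genes(self) -> list[str]:
        return list(self.record_lengths)


def _locate_patterns(seq: str, patterns: Sequence[str]) -> list[Site]:
    sites: list[Site] = []
    for pat in patterns:
        pat = _validate_acgt(pat, "site pattern")
        rc = reverse_complement(pat)
        for s in find_occurrences(seq, pat):
            sites.append(Site(s, s + len(pat), "+", pat))
        if rc != pat:  # palindromes counted once per window
            for s in find_occurrences(seq, rc):
                sites.append(Site(s, s + len(pat), "-", pat))
    sites.sort(key=lambda x: (x.start, x.strand, x.pattern))
    return sites


def locate_sites(
    promoters: Mapping[str, str],
    kbs_patterns: Sequence[str] = DEFAULT_KBS_PATTERNS,
    hbs_patterns: Sequence[str] = DEFAULT_HBS_PATTERNS,
) -> SiteCatalog:
    """Exact-match occurrences of KBS/HBS patterns (and reverse complements)."""
    if not kbs_patterns or not hbs_patterns:
        raise ValueError("pattern lists must be non-empty")
    kbs: dict[str, list[Site]] = {}
    hbs: dict[str, list[Site]] = {}
    lengths: dict[str, int] = {}
    for gene, seq in promoters.items():
        seq = seq.upper()
        kbs[gene] = _locate_patterns(seq, kbs_patterns)
        hbs[gene] = _locate_patterns(seq, hbs_patterns)
        lengths[gene] = len(seq)
    return SiteCatalog(kbs, hbs, lengths)


@dataclass(frozen=True)
class SitePair:
    gene_id: str
    kbs: Site
    hbs: Site
    distance: int
    orientation: str


def _orientation(kbs: Site, hbs: Site) -> str:
    if hbs.start > kbs.start:
        return HBS_DOWNSTREAM
    if kbs.start > hbs.start:
        return KBS_DOWNSTREAM
    return COINCIDENT


def _pair_key(kbs: Site, hbs: Site) -> tuple:
    # Minimise distance; break ties by the pair closest to the TSS (largest
    # coordinate in the upstream record), then by smaller KBS start.
    return (abs(kbs.start - hbs.start), -max(kbs.start, hbs.start), kbs.start)


def pair_sites(catalog: SiteCatalog) -> tuple[list[SitePair], int]:
    """One nearest (KBS, HBS) pair per gene carrying both site types.

    Returns the pairs plus the number of genes excluded for lacking one or
    both sites.  Nearest means minimal |kbs.start - hbs.start|; candidate
    HBS neighbours of each KBS are found by bisection on sorted starts.
    """
    pairs: list[SitePair] = []
    excluded = 0
    for gene in catalog.genes():
        ks, hs = catalog.kbs.get(gene, []), catalog.hbs.get(gene, [])
        if not ks or not hs:
            excluded += 1
            continue
        hstarts = [h.start for h in hs]
        best: tuple | None = None
        best_pair: tuple[Site, Site] | None = None
        for k_site in ks:
            i = bisect.bisect_left(hstarts, k_site.start)
            for j in (i - 1, i, i + 1):
                if 0 <= j < len(hs):
                    key = _pair_key(k_site, hs[j])
                    if best is None or key < best:
                        best, best_pair = key, (k_site, hs[j])
        k_site, h_site = best_pair  # type: ignore[misc]
        pairs.append(
            SitePair(gene, k_site, h_site, best[0], _orientation(k_site, h_site))
        )
    return pairs, excluded


@dataclass
class DistanceSummary:
    """Cohort-level distance fractions and orientation split."""

    n_pairs: int
    n_excluded: int
    frac_within: dict[int, float | None]
    orientation_split: dict[str, float | None]
    n_coincident: int

    def pct_within(self, threshold: int) -> float | None:
        f = self.frac_within[threshold]
        return None if f is None else 100.0 * f


def distance_summary(
    pairs: Sequence[SitePair],
    thresholds: Sequence[int] = (1000, 300),
    n_excluded: int = 0,
) -> DistanceSummary:
    """Fractions of genes with nearest-pair distance strictly below thresholds.

    Orientation fractions are computed over genes whose nearest pair is not
    coincident.  An empty pair list yields None fractions (flagged n = 0).
    """
    if any(t <= 0 for t in thresholds):
        raise ValueError("distance thresholds must be positive")
    n = len(pairs)
    frac: dict[int, float | None] = {}
    for t in thresholds:
        frac[int(t)] = None if n == 0 else sum(p.distance < t for p in pairs) / n
    oriented = [p for p in pairs if p.orientation != COINCIDENT]
    split: dict[str, float | None]
    if oriented:
        split = {
            HBS_DOWNSTREAM: sum(p.orientation == HBS_DOWNSTREAM for p in oriented)
            / len(oriented),
            KBS_DOWNSTREAM: sum(p.orientation == KBS_DOWNSTREAM for p in oriented)
            / len(oriented),
        }
    else:
        split = {HBS_DOWNSTREAM: None, KBS_DOWNSTREAM: None}
    return DistanceSummary(n, n_excluded, frac, split, n - len(oriented))
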