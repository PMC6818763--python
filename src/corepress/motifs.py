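"""Seed-motif k-mer probe enumeration and strand-aware promoter scanning.

The Kr-h1 binding site (KBS) was originally defined in *Bombyx mori* as a
30-bp core sequence.  To localise the mosquito site, the 30-mer is sliced
into overlapping k-mers ("probes", default k = 8) with a one-base sliding
window, and each probe plus its reverse complement is matched exactly
against a set of 5'-upstream regions.  Observed occurrence counts are
compared against the count expected under an i.i.d. background ("random
chance"), with an upper-tail Poisson (or exact binomial) significance, or
against an empirical dinucleotide-preserving shuffle null.

Coordinates are 0-based half-open within each upstream record; the last
base of a record is taken to abut the transcription start site, so a hit's
TSS distance is ``record_length - hit.end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: The 30-mer Bombyx mori Kr-h1 binding-site core used as the default seed.
BMKBS_30MER = "GACCTACGCTAACGCTAAATAGAGTTCCGA"

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over the A/C/G/T/N alphabet.

    Raises ``ValueError`` on any other character.
    """
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"non-ACGTN character in sequence: {exc.args[0]!r}") from exc


def _validate_acgt(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    bad = set(seq) - {"A", "C", "G", "T"}
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class SeedMotif:
    """A seed motif to be sliced into overlapping k-mer probes."""

    sequence: str
    window_k: int = 8

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _validate_acgt(self.sequence, "seed motif"))
        if self.window_k < 1:
            raise ValueError("window_k must be positive")
        if len(self.sequence) < self.window_k:
            raise ValueError("seed motif shorter than the window size")


@dataclass(frozen=True)
class Probe:
    """One k-mer window of a seed motif, with its reverse complement."""

    probe_id: str
    forward: str
    revcomp: str
    is_palindromic: bool

    @classmethod
    def from_kmer(cls, probe_id: str, kmer: str) -> "Probe":
        kmer = _validate_acgt(kmer, "probe")
        rc = reverse_complement(kmer)
        return cls(probe_id, kmer, rc, kmer == rc)


def enumerate_probes(seed: SeedMotif | str, window_k: int = 8, prefix: str = "KBS") -> list[Probe]:
    """Slice a seed motif into its overlapping k-mer probes.

    Probes are numbered by 1-based window start (KBS1 = first window), so a
    seed of length L yields L - k + 1 probes.  Duplicate k-mers are retained
    under distinct identifiers.
    """
    if isinstance(seed, str):
        seed = SeedMotif(seed, window_k)
    k = seed.window_k
    return [
        Probe.from_kmer(f"{prefix}{i + 1}", seed.sequence[i : i + k])
        for i in range(len(seed.sequence) - k + 1)
    ]


@dataclass(frozen=True)
class MotifHit:
    """A located probe occurrence within one upstream record."""

    gene_id: str
    probe_id: str
    strand: str  # "+" forward string matched, "-" reverse complement matched
    start: int
    end: int
    tss_distance: int


def find_occurrences(seq: str, pattern: str) -> list[int]:
    """0-based start positions of every (overlapping) exact occurrence."""
    starts: list[int] = []
    i = seq.find(pattern)
    while i != -1:
        starts.append(i)
        i = seq.find(pattern, i + 1)
    return starts


def scan_probe(promoters: Mapping[str, str], probe: Probe) -> list[MotifHit]:
    """Strand-aware exact scan of a probe over a promoter set.

    Overlapping matches are all reported.  A palindromic probe yields exactly
    one hit per matching window.  Windows containing N never match (exact
    string equality).
    """
    k = len(probe.forward)
    hits: list[MotifHit] = []
    for gene_id, seq in promoters.items():
        seq = seq.upper()
        L = len(seq)
        found = [(s, "+") for s in find_occurrences(seq, probe.forward)]
        if not probe.is_palindromic:
            found += [(s, "-") for s in find_occurrences(seq, probe.revcomp)]
        for start, strand in sorted(found):
            hits.append(MotifHit(gene_id, probe.probe_id, strand, start, start + k, L - (start + k)))
    return hits


@dataclass(frozen=True)
class Background:
    """i.i.d. base-composition null model (A, C, G, T frequencies)."""

    freqs: tuple[float, float, float, float]
    source: str = "uniform"

    def __post_init__(self) -> None:
        if abs(sum(self.freqs) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        if any(f < 0 for f in self.freqs):
            raise ValueError("background frequencies must be non-negative")

    def prob(self, kmer: str) -> float:
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        p = 1.0
        for b in kmer:
            p *= self.freqs[idx[b]]
        return p


def uniform_background() -> Background:
    return Background((0.25, 0.25, 0.25, 0.25), "uniform")


def estimate_background(promoters: Mapping[str, str], source: str = "global") -> Background:
    """Estimate base frequencies from the scanned promoter set (N ignored)."""
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    for seq in promoters.values():
        s = seq.upper()
        for b in counts:
            counts[b] += s.count(b)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("cannot estimate background from empty promoter set")
    return Background(tuple(counts[b] / total for b in "ACGT"), source)


def n_windows(promoters: Mapping[str, str], k: int) -> int:
    """Number of length-k windows per strand over a promoter set."""
    return sum(max(0, len(s) - k + 1) for s in promoters.values())


def expected_hits(promoters: Mapping[str, str], probe: Probe, background: Background) -> float:
    """Expected occurrence count of a probe (both strands) under the i.i.d. null.

    Sum over records of (L - k + 1) * [p(forward) + p(revcomp)]; the reverse-
    complement term is dropped for palindromic probes since each matching
    window is counted once.
    """
    k = len(probe.forward)
    p = background.prob(probe.forward)
    if not probe.is_palindromic:
        p += background.prob(probe.revcomp)
    return n_windows(promoters, k) * p


def probe_significance(
    observed: int,
    expected: float,
    n_windows: int | None = None,
    method: str = "poisson",
) -> float:
    """Upper-tail probability of observing at least `observed` hits under the null.

    Poisson: P(X >= observed | mean = expected).  Binomial: exact tail with
    per-window success probability expected / n_windows.
    """
    if observed < 0:
        raise ValueError("observed count must be non-negative")
    if expected < 0:
        raise ValueError("expected count must be non-negative")
    if observed == 0:
        return 1.0
    if method == "poisson":
        return float(stats.poisson.sf(observed - 1, expected))
    if method == "binomial":
        if not n_windows:
            raise ValueError("binomial significance requires n_windows")
        p = min(1.0, expected / n_windows)
        return float(stats.binom.sf(observed - 1, n_windows, p))
    raise ValueError(f"unknown significance method: {method!r}")


# ---------------------------------------------------------------------------
# Dinucleotide-preserving shuffle null (Altschul & Erickson style)
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts.

    Builds the first-order transition multigraph of the sequence, fixes one
    terminal edge per vertex so the terminal edges form a tree into the last
    character (guaranteeing an Eulerian walk), permutes the remaining edges
    and reads the walk back off.  First and last characters are preserved.
    """
    if len(seq) <= 3:
        return seq
    seq = seq.upper()
    chars = sorted(set(seq))
    edges: dict[str, list[str]] = {c: [] for c in chars}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]

    while True:  # rejection-sample terminal edges forming a tree into `last`
        term: dict[str, str] = {}
        for c in chars:
            if c == last or not edges[c]:
                continue
            term[c] = edges[c][int(rng.integers(len(edges[c])))]
        ok = True
        for c in term:
            seen: set[str] = set()
            cur = c
            while cur != last:
                if cur in seen or cur not in term:
                    ok = False
                    break
                seen.add(cur)
                cur = term[cur]
            if not ok:
                break
        if ok:
            break

    walk_edges: dict[str, list[str]] = {}
    for c in chars:
        rest = list(edges[c])
        if c in term:
            rest.remove(term[c])
        order = rng.permutation(len(rest))
        rest = [rest[i] for i in order]
        if c in term:
            rest.append(term[c])
        walk_edges[c] = rest

    out = [seq[0]]
    cursor = {c: 0 for c in chars}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = walk_edges[cur][cursor[cur]]
        cursor[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def shuffle_null_pvalues(
    promoters: Mapping[str, str],
    probes: Sequence[Probe],
    n_shuffles: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Empirical upper-tail p per probe from dinucleotide-shuffled promoters.

    p = (1 + #{shuffles with count >= observed}) / (n_shuffles + 1).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    observed = {p.probe_id: len(scan_probe(promoters, p)) for p in probes}
    at_least = {p.probe_id: 0 for p in probes}
    for _ in range(n_shuffles):
        shuffled = {g: dinucleotide_shuffle(s, rng) for g, s in promoters.items()}
        for p in probes:
            if len(scan_probe(shuffled, p)) >= observed[p.probe_id]:
                at_least[p.probe_id] += 1
    return {pid: (1 + c) / (n_shuffles + 1) for pid, c in at_least.items()}


def hit_frequency_table(
    promoters: Mapping[str, str],
    probes: Sequence[Probe],
    background: Background | None = None,
    method: str = "poisson",
    n_shuffles: int = 1000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Observed/expected occurrence table for a probe panel over a promoter set.

    One row per probe in input order: observed hits (both strands), number of
    genes with at least one hit, expected hits under the background, the
    upper-tail p-value (``method``: poisson, binomial or shuffle), a
    Bonferroni-scaled column for transparency, and an ``is_max`` flag on the
    probe(s) with the strictly largest non-zero observed count.
    """
    if background is None:
        background = estimate_background(promoters) if promoters else uniform_background()
    if method == "shuffle":
        shuffle_p = shuffle_null_pvalues(promoters, probes, n_shuffles, rng)
    rows = []
    for probe in probes:
        hits = scan_probe(promoters, probe)
        obs = len(hits)
        exp = expected_hits(promoters, probe, background)
        nw = n_windows(promoters, len(probe.forward))
        if method == "shuffle":
            p = shuffle_p[probe.probe_id]
        else:
            p = probe_significance(obs, exp, nw, method)
        rows.append(
            {
                "probe_id": probe.probe_id,
                "forward": probe.forward,
                "revcomp": probe.revcomp,
                "palindromic": probe.is_palindromic,
                "observed_hits": obs,
                "genes_with_hit": len({h.gene_id for h in hits}),
                "expected_hits": exp,
                "n_windows": nw,
                "p_value": p,
                "p_bonferroni": min(1.0, p * len(probes)),
            }
        )
    table = pd.DataFrame(rows)
    max_obs = table["observed_hits"].max() if len(table) else 0
    table["is_max"] = (table["observed_hits"] == max_obs) & (table["observed_hits"] > 0)
    return table
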