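"""Probe enumeration, strand-aware scanning and the occurrence null model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from corepress.motifs import (
    BMKBS_30MER,
    Background,
    Probe,
    dinucleotide_shuffle,
    enumerate_probes,
    estimate_background,
    expected_hits,
    find_occurrences,
    hit_frequency_table,
    n_windows,
    probe_significance,
    reverse_complement,
    scan_probe,
    shuffle_null_pvalues,
    uniform_background,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=300)


def naive_count(seq: str, probe: Probe) -> int:
    """Independent O(L*k) sliding-window comparison oracle."""
    k = len(probe.forward)
    total = 0
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if window == probe.forward:
            total += 1
        elif not probe.is_palindromic and window == probe.revcomp:
            total += 1
    return total


class TestReverseComplement:
    def test_printed_motif(self):
        assert reverse_complement("TAAATAGA") == "TCTATTTA"

    def test_palindromic_ebox(self):
        assert reverse_complement("CACGTG") == "CACGTG"

    def test_empty(self):
        assert reverse_complement("") == ""

    def test_rejects_other_letters(self):
        with pytest.raises(ValueError):
            reverse_complement("ACGU")

    @settings(derandomize=True, max_examples=100)
    @given(dna)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq


class TestEnumerateProbes:
    def test_bombyx_seed_yields_23_probes(self):
        probes = enumerate_probes(BMKBS_30MER)
        assert len(probes) == 23
        assert probes[0].probe_id == "KBS1" and probes[0].forward == "GACCTACG"
        kbs16 = probes[15]
        assert kbs16.probe_id == "KBS16"
        assert kbs16.forward == "TAAATAGA" and kbs16.revcomp == "TCTATTTA"

    def test_seed_equal_to_window_gives_single_probe(self):
        probes = enumerate_probes("TAAATAGA")
        assert len(probes) == 1 and probes[0].forward == "TAAATAGA"

    def test_non_acgt_seed_rejected(self):
        with pytest.raises(ValueError):
            enumerate_probes("ACGTNACGT")

    @settings(derandomize=True, max_examples=60)
    @given(st.text(alphabet="ACGT", min_size=8, max_size=50))
    def test_length_law(self, seed):
        assert len(enumerate_probes(seed)) == len(seed) - 8 + 1


class TestScan:
    def test_single_planted_minus_strand_hit(self):
        probes = enumerate_probes(BMKBS_30MER)
        kbs16 = probes[15]
        hits = scan_probe({"g": "AAATCTATTTAGCC"}, kbs16)
        assert len(hits) == 1
        (h,) = hits
        assert (h.strand, h.start, h.end) == ("-", 3, 11)
        assert h.tss_distance == len("AAATCTATTTAGCC") - 11

    def test_empty_promoter_set(self):
        assert scan_probe({}, Probe.from_kmer("p", "ACGTACGT")) == []

    def test_overlapping_matches_counted(self):
        probe = Probe.from_kmer("p", "AAAAAAAA")
        assert len(scan_probe({"g": "AAAAAAAAA"}, probe)) == 2

    def test_palindromic_window_counted_once(self):
        probe = Probe.from_kmer("p", "ACGTACGT")  # self-reverse-complementary
        assert probe.is_palindromic
        assert len(scan_probe({"g": "CCACGTACGTCC"}, probe)) == 1

    def test_n_windows_never_match(self):
        probe = Probe.from_kmer("p", "AAAAAAAA")
        assert scan_probe({"g": "AAAANAAAA"}, probe) == []

    @settings(derandomize=True, max_examples=150)
    @given(dna, st.text(alphabet="ACGT", min_size=8, max_size=30), st.integers(0, 22))
    def test_scanner_equals_naive_oracle(self, seq, seed, offset):
        probes = enumerate_probes(seed)
        probe = probes[offset % len(probes)]
        assert len(scan_probe({"g": seq}, probe)) == naive_count(seq, probe)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.text(alphabet="ACGT", min_size=20, max_size=200), min_size=1, max_size=5))
    def test_strand_symmetry(self, seqs):
        """Reverse-complementing every record preserves each probe's total count."""
        promoters = {f"g{i}": s for i, s in enumerate(seqs)}
        flipped = {g: reverse_complement(s) for g, s in promoters.items()}
        for probe in enumerate_probes(BMKBS_30MER)[::5]:
            assert len(scan_probe(promoters, probe)) == len(scan_probe(flipped, probe))


class TestNullModel:
    def test_expected_hits_closed_form(self):
        promoters = {"g": "A" * 5000}
        probe = Probe.from_kmer("p", "GACCTACG")  # non-palindromic
        exp = expected_hits(promoters, probe, uniform_background())
        assert exp == pytest.approx(4993 * 2 * 0.25**8, rel=1e-12)

    def test_palindromic_probe_half_expectation(self):
        promoters = {"g": "A" * 5000}
        probe = Probe.from_kmer("p", "ACGTACGT")
        exp = expected_hits(promoters, probe, uniform_background())
        assert exp == pytest.approx(4993 * 0.25**8, rel=1e-12)

    def test_zero_frequency_base_gives_zero_expectation(self):
        bg = Background((0.5, 0.25, 0.25, 0.0), "custom")  # freq(T) = 0
        probe = Probe.from_kmer("p", "AATTCCGG")
        assert expected_hits({"g": "A" * 100}, probe, bg) == 0.0

    def test_expected_hits_monte_carlo(self):
        """Mean occurrence count of a fixed 8-mer (both strands) over random
        uniform 5-kb sequences approaches 2 * 4993 / 4^8 ~= 0.1524."""
        rng = np.random.default_rng(11)
        bases = np.frombuffer(b"ACGT", dtype="S1")
        probe = Probe.from_kmer("p", "GACCTACG")
        n_seq = 5000
        total = 0
        for _ in range(n_seq):
            seq = bases[rng.integers(0, 4, size=5000)].tobytes().decode()
            total += len(find_occurrences(seq, probe.forward))
            total += len(find_occurrences(seq, probe.revcomp))
        assert total / n_seq == pytest.approx(0.15237, abs=0.02)

    def test_significance_examples(self):
        assert probe_significance(0, 3.7) == 1.0
        # P(X >= 3 | mean 0.5) = 1 - e^-0.5 (1 + 0.5 + 0.125)
        assert probe_significance(3, 0.5) == pytest.approx(0.014388, abs=1e-5)
        with pytest.raises(ValueError):
            probe_significance(-1, 0.5)

    def test_large_excess_is_astronomically_significant(self):
        # 61 observed against a sub-unit expectation: log-survival stays finite
        assert 0 < probe_significance(61, 0.15) < 1e-15

    def test_binomial_option_close_to_poisson_in_sparse_regime(self):
        poisson = probe_significance(4, 0.8)
        binom = probe_significance(4, 0.8, n_windows=100_000, method="binomial")
        assert binom == pytest.approx(poisson, rel=1e-3)

    def test_estimated_background_matches_composition(self):
        bg = estimate_background({"g": "AACCGGTT", "h": "ACGT"})
        assert bg.freqs == pytest.approx((0.25, 0.25, 0.25, 0.25))


class TestHitTable:
    def test_deterministic_output(self):
        rng = np.random.default_rng(5)
        bases = np.frombuffer(b"ACGT", dtype="S1")
        promoters = {
            f"g{i}": bases[rng.integers(0, 4, 500)].tobytes().decode() for i in range(5)
        }
        probes = enumerate_probes(BMKBS_30MER)
        a = hit_frequency_table(promoters, probes).to_csv()
        b = hit_frequency_table(promoters, probes).to_csv()
        assert a == b

    def test_argmax_undefined_on_matchless_input(self):
        promoters = {"g": "C" * 1000}
        probes = enumerate_probes(BMKBS_30MER)
        table = hit_frequency_table(promoters, probes, uniform_background())
        assert (table["observed_hits"] == 0).all()
        assert not table["is_max"].any()

    def test_window_count_bookkeeping(self):
        assert n_windows({"a": "A" * 100, "b": "A" * 8, "c": "A" * 3}, 8) == 93 + 1 + 0


class TestShuffleNull:
    def test_shuffle_preserves_dinucleotide_counts(self):
        rng = np.random.default_rng(17)
        bases = np.frombuffer(b"ACGT", dtype="S1")
        seq = bases[rng.integers(0, 4, 400)].tobytes().decode()

        def dinucs(s):
            counts = {}
            for a, b in zip(s, s[1:]):
                counts[a + b] = counts.get(a + b, 0) + 1
            return counts

        for _ in range(5):
            shuffled = dinucleotide_shuffle(seq, rng)
            assert dinucs(shuffled) == dinucs(seq)
            assert shuffled[0] == seq[0] and shuffled[-1] == seq[-1]

    def test_empirical_pvalues_in_unit_interval(self):
        rng = np.random.default_rng(23)
        bases = np.frombuffer(b"ACGT", dtype="S1")
        promoters = {"g": bases[rng.integers(0, 4, 600)].tobytes().decode()}
        probes = enumerate_probes(BMKBS_30MER)[:3]
        pvals = shuffle_null_pvalues(promoters, probes, n_shuffles=50, rng=rng)
        assert all(0 < p <= 1 for p in pvals.values())
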