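"""Ground-truth generators: determinism, planted effects, background laws."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from corepress.expression import call_upregulated
from corepress.motifs import reverse_complement
from corepress.synthetic import (
    SyntheticConfig,
    ThreeWayPlan,
    allocate_three_way,
    gen_annotation,
    gen_expression,
    gen_promoters,
)


def _ids(n):
    return [f"T{i + 1:06d}" for i in range(n)]


class TestConfigValidation:
    def test_background_freqs_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SyntheticConfig(background_freqs=(0.5, 0.5, 0.5, 0.5))

    def test_planted_set_must_lie_in_universe(self):
        with pytest.raises(ValueError):
            SyntheticConfig(
                n_transcripts=10, planted_up_sets={"iMet": frozenset({"nope"})}
            )

    def test_plant_must_fit_promoter(self):
        with pytest.raises(ValueError):
            SyntheticConfig(
                promoter_length=100,
                promoter_ids=("g",),
                plant_plan=(("g", "ACGTACGT", "+", 95),),
            )

    def test_plant_motif_must_be_dna(self):
        with pytest.raises(ValueError):
            SyntheticConfig(
                promoter_ids=("g",), plant_plan=(("g", "ACGU", "+", 0),)
            )


class TestExpression:
    def test_regeneration_is_byte_identical(self):
        cfg = SyntheticConfig(rng_seed=3, n_transcripts=100)
        a, _ = gen_expression(cfg)
        b, _ = gen_expression(cfg)
        assert a.to_csv() == b.to_csv()

    def test_zero_noise_planted_fold_is_exact(self):
        planted = frozenset(_ids(50)[:10])
        cfg = SyntheticConfig(
            rng_seed=1,
            n_transcripts=50,
            noise_cv=0.0,
            planted_log2fc=2.0,
            planted_up_sets={"iKr-h1": planted},
        )
        table, truth = gen_expression(cfg)
        ratio = table["iKr-h1"] / table["iLuc"]
        assert np.allclose(ratio[sorted(planted)], 4.0)
        others = [t for t in table.index if t not in planted]
        assert np.allclose(ratio[others], 1.0)
        assert truth.up_sets_by_treatment["iKr-h1"] == set(planted)

    def test_zero_noise_recovery_is_set_exact(self):
        planted = frozenset(_ids(300)[:231])
        cfg = SyntheticConfig(
            rng_seed=2, n_transcripts=300, noise_cv=0.0,
            planted_up_sets={"iKr-h1": planted},
        )
        table, _ = gen_expression(cfg)
        up, _ = call_upregulated(table, "iKr-h1", "iLuc")
        assert up == set(planted) and len(up) == 231

    def test_noisy_recovery_rate(self):
        """A planted four-fold effect with 10% multiplicative noise is
        recovered in at least 95% of planted transcripts."""
        planted = frozenset(_ids(2000)[:200])
        cfg = SyntheticConfig(
            rng_seed=5, n_transcripts=2000, noise_cv=0.1,
            planted_up_sets={"iKr-h1": planted},
        )
        table, _ = gen_expression(cfg)
        up, _ = call_upregulated(table, "iKr-h1", "iLuc")
        assert len(up & planted) / len(planted) >= 0.95

    def test_baseline_floor_applies_to_planted_only(self):
        planted = frozenset(_ids(500)[:100])
        cfg = SyntheticConfig(
            rng_seed=6, n_transcripts=500, noise_cv=0.0,
            planted_up_sets={"iMet": planted}, planted_min_fpkm=50.0,
        )
        table, _ = gen_expression(cfg)
        assert (table.loc[sorted(planted), "iLuc"] >= 50.0).all()


class TestPromoters:
    def test_regeneration_is_byte_identical(self):
        cfg = SyntheticConfig(rng_seed=4, promoter_ids=("a", "b"), promoter_length=500)
        a, _ = gen_promoters(cfg)
        b, _ = gen_promoters(cfg)
        assert a == b

    def test_minus_strand_plant_written_as_revcomp(self):
        cfg = SyntheticConfig(
            rng_seed=0,
            promoter_ids=("g",),
            promoter_length=300,
            plant_plan=(("g", "TAAATAGA", "-", 100),),
        )
        promoters, truth = gen_promoters(cfg)
        assert promoters["g"][100:108] == "TCTATTTA"
        assert truth.planted_sites == [("g", "TAAATAGA", "-", 100, 108)]

    def test_truth_records_surviving_plants_only(self):
        cfg = SyntheticConfig(
            rng_seed=0,
            promoter_ids=("g",),
            promoter_length=100,
            plant_plan=(("g", "AAAAAAAA", "+", 10), ("g", "CCCCCCCC", "+", 14)),
        )
        promoters, truth = gen_promoters(cfg)
        assert promoters["g"][14:22] == "CCCCCCCC"
        assert truth.planted_sites == [("g", "CCCCCCCC", "+", 14, 22)]

    def test_every_planted_site_matches_emitted_sequence(self):
        rng = np.random.default_rng(12)
        plan = []
        for i in range(30):
            gene = f"g{i % 6}"
            start = int(rng.integers(0, 5000 - 9))
            strand = "+" if rng.random() < 0.5 else "-"
            plan.append((gene, "TCTATTTAG", strand, start))
        cfg = SyntheticConfig(
            rng_seed=13,
            promoter_ids=tuple(f"g{i}" for i in range(6)),
            plant_plan=tuple(plan),
        )
        promoters, truth = gen_promoters(cfg)
        for gene, motif, strand, start, end in truth.planted_sites:
            expected = motif if strand == "+" else reverse_complement(motif)
            assert promoters[gene][start:end] == expected

    def test_background_composition_converges(self):
        """Chi-square goodness of fit over >= 1e6 background bases is not
        rejected at alpha = 0.001."""
        freqs = (0.3, 0.2, 0.2, 0.3)
        cfg = SyntheticConfig(
            rng_seed=21,
            promoter_ids=tuple(f"g{i}" for i in range(200)),
            promoter_length=5000,
            background_freqs=freqs,
        )
        promoters, _ = gen_promoters(cfg)
        joined = "".join(promoters.values())
        counts = np.array([joined.count(b) for b in "ACGT"])
        assert counts.sum() == 1_000_000
        _, p = stats.chisquare(counts, counts.sum() * np.array(freqs))
        assert p > 0.001


class TestAnnotation:
    def test_exact_mode_is_deterministic_and_counted(self):
        cfg = SyntheticConfig(
            rng_seed=8,
            n_transcripts=100,
            category_labels=tuple("OVTW"),
            enriched_gene_set=frozenset(_ids(100)[:20]),
            target_category_counts={"O": 12, "V": 6},
        )
        a, truth = gen_annotation(cfg)
        b, _ = gen_annotation(cfg)
        assert a.equals(b)
        target = _ids(100)[:20]
        assert (a[target] == "O").sum() == 12 and (a[target] == "V").sum() == 6
        assert truth.enriched_categories == ["O", "V"]

    def test_ratio_one_is_null(self):
        cfg = SyntheticConfig(
            rng_seed=9, n_transcripts=200, category_labels=tuple("ABCD"),
            enriched_category="A", enrichment_ratio=1.0,
            enriched_gene_set=frozenset(_ids(200)[:50]),
        )
        _, truth = gen_annotation(cfg)
        assert truth.enriched_categories == []

    def test_infeasible_ratio_rejected(self):
        cfg_kwargs = dict(
            rng_seed=0, n_transcripts=10, category_labels=tuple("AB"),
            enriched_category="A", enrichment_ratio=3.0,
            enriched_gene_set=frozenset(_ids(10)[:5]),
        )
        cfg = SyntheticConfig(**cfg_kwargs)
        with pytest.raises(ValueError):
            gen_annotation(cfg)


class TestThreeWayAllocation:
    def test_region_sizes_and_memberships(self):
        plan = ThreeWayPlan(a_only=5, b_only=4, c_only=3, ab=2, ac=2, bc=1, abc=6)
        ids = _ids(30)
        sets, regions = allocate_three_way(plan, ids)
        assert len(sets["A"]) == 5 + 2 + 2 + 6
        assert len(sets["B"]) == 4 + 2 + 1 + 6
        assert len(sets["C"]) == 3 + 2 + 1 + 6
        assert sets["A"] & sets["B"] & sets["C"] == set(regions["abc"])
        assert len(sets["A"] & sets["C"]) == plan.ac + plan.abc

    def test_insufficient_ids_rejected(self):
        plan = ThreeWayPlan(10, 10, 10, 0, 0, 0, 0)
        with pytest.raises(ValueError):
            allocate_three_way(plan, _ids(20))
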