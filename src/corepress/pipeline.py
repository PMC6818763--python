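"""End-to-end driver and ground-truth fixture bundles.

The analysis graph mirrors the study design: per-replicate FPKM tables are
abundance-filtered (top-N per treatment/control pair) and fold-change
called; the knockdown up-sets are intersected (Met/Hairy/Kr-h1 Venn and
the three-replicate Kr-h1 consensus); 5-kb upstream regions of the
Met∩Kr-h1 up-set are scanned with the 23 KBS probes; KBS-HBS nearest-pair
distances and orientations are summarised over the three-way co-repressed
cohort; and that cohort is tested for orthologous-group overrepresentation
against the abundance-filtered universe.

``make_fixture_bundle`` writes a fully synthetic input bundle at either a
small scale (fast tests) or the published scale (set sizes 1613/311/231,
overlaps 212/137/130, replicate consensus 207, 61 top-probe occurrences,
92%/70% distance fractions, 53%/47% orientation split) with every quantity
planted, so the pipeline's outputs can be checked exactly.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from . import io as cio
from .cooccurrence import (
    DistanceSummary,
    SitePair,
    distance_summary,
    locate_sites,
    pair_sites,
)
from .enrichment import enrich_categories
from .expression import (
    OverlapResult,
    call_upregulated,
    overlap_sets,
    replicate_consensus,
    select_top_abundant,
)
from .motifs import (
    BMKBS_30MER,
    MotifHit,
    enumerate_probes,
    estimate_background,
    hit_frequency_table,
    scan_probe,
)
from .synthetic import (
    SyntheticConfig,
    ThreeWayPlan,
    allocate_three_way,
    gen_annotation,
    gen_expression,
    gen_promoters,
)


class PipelineError(RuntimeError):
    """Stage-labelled pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    expression_tables: tuple[str, ...]
    out_dir: str
    control: str = "iLuc"
    consensus_treatment: str = "iKr-h1"
    scan_fasta: str | None = None
    cooccur_fasta: str | None = None
    annotation: str | None = None
    external_up_sets: dict[str, str] = field(default_factory=dict)
    log2fc_threshold: float = 1.0
    pseudocount: float = 0.01
    top_n: int = 10000
    seed_motif: str = BMKBS_30MER
    window_k: int = 8
    kbs_patterns: tuple[str, ...] = ("TCTATTTAG",)
    hbs_patterns: tuple[str, ...] = ("CACGTG",)
    distance_thresholds: tuple[int, ...] = (1000, 300)
    alpha: float = 0.01
    null_model: str = "analytic"  # or "shuffle"
    n_shuffles: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for value, name in (
            (self.log2fc_threshold, "log2fc_threshold"),
            (self.top_n, "top_n"),
            (self.window_k, "window_k"),
            (self.alpha, "alpha"),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("expression_tables", "kbs_patterns", "hbs_patterns", "distance_thresholds"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for key, value in data.items():
            if isinstance(value, tuple):
                data[key] = list(value)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# Run
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    up_sets: list[dict[str, set[str]]]          # per replicate: treatment -> up-set
    universes: list[dict[str, list[str]]]       # per replicate: treatment -> top-N ids
    overlap: OverlapResult
    consensus: set[str]
    hit_table: pd.DataFrame
    hits: list[MotifHit]
    pairs: list[SitePair]
    site_summary: DistanceSummary
    enrichment: pd.DataFrame
    manifest: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis graph, writing stage outputs under out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "inputs": {},
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    try:
        # ---- stage: differential ------------------------------------------
        stage = "differential"
        external = {
            label: cio.read_gene_set(_require(path, stage))
            for label, path in config.external_up_sets.items()
        }
        up_sets: list[dict[str, set[str]]] = []
        universes: list[dict[str, list[str]]] = []
        for rep, path in enumerate(config.expression_tables, start=1):
            table = cio.read_expression_tsv(_require(path, stage))
            manifest["inputs"][f"expression_rep{rep}"] = cio.sha256_of(path)
            rep_up: dict[str, set[str]] = {}
            rep_universe: dict[str, list[str]] = {}
            for treatment in table.columns:
                if treatment == config.control:
                    continue
                universe = select_top_abundant(
                    table, treatment, config.control, min(config.top_n, len(table))
                )
                rep_universe[treatment] = list(universe)
                if treatment in external:
                    rep_up[treatment] = set(external[treatment])
                    continue
                up, _ = call_upregulated(
                    table,
                    treatment,
                    config.control,
                    config.log2fc_threshold,
                    config.pseudocount,
                    universe=universe,
                )
                rep_up[treatment] = up
            up_sets.append(rep_up)
            universes.append(rep_universe)
            for treatment, ids in rep_up.items():
                cio.write_gene_set(ids, out / f"upset_rep{rep}_{_slug(treatment)}.txt")
        manifest["stages"]["differential"] = {
            f"rep{r + 1}": {t: len(s) for t, s in rep.items()}
            for r, rep in enumerate(up_sets)
        }

        # ---- stage: overlap ----------------------------------------------
        stage = "overlap"
        overlap = overlap_sets(up_sets[0])
        overlap.to_frame().to_csv(out / "overlap_rep1.tsv", sep="\t", index=False)
        manifest["stages"]["overlap"] = {
            "&".join(labels): size
            for labels, size in (
                ((a,), overlap.size(a)) for a in overlap.labels
            )
        }

        # ---- stage: consensus --------------------------------------------
        stage = "consensus"
        kr_label = config.consensus_treatment
        consensus = replicate_consensus([rep[kr_label] for rep in up_sets])
        cio.write_gene_set(consensus, out / "consensus.txt")
        manifest["stages"]["consensus"] = {"size": len(consensus)}

        # ---- stage: scan --------------------------------------------------
        stage = "scan"
        hit_table = pd.DataFrame()
        hits: list[MotifHit] = []
        if config.scan_fasta:
            promoters = cio.read_promoters(_require(config.scan_fasta, stage))
            manifest["inputs"]["scan_fasta"] = cio.sha256_of(config.scan_fasta)
            cohort = _scan_cohort(up_sets[0], config)
            if cohort is not None:
                promoters = {g: s for g, s in promoters.items() if g in cohort}
            if not promoters:
                raise PipelineError(stage, "no promoter records for the scan cohort")
            probes = enumerate_probes(config.seed_motif, config.window_k)
            background = estimate_background(promoters)
            method = "poisson" if config.null_model == "analytic" else "shuffle"
            import numpy as np

            hit_table = hit_frequency_table(
                promoters,
                probes,
                background,
                method=method,
                n_shuffles=config.n_shuffles,
                rng=np.random.default_rng(config.rng_seed),
            )
            hit_table.to_csv(out / "hit_table.tsv", sep="\t", index=False)
            for probe in probes:
                hits.extend(scan_probe(promoters, probe))
            cio.write_bed6(hits, out / "hits.bed")
            manifest["stages"]["scan"] = {
                "n_promoters": len(promoters),
                "total_hits": int(hit_table["observed_hits"].sum()),
            }

        # ---- stage: cooccurrence -----------------------------------------
        stage = "cooccurrence"
        pairs: list[SitePair] = []
        summary = distance_summary([], config.distance_thresholds)
        if config.cooccur_fasta:
            promoters = cio.read_promoters(_require(config.cooccur_fasta, stage))
            manifest["inputs"]["cooccur_fasta"] = cio.sha256_of(config.cooccur_fasta)
            cohort = _triple_cohort(up_sets[0], config)
            if cohort is not None:
                promoters = {g: s for g, s in promoters.items() if g in cohort}
            if not promoters:
                raise PipelineError(stage, "no promoter records for the co-occurrence cohort")
            catalog = locate_sites(promoters, config.kbs_patterns, config.hbs_patterns)
            pairs, excluded = pair_sites(catalog)
            summary = distance_summary(pairs, config.distance_thresholds, excluded)
            _write_pairs(pairs, out / "site_pairs.tsv")
            _write_summary(summary, out / "distance_summary.tsv")
            manifest["stages"]["cooccurrence"] = {
                "n_pairs": summary.n_pairs,
                "n_excluded": summary.n_excluded,
            }

        # ---- stage: enrichment -------------------------------------------
        stage = "enrichment"
        enrichment = pd.DataFrame()
        if config.annotation:
            annot = cio.read_annotation(_require(config.annotation, stage))
            manifest["inputs"]["annotation"] = cio.sha256_of(config.annotation)
            background = set(universes[0][config.consensus_treatment])
            target = _triple_cohort(up_sets[0], config) or set()
            target = set(target) & background
            enrichment = enrich_categories(target, background, annot, config.alpha)
            enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            manifest["stages"]["enrichment"] = {
                "n_significant": int(enrichment["significant"].sum())
                if len(enrichment)
                else 0
            }
    except PipelineError:
        (out / "FAILED").write_text(stage)
        raise
    except Exception as exc:  # noqa: BLE001 - re-label with the failing stage
        (out / "FAILED").write_text(stage)
        raise PipelineError(stage, str(exc)) from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return PipelineResult(
        up_sets, universes, overlap, consensus, hit_table, hits, pairs, summary,
        enrichment, manifest,
    )


def _require(path: str | Path, stage: str) -> str:
    if not Path(path).exists():
        raise PipelineError(stage, f"missing input file: {path}")
    return str(path)


def _slug(label: str) -> str:
    return label.replace("/", "_").replace(" ", "_")


def _scan_cohort(rep1: Mapping[str, set[str]], config: PipelineConfig) -> set[str] | None:
    """Met∩Kr-h1 up-set (the scan substrate) when both labels are present."""
    if "iMet" in rep1 and config.consensus_treatment in rep1:
        return rep1["iMet"] & rep1[config.consensus_treatment]
    return None


def _triple_cohort(rep1: Mapping[str, set[str]], config: PipelineConfig) -> set[str] | None:
    labels = ("iMet", "iHairy", config.consensus_treatment)
    if all(lab in rep1 for lab in labels):
        return rep1[labels[0]] & rep1[labels[1]] & rep1[labels[2]]
    return None


def _write_pairs(pairs: Sequence[SitePair], path: Path) -> None:
    rows = [
        {
            "gene_id": p.gene_id,
            "kbs_start": p.kbs.start,
            "kbs_strand": p.kbs.strand,
            "hbs_start": p.hbs.start,
            "hbs_strand": p.hbs.strand,
            "distance": p.distance,
            "orientation": p.orientation,
        }
        for p in pairs
    ]
    pd.DataFrame(rows, columns=[
        "gene_id", "kbs_start", "kbs_strand", "hbs_start", "hbs_strand",
        "distance", "orientation",
    ]).to_csv(path, sep="\t", index=False)


def _write_summary(summary: DistanceSummary, path: Path) -> None:
    rows = [{"metric": "n_pairs", "value": summary.n_pairs},
            {"metric": "n_excluded", "value": summary.n_excluded}]
    for t, f in summary.frac_within.items():
        rows.append({"metric": f"frac_within_{t}bp", "value": f})
    for o, f in summary.orientation_split.items():
        rows.append({"metric": f"frac_{o}", "value": f})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Fixture bundles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalePlan:
    """Planted structure of a synthetic bundle (all counts are ground truth)."""

    name: str
    n_transcripts: int
    top_n: int
    venn: ThreeWayPlan  # A = iMet, B = iHairy, C = iKr-h1 (replicate 1)
    core_size: int       # Kr-h1 up-set common to all three replicates
    core_in_met: int
    rep_extras: tuple[tuple[int, int], ...]  # (extra, extra∩Met) for reps 2, 3
    scan_probe_counts: dict[str, int]
    cooccur_distances: tuple[int, ...]
    n_hbs_downstream: int
    n_kbs_only: int
    n_hbs_only: int
    category_labels: tuple[str, ...]
    target_category_counts: dict[str, int]
    significant_categories: tuple[str, ...] = ()
    promoter_length: int = 5000
    planted_log2fc: float = 2.0
    noise_cv: float = 0.0
    planted_min_fpkm: float = 50.0


def _band(counts: Sequence[int], first: int = 10) -> dict[str, int]:
    return {f"KBS{first + i}": c for i, c in enumerate(counts)}


#: Published-scale plan.  Replicate-1 Venn regions follow from the printed
#: counts (|Met|=1613, |Hairy|=311, |Kr|=231, |Met∩Kr|=212, |Kr∩Hairy|=137,
#: triple=130 and |(Kr∪Hairy)∩Met|=329 hence |Met∩Hairy|=247); the
#: significant probe band KBS10-KBS21 peaks at 61 occurrences for KBS16.
PAPER_PLAN = ScalePlan(
    name="paper",
    n_transcripts=12000,
    top_n=10000,
    venn=ThreeWayPlan(
        a_only=1284, b_only=57, c_only=12, ab=117, ac=82, bc=7, abc=130
    ),
    core_size=207,
    core_in_met=198,
    rep_extras=((37, 24), (16, 3)),
    scan_probe_counts=_band([18, 22, 26, 30, 34, 38, 61, 42, 37, 29, 23, 19]),
    cooccur_distances=tuple(
        [60 + 3 * i for i in range(70)]
        + [350 + 25 * i for i in range(22)]
        + [1100 + 100 * i for i in range(8)]
    ),
    n_hbs_downstream=53,
    n_kbs_only=15,
    n_hbs_only=10,
    category_labels=tuple("OVTWPQCEFGHIDMNUZABK"),
    target_category_counts={"O": 26, "V": 22, "T": 20, "P": 18, "Q": 18, "W": 2},
    significant_categories=("O", "P", "Q", "T", "V"),
)

SMALL_PLAN = ScalePlan(
    name="small",
    n_transcripts=600,
    top_n=500,
    venn=ThreeWayPlan(a_only=124, b_only=14, c_only=1, ab=9, ac=12, bc=2, abc=15),
    core_size=24,
    core_in_met=23,
    rep_extras=((8, 6), (4, 2)),
    scan_probe_counts={"KBS12": 4, "KBS16": 9, "KBS19": 3},
    cooccur_distances=(80, 110, 140, 170, 200, 230, 260, 400, 600, 1200),
    n_hbs_downstream=5,
    n_kbs_only=3,
    n_hbs_only=1,
    category_labels=tuple("OVTWPQCE"),
    target_category_counts={"O": 8, "V": 7},
    significant_categories=("O", "V"),
)

_PLANS = {"paper": PAPER_PLAN, "small": SMALL_PLAN}


@dataclass
class FixtureBundle:
    root: Path
    config: PipelineConfig
    truth: dict


def _replicate_kr_sets(
    plan: ScalePlan, regions: Mapping[str, list[str]], unassigned: list[str]
) -> tuple[list[set[str]], set[str]]:
    """Kr-h1 up-sets for replicates 1..3 sharing a fixed consensus core."""
    k1 = set(regions["abc"]) | set(regions["ac"]) | set(regions["bc"]) | set(regions["c_only"])
    n_from_ac = plan.core_in_met - len(regions["abc"])
    n_non_met = plan.core_size - plan.core_in_met
    non_met_pool = regions["bc"] + regions["c_only"]
    if not (0 <= n_from_ac <= len(regions["ac"]) and 0 <= n_non_met <= len(non_met_pool)):
        raise ValueError("consensus core incompatible with the Venn regions")
    core = set(regions["abc"]) | set(regions["ac"][:n_from_ac]) | set(non_met_pool[:n_non_met])
    kr_sets = [k1]
    met_pool = list(regions["a_only"])  # in Met, outside replicate-1 Kr set
    fresh_pool = list(unassigned)
    for extra, extra_in_met in plan.rep_extras:
        n_fresh = extra - extra_in_met
        if extra_in_met > len(met_pool) or n_fresh > len(fresh_pool):
            raise ValueError("not enough spare IDs for replicate extras")
        extras = set(met_pool[:extra_in_met]) | set(fresh_pool[:n_fresh])
        met_pool = met_pool[extra_in_met:]
        fresh_pool = fresh_pool[n_fresh:]
        kr_sets.append(core | extras)
    return kr_sets, core


def _padded_plant(content: str, probes: Sequence) -> str:
    """Pad a planted k-mer with flanking bases that add no spurious probe match.

    On a homogeneous poly-C background a bare plant can recreate an adjacent
    window of the same seed (overlapping k-mers of one 30-mer necessarily
    share 7 bases), so the flanks are chosen by brute force: embed the padded
    plant in a C sea and require that exactly one probe window matches.
    """
    from .motifs import find_occurrences

    for left in "GCAT":
        for right in "GCAT":
            padded = left + content + right
            probe_sea = "C" * 20 + padded + "C" * 20
            total = 0
            for q in probes:
                total += len(find_occurrences(probe_sea, q.forward))
                if not q.is_palindromic:
                    total += len(find_occurrences(probe_sea, q.revcomp))
            if total == 1:
                return padded
    raise ValueError(f"no collision-free flanks for plant {content!r}")


def _scan_plant_plan(
    genes: Sequence[str], probe_counts: Mapping[str, int], probes_by_id, gap: int = 12
) -> list[tuple[str, str, str, int]]:
    """Distribute planted probe occurrences over genes, padded and spaced.

    Minus-strand occurrences are planted as the reverse complement of the
    probe (written on the plus strand of the record), so the scanner reports
    them as '-' hits.  All plants are written as '+' strand plan entries of
    their padded content.
    """
    probes = list(probes_by_id.values())
    plan: list[tuple[str, str, str, int]] = []
    cursor = {g: 100 for g in genes}
    gi = 0
    for pid, count in probe_counts.items():
        probe = probes_by_id[pid]
        from .motifs import reverse_complement

        padded = {
            "+": _padded_plant(probe.forward, probes),
            "-": _padded_plant(reverse_complement(probe.forward), probes),
        }
        for j in range(count):
            g = genes[gi % len(genes)]
            content = padded["+" if j % 2 == 0 else "-"]
            plan.append((g, content, "+", cursor[g]))
            cursor[g] += len(content) + gap
            gi += 1
    return plan


def _cooccur_plant_plan(
    plan: ScalePlan, genes: Sequence[str], kbs: str, hbs: str, anchor: int = 2500
) -> list[tuple[str, str, str, int]]:
    plants: list[tuple[str, str, str, int]] = []
    n_both = len(plan.cooccur_distances)
    for i, gene in enumerate(genes):
        if i < n_both:
            d = plan.cooccur_distances[i]
            strand = "+" if i % 2 == 0 else "-"
            if i < plan.n_hbs_downstream:  # HBS closer to the TSS
                plants.append((gene, kbs, strand, anchor))
                plants.append((gene, hbs, "+", anchor + d))
            else:
                plants.append((gene, hbs, "+", anchor))
                plants.append((gene, kbs, strand, anchor + d))
        elif i < n_both + plan.n_kbs_only:
            plants.append((gene, kbs, "+", 2000))
        elif i < n_both + plan.n_kbs_only + plan.n_hbs_only:
            plants.append((gene, hbs, "+", 2200))
    return plants


def make_fixture_bundle(
    seed: int, scale: str = "small", out_dir: str | Path = "scratch/bundle"
) -> FixtureBundle:
    """Write a complete synthetic input bundle with truth sidecars.

    Noise-free expression tables (planted four-fold effects, baselines
    floored at 50 FPKM so abundance filtering keeps every planted
    transcript) plus poly-C promoters with planted motifs, so every
    downstream count equals the plan exactly.
    """
    if scale not in _PLANS:
        raise ValueError(f"unknown scale {scale!r}; choose from {sorted(_PLANS)}")
    plan = _PLANS[scale]
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    (root / "truth").mkdir(exist_ok=True)

    base = SyntheticConfig(rng_seed=seed, n_transcripts=plan.n_transcripts)
    ids = base.transcript_ids()
    sets, regions = allocate_three_way(plan.venn, ids)
    met, hairy = sets["A"], sets["B"]
    unassigned = ids[plan.venn.total():]
    kr_sets, core = _replicate_kr_sets(plan, regions, unassigned)

    table_paths = []
    for rep, kr in enumerate(kr_sets, start=1):
        cfg = SyntheticConfig(
            rng_seed=seed * 16 + rep,
            n_transcripts=plan.n_transcripts,
            planted_up_sets={
                "iMet": frozenset(met),
                "iHairy": frozenset(hairy),
                "iKr-h1": frozenset(kr),
            },
            planted_log2fc=plan.planted_log2fc,
            noise_cv=plan.noise_cv,
            planted_min_fpkm=plan.planted_min_fpkm,
        )
        table, _ = gen_expression(cfg)
        path = root / f"expression_rep{rep}.tsv"
        cio.write_expression_tsv(table, path)
        table_paths.append(str(path))
        for label, idset in cfg.planted_up_sets.items():
            cio.write_gene_set(idset, root / "truth" / f"up_rep{rep}_{_slug(label)}.txt")

    probes_by_id = {p.probe_id: p for p in enumerate_probes(BMKBS_30MER)}
    scan_genes = regions["abc"] + regions["ac"]  # Met ∩ Kr-h1 (replicate 1)
    scan_plan = _scan_plant_plan(scan_genes, plan.scan_probe_counts, probes_by_id)
    scan_cfg = SyntheticConfig(
        rng_seed=seed * 16 + 8,
        promoter_ids=tuple(scan_genes),
        promoter_length=plan.promoter_length,
        background_freqs=(0.0, 1.0, 0.0, 0.0),  # poly-C: no spurious matches
        plant_plan=tuple(scan_plan),
    )
    scan_promoters, scan_truth = gen_promoters(scan_cfg)
    scan_fasta = root / "scan_promoters.fasta"
    cio.write_promoters(scan_promoters, scan_fasta, f"upstream:{plan.promoter_length}")

    triple_genes = regions["abc"]
    cooccur_plan = _cooccur_plant_plan(plan, triple_genes, "TCTATTTAG", "CACGTG")
    cooccur_cfg = SyntheticConfig(
        rng_seed=seed * 16 + 9,
        promoter_ids=tuple(triple_genes),
        promoter_length=plan.promoter_length,
        background_freqs=(0.0, 1.0, 0.0, 0.0),
        plant_plan=tuple(cooccur_plan),
    )
    cooccur_promoters, cooccur_truth = gen_promoters(cooccur_cfg)
    cooccur_fasta = root / "cooccur_promoters.fasta"
    cio.write_promoters(cooccur_promoters, cooccur_fasta, f"upstream:{plan.promoter_length}")

    annot_cfg = SyntheticConfig(
        rng_seed=seed * 16 + 10,
        n_transcripts=plan.n_transcripts,
        category_labels=plan.category_labels,
        enriched_gene_set=frozenset(triple_genes),
        target_category_counts=plan.target_category_counts,
    )
    annotation, annot_truth = gen_annotation(annot_cfg)
    annot_path = root / "annotation.tsv"
    cio.write_annotation(annotation, annot_path)

    sites_frame = pd.DataFrame(
        scan_truth.planted_sites + cooccur_truth.planted_sites,
        columns=["gene_id", "motif", "strand", "start", "end"],
    )
    sites_frame.to_csv(root / "truth" / "planted_sites.tsv", sep="\t", index=False)
    cio.write_gene_set(core, root / "truth" / "consensus.txt")

    config = PipelineConfig(
        expression_tables=tuple(table_paths),
        out_dir=str(root / "out"),
        scan_fasta=str(scan_fasta),
        cooccur_fasta=str(cooccur_fasta),
        annotation=str(annot_path),
        top_n=plan.top_n,
        rng_seed=seed,
    )
    config.to_yaml(root / "config.yaml")

    n_both = len(plan.cooccur_distances)
    truth = {
        "plan": plan,
        "met": met,
        "hairy": hairy,
        "kr_sets": kr_sets,
        "core": core,
        "triple": set(triple_genes),
        "met_kr": set(scan_genes),
        "regions": regions,
        "scan_probe_counts": dict(plan.scan_probe_counts),
        "distances": list(plan.cooccur_distances),
        "n_both": n_both,
        "n_hbs_downstream": plan.n_hbs_downstream,
        "enriched_categories": sorted(plan.significant_categories),
        "planted_sites": scan_truth.planted_sites + cooccur_truth.planted_sites,
    }
    return FixtureBundle(root, config, truth)
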