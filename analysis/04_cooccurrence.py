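"""KBS-HBS distance and orientation over the co-repressed cohort.

Locates the validated 9-mer Kr-h1 site (TCTATTTAG) and the Hairy E-box
(CACGTG) in the upstream regions of the Met/Hairy/Kr-h1 co-repressed
genes, keeps the nearest pair per gene and summarises distances
(<1 kb, <300 bp) and which site sits closer to the TSS.
Writes results/site_pairs.tsv and results/distance_summary.tsv.

Requires the bundle from analysis/01_simulate.py.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from corepress import io as cio  # noqa: E402
from corepress.cooccurrence import distance_summary, locate_sites, pair_sites  # noqa: E402
from corepress.pipeline import PipelineConfig, _write_pairs, _write_summary  # noqa: E402

RESULTS = Path("results")


def main() -> None:
    config = PipelineConfig.from_yaml("scratch/study_bundle/config.yaml")
    RESULTS.mkdir(exist_ok=True)
    promoters = cio.read_promoters(config.cooccur_fasta)
    catalog = locate_sites(promoters, config.kbs_patterns, config.hbs_patterns)
    pairs, excluded = pair_sites(catalog)
    summary = distance_summary(pairs, config.distance_thresholds, excluded)
    _write_pairs(pairs, RESULTS / "site_pairs.tsv")
    _write_summary(summary, RESULTS / "distance_summary.tsv")

    print(f"{len(promoters)} upstream regions; {summary.n_pairs} genes carry "
          f"both a KBS and an HBS ({summary.n_excluded} lack one or both)")
    for t in config.distance_thresholds:
        print(f"distance < {t} bp in {summary.pct_within(t):.0f}% of paired genes")
    split = summary.orientation_split
    print(f"HBS downstream of KBS in {100 * split['HBS_downstream']:.0f}%, "
          f"KBS downstream of HBS in {100 * split['KBS_downstream']:.0f}%")


if __name__ == "__main__":
    main()
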