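"""Scan the Met∩Kr-h1 upstream regions with the 23 KBS 8-mer probes.

Slides an 8-base window over the 30-mer silkworm KBS core, scans each
probe and its reverse complement over the 5-kb upstream regions of the
Met/Kr-h1 co-repressed cohort, and compares observed occurrence counts
with the i.i.d.-background expectation (Poisson upper tail).
Writes results/hit_table.tsv and results/hits.bed.

Requires the bundle from analysis/01_simulate.py.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from corepress import io as cio  # noqa: E402
from corepress.motifs import (  # noqa: E402
    enumerate_probes,
    estimate_background,
    hit_frequency_table,
    scan_probe,
)
from corepress.pipeline import PipelineConfig  # noqa: E402

RESULTS = Path("results")


def main() -> None:
    config = PipelineConfig.from_yaml("scratch/study_bundle/config.yaml")
    RESULTS.mkdir(exist_ok=True)
    promoters = cio.read_promoters(config.scan_fasta)
    probes = enumerate_probes(config.seed_motif, config.window_k)
    table = hit_frequency_table(promoters, probes, estimate_background(promoters))
    table.to_csv(RESULTS / "hit_table.tsv", sep="\t", index=False)
    hits = [h for p in probes for h in scan_probe(promoters, p)]
    cio.write_bed6(hits, RESULTS / "hits.bed")

    top = table.loc[table["is_max"]].iloc[0]
    significant = table.loc[table["p_value"] < 0.01, "probe_id"].tolist()
    print(f"scanned {len(promoters)} upstream regions with {len(probes)} probes")
    print(f"top probe: {top['probe_id']} ({top['forward']}/{top['revcomp']}) "
          f"with {top['observed_hits']} occurrences "
          f"(expected {top['expected_hits']:.3f}, p={top['p_value']:.2e})")
    print(f"probes above random expectation at p<0.01: "
          f"{significant[0]}..{significant[-1]} ({len(significant)} of {len(probes)})")


if __name__ == "__main__":
    main()
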