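"""Fold-change calling, knockdown-transcriptome overlaps and consensus.

For each replicate table: restrict to the 10,000 most abundant transcripts
per knockdown/control pair, call the >2-fold up-sets, then intersect them
(three-way Venn for replicate 1, Kr-h1 consensus across replicates).
Writes results/up_set_sizes.tsv, results/overlap_rep1.tsv and
results/consensus.txt.

Requires the bundle from analysis/01_simulate.py.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd  # noqa: E402

from corepress import io as cio  # noqa: E402
from corepress.expression import (  # noqa: E402
    call_upregulated,
    overlap_sets,
    replicate_consensus,
    select_top_abundant,
)
from corepress.pipeline import PipelineConfig  # noqa: E402

RESULTS = Path("results")


def main() -> None:
    config = PipelineConfig.from_yaml("scratch/study_bundle/config.yaml")
    RESULTS.mkdir(exist_ok=True)

    up_by_rep = []
    size_rows = []
    for rep, path in enumerate(config.expression_tables, start=1):
        table = cio.read_expression_tsv(path)
        ups = {}
        for treatment in table.columns:
            if treatment == config.control:
                continue
            universe = select_top_abundant(table, treatment, config.control, config.top_n)
            ups[treatment], _ = call_upregulated(
                table, treatment, config.control,
                config.log2fc_threshold, config.pseudocount, universe,
            )
            size_rows.append({"replicate": rep, "treatment": treatment,
                              "n_up": len(ups[treatment])})
        up_by_rep.append(ups)
    pd.DataFrame(size_rows).to_csv(RESULTS / "up_set_sizes.tsv", sep="\t", index=False)

    ov = overlap_sets(up_by_rep[0])
    ov.to_frame().to_csv(RESULTS / "overlap_rep1.tsv", sep="\t", index=False)
    consensus = replicate_consensus([rep["iKr-h1"] for rep in up_by_rep])
    cio.write_gene_set(consensus, RESULTS / "consensus.txt")

    kr = ov.size("iKr-h1")
    print(f"replicate 1: {kr} transcripts up in iKr-h1; "
          f"{ov.intersection_size('iMet', 'iKr-h1')} shared with iMet "
          f"({ov.percent('iKr-h1', 'iMet'):.0f}%)")
    print(f"{ov.intersection_size('iKr-h1', 'iHairy')} shared with iHairy "
          f"({ov.percent('iKr-h1', 'iHairy'):.1f}% of iKr-h1, "
          f"{ov.percent('iHairy', 'iKr-h1'):.1f}% of iHairy); "
          f"three-way core {ov.intersection_size('iMet', 'iHairy', 'iKr-h1')}")
    print(f"iKr-h1 up-sets across replicates: "
          f"{[len(r['iKr-h1']) for r in up_by_rep]}; consensus {len(consensus)}")


if __name__ == "__main__":
    main()
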