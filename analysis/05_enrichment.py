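"""Orthologous-group overrepresentation of the co-repressed core.

Tests the Met/Hairy/Kr-h1 co-repressed gene set against the abundance-
filtered transcript universe for overrepresented single-letter functional
categories (hypergeometric upper tail, raw p < 0.01).
Writes results/enrichment.tsv.

Requires the bundle from analysis/01_simulate.py.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from corepress import io as cio  # noqa: E402
from corepress.enrichment import enrich_categories  # noqa: E402
from corepress.expression import call_upregulated, select_top_abundant  # noqa: E402
from corepress.pipeline import PipelineConfig  # noqa: E402

RESULTS = Path("results")


def main() -> None:
    config = PipelineConfig.from_yaml("scratch/study_bundle/config.yaml")
    RESULTS.mkdir(exist_ok=True)
    table = cio.read_expression_tsv(config.expression_tables[0])
    annotation = cio.read_annotation(config.annotation)

    ups = {}
    for treatment in ("iMet", "iHairy", "iKr-h1"):
        universe = select_top_abundant(table, treatment, config.control, config.top_n)
        ups[treatment], _ = call_upregulated(
            table, treatment, config.control,
            config.log2fc_threshold, config.pseudocount, universe,
        )
    background = set(select_top_abundant(table, "iKr-h1", config.control, config.top_n))
    target = (ups["iMet"] & ups["iHairy"] & ups["iKr-h1"]) & background

    enr = enrich_categories(target, background, annotation, config.alpha)
    enr.to_csv(RESULTS / "enrichment.tsv", sep="\t", index=False)

    sig = enr.loc[enr["significant"]]
    print(f"target: {len(target)} co-repressed genes against a background of "
          f"{len(background)} transcripts")
    print(f"{len(sig)} categories overrepresented at p < {config.alpha}:")
    for _, row in sig.iterrows():
        print(f"  [{row['category']}] k={row['k']}/{row['n']} vs K={row['K']}/{row['N']} "
              f"(p={row['p_value']:.2e})")


if __name__ == "__main__":
    main()
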