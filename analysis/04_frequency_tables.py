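#!/usr/bin/env python
"""Exclusive and cumulative frequency tables with regional stratification.

Aggregates the haplogroup calls into the per-row frequency table (overall
and East/North/South columns, percentages of the whole 2139-male cohort)
and the headline clade summaries. Writes results/frequencies/.
"""

from pathlib import Path

import pandas as pd

from yhap.calling import call_cohort
from yhap.fixtures import TOTAL_COHORT_N, table1_tree
from yhap.frequency import (
    build_frequency_table,
    cumulative_summary,
    regional_clade_frequency,
)
from yhap.genotype_io import read_genotype_matrix, read_metadata, region_series

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tree = table1_tree()
    matrix = read_genotype_matrix(BASE / "cohort" / "genotypes.tsv")
    metadata = read_metadata(BASE / "cohort" / "metadata.tsv")
    out = BASE / "frequencies"
    out.mkdir(parents=True, exist_ok=True)

    assignments = call_cohort(tree, matrix)
    table = build_frequency_table(assignments, region_series(metadata),
                                  TOTAL_COHORT_N, tree)
    table.write_tsv(out / "frequencies.tsv")
    print(table.formatted().to_string())

    print("\nclade summaries (percent of the 2139-male cohort unless noted):")
    root = cumulative_summary(tree, table, "O2a1c")
    main_branch = cumulative_summary(tree, table, "O2a1c1",
                                     denominator="root_clade")
    print(f"  O2a1c (whole clade): {root.cumulative_count} samples, "
          f"{root.cumulative_freq}%")
    print(f"  O2a1c1 share of the clade: {main_branch.cumulative_freq}%")
    summaries = {}
    for node in ("O2a1c1a", "O2a1c1b"):
        s = cumulative_summary(tree, table, node)
        summaries[node] = s.to_dict()
        print(f"  {node}: {s.cumulative_count} samples, {s.cumulative_freq}%")
    for node in ("O2a1c1a1", "O2a1c1a5", "O2a1c1a7"):
        s = cumulative_summary(tree, table, node, decimals=3)
        summaries[node] = s.to_dict()
        print(f"  {node}: {s.cumulative_count} samples, {s.cumulative_freq}%")

    print("\nF449-clade (O2a1c1b) regional frequencies, printed-column sums:")
    for region in ("East", "North", "South"):
        pct = regional_clade_frequency(tree, table, "O2a1c1b", region,
                                       mode="rounded")
        summaries[f"O2a1c1b_{region}"] = float(pct)
        print(f"  {region}: {pct}%")

    import json

    (out / "clade_summaries.json").write_text(
        json.dumps(summaries, indent=2) + "\n")


if __name__ == "__main__":
    main()
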