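#!/usr/bin/env python
"""Regenerate the study cohort from the packaged haplogroup count table.

The published per-sample genotypes are not redistributed; instead the 23
exclusive haplogroup counts (305 in-clade samples) plus the 1834
outside-clade males are expanded into a deterministic, error-free 2139 x 68
genotype matrix with regional labels. Writes genotypes, truth labels and
metadata under results/cohort/.
"""

from pathlib import Path

from yhap.fixtures import table1_cohort, table1_tree
from yhap.genotype_io import write_genotype_matrix, write_metadata

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tree = table1_tree()
    matrix, truth, metadata = table1_cohort()

    write_genotype_matrix(matrix, OUT / "genotypes.tsv")
    truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)
    write_metadata(metadata, OUT / "metadata.tsv")
    tree.to_json(OUT / "tree.json")
    (OUT / "tree.nwk").write_text(tree.to_newick() + "\n")

    n_in = int((truth["true_node"] != "outside").sum())
    print(f"cohort: {matrix.shape[0]} samples x {matrix.shape[1]} markers, "
          f"{n_in} inside the root clade")
    print(f"regions: {truth['region'].value_counts().to_dict()}")


if __name__ == "__main__":
    main()
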