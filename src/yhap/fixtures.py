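"""Reference fixture: the published O2a1c-002611 haplogroup tree and counts.

Encodes the refined tree of Y-haplogroup O2a1c-002611 (rooted at
IMS-JST002611, written ``002611``) together with the published exclusive
haplogroup counts for 2139 Han Chinese males, 305 of whom fall inside the
clade, stratified into East / North / South regions.

Marker equivalence sets follow the published text. Ten internal nodes'
defining SNPs appear only in the source's figure image, not in text; these
carry synthetic placeholder marker names ``FX1``..``FX10`` (clearly not real
SNP identifiers). Two nodes are *latent*: O2a1c1a6, whose ISOGG defining
SNP was not genotyped in the source study, and O2a1c1a6a1, an untyped
sibling placeholder that keeps the published child index of O2a1c1a6a2.

Regional integer counts are reconstructed from the published regional
percentages as ``round(pct * 2139 / 100)``; every reconstructed row sums
exactly to its published total count.
"""

from __future__ import annotations

import pandas as pd

from .haplotree import CladeNode, Haplotree

__all__ = ["TOTAL_COHORT_N", "IN_CLADE_N", "table1_tree", "table1_counts",
           "table1_exclusive_counts", "table1_region_counts", "table1_cohort",
           "PRIMARY_MARKERS", "CHILD_ORDER"]

TOTAL_COHORT_N = 2139
IN_CLADE_N = 305

# node -> (defining markers, primary first). FX* = synthetic placeholders.
_MARKERS: dict[str, tuple[str, ...]] = {
    "O2a1c": ("002611", "F61", "CTS1872", "F240", "F247", "CTS2483", "F302",
              "F309", "CTS5879", "F460", "F562"),
    "O2a1c1": ("F18",),
    "O2a1c1a": ("F11", "F425"),
    "O2a1c1a1": ("F632",),
    "O2a1c1a1a": ("FX1",),
    "O2a1c1a1a1": ("FX2",),
    "O2a1c1a1a1a": ("FX3",),
    "O2a1c1a1a1a1": ("FX4",),
    "O2a1c1a1a1a1a": ("FX5",),
    "O2a1c1a1a1b": ("FX6",),
    "O2a1c1a2": ("F38", "F136", "F178", "F270", "F286", "F358", "F381",
                 "F475", "F479", "F485", "F3131"),
    "O2a1c1a3": ("F12", "F196", "F480"),
    "O2a1c1a4": ("F1232", "F2356", "F2589"),
    "O2a1c1a4a": ("FX7",),
    "O2a1c1a5": ("F1365", "F1676", "F2109", "F2180", "F2213", "F3232"),
    "O2a1c1a6a": ("F2527",),
    "O2a1c1a6a2": ("F4073", "F4119", "F2941"),
    "O2a1c1a7": ("F723", "F971", "F1210", "F1351", "F1638", "F4171", "F2357",
                 "F2719", "F3042", "F3103"),
    "O2a1c1b": ("F449",),
    "O2a1c1b1": ("F238",),
    "O2a1c1b1a": ("FX8",),
    "O2a1c1b1a1": ("FX9",),
    "O2a1c1b1a2": ("FX10",),
    "O2a1c1b2": ("F1266", "F2016", "F4267"),
    "O2a1c2": ("L133.2",),
}

_LATENT = {"O2a1c1a6", "O2a1c1a6a1"}

# child lists in the published sibling order (determines YCC child indices)
_CHILDREN: dict[str, tuple[str, ...]] = {
    "O2a1c": ("O2a1c1", "O2a1c2"),
    "O2a1c1": ("O2a1c1a", "O2a1c1b"),
    "O2a1c1a": ("O2a1c1a1", "O2a1c1a2", "O2a1c1a3", "O2a1c1a4", "O2a1c1a5",
                "O2a1c1a6", "O2a1c1a7"),
    "O2a1c1a1": ("O2a1c1a1a",),
    "O2a1c1a1a": ("O2a1c1a1a1",),
    "O2a1c1a1a1": ("O2a1c1a1a1a", "O2a1c1a1a1b"),
    "O2a1c1a1a1a": ("O2a1c1a1a1a1",),
    "O2a1c1a1a1a1": ("O2a1c1a1a1a1a",),
    "O2a1c1a4": ("O2a1c1a4a",),
    "O2a1c1a6": ("O2a1c1a6a",),
    "O2a1c1a6a": ("O2a1c1a6a1", "O2a1c1a6a2"),
    "O2a1c1b": ("O2a1c1b1", "O2a1c1b2"),
    "O2a1c1b1": ("O2a1c1b1a",),
    "O2a1c1b1a": ("O2a1c1b1a1", "O2a1c1b1a2"),
}

#: Primary (name-giving) marker per non-latent node, for placement configs.
PRIMARY_MARKERS: tuple[str, ...] = tuple(ms[0] for ms in _MARKERS.values())

#: Global sibling priority (primary markers in published order).
CHILD_ORDER: tuple[str, ...] = tuple(
    _MARKERS[child][0]
    for parent in _CHILDREN
    for child in _CHILDREN[parent]
    if child not in _LATENT
)

# display row -> (exclusive count, East, North, South); regional counts
# reconstructed from the published regional percentages (see module docs)
_TABLE1: dict[str, tuple[int, int, int, int]] = {
    "O2a1c*": (1, 1, 0, 0),
    "O2a1c1*": (12, 2, 3, 7),
    "O2a1c1a*": (53, 20, 7, 26),
    "O2a1c1a1*": (8, 4, 0, 4),
    "O2a1c1a1a*": (27, 8, 12, 7),
    "O2a1c1a1a1*": (14, 5, 2, 7),
    "O2a1c1a1a1a1*": (1, 0, 0, 1),
    "O2a1c1a1a1a1a": (6, 3, 0, 3),
    "O2a1c1a1a1b": (20, 4, 11, 5),
    "O2a1c1a2": (7, 0, 7, 0),
    "O2a1c1a3": (16, 8, 5, 3),
    "O2a1c1a4*": (6, 1, 4, 1),
    "O2a1c1a4a": (4, 1, 1, 2),
    "O2a1c1a5": (57, 17, 25, 15),
    "O2a1c1a6a*": (6, 1, 1, 4),
    "O2a1c1a6a2": (9, 6, 2, 1),
    "O2a1c1a7": (4, 1, 1, 2),
    "O2a1c1b1*": (13, 1, 6, 6),
    "O2a1c1b1a*": (9, 2, 2, 5),
    "O2a1c1b1a1": (17, 4, 12, 1),
    "O2a1c1b1a2": (1, 1, 0, 0),
    "O2a1c1b2": (7, 2, 4, 1),
    "O2a1c2": (7, 1, 3, 3),
}


def table1_tree() -> Haplotree:
    """The published refined tree (27 nodes, two of them latent)."""

    def build(name: str) -> CladeNode:
        return CladeNode(
            ycc_name=name,
            defining_markers=_MARKERS.get(name, ()),
            latent=name in _LATENT,
            children=[build(c) for c in _CHILDREN.get(name, ())],
        )

    return Haplotree(build("O2a1c"), root_letter="O")


def table1_counts() -> pd.DataFrame:
    """Published exclusive counts: rows = display names (starred paragroups),
    columns count/East/North/South."""
    df = pd.DataFrame.from_dict(
        _TABLE1, orient="index", columns=["count", "East", "North", "South"])
    df.index.name = "haplogroup"
    return df


def table1_exclusive_counts() -> dict[str, int]:
    """Exclusive counts keyed by ycc node name (stars stripped)."""
    return {row.rstrip("*"): c for row, (c, *_rest) in _TABLE1.items()}


def table1_region_counts() -> dict[str, dict[str, int]]:
    return {
        row.rstrip("*"): {"East": e, "North": n, "South": s}
        for row, (_c, e, n, s) in _TABLE1.items()
    }


def table1_cohort(include_outside: bool = True):
    """Deterministic cohort regenerated from the published counts.

    Returns (GenotypeMatrix, truth table, metadata) for 2139 samples: 305
    in-clade per the published rows plus, when ``include_outside``, 1834
    all-ancestral males completing the genotyped cohort.
    """
    from .simulate import OUTSIDE, expected_counts_cohort

    counts = table1_exclusive_counts()
    regions = table1_region_counts()
    if include_outside:
        counts[OUTSIDE] = TOTAL_COHORT_N - IN_CLADE_N
    return expected_counts_cohort(table1_tree(), counts, regions)
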