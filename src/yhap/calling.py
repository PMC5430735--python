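"""Per-sample haplogroup assignment with paragroup (*) semantics.

A sample is walked down the tree from the root: at each node it descends
into the unique child for which at least one defining marker is observed
derived. Where it stops is its haplogroup. If the stopping node has typed
subclades the call is a paragroup (starred): the sample belongs to the node
but to none of its known branches — either confirmed (downstream markers
observed ancestral) or unresolved (downstream markers all no-call), a
distinction preserved in the assignment but collapsed in frequency tables.

Latent nodes (untyped defining SNP) are transparent to the walk: a latent
child qualifies whenever a marker anywhere in its subtree is derived,
because only its descendants are observable. A sample truly belonging to a
latent node's exclusive lineage is therefore indistinguishable from its
parent's paragroup and is called as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .genotype_io import GenotypeMatrix
from .haplotree import CladeNode, Haplotree

__all__ = ["Assignment", "OUTSIDE_CLADE", "call_sample", "call_cohort",
           "assignments_frame", "write_assignments"]

#: Sentinel node label for samples ancestral/no-call at every root marker.
OUTSIDE_CLADE = "outside-root-clade"


@dataclass
class Assignment:
    sample_id: str
    node: str  # ycc name, or OUTSIDE_CLADE
    is_paragroup: bool = False
    path_conflicts: list[tuple[str, str, str]] = field(default_factory=list)
    unresolved_children: list[str] = field(default_factory=list)

    @property
    def in_clade(self) -> bool:
        return self.node != OUTSIDE_CLADE

    def display_name(self) -> str:
        """Table-style label: starred when the call is a paragroup."""
        return self.node + "*" if self.is_paragroup else self.node


def _subtree_markers(node: CladeNode) -> list[str]:
    out: list[str] = []
    for n in node.preorder():
        out.extend(n.defining_markers)
    return out


def _qualifies(node: CladeNode, row: Mapping[str, str]) -> bool:
    """Does the sample show evidence for this branch?

    Non-latent: >=1 defining marker derived. Latent: >=1 derived marker
    anywhere in the subtree (look-through).
    """
    if node.latent:
        return any(row.get(m, "N") == "D" for m in _subtree_markers(node))
    return any(row.get(m, "N") == "D" for m in node.defining_markers)


def call_sample(tree: Haplotree, row: Mapping[str, str],
                sample_id: str = "") -> Assignment:
    """Assign one sample (marker -> call mapping) on the tree.

    Markers absent from ``row`` are treated as no-calls. A sample with no
    derived call at any root defining marker is assigned outside the clade.
    """
    root = tree.root
    if not any(row.get(m, "N") == "D" for m in root.defining_markers):
        return Assignment(sample_id=sample_id, node=OUTSIDE_CLADE)

    assignment = Assignment(sample_id=sample_id, node=root.ycc_name)
    node = root
    while True:
        # within-class inconsistency: some defining markers derived, some
        # observed ancestral, on a node we stand on
        derived_here = [m for m in node.defining_markers if row.get(m, "N") == "D"]
        if derived_here:
            for m in node.defining_markers:
                if row.get(m, "N") == "A":
                    assignment.path_conflicts.append((m, "D", "A"))

        qualifying = [c for c in node.children if _qualifies(c, row)]
        if len(qualifying) > 1:
            # impossible on a perfect phylogeny; make the conservative
            # parent call and flag every competing branch
            for child in qualifying:
                marker = child.primary_marker or _subtree_markers(child)[0]
                assignment.path_conflicts.append((marker, "single-path", "multiple"))
            break
        if not qualifying:
            break
        child = qualifying[0]
        if child.latent and not any(
            row.get(m, "N") == "D" for m in child.defining_markers
        ):
            # walked through on downstream evidence only; nothing to check here
            pass
        node = child
        assignment.node = node.ycc_name

    if node.children:
        assignment.is_paragroup = True
        for child in node.children:
            markers = child.defining_markers or _subtree_markers(child)
            if markers and all(row.get(m, "N") == "N" for m in markers):
                assignment.unresolved_children.extend(markers)
        # derived evidence below a non-qualifying branch is unreachable:
        # record it as a conflict rather than guessing a path
        for child in node.children:
            if child in (qualifying if len(qualifying) > 1 else []):
                continue
            for m in _subtree_markers(child):
                if row.get(m, "N") == "D" and not _qualifies(child, row):
                    assignment.path_conflicts.append((m, "A", "D"))
    return assignment


def call_cohort(tree: Haplotree, matrix: GenotypeMatrix) -> list[Assignment]:
    """Assign every sample; deterministic in matrix order."""
    calls = matrix.calls
    markers = list(calls.columns)
    out = []
    for sample_id, values in zip(calls.index, calls.to_numpy(dtype=object)):
        row = dict(zip(markers, values))
        out.append(call_sample(tree, row, sample_id=str(sample_id)))
    return out


def assignments_frame(assignments: list[Assignment],
                      tree: Haplotree | None = None) -> pd.DataFrame:
    """Assignment table: sample_id, ycc_name, mutation_name, flags."""
    rows = []
    for a in assignments:
        mut = ""
        if tree is not None and a.in_clade:
            mut = tree.node(a.node).mutation_name(tree.root_letter) or ""
        rows.append({
            "sample_id": a.sample_id,
            "ycc_name": a.display_name(),
            "mutation_name": mut,
            "is_paragroup": a.is_paragroup,
            "n_conflicts": len(a.path_conflicts),
        })
    return pd.DataFrame(
        rows, columns=["sample_id", "ycc_name", "mutation_name",
                       "is_paragroup", "n_conflicts"])


def write_assignments(assignments: list[Assignment], path,
                      tree: Haplotree | None = None) -> None:
    assignments_frame(assignments, tree).to_csv(path, sep="\t", index=False)
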