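"""Rooted haplogroup tree model and YCC-style nomenclature.

A haplogroup tree is a rooted tree of clades. Each clade is defined by a set
of phylogenetically equivalent binary Y-SNPs (markers that mutated once on
the same edge, so every sample carrying one derived allele carries them all).
Clade labels follow the Y Chromosome Consortium convention of alternating
digits and lowercase letters appended to the parent label (O2a1c -> O2a1c1
-> O2a1c1a ...), and each clade also carries a mutation-based alias built
from the major haplogroup letter and its primary defining marker (O-F11).

Internal nodes whose defining SNP was not genotyped can be declared as
*latent*: they occupy a position (and a child index, hence a name) in the
tree but have an empty marker set. Latent nodes are configuration-only;
nothing in this package ever infers one from data.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterator

__all__ = [
    "Marker",
    "CladeNode",
    "Haplotree",
    "ycc_child_name",
    "mutation_name",
    "NomenclatureError",
]

_VALID_BASES = {"A", "C", "G", "T"}

# uppercase haplogroup letter, then alternating digit-runs / single lowercase
# letters, in either starting order (O2a1c1a, O2a1c, Q1b...).
_NAME_RE = re.compile(r"^[A-Z](?:[0-9]+)?(?:[a-z][0-9]+)*[a-z]?$")


class NomenclatureError(ValueError):
    """Raised when a haplogroup name cannot be formed or parsed."""


@dataclass(frozen=True)
class Marker:
    """A binary Y-SNP.

    Parameters
    ----------
    name:
        Marker identifier, e.g. ``"F11"`` or ``"IMS-JST002611"``. Names with
        recurrence suffixes (``"L133.2"``) are treated as opaque strings.
    position:
        Optional 1-based hg19 coordinate. Metadata only; never used in
        inference, which depends solely on ancestral/derived status.
    ancestral_allele, derived_allele:
        The pre-mutation and mutated base, each one of A/C/G/T when given.
    """

    name: str
    position: int | None = None
    ancestral_allele: str | None = None
    derived_allele: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("marker name must be nonempty")
        for allele in (self.ancestral_allele, self.derived_allele):
            if allele is not None and allele not in _VALID_BASES:
                raise ValueError(f"invalid allele {allele!r} for marker {self.name}")
        if (
            self.ancestral_allele is not None
            and self.derived_allele is not None
            and self.ancestral_allele == self.derived_allele
        ):
            raise ValueError(
                f"marker {self.name}: ancestral and derived alleles are both "
                f"{self.ancestral_allele!r}"
            )


def ycc_child_name(parent_name: str, child_index: int) -> str:
    """Name of the ``child_index``-th (1-based) child of ``parent_name``.

    Following YCC convention the appended character class alternates with the
    parent's terminal class: a name ending in a digit gains a lowercase
    letter (a, b, c, ...), a name ending in a letter gains decimal digits.

    >>> ycc_child_name("O2a1c1", 1)
    'O2a1c1a'
    >>> ycc_child_name("O2a1c1a", 7)
    'O2a1c1a7'
    """
    if not _NAME_RE.match(parent_name):
        raise NomenclatureError(f"not a valid haplogroup name: {parent_name!r}")
    if child_index < 1:
        raise NomenclatureError(f"child_index must be >= 1, got {child_index}")
    if parent_name[-1].isdigit():
        # append a lowercase letter; the convention has no double letters
        if child_index > 26:
            raise NomenclatureError(
                f"cannot name child {child_index} of {parent_name!r}: "
                "only 26 single-letter branches exist"
            )
        return parent_name + chr(ord("a") + child_index - 1)
    return parent_name + str(child_index)


def mutation_name(root_letter: str, primary_marker: str) -> str:
    """Mutation-based haplogroup alias, e.g. ``mutation_name("O", "F11") == "O-F11"``."""
    if not root_letter or not primary_marker:
        raise ValueError("root_letter and primary_marker must be nonempty")
    return f"{root_letter}-{primary_marker}"


@dataclass
class CladeNode:
    """One clade: a YCC name plus its set of equivalent defining markers.

    ``defining_markers`` is an ordered tuple; the first entry is the primary
    marker used for the mutation-based alias. Latent nodes (untyped defining
    SNP) have an empty tuple and ``latent=True``.
    """

    ycc_name: str
    defining_markers: tuple[str, ...] = ()
    latent: bool = False
    children: list["CladeNode"] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.defining_markers = tuple(self.defining_markers)
        if self.latent and self.defining_markers:
            raise ValueError(f"latent node {self.ycc_name} cannot carry markers")
        if not self.latent and not self.defining_markers:
            raise ValueError(f"node {self.ycc_name} needs >=1 defining marker (or latent=True)")

    @property
    def primary_marker(self) -> str | None:
        return self.defining_markers[0] if self.defining_markers else None

    def mutation_name(self, root_letter: str) -> str | None:
        if self.primary_marker is None:
            return None
        return mutation_name(root_letter, self.primary_marker)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["CladeNode"]:
        yield self
        for child in self.children:
            yield from child.preorder()


class Haplotree:
    """A rooted haplogroup tree with unique names and disjoint marker sets."""

    def __init__(self, root: CladeNode, root_letter: str | None = None):
        self.root = root
        self.root_letter = root_letter or root.ycc_name[0]
        self._by_name: dict[str, CladeNode] = {}
        self._node_of_marker: dict[str, str] = {}
        self._parent: dict[str, str | None] = {root.ycc_name: None}
        self._index(root)

    def _index(self, node: CladeNode) -> None:
        if node.ycc_name in self._by_name:
            raise ValueError(f"duplicate haplogroup name {node.ycc_name!r}")
        self._by_name[node.ycc_name] = node
        for m in node.defining_markers:
            if m in self._node_of_marker:
                raise ValueError(
                    f"marker {m!r} defines both {self._node_of_marker[m]!r} "
                    f"and {node.ycc_name!r}"
                )
            self._node_of_marker[m] = node.ycc_name
        for child in node.children:
            self._parent[child.ycc_name] = node.ycc_name
            self._index(child)

    # -- queries ---------------------------------------------------------

    def node(self, ycc_name: str) -> CladeNode:
        try:
            return self._by_name[ycc_name]
        except KeyError:
            raise KeyError(f"no haplogroup named {ycc_name!r} in tree") from None

    def __contains__(self, ycc_name: str) -> bool:
        return ycc_name in self._by_name

    def node_names(self) -> list[str]:
        return [n.ycc_name for n in self.root.preorder()]

    def parent_name(self, ycc_name: str) -> str | None:
        self.node(ycc_name)
        return self._parent[ycc_name]

    def node_of_marker(self, marker: str) -> str:
        try:
            return self._node_of_marker[marker]
        except KeyError:
            raise KeyError(f"marker {marker!r} defines no node in tree") from None

    def markers(self) -> list[str]:
        """All defining markers, in preorder of their nodes."""
        out: list[str] = []
        for node in self.root.preorder():
            out.extend(node.defining_markers)
        return out

    def subtree_nodes(self, node_name: str) -> list[CladeNode]:
        """The node and all its descendants in preorder (stable)."""
        return list(self.node(node_name).preorder())

    def path_to(self, node_name: str) -> list[CladeNode]:
        """Nodes on the root->node path, root first."""
        names: list[str] = []
        cur: str | None = self.node(node_name).ycc_name
        while cur is not None:
            names.append(cur)
            cur = self._parent[cur]
        return [self._by_name[n] for n in reversed(names)]

    # -- nomenclature ----------------------------------------------------

    def assign_names(self, root_name: str | None = None) -> None:
        """(Re)assign YCC names from the root downward by child index.

        Used after tree construction from genotype data, where child order
        comes from configuration and names must follow the convention.
        """
        root_name = root_name or self.root.ycc_name

        def recurse(node: CladeNode, name: str) -> None:
            node.ycc_name = name
            for i, child in enumerate(node.children, start=1):
                recurse(child, ycc_child_name(name, i))

        recurse(self.root, root_name)
        # rebuild indices under the new names
        self._by_name.clear()
        self._node_of_marker.clear()
        self._parent = {self.root.ycc_name: None}
        self._index(self.root)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        def node_dict(node: CladeNode) -> dict:
            return {
                "ycc_name": node.ycc_name,
                "defining_markers": list(node.defining_markers),
                "latent": node.latent,
                "children": [node_dict(c) for c in node.children],
            }

        return {"root_letter": self.root_letter, "root": node_dict(self.root)}

    @classmethod
    def from_dict(cls, data: dict) -> "Haplotree":
        def build(d: dict) -> CladeNode:
            return CladeNode(
                ycc_name=d["ycc_name"],
                defining_markers=tuple(d.get("defining_markers", ())),
                latent=bool(d.get("latent", False)),
                children=[build(c) for c in d.get("children", ())],
            )

        return cls(build(data["root"]), root_letter=data.get("root_letter"))

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "Haplotree":
        """Load from a JSON string or a file path."""
        text = str(source)
        if not text.lstrip().startswith("{"):
            with open(source, "r", encoding="utf-8") as fh:
                text = fh.read()
        return cls.from_dict(json.loads(text))

    def to_newick(self) -> str:
        """Newick string with quoted labels ``'ycc_name:marker1/marker2'``."""
        import dendropy

        tree = dendropy.Tree()

        def label(node: CladeNode) -> str:
            return f"{node.ycc_name}:{'/'.join(node.defining_markers)}"

        def build(node: CladeNode, dnode) -> None:
            dnode.label = label(node)
            for child in node.children:
                build(child, dnode.new_child())

        build(self.root, tree.seed_node)
        return tree.as_string(schema="newick", suppress_rooting=True).strip()
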