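"""Parsimony placement: refine a haplogroup tree from derived-allele sharing.

On a perfect phylogeny every binary marker mutates exactly once, so the set
of samples carrying a marker's derived allele is either identical to, nested
within, or disjoint from every other marker's carrier set. Identical carrier
sets mean the markers are phylogenetically equivalent (same tree edge);
strict containment orders the edges into a rooted tree. This module infers
that structure directly from a haploid genotype matrix, restricted to the
samples derived at a designated root marker.

Missing data policy: every pairwise relation is evaluated only on samples
observed (non-N) at *both* markers — the one convention that never invents
calls. Pairs whose joint observations contain no derived call at all are
"equivalent by vacuity" and flagged ambiguous rather than silently merged
as informative.

A pair of markers whose carrier sets overlap without nesting violates the
perfect-phylogeny assumption (homoplasy / genotyping error). The default
policy is a hard error naming the pair and its contingency counts; an
opt-in policy drops the lower-call-rate marker instead and records it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

from .genotype_io import GenotypeMatrix
from .haplotree import CladeNode, Haplotree

__all__ = [
    "DerivedSet",
    "PairRelation",
    "PlacementReport",
    "IncompatibleMarkersError",
    "derived_set",
    "classify_pair",
    "detect_incompatibilities",
    "build_refined_tree",
]

Relation = Literal["equivalent", "ancestor", "descendant", "disjoint", "incompatible"]


@dataclass(frozen=True)
class DerivedSet:
    """Carrier (= derived) and observed sample sets for one marker."""

    marker: str
    carriers: frozenset
    observed: frozenset

    def __post_init__(self):
        if not self.carriers <= self.observed:
            raise ValueError(f"{self.marker}: carriers must be observed")


@dataclass(frozen=True)
class PairRelation:
    """Relation of marker A to marker B on their jointly observed samples.

    The four contingency cells count jointly observed samples that are
    derived at both (``n_both``), at A only, at B only, and at neither.
    ``ambiguous`` marks relations forced by lack of joint derived
    observations rather than by evidence.
    """

    relation: Relation
    n_both: int
    n_a_only: int
    n_b_only: int
    n_neither: int
    ambiguous: bool = False


def derived_set(matrix: GenotypeMatrix, marker: str) -> DerivedSet:
    col = matrix.column(marker)
    return DerivedSet(
        marker=marker,
        carriers=frozenset(col.index[col == "D"]),
        observed=frozenset(col.index[col != "N"]),
    )


def classify_pair(a: DerivedSet, b: DerivedSet) -> PairRelation:
    """Classify two markers by their carrier sets on joint observations."""
    joint = a.observed & b.observed
    ca = a.carriers & joint
    cb = b.carriers & joint
    n_both = len(ca & cb)
    n_a_only = len(ca - cb)
    n_b_only = len(cb - ca)
    n_neither = len(joint) - n_both - n_a_only - n_b_only

    if not joint or (not ca and not cb):
        return PairRelation("equivalent", n_both, n_a_only, n_b_only, n_neither,
                            ambiguous=True)
    if n_both > 0:
        if n_a_only == 0 and n_b_only == 0:
            return PairRelation("equivalent", n_both, n_a_only, n_b_only, n_neither)
        if n_b_only == 0:
            return PairRelation("ancestor", n_both, n_a_only, n_b_only, n_neither)
        if n_a_only == 0:
            return PairRelation("descendant", n_both, n_a_only, n_b_only, n_neither)
        return PairRelation("incompatible", n_both, n_a_only, n_b_only, n_neither)
    # no joint carriers: one side vacuous is uninformative, both nonempty is
    # genuine disjointness
    if n_a_only > 0 and n_b_only > 0:
        return PairRelation("disjoint", n_both, n_a_only, n_b_only, n_neither)
    return PairRelation("disjoint", n_both, n_a_only, n_b_only, n_neither,
                        ambiguous=True)


class IncompatibleMarkersError(ValueError):
    """Perfect-phylogeny violation under the strict homoplasy policy."""

    def __init__(self, pairs: Sequence[tuple[str, str, PairRelation]]):
        self.pairs = list(pairs)
        lines = [
            f"{a} vs {b}: both={rel.n_both}, {a}-only={rel.n_a_only}, "
            f"{b}-only={rel.n_b_only}, neither={rel.n_neither}"
            for a, b, rel in self.pairs
        ]
        super().__init__(
            "incompatible marker pairs (homoplasy or genotyping error):\n  "
            + "\n  ".join(lines)
        )


@dataclass
class PlacementReport:
    """Per-marker dispositions and anomalies from tree construction."""

    root_marker: str = ""
    n_root_carriers: int = 0
    excluded_samples: list[str] = field(default_factory=list)
    placed: dict[str, str] = field(default_factory=dict)  # marker -> class primary
    unplaced_no_carriers: list[str] = field(default_factory=list)
    dropped_incompatible: list[str] = field(default_factory=list)
    ambiguous_merges: list[tuple[str, str]] = field(default_factory=list)
    root_conflicts: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "root_marker": self.root_marker,
            "n_root_carriers": self.n_root_carriers,
            "excluded_samples": list(self.excluded_samples),
            "placed": dict(self.placed),
            "unplaced_no_carriers": list(self.unplaced_no_carriers),
            "dropped_incompatible": list(self.dropped_incompatible),
            "ambiguous_merges": [list(p) for p in self.ambiguous_merges],
            "root_conflicts": {k: list(v) for k, v in self.root_conflicts.items()},
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def detect_incompatibilities(matrix: GenotypeMatrix, root_marker: str
                             ) -> list[tuple[str, str, PairRelation]]:
    """All marker pairs violating nesting among root-marker carriers.

    Each unordered pair is reported once, in sorted marker order.
    """
    root = derived_set(matrix, root_marker)
    sub = matrix.subset(samples=sorted(root.carriers))
    sets = {m: derived_set(sub, m) for m in sub.marker_names}
    names = sorted(sets)
    out = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            rel = classify_pair(sets[a], sets[b])
            if rel.relation == "incompatible":
                out.append((a, b, rel))
    return out


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y):
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            # deterministic: smaller name becomes the root
            if ry < rx:
                rx, ry = ry, rx
            self.parent[ry] = rx


def build_refined_tree(
    matrix: GenotypeMatrix,
    root_marker: str,
    root_name: str = "root",
    root_letter: str | None = None,
    child_order: Mapping[str, Sequence[str]] | Sequence[str] | None = None,
    primary_markers: Sequence[str] | None = None,
    homoplasy_policy: Literal["strict", "drop-lower-callrate"] = "strict",
) -> tuple[Haplotree, PlacementReport]:
    """Infer the refined haplogroup tree below ``root_marker``.

    Steps: restrict to samples derived at the root marker; group markers
    into equivalence classes by identical carrier sets (on joint
    observations); order classes by strict carrier-set containment, each
    class's parent being its smallest strict container; name nodes from
    ``root_name`` by YCC child indexing.

    ``primary_markers`` lists markers that should head their equivalence
    class (and hence supply the mutation name); ``child_order`` fixes
    sibling order as a global priority list of primary markers (default:
    lexicographic by class primary marker).
    """
    report = PlacementReport(root_marker=root_marker)
    root_set_full = derived_set(matrix, root_marker)
    root_samples = sorted(root_set_full.carriers)
    if not root_samples:
        raise ValueError(f"no samples derived at root marker {root_marker!r}")
    report.n_root_carriers = len(root_samples)
    report.excluded_samples = sorted(set(matrix.sample_ids) - set(root_samples))

    sub = matrix.subset(samples=root_samples)
    markers = sorted(sub.marker_names)
    sets = {m: derived_set(sub, m) for m in markers}

    # samples ancestral at the root but derived downstream are conflicts;
    # they were already excluded from every carrier set by the restriction
    for m in markers:
        if m == root_marker:
            continue
        outside = derived_set(matrix, m).carriers - root_set_full.carriers
        if outside:
            report.root_conflicts[m] = sorted(outside)

    active = [m for m in markers if sets[m].carriers]
    report.unplaced_no_carriers = [m for m in markers if not sets[m].carriers]

    # homoplasy handling
    incompatible = [
        (a, b, rel)
        for a, b, rel in detect_incompatibilities(matrix, root_marker)
        if a in active and b in active
    ]
    if incompatible:
        if homoplasy_policy == "strict":
            raise IncompatibleMarkersError(incompatible)
        if homoplasy_policy != "drop-lower-callrate":
            raise ValueError(f"unknown homoplasy policy {homoplasy_policy!r}")
        rates = sub.marker_call_rates()
        dropped: set[str] = set()
        for a, b, rel in incompatible:
            if a in dropped or b in dropped:
                continue
            # drop the lower-call-rate member; tie -> the later-sorting name
            victim = a if (rates[a], b) < (rates[b], a) else b
            dropped.add(victim)
        report.dropped_incompatible = sorted(dropped)
        active = [m for m in active if m not in dropped]

    # equivalence classes via union-find over pairwise 'equivalent'
    uf = _UnionFind(active)
    for i, a in enumerate(active):
        for b in active[i + 1:]:
            rel = classify_pair(sets[a], sets[b])
            if rel.relation == "equivalent":
                uf.union(a, b)
                if rel.ambiguous:
                    report.ambiguous_merges.append((a, b))

    classes: dict[str, list[str]] = {}
    for m in active:
        classes.setdefault(uf.find(m), []).append(m)

    primary_set = set(primary_markers or ())

    def class_key(members: list[str]) -> str:
        preferred = sorted(set(members) & primary_set)
        return preferred[0] if preferred else sorted(members)[0]

    def ordered_members(members: list[str]) -> tuple[str, ...]:
        key = class_key(members)
        return (key, *sorted(m for m in members if m != key))

    # class carrier set = union over members (members agree wherever jointly
    # observed; the union is the best available estimate under missingness)
    class_carriers: dict[str, frozenset] = {}
    class_members: dict[str, tuple[str, ...]] = {}
    for members in classes.values():
        key = class_key(members)
        class_members[key] = ordered_members(members)
        carriers: frozenset = frozenset()
        for m in members:
            carriers |= sets[m].carriers
        class_carriers[key] = carriers

    if root_marker not in class_members.get(class_key(classes[uf.find(root_marker)]), ()):
        raise AssertionError("root marker lost during class construction")
    root_key = class_key(classes[uf.find(root_marker)])
    # the root class heads the tree and is named by the root marker
    members = list(class_members[root_key])
    members.remove(root_marker)
    class_members.pop(root_key)
    class_carriers[root_marker] = class_carriers.pop(root_key)
    class_members[root_marker] = (root_marker, *members)
    root_key = root_marker

    for m, disposition in ((m, k) for k, ms in class_members.items() for m in ms):
        report.placed[m] = disposition

    # parent = smallest strictly containing class
    keys = sorted(class_members)
    parent: dict[str, str | None] = {}
    for k in keys:
        containers = [
            j for j in keys
            if j != k and class_carriers[k] < class_carriers[j]
        ]
        if k == root_key:
            parent[k] = None
            continue
        if not containers:
            raise ValueError(
                f"marker class {k!r} is not nested inside the root class; "
                "cannot attach it to the tree"
            )
        smallest = min(len(class_carriers[j]) for j in containers)
        minimal = sorted(j for j in containers
                         if len(class_carriers[j]) == smallest)
        if len(minimal) > 1:
            raise ValueError(
                f"ambiguous parent for class {k!r}: {minimal} are tied "
                "minimal containers"
            )
        parent[k] = minimal[0]

    if child_order is None:
        priority: dict[str, int] = {}
    elif isinstance(child_order, Mapping):
        priority = {m: i for i, m in enumerate(
            m for seq in child_order.values() for m in seq)}
    else:
        priority = {m: i for i, m in enumerate(child_order)}

    def sibling_key(k: str):
        return (priority.get(k, len(priority)), k)

    children_of: dict[str, list[str]] = {k: [] for k in keys}
    for k, p in parent.items():
        if p is not None:
            children_of[p].append(k)
    for p in children_of:
        children_of[p].sort(key=sibling_key)

    def build(key: str) -> CladeNode:
        return CladeNode(
            ycc_name=key,  # placeholder; assign_names renames below
            defining_markers=class_members[key],
            children=[build(c) for c in children_of[key]],
        )

    tree = Haplotree(build(root_key), root_letter=root_letter or root_name[0])
    tree.assign_names(root_name)
    return tree, report
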