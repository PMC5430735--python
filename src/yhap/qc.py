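"""Quality control: call-rate filtering and relatedness-based exclusion.

Mirrors standard array QC practice: drop samples and markers whose genotype
call rate falls below a threshold (default 98.5%), then, among the survivors,
resolve pairs with a relatedness score above a cutoff (default 0.125, about
third-degree relatives) by excluding one member per conflicting pair.

The relatedness step removes a *minimum-size* set of samples that leaves no
retained pair above the threshold (exact minimum vertex cover per connected
component of the violation graph). Ties between equally small exclusion sets
are broken by call rate — the lower-call-rate samples go — and then
lexicographically (the larger sample id goes), so the result is deterministic
and independent of input order.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .genotype_io import GenotypeMatrix

__all__ = ["QCReport", "EmptyMatrixError", "filter_call_rate", "exclude_related",
           "read_pair_scores"]

CALL_RATE_THRESHOLD = 0.985
RELATEDNESS_THRESHOLD = 0.125

# exact vertex-cover search is exponential; beyond this component size fall
# back to greedy max-degree removal
_EXACT_COMPONENT_LIMIT = 20


class EmptyMatrixError(ValueError):
    """All samples or all markers were removed by filtering."""


@dataclass
class QCReport:
    call_rate_threshold: float | None = None
    relatedness_threshold: float | None = None
    removed_samples_callrate: list[str] = field(default_factory=list)
    removed_markers_callrate: list[str] = field(default_factory=list)
    removed_samples_related: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "call_rate_threshold": self.call_rate_threshold,
            "relatedness_threshold": self.relatedness_threshold,
            "removed_samples_callrate": list(self.removed_samples_callrate),
            "removed_markers_callrate": list(self.removed_markers_callrate),
            "removed_samples_related": list(self.removed_samples_related),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def filter_call_rate(matrix: GenotypeMatrix, threshold: float = CALL_RATE_THRESHOLD
                     ) -> tuple[GenotypeMatrix, QCReport]:
    """Iteratively drop samples, then markers, with call rate < threshold.

    Removing a low-call-rate sample can raise or lower marker call rates, so
    the two passes repeat until stable; on return every retained sample and
    marker meets the threshold.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    report = QCReport(call_rate_threshold=threshold)
    current = matrix
    while True:
        bad_samples = [
            s for s, r in current.sample_call_rates().items() if r < threshold
        ]
        if bad_samples:
            report.removed_samples_callrate.extend(bad_samples)
            keep = [s for s in current.sample_ids if s not in set(bad_samples)]
            if not keep:
                raise EmptyMatrixError("call-rate filter removed every sample")
            current = current.subset(samples=keep)
        bad_markers = [
            m for m, r in current.marker_call_rates().items() if r < threshold
        ]
        if bad_markers:
            report.removed_markers_callrate.extend(bad_markers)
            keep = [m for m in current.marker_names if m not in set(bad_markers)]
            if not keep:
                raise EmptyMatrixError("call-rate filter removed every marker")
            current = current.subset(markers=keep)
        if not bad_samples and not bad_markers:
            return current, report


def read_pair_scores(path) -> dict[tuple[str, str], float]:
    """Relatedness scores from a 3-column TSV (id1, id2, score)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    df.columns = ["id1", "id2", "score"][: len(df.columns)]
    return {(r.id1, r.id2): float(r.score) for r in df.itertuples(index=False)}


def _normalise_scores(pair_scores: Mapping[tuple[str, str], float]
                      ) -> dict[frozenset, float]:
    out: dict[frozenset, float] = {}
    for (a, b), score in pair_scores.items():
        if a == b:
            continue
        key = frozenset((a, b))
        if key in out and out[key] != score:
            raise ValueError(f"asymmetric scores for pair ({a}, {b}): "
                             f"{out[key]} vs {score}")
        out[key] = score
    return out


def _min_cover(component: list[str], edges: list[tuple[str, str]],
               call_rates: Mapping[str, float]) -> list[str]:
    """Deterministic minimum vertex cover of one violation component."""

    def covers(subset: frozenset) -> bool:
        return all(a in subset or b in subset for a, b in edges)

    if len(component) <= _EXACT_COMPONENT_LIMIT:
        for size in range(1, len(component) + 1):
            candidates = [
                c for c in itertools.combinations(sorted(component), size)
                if covers(frozenset(c))
            ]
            if candidates:
                # prefer removing lower call rates; among ties remove the
                # lexicographically larger ids
                low = min(sum(call_rates.get(s, 1.0) for s in c)
                          for c in candidates)
                tied = [c for c in candidates
                        if sum(call_rates.get(s, 1.0) for s in c) == low]
                return list(max(tied, key=lambda c: tuple(sorted(c))))
    # greedy fallback: repeatedly remove the highest-degree sample,
    # preferring lower call rate, then the lexicographically larger id
    removed: set[str] = set()
    live = list(edges)
    while live:
        degree: dict[str, int] = {}
        for a, b in live:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        victim = min(
            degree,
            key=lambda s: (-degree[s], call_rates.get(s, 1.0),
                           tuple(-ord(c) for c in s)),
        )
        removed.add(victim)
        live = [(a, b) for a, b in live if victim not in (a, b)]
    return sorted(removed)


def exclude_related(sample_ids: Iterable[str],
                    pair_scores: Mapping[tuple[str, str], float],
                    threshold: float = RELATEDNESS_THRESHOLD,
                    call_rates: Mapping[str, float] | None = None
                    ) -> tuple[list[str], QCReport]:
    """Remove one member of every pair with relatedness score > threshold.

    Returns the retained ids (input order preserved) and a report listing
    the exclusions. The exclusion set is minimum-size; within a tied pair the
    lower-call-rate member is removed (tie: lexicographically larger id).
    """
    ids = list(sample_ids)
    id_set = set(ids)
    if len(ids) != len(id_set):
        raise ValueError("duplicate sample ids")
    call_rates = dict(call_rates or {})
    scores = _normalise_scores(pair_scores)

    edges = sorted(
        tuple(sorted(pair)) for pair, s in scores.items()
        if s > threshold and pair <= id_set
    )
    report = QCReport(relatedness_threshold=threshold)
    if edges:
        adjacency: dict[str, set[str]] = {}
        for a, b in edges:
            adjacency.setdefault(a, set()).add(b)
            adjacency.setdefault(b, set()).add(a)
        seen: set[str] = set()
        removed: set[str] = set()
        for start in sorted(adjacency):
            if start in seen:
                continue
            stack, component = [start], []
            while stack:
                node = stack.pop()
                if node in seen:
                    continue
                seen.add(node)
                component.append(node)
                stack.extend(adjacency[node] - seen)
            comp_edges = [e for e in edges if e[0] in component]
            removed.update(_min_cover(component, comp_edges, call_rates))
        report.removed_samples_related = sorted(removed)
    retained = [s for s in ids if s not in set(report.removed_samples_related)]
    return retained, report
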