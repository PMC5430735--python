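"""Synthetic cohorts with the statistical structure the pipeline assumes.

Each simulated male draws a true haplogroup (or "outside the clade") from a
vector of exclusive frequencies on a known tree. His error-free genotype is
derived at every defining marker on the root-to-haplogroup path and
ancestral elsewhere; genotyping noise is then layered on as independent
symmetric A<->D flips (per-genotype error rate) followed by no-call masking.
Regions are drawn independently of haplogroup. Everything is reproducible
from one integer seed.

``expected_counts_cohort`` is the deterministic counterpart: it emits
exactly the requested number of error-free samples per node (and region),
and is how printed count tables are turned back into a cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .genotype_io import GenotypeMatrix, SampleMetadata
from .haplotree import Haplotree

__all__ = ["SimulationConfig", "simulate_cohort", "expected_counts_cohort",
           "concordance", "OUTSIDE"]

#: Key used for the outside-the-root-clade category in frequency/count maps.
OUTSIDE = "outside"


@dataclass
class SimulationConfig:
    """Study-design parameters for one simulated cohort.

    ``exclusive_freqs`` maps node ycc names to exclusive probabilities; the
    reserved key ``"outside"`` holds the outside-clade probability (added
    automatically as the complement when absent). Probabilities must sum
    to 1 (within 1e-9).
    """

    tree: Haplotree
    exclusive_freqs: dict[str, float]
    n_samples: int
    nocall_rate: float = 0.0
    error_rate: float = 0.0
    region_probs: dict[str, float] = field(
        default_factory=lambda: {"East": 1 / 3, "North": 1 / 3, "South": 1 / 3})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for name, p in (*self.exclusive_freqs.items(), *self.region_probs.items()):
            if not 0 <= p <= 1:
                raise ValueError(f"probability for {name!r} outside [0, 1]: {p}")
        for rate in (self.nocall_rate, self.error_rate):
            if not 0 <= rate <= 1:
                raise ValueError(f"rate outside [0, 1]: {rate}")
        for name in self.exclusive_freqs:
            if name != OUTSIDE and name not in self.tree:
                raise ValueError(f"unknown node {name!r} in exclusive_freqs")
        inside = sum(p for n, p in self.exclusive_freqs.items() if n != OUTSIDE)
        if OUTSIDE not in self.exclusive_freqs:
            if inside > 1 + 1e-9:
                raise ValueError("exclusive frequencies exceed 1")
            self.exclusive_freqs = {**self.exclusive_freqs,
                                    OUTSIDE: max(0.0, 1.0 - inside)}
        total = sum(self.exclusive_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, not 1")
        region_total = sum(self.region_probs.values())
        if abs(region_total - 1.0) > 1e-9:
            raise ValueError(f"region probabilities sum to {region_total}, not 1")

    @classmethod
    def from_file(cls, path, tree: Haplotree | None = None) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if tree is None:
            tree = Haplotree.from_dict(data["tree"])
        return cls(
            tree=tree,
            exclusive_freqs=dict(data["exclusive_freqs"]),
            n_samples=int(data["n_samples"]),
            nocall_rate=float(data.get("nocall_rate", 0.0)),
            error_rate=float(data.get("error_rate", 0.0)),
            region_probs=dict(data.get("region_probs", {
                "East": 1 / 3, "North": 1 / 3, "South": 1 / 3})),
            seed=int(data.get("seed", 0)),
        )

    def to_file(self, path) -> None:
        data = {
            "tree": self.tree.to_dict(),
            "exclusive_freqs": self.exclusive_freqs,
            "n_samples": self.n_samples,
            "nocall_rate": self.nocall_rate,
            "error_rate": self.error_rate,
            "region_probs": self.region_probs,
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(data, fh, indent=2)


def _path_markers(tree: Haplotree, node_name: str) -> set[str]:
    markers: set[str] = set()
    for node in tree.path_to(node_name):
        markers.update(node.defining_markers)
    return markers


def _clean_genotypes(tree: Haplotree, truth: Sequence[str],
                     sample_ids: Sequence[str]) -> pd.DataFrame:
    markers = tree.markers()
    marker_index = {m: j for j, m in enumerate(markers)}
    grid = np.full((len(truth), len(markers)), "A", dtype=object)
    path_cache: dict[str, list[int]] = {}
    for i, node_name in enumerate(truth):
        if node_name == OUTSIDE:
            continue
        if node_name not in path_cache:
            path_cache[node_name] = [marker_index[m]
                                     for m in _path_markers(tree, node_name)]
        grid[i, path_cache[node_name]] = "D"
    return pd.DataFrame(grid, index=list(sample_ids), columns=markers)


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[GenotypeMatrix, pd.DataFrame, list[SampleMetadata]]:
    """Draw a cohort; returns (genotypes, truth table, metadata).

    The truth table has columns sample_id, true_node, region; genotype
    errors flip A<->D before the no-call mask is applied, so a flipped call
    can still be hidden by missingness.
    """
    rng = np.random.default_rng(config.seed)
    nodes = sorted(config.exclusive_freqs)
    probs = np.array([config.exclusive_freqs[n] for n in nodes], dtype=float)
    probs = probs / probs.sum()
    sample_ids = [f"S{i:05d}" for i in range(config.n_samples)]
    truth = list(rng.choice(nodes, size=config.n_samples, p=probs))

    regions = sorted(config.region_probs)
    region_p = np.array([config.region_probs[r] for r in regions], dtype=float)
    region_draw = list(rng.choice(regions, size=config.n_samples,
                                  p=region_p / region_p.sum()))

    calls = _clean_genotypes(config.tree, truth, sample_ids)
    values = calls.to_numpy(dtype=object)
    if config.error_rate > 0:
        flip = rng.random(values.shape) < config.error_rate
        flip_a, flip_d = flip & (values == "A"), flip & (values == "D")
        values[flip_a] = "D"
        values[flip_d] = "A"
    if config.nocall_rate > 0:
        values[rng.random(values.shape) < config.nocall_rate] = "N"
    matrix = GenotypeMatrix(pd.DataFrame(values, index=calls.index,
                                         columns=calls.columns))
    truth_df = pd.DataFrame({"sample_id": sample_ids, "true_node": truth,
                             "region": region_draw})
    metadata = [SampleMetadata(sample_id=s, region=r)
                for s, r in zip(sample_ids, region_draw)]
    return matrix, truth_df, metadata


def expected_counts_cohort(
    tree: Haplotree,
    exclusive_counts: Mapping[str, int],
    region_counts: Mapping[str, Mapping[str, int]] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, list[SampleMetadata]]:
    """Deterministically emit exactly ``exclusive_counts[node]`` samples per node.

    ``exclusive_counts`` may include the reserved key ``"outside"`` for
    all-ancestral samples. ``region_counts[node]`` optionally splits a node's
    count over regions (must sum to the node count); nodes without a split
    get region Unknown. Genotypes are error-free and fully called.
    """
    truth: list[str] = []
    region: list[str] = []
    for node_name in sorted(exclusive_counts):
        count = int(exclusive_counts[node_name])
        if count < 0:
            raise ValueError(f"negative count for {node_name!r}")
        if node_name != OUTSIDE and node_name not in tree:
            raise KeyError(f"unknown node {node_name!r}")
        split = dict((region_counts or {}).get(node_name, {}))
        if split:
            if sum(split.values()) != count:
                raise ValueError(
                    f"region counts for {node_name!r} sum to "
                    f"{sum(split.values())}, expected {count}")
            for r in sorted(split):
                truth.extend([node_name] * int(split[r]))
                region.extend([r] * int(split[r]))
        else:
            truth.extend([node_name] * count)
            region.extend(["Unknown"] * count)

    sample_ids = [f"S{i:05d}" for i in range(len(truth))]
    calls = _clean_genotypes(tree, truth, sample_ids)
    matrix = GenotypeMatrix(calls)
    truth_df = pd.DataFrame({"sample_id": sample_ids, "true_node": truth,
                             "region": region})
    metadata = [SampleMetadata(sample_id=s, region=r)
                for s, r in zip(sample_ids, region)]
    return matrix, truth_df, metadata


def concordance(truth: pd.DataFrame, called: pd.DataFrame
                ) -> tuple[float, list[tuple[str, str, int]]]:
    """Exact-node agreement between truth labels and calls.

    ``truth`` needs columns sample_id/true_node; ``called`` needs
    sample_id/called_node. Returns the agreement fraction and a list of
    (true_node, called_node, n) confusion pairs for the disagreements.
    """
    t = truth.set_index("sample_id")["true_node"]
    c = called.set_index("sample_id")["called_node"]
    if set(t.index) != set(c.index):
        raise ValueError("sample ids of truth and calls differ")
    c = c.reindex(t.index)
    agree = (t == c)
    wrong = pd.DataFrame({"true": t[~agree], "called": c[~agree]})
    confusion = [
        (str(true), str(called_node), int(n))
        for (true, called_node), n in
        wrong.value_counts(["true", "called"]).sort_index().items()
    ]
    return float(agree.mean()) if len(t) else 1.0, confusion
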