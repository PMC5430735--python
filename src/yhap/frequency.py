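"""Exclusive and cumulative haplogroup frequency tables.

*Exclusive* count of a node: samples whose walk terminates exactly there
(paragroup rows, starred, when the node has subclades). *Cumulative* count:
all samples anywhere in the node's subtree; it always equals the exclusive
count plus the children's cumulative counts.

Frequencies are percentages of the whole genotyped cohort — also for the
regional columns, which therefore sum across regions to the overall column
rather than to 100% within a region. Rounding is decimal half-up. Two styles
are supported: ``plain`` rounds the raw fraction once at the requested
precision; ``table1`` reproduces the source table's printing convention, in
which the overall column was rounded to thousandths of a percent before
being printed at hundredths (so 57/2139 prints as 2.67, via 2.665) while
regional columns were rounded once (17/2139 prints as 0.79). Raw counts are
always retained, so nothing downstream compounds rounding error unless the
explicit "rounded" mode is requested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Literal, Mapping, Sequence

import pandas as pd

from .calling import Assignment
from .haplotree import Haplotree

__all__ = [
    "FrequencyTable",
    "CladeSummary",
    "round_percent",
    "build_frequency_table",
    "cumulative_summary",
    "regional_clade_frequency",
]

REGION_COLUMNS = ("East", "North", "South", "Unknown")

RoundingStyle = Literal["plain", "table1"]


def round_percent(count: int, denominator: int, decimals: int = 2,
                  style: RoundingStyle = "plain") -> Decimal:
    """Percentage ``100*count/denominator`` rounded half-up.

    ``table1`` style rounds via 3 decimals first when fewer are requested,
    matching how the reference table's overall column was printed.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(100 * count) / Decimal(denominator)
    if style == "table1" and decimals < 3:
        pct = pct.quantize(Decimal(1).scaleb(-3), rounding=ROUND_HALF_UP)
    return pct.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP)


@dataclass
class FrequencyTable:
    """Per-haplogroup exclusive counts and percent frequencies.

    ``counts`` rows are keyed by display name (starred paragroups) and hold
    integer exclusive counts: overall ``count`` plus one column per region.
    """

    counts: pd.DataFrame
    total_cohort_n: int
    node_of_row: dict[str, str]  # display name -> ycc name

    def row_names(self) -> list[str]:
        return list(self.counts.index)

    def exclusive_count(self, row: str) -> int:
        return int(self.counts.loc[row, "count"])

    def regional_count(self, row: str, region: str) -> int:
        if region not in REGION_COLUMNS:
            raise ValueError(f"unknown region {region!r}")
        return int(self.counts.loc[row, region])

    def formatted(self, decimals: int = 2, style: RoundingStyle = "table1"
                  ) -> pd.DataFrame:
        """Printable table: Haplogroup, Count, Sum, East, North, South.

        In ``table1`` style the overall (Sum) column is double-rounded and
        the regional columns single-rounded, as in the reference layout.
        """
        sum_style = style
        rows = []
        for name in self.counts.index:
            rec = {"Haplogroup": name,
                   "Count": int(self.counts.loc[name, "count"]),
                   "Sum": float(round_percent(int(self.counts.loc[name, "count"]),
                                              self.total_cohort_n, decimals,
                                              sum_style))}
            for region in ("East", "North", "South"):
                rec[region] = float(round_percent(
                    int(self.counts.loc[name, region]), self.total_cohort_n,
                    decimals, "plain"))
            rows.append(rec)
        return pd.DataFrame(rows).set_index("Haplogroup")

    def write_tsv(self, path, decimals: int = 2,
                  style: RoundingStyle = "table1") -> None:
        df = self.formatted(decimals, style)
        df = df.map(lambda v: f"{v:.{decimals}f}%" if isinstance(v, float) else v)
        df.to_csv(path, sep="\t")


@dataclass
class CladeSummary:
    node: str
    cumulative_count: int
    cumulative_freq: Decimal  # percent, per the chosen denominator
    share_of_root: Decimal  # percent of the root clade
    denominator: str
    denominator_n: int

    def to_dict(self) -> dict:
        return {
            "node": self.node,
            "cumulative_count": self.cumulative_count,
            "cumulative_freq": float(self.cumulative_freq),
            "share_of_root": float(self.share_of_root),
            "denominator": self.denominator,
            "denominator_n": self.denominator_n,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def _display_name(tree: Haplotree, ycc_name: str) -> str:
    return ycc_name + "*" if tree.node(ycc_name).children else ycc_name


def build_frequency_table(assignments: Sequence[Assignment],
                          regions: Mapping[str, str] | pd.Series,
                          total_cohort_n: int,
                          tree: Haplotree | None = None) -> FrequencyTable:
    """Tabulate exclusive counts per assigned node, overall and per region.

    ``total_cohort_n`` is the full genotyped cohort (in-clade and outside);
    it is the denominator for every percentage. Unresolved and confirmed
    paragroups collapse onto the same starred row. Row order follows tree
    preorder when a tree is given, else sorted display name.
    """
    in_clade = [a for a in assignments if a.in_clade]
    if total_cohort_n < len(in_clade):
        raise ValueError("total_cohort_n smaller than number of in-clade samples")
    regions = dict(regions) if not isinstance(regions, dict) else regions
    counts: dict[str, dict[str, int]] = {}
    node_of_row: dict[str, str] = {}
    for a in in_clade:
        name = a.display_name() if tree is None else _display_name(tree, a.node)
        region = regions.get(a.sample_id, "Unknown")
        if region not in REGION_COLUMNS:
            raise ValueError(f"invalid region {region!r} for sample {a.sample_id}")
        rec = counts.setdefault(name, {c: 0 for c in ("count",) + REGION_COLUMNS})
        rec["count"] += 1
        rec[region] += 1
        node_of_row[name] = a.node

    if tree is not None:
        order = [n for n in tree.node_names()
                 for disp in (_display_name(tree, n),) if disp in counts]
        row_order = [_display_name(tree, n) for n in order]
    else:
        row_order = sorted(counts)
    df = pd.DataFrame.from_dict(counts, orient="index").loc[row_order]
    df.index.name = "haplogroup"
    return FrequencyTable(counts=df, total_cohort_n=total_cohort_n,
                          node_of_row=node_of_row)


def _cumulative_count(tree: Haplotree, table: FrequencyTable, node_name: str,
                      column: str = "count") -> int:
    subtree = {n.ycc_name for n in tree.subtree_nodes(node_name)}
    total = 0
    for row in table.row_names():
        if table.node_of_row[row] in subtree:
            total += (table.exclusive_count(row) if column == "count"
                      else table.regional_count(row, column))
    return total


def cumulative_summary(tree: Haplotree, table: FrequencyTable, node_name: str,
                       denominator: Literal["cohort", "root_clade"] = "cohort",
                       decimals: int = 2,
                       style: RoundingStyle = "plain") -> CladeSummary:
    """Cumulative count and frequency of a clade (node plus descendants)."""
    if node_name not in tree:
        raise KeyError(f"unknown node {node_name!r}")
    count = _cumulative_count(tree, table, node_name)
    root_total = _cumulative_count(tree, table, tree.root.ycc_name)
    denom_n = table.total_cohort_n if denominator == "cohort" else root_total
    if denominator not in ("cohort", "root_clade"):
        raise ValueError(f"unknown denominator {denominator!r}")
    return CladeSummary(
        node=node_name,
        cumulative_count=count,
        cumulative_freq=round_percent(count, denom_n, decimals, style),
        share_of_root=round_percent(count, root_total, decimals, style),
        denominator=denominator,
        denominator_n=denom_n,
    )


def regional_clade_frequency(tree: Haplotree, table: FrequencyTable,
                             node_name: str, region: str,
                             mode: Literal["raw", "rounded", "table1"] = "raw",
                             decimals: int = 2) -> Decimal:
    """Percent of the whole cohort inside a clade, within one region.

    ``raw`` sums the regional counts over the clade's rows and rounds once.
    ``rounded`` (alias ``table1``) sums the already-rounded per-row regional
    percentages — exactly the arithmetic of reading the printed table's
    regional column — and exists to reproduce figures derived that way.
    """
    if mode == "table1":
        mode = "rounded"
    if node_name not in tree:
        raise KeyError(f"unknown node {node_name!r}")
    if region not in REGION_COLUMNS:
        raise ValueError(f"unknown region {region!r}")
    subtree = {n.ycc_name for n in tree.subtree_nodes(node_name)}
    rows = [r for r in table.row_names() if table.node_of_row[r] in subtree]
    if mode == "raw":
        count = sum(table.regional_count(r, region) for r in rows)
        return round_percent(count, table.total_cohort_n, decimals)
    if mode != "rounded":
        raise ValueError(f"unknown mode {mode!r}")
    total = sum(
        (round_percent(table.regional_count(r, region), table.total_cohort_n,
                       decimals, "plain") for r in rows),
        Decimal(0),
    )
    return total.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP)
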