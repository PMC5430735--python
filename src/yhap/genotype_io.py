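"""Readers/writers for genotype matrices, marker tables, metadata and regions.

All files are plain UTF-8 TSV (or YAML/JSON for the region config). Genotype
calls are haploid: every cell is one of ``A`` (ancestral), ``D`` (derived) or
``N`` (no call). Raw-base input is converted through the marker definition
table; any base matching neither allele — including heterozygous-looking
two-base cells, which cannot be genuine on the hemizygous Y — becomes ``N``
with a counted warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .haplotree import Marker

logger = logging.getLogger(__name__)

CALLS = ("A", "D", "N")
REGIONS = ("East", "North", "South", "Unknown")

#: Default province -> region map. East per the study design (Jiangsu, Anhui,
#: Zhejiang, Shanghai); other provinces split by whether their capital lies
#: north or south of the Qinling Mountains–Huai River line.
DEFAULT_REGION_CONFIG: dict[str, str] = {
    "Jiangsu": "East",
    "Anhui": "East",
    "Zhejiang": "East",
    "Shanghai": "East",
    "Beijing": "North",
    "Tianjin": "North",
    "Hebei": "North",
    "Shanxi": "North",
    "Shaanxi": "North",
    "Shandong": "North",
    "Henan": "North",
    "Gansu": "North",
    "Qinghai": "North",
    "Ningxia": "North",
    "Xinjiang": "North",
    "Liaoning": "North",
    "Jilin": "North",
    "Heilongjiang": "North",
    "Inner Mongolia": "North",
    "Hubei": "South",
    "Hunan": "South",
    "Jiangxi": "South",
    "Fujian": "South",
    "Guangdong": "South",
    "Guangxi": "South",
    "Hainan": "South",
    "Sichuan": "South",
    "Chongqing": "South",
    "Guizhou": "South",
    "Yunnan": "South",
    "Tibet": "South",
    "Taiwan": "South",
    "Hong Kong": "South",
    "Macau": "South",
}


class GenotypeMatrix:
    """Samples x markers matrix of haploid calls in ``{A, D, N}``.

    Thin wrapper over a pandas DataFrame (index = sample ids, columns =
    marker names) that enforces the call alphabet and unique labels.
    """

    def __init__(self, calls: pd.DataFrame):
        if calls.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if calls.columns.has_duplicates:
            raise ValueError("duplicate marker names")
        values = calls.to_numpy(dtype=object)
        bad = ~np.isin(values, CALLS)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid call {values[i, j]!r} at sample {calls.index[i]!r}, "
                f"marker {calls.columns[j]!r}"
            )
        self.calls = calls.astype(object)

    # -- basic properties ------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def marker_names(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape

    def column(self, marker: str) -> pd.Series:
        if marker not in self.calls.columns:
            raise KeyError(f"unknown marker {marker!r}")
        return self.calls[marker]

    def row(self, sample_id: str) -> pd.Series:
        return self.calls.loc[sample_id]

    def sample_call_rates(self) -> pd.Series:
        """Fraction of non-N entries per sample."""
        if self.shape[1] == 0:
            return pd.Series(1.0, index=self.calls.index)
        return (self.calls != "N").mean(axis=1)

    def marker_call_rates(self) -> pd.Series:
        if self.shape[0] == 0:
            return pd.Series(1.0, index=self.calls.columns)
        return (self.calls != "N").mean(axis=0)

    def subset(self, samples: Iterable[str] | None = None,
               markers: Iterable[str] | None = None) -> "GenotypeMatrix":
        df = self.calls
        if samples is not None:
            df = df.loc[list(samples)]
        if markers is not None:
            df = df[list(markers)]
        return GenotypeMatrix(df.copy())

    def __eq__(self, other) -> bool:
        return isinstance(other, GenotypeMatrix) and self.calls.equals(other.calls)


@dataclass
class SampleMetadata:
    sample_id: str
    province: str | None = None
    region: str = "Unknown"

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"invalid region {self.region!r}")


# -- marker definitions --------------------------------------------------

def read_marker_table(path) -> dict[str, Marker]:
    """Marker definition TSV: columns name, position, ancestral, derived."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "ancestral", "derived"}
    if not required.issubset(df.columns):
        raise ValueError(f"marker table needs columns {sorted(required)}")
    markers: dict[str, Marker] = {}
    for rec in df.itertuples(index=False):
        if rec.name in markers:
            raise ValueError(f"duplicate marker {rec.name!r}")
        pos = getattr(rec, "position", None)
        markers[rec.name] = Marker(
            name=rec.name,
            position=int(pos) if pos not in (None, "") and not pd.isna(pos) else None,
            ancestral_allele=rec.ancestral,
            derived_allele=rec.derived,
        )
    return markers


def write_marker_table(markers: Mapping[str, Marker], path) -> None:
    rows = [
        {
            "name": m.name,
            "position": "" if m.position is None else m.position,
            "ancestral": m.ancestral_allele,
            "derived": m.derived_allele,
        }
        for m in markers.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- genotype matrix -----------------------------------------------------

def read_genotype_matrix(path, marker_defs: Mapping[str, Marker] | None = None
                         ) -> GenotypeMatrix:
    """Read a genotype TSV (first column sample id, one column per marker).

    Cells may hold A/D/N codes directly, or raw bases when ``marker_defs``
    is given: the ancestral base maps to A, the derived base to D, anything
    else (unknown base, two-base heterozygous artifact, '.', '-') to N with
    a logged warning count.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    sample_col = df.columns[0]
    if df[sample_col].duplicated().any():
        dups = df[sample_col][df[sample_col].duplicated()].tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    df = df.set_index(sample_col)
    df.index.name = "sample_id"
    if df.columns.has_duplicates:
        raise ValueError("duplicate marker columns")

    if marker_defs is not None:
        missing = [m for m in df.columns if m not in marker_defs]
        if missing:
            raise ValueError(f"marker columns absent from definitions: {missing}")
        n_warn = 0
        converted = {}
        for m in df.columns:
            mk = marker_defs[m]
            col = df[m]
            out = pd.Series("N", index=col.index, dtype=object)
            out[col.isin(list(CALLS))] = col[col.isin(list(CALLS))]
            if mk.ancestral_allele:
                out[col == mk.ancestral_allele] = "A"
            if mk.derived_allele:
                out[col == mk.derived_allele] = "D"
            unrecognised = ~(col.isin(list(CALLS))
                             | (col == (mk.ancestral_allele or ""))
                             | (col == (mk.derived_allele or "")))
            n_warn += int(unrecognised.sum())
            converted[m] = out
        if n_warn:
            logger.warning("%d genotype cells matched neither allele; set to N", n_warn)
        df = pd.DataFrame(converted, index=df.index)[list(df.columns)]
    return GenotypeMatrix(df)


def write_genotype_matrix(matrix: GenotypeMatrix, path) -> None:
    matrix.calls.to_csv(path, sep="\t", index_label="sample_id")


# -- metadata and regions ------------------------------------------------

def load_region_config(path) -> dict[str, str]:
    """Province -> region map from a YAML or JSON file."""
    text = Path(path).read_text(encoding="utf-8")
    config = yaml.safe_load(text) if not text.lstrip().startswith("{") else json.loads(text)
    for province, region in config.items():
        if region not in REGIONS:
            raise ValueError(f"invalid region {region!r} for province {province!r}")
    return dict(config)


def assign_regions(rows: Iterable[Mapping[str, str | None]],
                   region_config: Mapping[str, str] | None = None
                   ) -> list[SampleMetadata]:
    """Attach a region to each metadata row via the province -> region map.

    Rows may carry a ``region`` directly (used when provinces are not
    published); an explicit region wins over the province lookup. Unmapped
    provinces degrade to ``Unknown`` with a logged warning.
    """
    config = DEFAULT_REGION_CONFIG if region_config is None else dict(region_config)
    out: list[SampleMetadata] = []
    n_unknown = 0
    for row in rows:
        province = row.get("province") or None
        region = row.get("region") or None
        if region is None:
            if province is not None and province in config:
                region = config[province]
            else:
                region = "Unknown"
                if province is not None:
                    n_unknown += 1
        out.append(SampleMetadata(sample_id=row["sample_id"], province=province,
                                  region=region))
    if n_unknown:
        logger.warning("%d samples with unmapped provinces set to region Unknown",
                       n_unknown)
    return out


def read_metadata(path, region_config: Mapping[str, str] | None = None
                  ) -> list[SampleMetadata]:
    """Metadata TSV with column sample_id plus province and/or region."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValueError("metadata needs a sample_id column")
    rows = df.to_dict(orient="records")
    return assign_regions(rows, region_config)


def write_metadata(metadata: Sequence[SampleMetadata], path) -> None:
    pd.DataFrame(
        [{"sample_id": m.sample_id, "province": m.province or "",
          "region": m.region} for m in metadata]
    ).to_csv(path, sep="\t", index=False)


def region_series(metadata: Sequence[SampleMetadata]) -> pd.Series:
    """Sample id -> region as a pandas Series."""
    return pd.Series({m.sample_id: m.region for m in metadata}, name="region")
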