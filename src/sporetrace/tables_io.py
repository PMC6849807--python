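"""Tabular IO and shared domain types.

All artifacts are plain tab-separated text: count tables (OTUs x samples),
sample metadata, taxonomy, hit annotations and reports.  TSV keeps fixtures
diffable and round-trips losslessly.  Identifier matching is case-sensitive
and whitespace-stripped throughout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "StationClass",
    "SampleRecord",
    "TableFormatError",
    "read_count_table",
    "write_count_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "validate_tables",
    "write_report",
]


class TableFormatError(ValueError):
    """A tabular artifact violates its schema or an invariant."""


class StationClass(str, enum.Enum):
    NON_TIDAL = "non_tidal"
    TIDAL = "tidal"
    MARINE = "marine"


@dataclass
class CountTable:
    """Non-negative integer OTU x sample matrix, raw or rarefied.

    ``counts`` is a pandas DataFrame indexed by OTU id with sample-id
    columns.  ``rarefied_depth``, when set, asserts that every sample column
    sums to exactly that many reads.
    """

    counts: pd.DataFrame
    rarefied_depth: int | None = None

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dupes = sorted(df.index[df.index.duplicated()].unique())
            raise TableFormatError(f"duplicate OTU id(s): {dupes}")
        if df.columns.has_duplicates:
            dupes = sorted(df.columns[df.columns.duplicated()].unique())
            raise TableFormatError(f"duplicate sample id(s): {dupes}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                raise TableFormatError("counts must be integers")
            df = df.astype(np.int64)
            object.__setattr__(self, "counts", df)
        if (df.to_numpy() < 0).any():
            raise TableFormatError("counts must be non-negative")
        if self.rarefied_depth is not None:
            depth = int(self.rarefied_depth)
            if depth <= 0:
                raise TableFormatError("rarefied_depth must be positive")
            sums = df.sum(axis=0)
            bad = sums[sums != depth]
            if len(bad):
                raise TableFormatError(
                    f"samples not at rarefied depth {depth}: {list(bad.index)}"
                )

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def __getitem__(self, key: tuple[str, str]) -> int:
        otu, sample = key
        return int(self.counts.at[otu, sample])


@dataclass(frozen=True)
class SampleRecord:
    """One pooled sample: station, station class, timepoint and medium."""

    sample_id: str
    station_id: str
    station_class: StationClass
    time_h: float
    medium_salinity: str = "brackish"

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise TableFormatError(f"negative time_h for sample {self.sample_id}")
        if self.medium_salinity not in ("brackish", "marine"):
            raise TableFormatError(
                f"unknown medium_salinity {self.medium_salinity!r} for {self.sample_id}"
            )


def _strip_index(items: Iterable) -> list[str]:
    return [str(x).strip() for x in items]


def read_count_table(path: str | Path, rarefied_depth: int | None = None) -> CountTable:
    """Read a TSV count table: first column OTU ids, header row sample ids."""
    # sniff the raw header: pandas mangles duplicate column names on read
    with open(path) as fh:
        header = [c.strip() for c in fh.readline().rstrip("\n").split("\t")][1:]
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise TableFormatError(f"duplicate sample id(s): {dupes}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise TableFormatError(f"cannot parse count table {path}: {exc}") from exc
    df.index = _strip_index(df.index)
    df.columns = _strip_index(df.columns)
    try:
        numeric = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise TableFormatError(f"non-numeric cell in count table {path}: {exc}") from exc
    return CountTable(numeric, rarefied_depth=rarefied_depth)


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.counts.rename_axis("otu_id").to_csv(path, sep="\t", lineterminator="\n")


def read_sample_metadata(path: str | Path) -> list[SampleRecord]:
    """Read sample metadata TSV (sample_id, station_id, station_class, time_h, medium_salinity)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = _strip_index(df.columns)
    required = {"sample_id", "station_id", "station_class", "time_h", "medium_salinity"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"metadata missing column(s): {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        cls_raw = str(row.station_class).strip()
        try:
            cls = StationClass(cls_raw)
        except ValueError as exc:
            raise TableFormatError(f"unknown station_class {cls_raw!r}") from exc
        records.append(
            SampleRecord(
                sample_id=str(row.sample_id).strip(),
                station_id=str(row.station_id).strip(),
                station_class=cls,
                time_h=float(row.time_h),
                medium_salinity=str(row.medium_salinity).strip(),
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise TableFormatError(f"duplicate sample id(s) in metadata: {dupes}")
    by_station: dict[str, StationClass] = {}
    for r in records:
        prev = by_station.setdefault(r.station_id, r.station_class)
        if prev is not r.station_class:
            raise TableFormatError(
                f"station {r.station_id} has inconsistent classes "
                f"({prev.value} vs {r.station_class.value})"
            )
    return records


def write_sample_metadata(records: Sequence[SampleRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "station_id": [r.station_id for r in records],
            "station_class": [r.station_class.value for r in records],
            "time_h": [r.time_h for r in records],
            "medium_salinity": [r.medium_salinity for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_taxonomy(path: str | Path) -> dict[str, list[str]]:
    """Read taxonomy TSV (otu_id, semicolon-joined lineage) into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = _strip_index(df.columns)
    if not {"otu_id", "lineage"} <= set(df.columns):
        raise TableFormatError("taxonomy needs columns otu_id, lineage")
    out: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        otu = str(row.otu_id).strip()
        if otu in out:
            raise TableFormatError(f"duplicate OTU id in taxonomy: {otu}")
        lineage = str(row.lineage) if not pd.isna(row.lineage) else ""
        out[otu] = [t.strip() for t in lineage.split(";") if t.strip()]
    return out


def write_taxonomy(taxonomy: Mapping[str, Sequence[str]], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "otu_id": list(taxonomy),
            "lineage": ["; ".join(v) for v in taxonomy.values()],
        }
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def lineage_phylum(lineage: Sequence[str]) -> str:
    """Extract the phylum rank from a domain-to-genus lineage, else 'Unassigned'."""
    for token in lineage:
        if token.startswith("p__"):
            return token[3:] or "Unassigned"
    return lineage[1] if len(lineage) > 1 else "Unassigned"


def validate_tables(
    table: CountTable,
    metadata: Sequence[SampleRecord],
    taxonomy: Mapping[str, Sequence[str]] | None = None,
) -> None:
    """Cross-check a count table against its metadata (and taxonomy).

    Every sample column must have a metadata record; every station must have
    a 0 h sample.  Missing taxonomy entries are permitted (reported
    downstream as 'Unassigned'), but a taxonomy keyed on unknown OTUs is
    rejected as a likely file mix-up.
    """
    meta_ids = {r.sample_id for r in metadata}
    missing = [s for s in table.sample_ids if s not in meta_ids]
    if missing:
        raise TableFormatError(f"samples missing from metadata: {missing}")
    used = [r for r in metadata if r.sample_id in set(table.sample_ids)]
    stations = {r.station_id for r in used}
    without_t0 = sorted(
        s for s in stations if not any(r.time_h == 0 for r in used if r.station_id == s)
    )
    if without_t0:
        raise TableFormatError(f"stations lacking a 0 h sample: {without_t0}")
    if taxonomy is not None:
        unknown = sorted(set(taxonomy) - set(table.otu_ids))
        if unknown:
            raise TableFormatError(f"taxonomy refers to unknown OTUs: {unknown[:5]}")


def write_report(
    assignments,
    enrichment,
    mpn_estimates,
    profiles,
    out_dir: str | Path,
    taxonomy: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, Path]:
    """Write the per-OTU source report plus MPN and EnvO profile tables.

    The main report has one row per enriched OTU: id, taxonomy, per-station
    maximum heated relative abundance, and the dispersal-history label,
    mirroring a supplementary-table layout.  Separate files carry the MPN
    estimates and the EnvO profile matrix.  All inputs must refer to the
    same OTU universe.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    label_by_otu = {a.otu_id: a for a in assignments}
    enriched = sorted(label_by_otu)
    extra = sorted(set(enriched) - set(enrichment.otu_ids))
    if extra:
        raise TableFormatError(f"assignments refer to OTUs absent from enrichment: {extra}")

    stations = enrichment.station_ids
    rows = []
    for otu in enriched:
        a = label_by_otu[otu]
        lineage = "; ".join(taxonomy.get(otu, [])) if taxonomy else ""
        row = {
            "otu_id": otu,
            "taxonomy": lineage or "Unassigned",
            "source": a.label.value,
        }
        for st in stations:
            cell = enrichment.cell(otu, st)
            row[f"max_heated_pct_{st}"] = round(cell.max_heated_fraction * 100, 4)
        rows.append(row)
    report = pd.DataFrame(
        rows,
        columns=["otu_id", "taxonomy", "source"]
        + [f"max_heated_pct_{st}" for st in stations],
    )
    paths["report"] = out_dir / "source_report.tsv"
    report.to_csv(paths["report"], sep="\t", index=False, lineterminator="\n")

    if mpn_estimates:
        mpn_rows = []
        for name, est in mpn_estimates.items():
            mpn, lo, hi = est.rounded
            mpn_rows.append(
                {
                    "assay": name,
                    "mpn_per_g": mpn,
                    "ci_low_per_g": lo,
                    "ci_high_per_g": hi,
                    "method": est.method,
                    "flag": est.flag,
                }
            )
        paths["mpn"] = out_dir / "mpn_estimates.tsv"
        pd.DataFrame(mpn_rows).to_csv(paths["mpn"], sep="\t", index=False, lineterminator="\n")

    if profiles:
        from .envo import heatmap_matrix

        paths["envo"] = out_dir / "envo_profiles.tsv"
        heatmap_matrix(profiles).rename_axis("term").to_csv(
            paths["envo"], sep="\t", lineterminator="\n"
        )
    return paths
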