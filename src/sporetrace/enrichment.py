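"""Enrichment calling from the 0 h baseline and heated time series.

An OTU is enriched at a station when it was absent or rare (relative
abundance strictly below 0.1%) in the unincubated 0 h sample and rose
strictly above 1% in at least one heated timepoint of that station's
pasteurized 50 degC incubation.  Both cutoffs are strict inequalities and
are exposed as configurable thresholds.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .abundance import RelAbundTable
from .tables_io import SampleRecord, StationClass, TableFormatError

__all__ = ["Thresholds", "Verdict", "EnrichmentCell", "EnrichmentMatrix", "call_enrichment", "enriched_otus"]


@dataclass(frozen=True)
class Thresholds:
    """Enrichment rule cutoffs (fractions, not percent)."""

    baseline_max_fraction: float = 0.001
    enriched_min_fraction: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.baseline_max_fraction < self.enriched_min_fraction < 1:
            raise ValueError(
                "need 0 < baseline_max_fraction < enriched_min_fraction < 1"
            )


class Verdict(str, enum.Enum):
    ENRICHED = "enriched"
    NOT_ENRICHED = "not_enriched"


@dataclass(frozen=True)
class EnrichmentCell:
    verdict: Verdict
    baseline_fraction: float
    max_heated_fraction: float
    time_of_max_h: float


@dataclass
class EnrichmentMatrix:
    """Per (OTU, station) verdicts with the supporting fractions."""

    cells: dict[tuple[str, str], EnrichmentCell]
    otu_ids: list[str]
    station_ids: list[str]
    station_classes: dict[str, StationClass]
    thresholds: Thresholds

    def cell(self, otu: str, station: str) -> EnrichmentCell:
        return self.cells[(otu, station)]

    def verdict(self, otu: str, station: str) -> Verdict:
        return self.cells[(otu, station)].verdict

    def is_enriched(self, otu: str, station: str) -> bool:
        return self.cells[(otu, station)].verdict is Verdict.ENRICHED

    def enriched_stations(self, otu: str) -> list[str]:
        return [s for s in self.station_ids if self.is_enriched(otu, s)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (otu, st), c in self.cells.items():
            rows.append(
                {
                    "otu_id": otu,
                    "station_id": st,
                    "verdict": c.verdict.value,
                    "baseline_fraction": c.baseline_fraction,
                    "max_heated_fraction": c.max_heated_fraction,
                    "time_of_max_h": c.time_of_max_h,
                }
            )
        return pd.DataFrame(rows)


def call_enrichment(
    rel: RelAbundTable,
    meta: Sequence[SampleRecord],
    thr: Thresholds = Thresholds(),
) -> EnrichmentMatrix:
    """Apply the enrichment rule per OTU per station.

    The baseline is the station's single 0 h (unincubated, pre-
    pasteurization) sample; an OTU absent there has baseline 0.  The heated
    value is the maximum over all later timepoints.  Verdict:
    ``baseline < baseline_max_fraction AND max_heated > enriched_min_fraction``,
    both strict.
    """
    by_sample = {r.sample_id: r for r in meta}
    missing = [s for s in rel.sample_ids if s not in by_sample]
    if missing:
        raise TableFormatError(f"samples missing from metadata: {missing}")
    used = [by_sample[s] for s in rel.sample_ids]
    stations = sorted({r.station_id for r in used})
    classes = {r.station_id: r.station_class for r in used}

    baseline_col: dict[str, str] = {}
    heated_cols: dict[str, list[str]] = {}
    for st in stations:
        zero = [r.sample_id for r in used if r.station_id == st and r.time_h == 0]
        heated = [r.sample_id for r in used if r.station_id == st and r.time_h > 0]
        if len(zero) != 1:
            raise TableFormatError(
                f"station {st} needs exactly one 0 h sample, found {len(zero)}"
            )
        if not heated:
            raise TableFormatError(f"station {st} has no heated samples")
        baseline_col[st] = zero[0]
        heated_cols[st] = heated

    times = {r.sample_id: r.time_h for r in used}
    cells: dict[tuple[str, str], EnrichmentCell] = {}
    for st in stations:
        base = rel.fractions[baseline_col[st]]
        heated = rel.fractions[heated_cols[st]]
        max_frac = heated.max(axis=1)
        tmax = heated.idxmax(axis=1).map(times)
        for otu in rel.otu_ids:
            b = float(base[otu])
            m = float(max_frac[otu])
            verdict = (
                Verdict.ENRICHED
                if b < thr.baseline_max_fraction and m > thr.enriched_min_fraction
                else Verdict.NOT_ENRICHED
            )
            cells[(otu, st)] = EnrichmentCell(verdict, b, m, float(tmax[otu]))
    return EnrichmentMatrix(cells, list(rel.otu_ids), stations, classes, thr)


def enriched_otus(matrix: EnrichmentMatrix) -> list[str]:
    """OTUs enriched at one or more stations, sorted by id."""
    return sorted(
        otu for otu in matrix.otu_ids if any(
            matrix.is_enriched(otu, st) for st in matrix.station_ids
        )
    )
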