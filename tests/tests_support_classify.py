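"""Shared helper: build an EnrichmentMatrix from marginal enrichment counts."""

from sporetrace.enrichment import (
    EnrichmentCell,
    EnrichmentMatrix,
    Thresholds,
    Verdict,
)
from sporetrace.tables_io import StationClass

STATIONS = {
    "A": StationClass.NON_TIDAL,
    "B": StationClass.TIDAL,
    "C": StationClass.TIDAL,
    "D": StationClass.TIDAL,
    "E": StationClass.TIDAL,
    "F": StationClass.MARINE,
}


def matrix_from_marginals(
    n_non_tidal: int,
    n_non_tidal_marine: int,
    n_tidal_only: int,
    n_tidal_marine: int,
) -> EnrichmentMatrix:
    """Presence/absence table matching per-class marginal counts.

    ``n_non_tidal`` OTUs are enriched at the non-tidal station (the first
    ``n_non_tidal_marine`` of them also at the marine station);
    ``n_tidal_only`` further OTUs are enriched only in tidal stations (the
    first ``n_tidal_marine`` of them also at the marine station).
    """
    patterns: dict[str, set[str]] = {}
    for i in range(n_non_tidal):
        stations = {"A"}
        if i < n_non_tidal_marine:
            stations.add("F")
        patterns[f"upstream{i:02d}"] = stations
    for i in range(n_tidal_only):
        stations = {"B", "E"}
        if i < n_tidal_marine:
            stations.add("F")
        patterns[f"tidal{i:02d}"] = stations

    cells = {}
    for otu, hit_stations in patterns.items():
        for st in STATIONS:
            hit = st in hit_stations
            cells[(otu, st)] = EnrichmentCell(
                Verdict.ENRICHED if hit else Verdict.NOT_ENRICHED,
                0.0,
                0.05 if hit else 0.0,
                24.0,
            )
    return EnrichmentMatrix(
        cells, sorted(patterns), sorted(STATIONS), dict(STATIONS), Thresholds()
    )
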