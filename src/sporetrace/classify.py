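"""Dispersal-history classification from spatial enrichment patterns.

Enrichment at the non-tidal station (upstream of the tidal limit) indicates
a terrestrial source; enrichment at the marine station indicates a marine
source; both together mark a cosmopolitan taxon able to grow under brackish
and marine conditions.  Station classes generalize the original single
non-tidal / single marine station design: flags are OR-ed within a class.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

from .enrichment import EnrichmentMatrix
from .tables_io import StationClass

__all__ = ["SourceLabel", "SourceAssignment", "classify_source", "summarize", "Summary"]


class SourceLabel(str, enum.Enum):
    TERRESTRIAL = "terrestrial"
    MARINE = "marine"
    COSMOPOLITAN = "cosmopolitan"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class SourceAssignment:
    otu_id: str
    label: SourceLabel
    enriched_non_tidal: bool
    enriched_tidal: bool
    enriched_marine: bool


def label_from_flags(non_tidal: bool, tidal: bool, marine: bool) -> SourceLabel:
    """Pure labelling rule over the three class-level evidence flags.

    cosmopolitan: enriched both upstream of the tidal limit and at sea;
    marine: enriched at sea but not upstream of the tidal limit;
    terrestrial: enriched somewhere in the estuary but not at sea;
    unclassified: enriched nowhere.
    """
    if non_tidal and marine:
        return SourceLabel.COSMOPOLITAN
    if marine:
        return SourceLabel.MARINE
    if non_tidal or tidal:
        return SourceLabel.TERRESTRIAL
    return SourceLabel.UNCLASSIFIED


def classify_source(
    matrix: EnrichmentMatrix,
    station_classes: Mapping[str, StationClass] | None = None,
) -> list[SourceAssignment]:
    """Assign one dispersal-history label to every OTU in the matrix.

    Requires a marine station: without the at-sea germination test the
    terrestrial/marine distinction is undefined.
    """
    classes = dict(station_classes or matrix.station_classes)
    present = {classes[st] for st in matrix.station_ids}
    if StationClass.MARINE not in present:
        raise ValueError("classification requires at least one marine station")

    out = []
    for otu in matrix.otu_ids:
        flags = {cls: False for cls in StationClass}
        for st in matrix.station_ids:
            if matrix.is_enriched(otu, st):
                flags[classes[st]] = True
        label = label_from_flags(
            flags[StationClass.NON_TIDAL],
            flags[StationClass.TIDAL],
            flags[StationClass.MARINE],
        )
        out.append(
            SourceAssignment(
                otu_id=otu,
                label=label,
                enriched_non_tidal=flags[StationClass.NON_TIDAL],
                enriched_tidal=flags[StationClass.TIDAL],
                enriched_marine=flags[StationClass.MARINE],
            )
        )
    return out


@dataclass(frozen=True)
class Summary:
    counts: dict[str, int]
    percentages: dict[str, int]
    terrestrial_derived_percent: int
    n_enriched: int


def summarize(assignments: Sequence[SourceAssignment]) -> Summary:
    """Counts and integer percentages per label over the enriched OTUs.

    The terrestrial-derived share pools terrestrial and cosmopolitan labels
    (both point to a land source) over all enriched OTUs.
    """
    if not assignments:
        raise ValueError("no assignments to summarize")
    enriched = [a for a in assignments if a.label is not SourceLabel.UNCLASSIFIED]
    n = len(enriched)
    counts = {
        lab.value: sum(1 for a in enriched if a.label is lab)
        for lab in (SourceLabel.TERRESTRIAL, SourceLabel.MARINE, SourceLabel.COSMOPOLITAN)
    }
    percentages = {k: round(100 * v / n) for k, v in counts.items()} if n else {}
    terr = counts["terrestrial"] + counts["cosmopolitan"]
    return Summary(
        counts=counts,
        percentages=percentages,
        terrestrial_derived_percent=round(100 * terr / n) if n else 0,
        n_enriched=n,
    )
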