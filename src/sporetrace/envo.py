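"""Environment-ontology term profiles from hit annotations.

Each OTU's closest database relatives carry Environment Ontology (EnvO)
term labels.  A profile is the frequency distribution of term occurrences
across the OTU's retained hits (identity at or above the cutoff, at least
one term).  Profiles sum to 100%; an OTU with no qualifying hits has no
profile at all rather than a zero-filled one.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .enrichment import EnrichmentMatrix
from .tables_io import TableFormatError

__all__ = [
    "HitAnnotation",
    "EnvoProfile",
    "read_hit_annotations",
    "build_profile",
    "build_profiles",
    "prevalence_filter",
    "heatmap_matrix",
    "DEFAULT_MIN_IDENTITY",
]

# Surface the identity cutoff rather than hiding it in the retrieval tool's
# defaults; 97% matches the OTU clustering radius.
DEFAULT_MIN_IDENTITY = 97.0


@dataclass(frozen=True)
class HitAnnotation:
    """One database hit for one OTU: identity and its ontology terms."""

    otu_id: str
    hit_id: str
    percent_identity: float
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 0 <= self.percent_identity <= 100:
            raise ValueError(
                f"percent_identity {self.percent_identity} outside [0, 100]"
            )


@dataclass(frozen=True)
class EnvoProfile:
    """Term -> frequency percent for one OTU; frequencies sum to 100."""

    otu_id: str
    frequencies: tuple[tuple[str, float], ...]

    def as_dict(self) -> dict[str, float]:
        return dict(self.frequencies)

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.frequencies)
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"profile frequencies sum to {total}, not 100")


def read_hit_annotations(path: str | Path) -> list[HitAnnotation]:
    """Read a hit table TSV (otu_id, hit_id, percent_identity, semicolon-joined terms)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"otu_id", "hit_id", "percent_identity", "terms"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"hit table missing column(s): {sorted(missing)}")
    hits = []
    for row in df.itertuples(index=False):
        terms_raw = "" if pd.isna(row.terms) else str(row.terms)
        terms = tuple(t.strip() for t in terms_raw.split(";") if t.strip())
        hits.append(
            HitAnnotation(
                otu_id=str(row.otu_id).strip(),
                hit_id=str(row.hit_id).strip(),
                percent_identity=float(row.percent_identity),
                terms=terms,
            )
        )
    return hits


def build_profile(
    hits: Iterable[HitAnnotation], min_identity: float = DEFAULT_MIN_IDENTITY
) -> EnvoProfile | None:
    """Term-occurrence frequency profile for one OTU, or None.

    Hits below ``min_identity`` or without terms are dropped; each retained
    hit contributes each of its terms once (multi-term hits are
    term-occurrence weighted; single-term hits reduce to hit-fraction
    weighting).  With nothing retained the profile is absent.
    """
    hits = list(hits)
    otus = {h.otu_id for h in hits}
    if len(otus) > 1:
        raise ValueError(f"hits span multiple OTUs: {sorted(otus)}")
    retained = [h for h in hits if h.percent_identity >= min_identity and h.terms]
    if not retained:
        return None
    tally: Counter[str] = Counter()
    for h in retained:
        tally.update(h.terms)
    total = sum(tally.values())
    freqs = tuple(
        (term, 100.0 * count / total)
        for term, count in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    return EnvoProfile(otu_id=next(iter(otus)), frequencies=freqs)


def build_profiles(
    hits: Iterable[HitAnnotation], min_identity: float = DEFAULT_MIN_IDENTITY
) -> dict[str, EnvoProfile]:
    """Profiles for every OTU with qualifying hits, keyed by OTU id."""
    by_otu: dict[str, list[HitAnnotation]] = {}
    for h in hits:
        by_otu.setdefault(h.otu_id, []).append(h)
    out = {}
    for otu in sorted(by_otu):
        profile = build_profile(by_otu[otu], min_identity)
        if profile is not None:
            out[otu] = profile
    return out


def prevalence_filter(
    profiles: Mapping[str, EnvoProfile],
    enrichment: EnrichmentMatrix,
    min_stations: int = 2,
) -> dict[str, EnvoProfile]:
    """Keep only profiles of OTUs enriched in at least ``min_stations`` libraries."""
    missing = sorted(set(profiles) - set(enrichment.otu_ids))
    if missing:
        raise ValueError(f"no enrichment data for profiled OTUs: {missing}")
    return {
        otu: prof
        for otu, prof in profiles.items()
        if len(enrichment.enriched_stations(otu)) >= min_stations
    }


def heatmap_matrix(profiles: Mapping[str, EnvoProfile] | Sequence[EnvoProfile]) -> pd.DataFrame:
    """Dense term x OTU percent matrix for heatmap plotting.

    Zero-filled where a term is absent from an OTU's profile; term rows are
    ordered by total frequency descending, ties broken lexicographically.
    Column sums are 100 for every profiled OTU.
    """
    if not isinstance(profiles, Mapping):
        profiles = {p.otu_id: p for p in profiles}
    if not profiles:
        raise ValueError("need at least one profile")
    df = pd.DataFrame(
        {otu: pd.Series(prof.as_dict()) for otu, prof in sorted(profiles.items())}
    ).fillna(0.0)
    totals = df.sum(axis=1)
    order = sorted(df.index, key=lambda t: (-totals[t], t))
    return df.loc[order]
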