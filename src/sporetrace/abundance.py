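"""Rarefaction and relative abundance.

Libraries are rarefied to the size of the smallest library by subsampling
reads without replacement (multivariate hypergeometric draw per sample), and
relative abundances for all downstream rules are computed on the rarefied
table.  When an OTU of interest is absent from a rarefied library, the raw
library is consulted to confirm the absence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import stream
from .tables_io import CountTable, TableFormatError

__all__ = [
    "RelAbundTable",
    "choose_rarefaction_depth",
    "rarefy",
    "relative_abundance",
    "AbsenceCheck",
    "confirm_absent",
]


@dataclass
class RelAbundTable:
    """Per-sample read fractions; every sample column sums to 1."""

    fractions: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.fractions.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = list(sums[~np.isclose(sums, 1.0, atol=1e-9)].index)
            raise TableFormatError(f"sample fractions do not sum to 1: {bad}")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fractions.columns)


def choose_rarefaction_depth(table: CountTable) -> int:
    """Depth of the smallest library (the rarefaction target)."""
    sizes = table.library_sizes()
    if len(sizes) == 0:
        raise TableFormatError("empty count table")
    empty = list(sizes[sizes == 0].index)
    if empty:
        raise TableFormatError(f"empty sample(s): {empty}")
    return int(sizes.min())


def rarefy(table: CountTable, depth: int | None = None, seed: int = 0) -> CountTable:
    """Subsample every library to ``depth`` reads without replacement.

    Each sample is drawn from its own RNG stream derived from
    ``(seed, sample_id)``, so results are reproducible per sample and
    independent of column order.
    """
    if depth is None:
        depth = choose_rarefaction_depth(table)
    depth = int(depth)
    if depth <= 0:
        raise TableFormatError("rarefaction depth must be positive")
    sizes = table.library_sizes()
    too_small = list(sizes[sizes < depth].index)
    if too_small:
        raise TableFormatError(
            f"library smaller than depth {depth}: {too_small}"
        )
    out = {}
    for sample in table.sample_ids:
        col = table.counts[sample].to_numpy()
        if col.sum() == depth:
            out[sample] = col
        else:
            rng = stream(seed, "rarefy", sample)
            out[sample] = rng.multivariate_hypergeometric(col, depth)
    df = pd.DataFrame(out, index=table.counts.index, columns=table.sample_ids)
    return CountTable(df, rarefied_depth=depth)


def relative_abundance(table: CountTable) -> RelAbundTable:
    """Count / library size, per sample."""
    sizes = table.library_sizes()
    empty = list(sizes[sizes == 0].index)
    if empty:
        raise TableFormatError(f"empty sample(s): {empty}")
    return RelAbundTable(table.counts / sizes)


class AbsenceCheck(str, enum.Enum):
    ABSENT_CONFIRMED = "absent_confirmed"
    PRESENT_UNRAREFIED = "present_unrarefied"


def confirm_absent(
    raw: CountTable, rarefied: CountTable, otu: str, sample: str
) -> tuple[AbsenceCheck, int]:
    """Check the raw library when an OTU is absent from a rarefied one.

    Returns ``(ABSENT_CONFIRMED, 0)`` if the raw count is also zero,
    otherwise ``(PRESENT_UNRAREFIED, raw_count)`` — the OTU was present but
    lost to subsampling.
    """
    if rarefied[otu, sample] != 0:
        raise ValueError(
            f"confirm_absent called for OTU {otu!r} with nonzero rarefied count "
            f"in sample {sample!r}"
        )
    raw_count = raw[otu, sample]
    if raw_count == 0:
        return (AbsenceCheck.ABSENT_CONFIRMED, 0)
    return (AbsenceCheck.PRESENT_UNRAREFIED, raw_count)
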