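"""Per-library abundance profiles and categorical labels.

Amplicon read counts from a mixed eDNA template are not quantitative, so
per-taxon abundance is reported categorically: high when a taxon holds more
than 30% of the library's Hemiptera-assigned reads, medium from 5 to 30%
(closed interval), low below 5%.  The denominator is the number of
Hemiptera-assigned reads — not all sequenced reads — since host (honey-bee)
background dominates raw libraries; host and unassigned reads are carried
alongside each profile but never enter the fractions.  The all-sequenced
denominator is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from honeytrace.taxonomic_assignment import ReadAssignment

import logging

log = logging.getLogger(__name__)


def categorize(fraction: float) -> str:
    """Categorical abundance label for a read fraction.

    high <=> fraction > 0.30; medium <=> 0.05 <= fraction <= 0.30;
    low <=> fraction < 0.05.  Both boundaries belong to medium.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    if fraction > 0.30:
        return "high"
    if fraction >= 0.05:
        return "medium"
    return "low"


@dataclass(frozen=True)
class ProfileRow:
    taxon: str  # display name: species, "Genus sp." or "Family spp."
    rank: str
    count: int
    fraction: float
    category: str


@dataclass
class LibraryProfile:
    library_id: str
    rows: list[ProfileRow] = field(default_factory=list)
    denominator: int = 0  # Hemiptera-assigned reads
    n_host: int = 0
    n_unassigned: int = 0

    def fraction_of(self, taxon: str) -> float:
        for row in self.rows:
            if row.taxon == taxon:
                return row.fraction
        raise KeyError(taxon)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "library": self.library_id,
                    "taxon": r.taxon,
                    "rank": r.rank,
                    "count": r.count,
                    "fraction": r.fraction,
                    "category": r.category,
                }
                for r in self.rows
            ]
        )


def _make_profile(
    library_id: str,
    counts: dict[tuple[str, str], int],
    n_host: int,
    n_unassigned: int,
    denominator_mode: str = "hemiptera",
) -> LibraryProfile:
    total_assigned = sum(counts.values())
    if denominator_mode == "hemiptera":
        denom = total_assigned
    elif denominator_mode == "all":
        denom = total_assigned + n_host + n_unassigned
    else:
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    profile = LibraryProfile(library_id, [], total_assigned, n_host, n_unassigned)
    if denom == 0:
        log.warning("library %s has no assigned reads; empty profile", library_id)
        return profile
    rows = [
        ProfileRow(taxon, rank, c, c / denom, categorize(c / denom))
        for (taxon, rank), c in counts.items()
    ]
    rows.sort(key=lambda r: (-r.count, r.taxon))
    profile.rows = rows
    return profile


def profile_library(
    assignments: Iterable[ReadAssignment],
    library_id: str,
    denominator_mode: str = "hemiptera",
) -> LibraryProfile:
    """Aggregate per-read assignments into one library profile.

    Counts are grouped by (taxon display name, rank) over species- and
    higher-rank assignments; host and unassigned reads are tallied
    separately.
    """
    counts: dict[tuple[str, str], int] = {}
    n_host = n_unassigned = 0
    for a in assignments:
        if a.status == "host":
            n_host += 1
        elif a.status == "unassigned":
            n_unassigned += 1
        else:
            name = a.lineage.display_name(a.rank)
            counts[(name, a.rank)] = counts.get((name, a.rank), 0) + 1
    return _make_profile(library_id, counts, n_host, n_unassigned, denominator_mode)


class CountTableError(ValueError):
    """A malformed row in a per-species count table."""


def _infer_rank(taxon: str) -> str:
    if taxon.endswith(" spp."):
        return "family"
    if taxon.endswith(" sp."):
        return "genus"
    return "species"


def load_count_table(
    source: str | Path | pd.DataFrame, denominator_mode: str = "hemiptera"
) -> dict[str, LibraryProfile]:
    """Build profiles directly from a (library, taxon, count) TSV.

    Equivalent to :func:`profile_library` fed one synthetic assignment per
    counted read — this lets a published per-species count table drive the
    summary stage without any sequencing data.  Rank is inferred from the
    taxon name (" sp." -> genus, " spp." -> family).
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", comment="#", dtype=str)
    required = {"library", "taxon", "count"}
    if not required.issubset(df.columns):
        raise CountTableError(f"count table needs columns {sorted(required)}")
    profiles: dict[str, LibraryProfile] = {}
    for lib, group in df.groupby("library", sort=False):
        counts: dict[tuple[str, str], int] = {}
        for idx, row in group.iterrows():
            try:
                c = int(row["count"])
            except (TypeError, ValueError):
                raise CountTableError(
                    f"line {idx + 2}: count {row['count']!r} is not an integer"
                ) from None
            if c < 0:
                raise CountTableError(f"line {idx + 2}: negative count")
            taxon = str(row["taxon"]).strip()
            if not taxon:
                raise CountTableError(f"line {idx + 2}: empty taxon")
            key = (taxon, _infer_rank(taxon))
            counts[key] = counts.get(key, 0) + c
        profiles[str(lib)] = _make_profile(str(lib), counts, 0, 0, denominator_mode)
    return profiles


def write_profiles_tsv(profiles: Iterable[LibraryProfile], path: str | Path) -> None:
    frames = [p.to_frame() for p in profiles if p.rows]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["library", "taxon", "rank", "count", "fraction", "category"]
    )
    df.to_csv(path, sep="\t", index=False)
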