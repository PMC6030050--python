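"""Within-species mitotype calling with a reliability filter.

Reads assigned to one species are aligned to that species' amplicon insert
and collapsed by exact sequence into candidate mitotypes.  Sequencing error
(substitutions and, on Ion Torrent, above all homopolymer indels) scatters
reads into spurious singleton candidates, so a candidate is only considered
a *reliable* mitotype if it is backed by at least 20 distinct reads and is
either already known from public database entries or carries at least 5% of
the species' reads.  Known status is an exact match to a published
haplotype projected onto the amplicon region; one short-region class may
group several long-region haplotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from honeytrace.alignment import align_semi_global
from honeytrace.community_summary import LibraryProfile
from honeytrace.read_qc import Read
from honeytrace.reference_db import HaplotypeClass, revcomp

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MitotypeParams:
    min_reads: int = 20
    min_fraction: float = 0.05
    require_full_span: bool = True
    min_species_reads: int = 10
    # "lenient" switches the ambiguous reliability parse to
    # (count >= min_reads AND known) OR fraction >= min_fraction
    rule: str = "strict"

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if not 0.0 < self.min_fraction < 1.0:
            raise ValueError("min_fraction must be in (0, 1)")
        if self.rule not in ("strict", "lenient"):
            raise ValueError("rule must be 'strict' or 'lenient'")


@dataclass
class MitotypeCall:
    species: str
    sequence: str  # insert-region sequence
    count: int
    fraction: float  # of the species' mitotypable reads
    known_ids: tuple[str, ...] = ()
    is_known: bool = False
    is_reliable: bool = False
    n_db_entries: int = 0


@dataclass
class MitotypeTable:
    calls: list[MitotypeCall] = field(default_factory=list)
    species_total: int = 0
    n_unplaced_reads: int = 0

    @property
    def reliable(self) -> list[MitotypeCall]:
        return [c for c in self.calls if c.is_reliable]


@dataclass
class CollapseResult:
    candidates: list[tuple[str, int]]  # (insert sequence, count), count desc
    n_unplaced: int
    n_reads: int


def collapse_reads(
    reads_of_species: Iterable[Read],
    species_amplicon: str,
    params: MitotypeParams | None = None,
    band: int = 16,
) -> CollapseResult:
    """Collapse one species' reads into exact-sequence candidates.

    Each read is aligned to the species' insert on both strands; the
    better-scoring orientation wins.  A read is *unplaced* when its
    alignment contains an indel (the dominant Ion Torrent error mode; real
    mitotypes here differ by substitutions only) or, when
    ``require_full_span`` is set, does not cover the whole insert.  The
    candidate key is the read's aligned sequence over the insert.
    """
    params = params or MitotypeParams()
    counts: dict[str, int] = {}
    n_unplaced = 0
    n_reads = 0
    tlen = len(species_amplicon)
    for read in reads_of_species:
        n_reads += 1
        key = None
        for q in (read.bases, revcomp(read.bases)):
            if q == species_amplicon:
                key = q
                break
        if key is None:
            best = None
            for q in (read.bases, revcomp(read.bases)):
                if not q:
                    continue
                res = align_semi_global(q, species_amplicon, band=band)
                if best is None or res.score > best[0].score:
                    best = (res, q)
            if best is None:
                n_unplaced += 1
                continue
            res, q = best
            full_span = res.t_start == 0 and res.t_end == tlen
            if res.n_gap_columns > 0 or (params.require_full_span and not full_span):
                n_unplaced += 1
                continue
            key = q[res.q_start : res.q_end]
            if len(key) != res.t_end - res.t_start:
                n_unplaced += 1  # defensive: gapless core must be colinear
                continue
        counts[key] = counts.get(key, 0) + 1
    candidates = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return CollapseResult(candidates, n_unplaced, n_reads)


def call_mitotypes(
    collapsed: CollapseResult | Sequence[tuple[str, int]],
    known_classes: Sequence[HaplotypeClass],
    species: str,
    params: MitotypeParams | None = None,
) -> MitotypeTable:
    """Apply the reliability filter and known-haplotype matching.

    Under the default ("strict") rule a candidate is reliable iff
    ``count >= min_reads`` and (known or ``fraction >= min_fraction``): the
    20-read floor is the sequencing-error guard and always applies.
    Unreliable candidates stay in the table, flagged.  Fractions are over
    mitotypable (placed) reads.
    """
    params = params or MitotypeParams()
    if isinstance(collapsed, CollapseResult):
        candidates = collapsed.candidates
        n_unplaced = collapsed.n_unplaced
        species_total = collapsed.n_reads
    else:
        candidates = list(collapsed)
        n_unplaced = 0
        species_total = sum(c for _, c in candidates)
    by_seq = {cls.class_sequence: cls for cls in known_classes}
    total = sum(c for _, c in candidates)
    table = MitotypeTable([], species_total, n_unplaced)
    if total == 0:
        return table
    for seq, count in candidates:
        cls = by_seq.get(seq)
        fraction = count / total
        is_known = cls is not None
        if params.rule == "strict":
            reliable = count >= params.min_reads and (
                is_known or fraction >= params.min_fraction
            )
        else:
            reliable = (count >= params.min_reads and is_known) or (
                fraction >= params.min_fraction
            )
        table.calls.append(
            MitotypeCall(
                species=species,
                sequence=seq,
                count=count,
                fraction=fraction,
                known_ids=cls.member_haplotype_ids if cls else (),
                is_known=is_known,
                is_reliable=reliable,
                n_db_entries=cls.total_n_db_entries if cls else 0,
            )
        )
    table.calls.sort(key=lambda c: (-c.count, c.sequence))
    return table


def mitotype_frequencies(table: MitotypeTable) -> list[tuple[MitotypeCall, float]]:
    """Frequencies over reliable calls only, renormalized, sorted descending."""
    if not table.calls:
        raise ValueError("empty mitotype table")
    reliable = table.reliable
    total = sum(c.count for c in reliable)
    if total == 0:
        log.warning("no reliable mitotype calls")
        return []
    return [(c, c.count / total) for c in reliable]


def eligible_species(
    profiles: Iterable[LibraryProfile], params: MitotypeParams | None = None
) -> list[str]:
    """Species worth mitotype analysis across a set of libraries.

    The species with the highest overall read total is always eligible;
    so is any species with at least ``min_species_reads`` reads in at least
    two libraries.  Returned sorted by overall total, descending.
    """
    params = params or MitotypeParams()
    totals: dict[str, int] = {}
    n_libs_over: dict[str, int] = {}
    for profile in profiles:
        for row in profile.rows:
            if row.rank != "species":
                continue
            totals[row.taxon] = totals.get(row.taxon, 0) + row.count
            if row.count >= params.min_species_reads:
                n_libs_over[row.taxon] = n_libs_over.get(row.taxon, 0) + 1
    if not totals:
        return []
    top = max(totals, key=lambda sp: (totals[sp], sp))
    chosen = {top} | {sp for sp, n in n_libs_over.items() if n >= 2}
    return sorted(chosen, key=lambda sp: (-totals[sp], sp))
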