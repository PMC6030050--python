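"""Per-read taxonomic assignment under identity/coverage thresholds.

Each retained read is aligned against candidate reference amplicons
(gathered through shared k-mers on both strands) and assigned the taxon of
its best hit, provided that hit reaches >= 97% identity with 95-100% query
coverage.  When two or more species tie at the top score, the read is
assigned to the lowest common ancestor rank shared by the tied lineages
(genus, else family, else unassigned) — this is how a survey ends up
reporting rows like "Cinara sp." or "Aphididae spp.".  Reads whose best hit
is the honey-bee record are counted as host background rather than left
unmatched, mirroring total-minus-Hemiptera host accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from honeytrace.alignment import AlignmentResult, align_semi_global
from honeytrace.read_qc import Read
from honeytrace.reference_db import ReferenceDatabase, TaxonLineage, revcomp


@dataclass(frozen=True)
class AssignmentParams:
    min_identity: float = 0.97
    min_coverage: float = 0.95
    tie_margin: int = 0
    seed_k: int = 11
    band: int = 16

    def __post_init__(self) -> None:
        for t in (self.min_identity, self.min_coverage):
            if not 0.0 < t <= 1.0:
                raise ValueError("thresholds must be in (0, 1]")


@dataclass
class ReadAssignment:
    read_id: str
    status: str  # assigned_species | assigned_higher_rank | host | unassigned
    lineage: TaxonLineage | None = None
    rank: str = "none"  # species | genus | family | none
    best: AlignmentResult | None = None
    note: str = ""


def _candidates(db: ReferenceDatabase, query: str, k: int) -> set[str]:
    accs: set[str] = set()
    for off in range(len(query) - k + 1):
        postings = db.kmer_index.get(query[off : off + k])
        if postings:
            accs.update(acc for acc, _ in postings)
    return accs


def _align_query(query: str, target: str, band: int) -> AlignmentResult:
    # exact-substring shortcut: a perfect read needs no DP
    if "N" not in query and query in target:
        return AlignmentResult(
            score=len(query), identity=1.0, coverage=1.0, matches=len(query),
            columns=len(query), q_start=0, q_end=len(query),
            t_start=target.index(query), t_end=target.index(query) + len(query),
            n_gap_columns=0,
        )
    return align_semi_global(query, target, band=band)


def assign_read(
    read: Read, db: ReferenceDatabase, params: AssignmentParams | None = None
) -> ReadAssignment:
    """Assign one read.

    Candidates are gathered per strand via shared ``seed_k``-mers (falling
    back to all accessions when no seed matches at all); every candidate is
    aligned, hits failing either threshold are discarded, and the max-score
    passing hit wins.  Species ties within ``tie_margin`` are resolved by
    the deepest shared rank.
    """
    params = params or AssignmentParams()
    query_fwd = read.bases
    if not query_fwd:
        return ReadAssignment(read.read_id, "unassigned")
    query_rev = revcomp(query_fwd)
    per_strand = {"+": query_fwd, "-": query_rev}

    jobs: list[tuple[str, str]] = []  # (accession, strand)
    for strand, q in per_strand.items():
        for acc in _candidates(db, q, params.seed_k):
            jobs.append((acc, strand))
    if not jobs:
        jobs = [(acc, s) for acc in db.amplicons for s in ("+", "-")]

    passing: list[AlignmentResult] = []
    for acc, strand in jobs:
        target = db.amplicons[acc].with_primers_sequence
        res = _align_query(per_strand[strand], target, params.band)
        if res.identity >= params.min_identity and res.coverage >= params.min_coverage:
            res.accession = acc
            res.strand = strand
            passing.append(res)
    if not passing:
        return ReadAssignment(read.read_id, "unassigned")

    best_score = max(r.score for r in passing)
    tied = [r for r in passing if r.score >= best_score - params.tie_margin]
    # one representative per accession, then the deterministic best first
    by_acc: dict[str, AlignmentResult] = {}
    for r in sorted(tied, key=lambda r: (-r.score, -r.identity, r.accession, r.strand)):
        by_acc.setdefault(r.accession, r)
    tied = list(by_acc.values())
    best = tied[0]

    lineages = [db.lineage(r.accession) for r in tied]
    if any(l.is_host for l in lineages):
        # honey-bee background wins ties conservatively: an ambiguous
        # host/Hemiptera read must not inflate the Hemiptera profile
        host_best = next(r for r, l in zip(tied, lineages) if l.is_host)
        return ReadAssignment(read.read_id, "host", db.lineage(host_best.accession),
                              "species", host_best)

    species = {l.species for l in lineages}
    if len(species) == 1:
        return ReadAssignment(read.read_id, "assigned_species", lineages[0], "species", best)
    genera = {l.genus for l in lineages}
    if len(genera) == 1 and lineages[0].genus:
        lca = TaxonLineage(species="", genus=lineages[0].genus, family=lineages[0].family,
                           suborder=lineages[0].suborder, order=lineages[0].order)
        return ReadAssignment(read.read_id, "assigned_higher_rank", lca, "genus", best,
                              note=f"species tie: {sorted(species)}")
    families = {l.family for l in lineages}
    if len(families) == 1 and lineages[0].family:
        lca = TaxonLineage(species="", genus="", family=lineages[0].family,
                           suborder=lineages[0].suborder, order=lineages[0].order)
        return ReadAssignment(read.read_id, "assigned_higher_rank", lca, "family", best,
                              note=f"species tie: {sorted(species)}")
    return ReadAssignment(read.read_id, "unassigned",
                          note=f"unresolvable tie: {sorted(species)}")


def assign_batch(
    batch: Iterable[Read], db: ReferenceDatabase, params: AssignmentParams | None = None
) -> tuple[list[ReadAssignment], dict[str, int]]:
    """Assign a batch, order-preserving; the summary counts partition it."""
    params = params or AssignmentParams()
    assignments = [assign_read(r, db, params) for r in batch]
    summary = {
        "n_host": sum(a.status == "host" for a in assignments),
        "n_hemiptera": sum(
            a.status in ("assigned_species", "assigned_higher_rank") for a in assignments
        ),
        "n_unassigned": sum(a.status == "unassigned" for a in assignments),
    }
    return assignments, summary
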