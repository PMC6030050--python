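"""Taxonomy-annotated COI reference set and in-silico PCR.

The reference side of the pipeline: parse COI records whose FASTA headers
carry a pipe-delimited lineage, locate degenerate-primer binding sites by
IUPAC-aware Hamming matching, cut out the amplified region per record, and
index the amplicons for read assignment.  Known full-length haplotypes of a
species can be projected onto the (shorter) amplicon region, which may
collapse several long-region haplotypes into one amplicon-region mitotype
class.

Coordinates are 0-based half-open on the stored (+) sequence; the strand of
the amplified product is recorded explicitly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

# IUPAC degenerate nucleotide codes -> the set of plain bases each matches.
IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class InvalidAlphabetError(ValueError):
    """A symbol outside the IUPAC nucleotide alphabet was encountered."""


class EmptyDatabaseError(ValueError):
    """No reference record yielded a valid amplicon."""


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(pattern_base: str, base: str) -> bool:
    """True iff ``base`` lies in the IUPAC expansion of ``pattern_base``.

    ``N`` in the subject matches nothing (it counts as a mismatch): an
    undetermined reference base gives no evidence of a primer site.
    """
    try:
        expansion = IUPAC[pattern_base]
    except KeyError:
        raise InvalidAlphabetError(f"not an IUPAC code: {pattern_base!r}") from None
    if base == "N":
        return False
    if base not in "ACGT":
        raise InvalidAlphabetError(f"subject base must be A/C/G/T/N, got {base!r}")
    return base in expansion


@dataclass(frozen=True)
class TaxonLineage:
    """Taxonomic annotation of a reference record.

    ``species`` may be empty when the record is annotated at a higher rank
    only (then ``genus`` or ``family`` must be set).  ``is_host`` marks the
    honey-bee off-target lineage whose reads are accounted for but excluded
    from Hemiptera profiles.
    """

    species: str
    genus: str = ""
    family: str = ""
    suborder: str = ""
    order: str = "Hemiptera"
    is_host: bool = False

    def __post_init__(self) -> None:
        if not self.order:
            raise ValueError("order must be non-empty")
        if not (self.species or self.genus or self.family):
            raise ValueError("lineage needs species, genus or family")

    def display_name(self, rank: str = "species") -> str:
        if rank == "species":
            return self.species
        if rank == "genus":
            return f"{self.genus} sp."
        if rank == "family":
            return f"{self.family} spp."
        raise ValueError(f"unknown rank {rank!r}")


@dataclass(frozen=True)
class ReferenceRecord:
    accession: str
    lineage: TaxonLineage
    sequence: str


@dataclass(frozen=True)
class PrimerPair:
    """Degenerate primer pair, both written 5'->3' (reverse on the antisense
    strand, the usual bench convention)."""

    forward: str = "TGGAWCAGGAACAGGATGAAC"
    reverse: str = "AAATGAARTTGATTGCTCCTA"
    max_mismatches: int = 2
    min_amplicon_len: int = 100
    max_amplicon_len: int = 200

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise ValueError("primers must be non-empty")
        if self.min_amplicon_len > self.max_amplicon_len:
            raise ValueError("min_amplicon_len > max_amplicon_len")
        for p in (self.forward, self.reverse):
            for b in p:
                if b not in IUPAC:
                    raise InvalidAlphabetError(f"non-IUPAC primer base {b!r}")


@dataclass(frozen=True)
class AmpliconExtract:
    """One in-silico PCR product.

    ``start``/``end`` are on the stored (+) sequence; ``insert_sequence`` and
    ``with_primers_sequence`` are written in amplified (product) orientation.
    """

    accession: str
    start: int
    end: int
    insert_sequence: str
    with_primers_sequence: str
    strand: str  # "+" or "-"


def _mismatches(window: str, primer: str, budget: int) -> int:
    """IUPAC-aware Hamming distance, early-exiting past ``budget``."""
    n = 0
    for pb, b in zip(primer, window):
        if b == "N" or b not in IUPAC[pb]:
            n += 1
            if n > budget:
                return n
    return n


def find_primer_sites(
    sequence: str, primer: str, max_mismatches: int = 0
) -> list[tuple[int, int]]:
    """All windows where the primer binds within the mismatch budget.

    Hamming matching only (no indels): reference sequences are assumed
    high-quality, indel tolerance belongs to read alignment.  Returns
    ``(position, mismatches)`` sorted by position.
    """
    if not primer:
        raise ValueError("empty primer")
    hits = []
    plen = len(primer)
    for pos in range(len(sequence) - plen + 1):
        mm = _mismatches(sequence[pos : pos + plen], primer, max_mismatches)
        if mm <= max_mismatches:
            hits.append((pos, mm))
    return hits


def _extract_on_strand(
    seq: str, primers: PrimerPair
) -> tuple[int, int, str, str] | None:
    """Find the 5'-most valid product on one strand.

    Returns (start, end, with_primers, insert) in this strand's coordinates,
    or None.
    """
    fwd_sites = find_primer_sites(seq, primers.forward, primers.max_mismatches)
    if not fwd_sites:
        return None
    rev_rc = revcomp(primers.reverse)
    rev_sites = find_primer_sites(seq, rev_rc, primers.max_mismatches)
    if not rev_sites:
        return None
    flen, rlen = len(primers.forward), len(rev_rc)
    products = []
    for f, _ in fwd_sites:
        for r, _ in rev_sites:
            if r < f + flen:
                continue
            end = r + rlen
            span = end - f
            if primers.min_amplicon_len <= span <= primers.max_amplicon_len:
                products.append((f, end))
    if not products:
        return None
    if len(products) > 1:
        log.warning("multiple candidate products; keeping the 5'-most")
    f, end = min(products)
    with_primers = seq[f:end]
    insert = seq[f + flen : end - rlen]
    return f, end, with_primers, insert


def extract_amplicon(
    record: ReferenceRecord, primers: PrimerPair
) -> AmpliconExtract | None:
    """In-silico PCR of one record: search both strands, keep the 5'-most
    valid product on the strand that yields one ((+) strand preferred).

    Coordinates are always reported on the stored (+) sequence; product
    sequences are in amplified orientation.
    """
    hit = _extract_on_strand(record.sequence, primers)
    if hit is not None:
        start, end, wp, ins = hit
        return AmpliconExtract(record.accession, start, end, ins, wp, "+")
    rc = revcomp(record.sequence)
    hit = _extract_on_strand(rc, primers)
    if hit is not None:
        start_rc, end_rc, wp, ins = hit
        n = len(record.sequence)
        return AmpliconExtract(record.accession, n - end_rc, n - start_rc, ins, wp, "-")
    return None


@dataclass
class ReferenceDatabase:
    """Reference records plus their extracted amplicons and a k-mer index.

    The index maps each k-mer of the with-primers amplicon sequences to
    sorted postings ``(accession, offset)``; it is rebuilt deterministically
    from the amplicons, so serialization is byte-stable.
    """

    records: dict[str, ReferenceRecord]
    amplicons: dict[str, AmpliconExtract]
    k: int = 11
    excluded: list[tuple[str, str]] = field(default_factory=list)
    kmer_index: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.kmer_index:
            self.rebuild_index()

    def rebuild_index(self) -> None:
        index: dict[str, list[tuple[str, int]]] = {}
        for acc in sorted(self.amplicons):
            seq = self.amplicons[acc].with_primers_sequence
            for off in range(len(seq) - self.k + 1):
                index.setdefault(seq[off : off + self.k], []).append((acc, off))
        self.kmer_index = index

    def lineage(self, accession: str) -> TaxonLineage:
        return self.records[accession].lineage

    @property
    def species(self) -> list[str]:
        return sorted({r.lineage.species for r in self.records.values() if r.lineage.species})

    def accessions_for_species(self, species: str) -> list[str]:
        return sorted(
            acc
            for acc, rec in self.records.items()
            if rec.lineage.species == species and acc in self.amplicons
        )

    def to_files(self, manifest_path: str | Path, fasta_path: str | Path) -> None:
        """Serialize as a JSON manifest plus a FASTA of amplicon sequences."""
        manifest = {
            "k": self.k,
            "records": [
                {
                    "accession": acc,
                    "lineage": vars(rec.lineage),
                    "amplicon": {
                        "start": self.amplicons[acc].start,
                        "end": self.amplicons[acc].end,
                        "strand": self.amplicons[acc].strand,
                    },
                }
                for acc, rec in sorted(self.records.items())
                if acc in self.amplicons
            ],
            "excluded": sorted(self.excluded),
        }
        Path(manifest_path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
        with open(fasta_path, "w") as fh:
            for acc in sorted(self.amplicons):
                fh.write(f">{acc}\n{self.amplicons[acc].with_primers_sequence}\n")


def parse_header(header: str) -> tuple[str, TaxonLineage]:
    """Parse ``accession|order|suborder|family|genus|species`` headers.

    Empty fields are allowed at lower ranks.  Records whose order is not
    Hemiptera are flagged as the host (honey bee) background lineage.
    """
    parts = header.split("|")
    if len(parts) != 6:
        raise ValueError(f"expected 6 pipe-delimited header fields, got {header!r}")
    accession, order, suborder, family, genus, species = (p.strip() for p in parts)
    lineage = TaxonLineage(
        species=species,
        genus=genus,
        family=family,
        suborder=suborder,
        order=order,
        is_host=order.lower() != "hemiptera",
    )
    return accession, lineage


def read_reference_fasta(path: str | Path) -> list[ReferenceRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        accession, lineage = parse_header(rec.description)
        records.append(ReferenceRecord(accession, lineage, str(rec.seq).upper()))
    return records


def build_database(
    records: Iterable[ReferenceRecord],
    primers: PrimerPair | None = None,
    k: int = 11,
) -> ReferenceDatabase:
    """Extract amplicons for every record and index them.

    Records without a valid product are excluded (and logged with a reason);
    an entirely empty result raises :class:`EmptyDatabaseError`.
    """
    primers = primers or PrimerPair()
    recs: dict[str, ReferenceRecord] = {}
    amps: dict[str, AmpliconExtract] = {}
    excluded: list[tuple[str, str]] = []
    for rec in records:
        if rec.accession in recs:
            raise ValueError(f"duplicate accession {rec.accession}")
        recs[rec.accession] = rec
        amp = extract_amplicon(rec, primers)
        if amp is None:
            excluded.append((rec.accession, "no valid amplicon"))
            log.warning("excluding %s: no valid amplicon", rec.accession)
        else:
            amps[rec.accession] = amp
    if not amps:
        raise EmptyDatabaseError("no record yielded a valid amplicon")
    return ReferenceDatabase(records=recs, amplicons=amps, k=k, excluded=excluded)


@dataclass(frozen=True)
class KnownHaplotype:
    haplotype_id: str
    full_sequence: str
    n_db_entries: int


@dataclass(frozen=True)
class KnownHaplotypeSet:
    """Published full-length haplotypes of one species, with the number of
    public database entries backing each."""

    species: str
    entries: tuple[KnownHaplotype, ...]

    def __post_init__(self) -> None:
        ids = [e.haplotype_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("haplotype_id not unique within species")


@dataclass(frozen=True)
class HaplotypeClass:
    """An amplicon-region equivalence class of known haplotypes."""

    class_sequence: str
    member_haplotype_ids: tuple[str, ...]
    total_n_db_entries: int


def read_known_haplotypes(path: str | Path) -> dict[str, KnownHaplotypeSet]:
    """Read a ``species|haplotype_id|n_db_entries`` FASTA into per-species sets."""
    by_species: dict[str, list[KnownHaplotype]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split("|")
        if len(parts) != 3:
            raise ValueError(f"expected species|haplotype_id|n_db_entries, got {rec.description!r}")
        species, hap_id, n = parts[0].strip(), parts[1].strip(), int(parts[2])
        by_species.setdefault(species, []).append(
            KnownHaplotype(hap_id, str(rec.seq).upper(), n)
        )
    return {
        sp: KnownHaplotypeSet(sp, tuple(haps)) for sp, haps in by_species.items()
    }


def project_haplotypes(
    known: KnownHaplotypeSet, primers: PrimerPair | None = None
) -> list[HaplotypeClass]:
    """Collapse full-length haplotypes onto the amplicon insert region.

    Haplotypes differing only outside the insert fall into one class, so a
    long-region haplotype panel generally projects to fewer amplicon-region
    mitotypes.  Classes are sorted by total database-entry support
    (descending), ties broken lexicographically on sequence.  Haplotypes
    without a valid amplicon are excluded and logged.
    """
    primers = primers or PrimerPair()
    classes: dict[str, list[KnownHaplotype]] = {}
    for hap in known.entries:
        rec = ReferenceRecord(hap.haplotype_id, TaxonLineage(species=known.species), hap.full_sequence)
        amp = extract_amplicon(rec, primers)
        if amp is None:
            log.warning("haplotype %s has no amplicon; excluded", hap.haplotype_id)
            continue
        classes.setdefault(amp.insert_sequence, []).append(hap)
    out = [
        HaplotypeClass(
            class_sequence=seq,
            member_haplotype_ids=tuple(h.haplotype_id for h in members),
            total_n_db_entries=sum(h.n_db_entries for h in members),
        )
        for seq, members in classes.items()
    ]
    out.sort(key=lambda c: (-c.total_n_db_entries, c.class_sequence))
    return out


def primer_mismatch_report(db: ReferenceDatabase, primers: PrimerPair | None = None):
    """Per-species minimum primer mismatch counts over the best binding site.

    The computational analog of a primer-efficiency comparison: species whose
    records carry more mismatches against the degenerate primers are expected
    to amplify less efficiently.  Species without a site within 5 mismatches
    on either strand are reported as "no site" (encoded as None).
    """
    import pandas as pd

    primers = primers or PrimerPair()
    if not db.records:
        raise EmptyDatabaseError("empty database")
    cap = 5
    rows: dict[str, dict[str, int | None]] = {}

    def best(seq: str, primer: str) -> int | None:
        hits = []
        for s in (seq, revcomp(seq)):
            hits.extend(mm for _, mm in find_primer_sites(s, primer, cap))
        return min(hits) if hits else None

    for rec in db.records.values():
        name = rec.lineage.species or rec.lineage.display_name(
            "genus" if rec.lineage.genus else "family"
        )
        f = best(rec.sequence, primers.forward)
        r = best(rec.sequence, revcomp(primers.reverse))
        cur = rows.setdefault(name, {"fwd": f, "rev": r})
        if f is not None and (cur["fwd"] is None or f < cur["fwd"]):
            cur["fwd"] = f
        if r is not None and (cur["rev"] is None or r < cur["rev"]):
            cur["rev"] = r
    return pd.DataFrame(
        [
            {
                "species": sp,
                "min_forward_mismatches": v["fwd"],
                "min_reverse_mismatches": v["rev"],
            }
            for sp, v in sorted(rows.items())
        ]
    )
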