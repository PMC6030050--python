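"""Read trimming and retention filtering.

Raw single-end amplicon reads are quality-trimmed at both ends, optionally
stripped of primer sequence (and reoriented to the forward strand when the
primer determines orientation), then retained only if at least 50 bp long
with a mean quality of at least Q20 — the retention rule of the upstream
Ion Torrent workflow this stage mirrors.  "Quality >= Q20" is interpreted as
mean read quality (the common Ion Torrent convention) and is a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from honeytrace.reference_db import PrimerPair, find_primer_sites, revcomp


@dataclass(frozen=True)
class Read:
    read_id: str
    bases: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError("bases and qualities length mismatch")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def mean_quality(self) -> float:
        return sum(self.qualities) / len(self.qualities) if self.qualities else 0.0

    def revcomp(self) -> "Read":
        return Read(self.read_id, revcomp(self.bases), self.qualities[::-1])

    @classmethod
    def from_seqrecord(cls, rec: SeqRecord) -> "Read":
        return cls(rec.id, str(rec.seq).upper(), tuple(rec.letter_annotations["phred_quality"]))

    def to_seqrecord(self) -> SeqRecord:
        rec = SeqRecord(Seq(self.bases), id=self.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(self.qualities)
        return rec


@dataclass(frozen=True)
class QCParams:
    min_length: int = 50
    min_mean_quality: float = 20.0
    window: int = 10
    window_quality: float = 20.0
    trim_primers: bool = True

    def __post_init__(self) -> None:
        if self.min_length < 1 or self.window < 1:
            raise ValueError("min_length and window must be >= 1")


@dataclass
class QCReport:
    """Per-batch retention accounting; dispositions are in input order."""

    n_input: int = 0
    n_retained: int = 0
    n_too_short: int = 0
    n_low_quality: int = 0
    dispositions: list[tuple[str, str]] = field(default_factory=list)


def _trim_3prime(bases: str, quals: Sequence[int], params: QCParams) -> int:
    """Length to keep after 3'-end trimming.

    Drops a trailing window whose mean phred is below ``window_quality`` or
    a trailing base below it, whichever applies, until the end is clean —
    so the surviving suffix passes both rules and re-trimming is a no-op.
    """
    end = len(bases)
    w = params.window
    while True:
        if end >= w and sum(quals[end - w : end]) / w < params.window_quality:
            end -= w
        elif end > 0 and quals[end - 1] < params.window_quality:
            end -= 1
        else:
            return end


def quality_trim(read: Read, params: QCParams | None = None) -> Read:
    """Symmetric two-ended quality trim.

    From the 3' end, drop trailing windows whose mean phred falls below
    ``window_quality`` and trailing bases individually below it until the
    end is clean; the same rule is mirrored once at the 5' end.  May return
    an empty read.
    """
    params = params or QCParams()
    end = _trim_3prime(read.bases, read.qualities, params)
    bases, quals = read.bases[:end], read.qualities[:end]
    # mirror at the 5' end by trimming the reversed read once
    keep = _trim_3prime(bases[::-1], quals[::-1], params)
    start = len(bases) - keep
    return Read(read.read_id, bases[start:], quals[start:])


def trim_primers(
    read: Read, primers: PrimerPair | None = None, max_mismatches: int = 2
) -> tuple[Read, tuple[bool, bool]]:
    """Strip primer sequence from the read ends; reorient if needed.

    A forward-primer site (or the reverse complement of the reverse primer)
    is searched within the first/last 25 bases on either strand.  When the
    found primers determine the orientation, the read is reverse-complemented
    to the forward strand first.  Returns the trimmed read and a
    (found at 5', found at 3') flag pair.
    """
    primers = primers or PrimerPair()
    if len(read) == 0:
        return read, (False, False)

    fwd = primers.forward
    rev_rc = revcomp(primers.reverse)  # 3' end of a forward-strand read

    def locate_5p(bases: str, primer: str) -> int | None:
        limit = min(25, len(bases))
        hits = [
            (mm, pos)
            for pos, mm in find_primer_sites(bases[: limit + len(primer) - 1], primer, max_mismatches)
            if pos < limit
        ]
        return min(hits)[1] if hits else None

    def locate_3p(bases: str, primer: str) -> int | None:
        tail_start = max(0, len(bases) - 25 - len(primer) + 1)
        hits = [
            (mm, pos + tail_start)
            for pos, mm in find_primer_sites(bases[tail_start:], primer, max_mismatches)
        ]
        return min(hits)[1] if hits else None

    oriented = read
    # reverse-strand evidence: reverse primer (as written) at 5', or the
    # reverse complement of the forward primer at 3'
    if locate_5p(read.bases, fwd) is None and locate_3p(read.bases, rev_rc) is None:
        rc = read.revcomp()
        if locate_5p(rc.bases, fwd) is not None or locate_3p(rc.bases, rev_rc) is not None:
            oriented = rc

    bases, quals = oriented.bases, oriented.qualities
    found5 = found3 = False
    pos = locate_5p(bases, fwd)
    if pos is not None:
        cut = pos + len(fwd)
        bases, quals = bases[cut:], quals[cut:]
        found5 = True
    pos = locate_3p(bases, rev_rc)
    if pos is not None:
        bases, quals = bases[:pos], quals[:pos]
        found3 = True
    return Read(read.read_id, bases, quals), (found5, found3)


def filter_reads(
    batch: Iterable[Read],
    params: QCParams | None = None,
    primers: PrimerPair | None = None,
    max_primer_mismatches: int = 2,
) -> tuple[list[Read], QCReport]:
    """Trim every read, then retain those >= ``min_length`` with mean
    quality >= ``min_mean_quality``.

    Length is checked after primer and quality trimming (trim-then-retain
    ordering).  Every input read lands in exactly one disposition bucket.
    """
    params = params or QCParams()
    report = QCReport()
    retained: list[Read] = []
    for read in batch:
        report.n_input += 1
        trimmed = quality_trim(read, params)
        if params.trim_primers and len(trimmed):
            trimmed, _found = trim_primers(trimmed, primers, max_primer_mismatches)
        if len(trimmed) < params.min_length:
            report.n_too_short += 1
            report.dispositions.append((read.read_id, "too_short"))
        elif trimmed.mean_quality < params.min_mean_quality:
            report.n_low_quality += 1
            report.dispositions.append((read.read_id, "low_quality"))
        else:
            report.n_retained += 1
            report.dispositions.append((read.read_id, "retained"))
            retained.append(trimmed)
    return retained, report


def read_fastq(path: str | Path) -> list[Read]:
    return [Read.from_seqrecord(r) for r in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    return SeqIO.write((r.to_seqrecord() for r in reads), str(path), "fastq")
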