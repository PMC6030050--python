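"""Synthetic honey amplicon libraries with known ground truth.

Real honey eDNA libraries are mixtures: one dominant planthopper species,
several minor aphid species, a within-species mix of mitochondrial
haplotypes (mitotypes), and a large honey-bee (host) background co-amplified
by the degenerate primers.  This module emulates exactly that shape so every
downstream stage — QC, assignment, profiling, mitotype calling — can be
validated against a truth manifest without a sequencing run.

Reads are single-end, cover the full 135-140 bp product (primers included),
are reverse-complemented with probability 0.5, and carry an Ion-Torrent-like
error model: per-base substitutions plus indels whose rate is boosted inside
homopolymer runs of length >= 3.  Per-base qualities are drawn from a normal
distribution and clamped to [2, 40]; they are independent of the planted
errors (a stated simplification).

All randomness flows from one :class:`numpy.random.Generator` stream, so a
fixture is bit-reproducible from its seed.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from honeytrace.read_qc import Read
from honeytrace.reference_db import (
    KnownHaplotype,
    KnownHaplotypeSet,
    PrimerPair,
    ReferenceRecord,
    TaxonLineage,
    revcomp,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class CommunityMember:
    species: str
    fraction: float
    mitotypes: tuple[tuple[str, float], ...]  # (haplotype_id, within-species fraction)


@dataclass(frozen=True)
class CommunitySpec:
    """Ground-truth composition of one simulated library."""

    members: tuple[CommunityMember, ...]
    host_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.host_fraction <= 1.0:
            raise ValueError("host_fraction must be in [0, 1]")
        total = sum(m.fraction for m in self.members)
        if self.members and abs(total - 1.0) > 1e-9:
            raise ValueError(f"member fractions sum to {total}, expected 1")
        for m in self.members:
            s = sum(f for _, f in m.mitotypes)
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"{m.species} mitotype fractions sum to {s}")


@dataclass(frozen=True)
class ErrorModel:
    substitution_rate: float = 0.005
    indel_rate: float = 0.005
    homopolymer_multiplier: float = 3.0
    quality_mean: float = 28.0
    quality_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.indel_rate):
            if not 0.0 <= r <= 0.2:
                raise ValueError("error rates must be in [0, 0.2]")
        if not 10.0 <= self.quality_mean <= 40.0:
            raise ValueError("quality_mean must be in [10, 40]")
        if self.homopolymer_multiplier < 1.0:
            raise ValueError("homopolymer_multiplier must be >= 1")


@dataclass
class TruthManifest:
    """Per-read provenance and realized per-library counts."""

    per_read: list[tuple[str, str, str, int]] = field(default_factory=list)
    # read_id, source_species ("host" for the honey bee), haplotype_id, n_errors
    species_counts: Counter = field(default_factory=Counter)
    mitotype_counts: Counter = field(default_factory=Counter)  # (species, hap_id)
    n_host: int = 0

    @property
    def n_reads(self) -> int:
        return len(self.per_read)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tsource_species\tsource_haplotype\tn_errors\n")
            for row in self.per_read:
                fh.write("\t".join(map(str, row)) + "\n")


def _homopolymer_runs(seq: np.ndarray) -> np.ndarray:
    """Length of the homopolymer run each position belongs to."""
    n = seq.shape[0]
    runs = np.empty(n, dtype=np.int32)
    i = 0
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        runs[i:j] = j - i
        i = j
    return runs


def mutate_sequence(
    sequence: str, model: ErrorModel, rng: np.random.Generator
) -> tuple[str, int]:
    """Apply substitutions and (homopolymer-boosted) indels to one sequence.

    Substitutions are drawn per base; indels per base with the rate
    multiplied by ``homopolymer_multiplier`` inside runs of length >= 3.
    An indel is a deletion or a random-base insertion with equal probability.
    Returns the mutated sequence and the total number of edits.
    """
    seq = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    n = seq.shape[0]
    n_errors = 0
    if model.substitution_rate > 0 and n:
        hit = np.flatnonzero(rng.random(n) < model.substitution_rate)
        for i in hit:
            alt = _BASES[_BASES != seq[i]]
            seq[i] = alt[rng.integers(len(alt))]
        n_errors += hit.size
    if model.indel_rate > 0 and n:
        rates = np.full(n, model.indel_rate)
        rates[_homopolymer_runs(seq) >= 3] *= model.homopolymer_multiplier
        hit = np.flatnonzero(rng.random(n) < rates)
        if hit.size:
            out = []
            prev = 0
            for i in hit:
                out.append(seq[prev:i])
                if rng.random() < 0.5:  # deletion: drop base i
                    pass
                else:  # insertion: keep base i, insert a random base after it
                    out.append(seq[i : i + 1])
                    b = int(rng.integers(4))
                    out.append(_BASES[b : b + 1])
                prev = i + 1
            out.append(seq[prev:])
            seq = np.concatenate(out) if out else seq
            n_errors += hit.size
    return seq.tobytes().decode("ascii"), int(n_errors)


class MissingSourceError(KeyError):
    """The community spec names a species/mitotype without a sequence."""


def simulate_library(
    amplicons: dict[tuple[str, str], str],
    host_amplicon: str | None,
    spec: CommunitySpec,
    model: ErrorModel,
    n_reads: int,
    rng: np.random.Generator | None = None,
    read_prefix: str = "read",
) -> tuple[list[Read], TruthManifest]:
    """Simulate one library of single-end amplicon reads.

    Each read draws its source multinomially (host fraction, then species,
    then mitotype), takes the with-primers amplicon, is reverse-complemented
    with probability 0.5, mutated under the error model, and given qualities
    ~ Normal(quality_mean, quality_sd) clamped to [2, 40].
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if spec.host_fraction > 0 and host_amplicon is None:
        raise MissingSourceError("host_fraction > 0 but no host amplicon given")
    for m in spec.members:
        for hap_id, _ in m.mitotypes:
            if (m.species, hap_id) not in amplicons:
                raise MissingSourceError(f"no amplicon for {m.species}/{hap_id}")
    rng = rng if rng is not None else np.random.default_rng(model.seed)

    species_p = np.array([m.fraction for m in spec.members])
    reads: list[Read] = []
    manifest = TruthManifest()
    width = len(str(n_reads))
    for idx in range(n_reads):
        read_id = f"{read_prefix}{idx + 1:0{width}d}"
        if spec.host_fraction > 0 and rng.random() < spec.host_fraction:
            species, hap_id, template = "host", "host", host_amplicon
            manifest.n_host += 1
        else:
            member = spec.members[rng.choice(len(spec.members), p=species_p)]
            hap_ids = [h for h, _ in member.mitotypes]
            hap_p = np.array([f for _, f in member.mitotypes])
            hap_id = hap_ids[rng.choice(len(hap_ids), p=hap_p)]
            species, template = member.species, amplicons[(member.species, hap_id)]
            manifest.mitotype_counts[(species, hap_id)] += 1
        manifest.species_counts[species] += 1
        bases, n_errors = mutate_sequence(template, model, rng)
        if rng.random() < 0.5:
            bases = revcomp(bases)
        quals = np.clip(
            np.rint(rng.normal(model.quality_mean, model.quality_sd, len(bases))),
            2,
            40,
        ).astype(int)
        reads.append(Read(read_id, bases, tuple(int(q) for q in quals)))
        manifest.per_read.append((read_id, species, hap_id, n_errors))
    return reads, manifest


@dataclass
class ReferenceFixture:
    """A self-consistent synthetic reference set.

    ``records`` hold one reference entry per (species, mitotype); ``known``
    maps each species to its known-haplotype panel (full-length sequences
    with flanks); ``amplicons`` maps (species, haplotype_id) to the
    with-primers product used as a read template.
    """

    records: list[ReferenceRecord]
    known: dict[str, KnownHaplotypeSet]
    amplicons: dict[tuple[str, str], str]
    inserts: dict[tuple[str, str], str]
    primers: PrimerPair

    def write_reference_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                lin = rec.lineage
                header = "|".join(
                    [rec.accession, lin.order, lin.suborder, lin.family, lin.genus, lin.species]
                )
                fh.write(f">{header}\n{rec.sequence}\n")

    def write_known_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sp in sorted(self.known):
                for hap in self.known[sp].entries:
                    fh.write(f">{sp}|{hap.haplotype_id}|{hap.n_db_entries}\n")
                    fh.write(hap.full_sequence + "\n")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode("ascii")


def realize_primer(primer: str, rng: np.random.Generator) -> str:
    """Replace each degenerate IUPAC code with one concrete base from its
    expansion: a real template carries plain bases at the primer site."""
    from honeytrace.reference_db import IUPAC

    out = []
    for code in primer:
        choices = sorted(IUPAC[code])
        out.append(choices[int(rng.integers(len(choices)))] if len(choices) > 1 else code)
    return "".join(out)


def _mutate_at(seq: str, positions, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    for p in positions:
        alt = _BASES[_BASES != arr[p]]
        arr[p] = alt[rng.integers(len(alt))]
    return arr.tobytes().decode("ascii")


def _hamming_identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    same = sum(x == y for x, y in zip(a, b))
    return same / len(a)


# Default aphid/planthopper-flavoured lineages for fixture species; cycled
# when more species are requested than names are listed.
_FIXTURE_LINEAGES = [
    ("Flatidae", "Metcalfa", "Metcalfa pruinosa", "Auchenorrhyncha"),
    ("Aphididae", "Rhopalosiphum", "Rhopalosiphum insertum", "Sternorrhyncha"),
    ("Aphididae", "Myzus", "Myzus persicae", "Sternorrhyncha"),
    ("Aphididae", "Aphis", "Aphis gossypii", "Sternorrhyncha"),
    ("Aphididae", "Aphis", "Aphis craccivora", "Sternorrhyncha"),
    ("Aphididae", "Cinara", "Cinara pectinatae", "Sternorrhyncha"),
    ("Issidae", "Issus", "Issus muscaeformis", "Auchenorrhyncha"),
    ("Aphididae", "Cavariella", "Cavariella aegopodii", "Sternorrhyncha"),
]


def make_reference_fixture(
    n_species: int,
    n_mitotypes: list[int] | None = None,
    divergence: float = 0.10,
    seed: int = 0,
    insert_len: int = 97,
    primers: PrimerPair | None = None,
    flank: int = 30,
) -> ReferenceFixture:
    """Generate a reference FASTA fixture with planted primer sites.

    Species amplicons descend from one ancestral insert mutated at
    ``round(divergence * insert_len)`` positions each, drawn so that every
    pairwise inter-species identity over the with-primers product is < 0.97
    (the assignment threshold); within a species, mitotypes differ at 1-3
    sites, keeping identity >= 0.97.  Exact primer sites are planted in every
    record, and the default insert of 97 nt gives a 139 bp product, inside
    the 135-140 bp target range.  Deterministic per seed.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    n_mitotypes = n_mitotypes if n_mitotypes is not None else [1] * n_species
    if len(n_mitotypes) != n_species:
        raise ValueError("n_mitotypes must have one entry per species")
    n_var = round(divergence * insert_len)
    if n_var < math.ceil(0.03 * (insert_len + 42)) + 3:
        raise ValueError(
            f"divergence {divergence} too low to guarantee <97% inter-species identity"
        )
    primers = primers or PrimerPair()
    rng = np.random.default_rng(seed)
    ancestor = _random_seq(rng, insert_len)

    # with-primers identity = (2*21 + matches) / (insert_len + 42); require < 0.97
    plen = len(primers.forward) + len(primers.reverse)
    insert_identity_cap = (0.97 * (insert_len + plen) - plen) / insert_len
    inserts: list[str] = []
    for _attempt in range(200):
        pos = rng.choice(insert_len, size=n_var, replace=False)
        cand = _mutate_at(ancestor, pos, rng)
        ok = all(
            _hamming_identity(cand, other) < insert_identity_cap for other in inserts
        ) and cand not in inserts
        if ok:
            inserts.append(cand)
            if len(inserts) == n_species:
                break
    if len(inserts) < n_species:
        raise ValueError("could not achieve requested inter-species divergence")

    records: list[ReferenceRecord] = []
    known: dict[str, KnownHaplotypeSet] = {}
    amplicons: dict[tuple[str, str], str] = {}
    insert_map: dict[tuple[str, str], str] = {}
    # one concrete realization of the degenerate primer sites, shared by all
    # records: the sites sit in regions conserved across the whole fixture
    fwd_site = realize_primer(primers.forward, rng)
    rev_rc = revcomp(realize_primer(primers.reverse, rng))
    for si in range(n_species):
        family, genus, species, suborder = _FIXTURE_LINEAGES[si % len(_FIXTURE_LINEAGES)]
        if si >= len(_FIXTURE_LINEAGES):
            species = f"{species} {si}"  # keep species names unique when cycling
        lineage = TaxonLineage(species=species, genus=genus, family=family,
                               suborder=suborder, order="Hemiptera")
        base_insert = inserts[si]
        haps: list[KnownHaplotype] = []
        seen = {base_insert}
        for mi in range(n_mitotypes[si]):
            if mi == 0:
                ins = base_insert
            else:
                for _ in range(100):
                    k = int(rng.integers(1, 4))  # 1-3 variant sites
                    pos = rng.choice(insert_len, size=k, replace=False)
                    ins = _mutate_at(base_insert, pos, rng)
                    if ins not in seen:
                        seen.add(ins)
                        break
                else:
                    raise ValueError("could not generate distinct mitotype")
            hap_id = f"Hap{mi + 1}"
            product = fwd_site + ins + rev_rc
            full = _random_seq(rng, flank) + product + _random_seq(rng, flank)
            accession = f"SYN{si + 1:02d}M{mi + 1}"
            records.append(ReferenceRecord(accession, lineage, full))
            # first mitotype gets strong database support, later ones little
            haps.append(KnownHaplotype(hap_id, full, 10 if mi == 0 else 1 + mi))
            amplicons[(species, hap_id)] = product
            insert_map[(species, hap_id)] = ins
        known[species] = KnownHaplotypeSet(species, tuple(haps))
    return ReferenceFixture(records, known, amplicons, insert_map, primers)


def make_host_record(
    seed: int = 0,
    insert_len: int = 97,
    primers: PrimerPair | None = None,
    flank: int = 30,
) -> tuple[ReferenceRecord, str]:
    """A honey-bee (Apis mellifera) reference record with planted primer
    sites, highly diverged from any fixture Hemiptera insert.

    Returns the record and its with-primers amplicon (the host read
    template).  The lineage order is Hymenoptera, so the record parses as
    the host background.
    """
    primers = primers or PrimerPair()
    rng = np.random.default_rng(seed + 7_000_003)
    ins = _random_seq(rng, insert_len)
    product = realize_primer(primers.forward, rng) + ins + revcomp(
        realize_primer(primers.reverse, rng)
    )
    full = _random_seq(rng, flank) + product + _random_seq(rng, flank)
    lineage = TaxonLineage(
        species="Apis mellifera",
        genus="Apis",
        family="Apidae",
        suborder="Apocrita",
        order="Hymenoptera",
        is_host=True,
    )
    return ReferenceRecord("HOST01", lineage, full), product


def make_projection_fixture(
    n_haplotypes: int = 19,
    n_classes: int = 11,
    seed: int = 0,
    species: str = "Metcalfa pruinosa",
    insert_len: int = 97,
    primers: PrimerPair | None = None,
    flank: int = 60,
) -> KnownHaplotypeSet:
    """A long-region haplotype panel that collapses to a known class count.

    Builds ``n_haplotypes`` full-length haplotypes containing exactly
    ``n_classes`` distinct insert patterns: class-defining variants sit
    inside the amplicon insert, while haplotypes sharing a class differ only
    in the flanking regions outside the amplified fragment.  Projecting the
    panel onto the amplicon region must therefore yield ``n_classes``
    equivalence classes.
    """
    if n_classes > n_haplotypes:
        raise ValueError("n_classes cannot exceed n_haplotypes")
    primers = primers or PrimerPair()
    rng = np.random.default_rng(seed)
    base_insert = _random_seq(rng, insert_len)
    class_inserts = [base_insert]
    seen = {base_insert}
    while len(class_inserts) < n_classes:
        k = int(rng.integers(1, 4))
        ins = _mutate_at(base_insert, rng.choice(insert_len, size=k, replace=False), rng)
        if ins not in seen:
            seen.add(ins)
            class_inserts.append(ins)
    fwd_site = realize_primer(primers.forward, rng)
    rev_rc = revcomp(realize_primer(primers.reverse, rng))
    left = _random_seq(rng, flank)
    right = _random_seq(rng, flank)
    haps = []
    seen_full = set()
    for hi in range(n_haplotypes):
        ins = class_inserts[hi % n_classes]
        for _ in range(100):
            # flank variation keeps same-class full sequences distinct
            lf = _mutate_at(left, rng.choice(flank, size=2, replace=False), rng)
            rf = _mutate_at(right, rng.choice(flank, size=2, replace=False), rng)
            full = lf + fwd_site + ins + rev_rc + rf
            if full not in seen_full:
                seen_full.add(full)
                break
        haps.append(KnownHaplotype(f"H{hi + 1}", full, int(rng.integers(1, 20))))
    return KnownHaplotypeSet(species, tuple(haps))
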