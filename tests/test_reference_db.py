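"""Reference parsing, in-silico PCR and haplotype projection."""

import random

import pytest

from honeytrace.reference_db import (
    EmptyDatabaseError,
    InvalidAlphabetError,
    KnownHaplotype,
    KnownHaplotypeSet,
    PrimerPair,
    ReferenceRecord,
    TaxonLineage,
    build_database,
    extract_amplicon,
    find_primer_sites,
    iupac_match,
    parse_header,
    primer_mismatch_report,
    project_haplotypes,
    revcomp,
)

PRIMERS = PrimerPair()
# realized primer sites as they appear on a concrete template (W -> T, R -> A)
FWD_SITE = "TGGATCAGGAACAGGATGAAC"
REV_RC = revcomp("AAATGAAATTGATTGCTCCTA")
LINEAGE = TaxonLineage(species="Metcalfa pruinosa", genus="Metcalfa",
                       family="Flatidae", order="Hemiptera")


def _product(insert: str) -> str:
    return FWD_SITE + insert + REV_RC


def _rand_seq(rnd, n):
    return "".join(rnd.choice("ACGT") for _ in range(n))


@pytest.mark.parametrize(
    "pattern,base,expected",
    [
        ("W", "A", True),   # W = A or T
        ("W", "T", True),
        ("R", "C", False),  # R = A or G
        ("R", "G", True),
        ("A", "A", True),
        ("N", "C", True),
        ("A", "N", False),  # undetermined subject base never matches
        ("W", "N", False),
    ],
)
def test_iupac_match(pattern, base, expected):
    assert iupac_match(pattern, base) is expected


def test_iupac_match_rejects_non_iupac():
    with pytest.raises(InvalidAlphabetError):
        iupac_match("X", "A")


def test_find_primer_sites_planted_exact():
    rnd = random.Random(0)
    x, y = _rand_seq(rnd, 50), _rand_seq(rnd, 50)
    site = "TGGAACAGGAACAGGATGAAC"  # W position realized as A
    s = x + site + y
    hits = find_primer_sites(s, PRIMERS.forward, 0)
    assert (50, 0) in hits
    # one base changed exceeds a zero budget at the planted site
    mutated = x + "TGGAACAGGAACAGGATGAAG" + y
    assert (50, 0) not in find_primer_sites(mutated, PRIMERS.forward, 0)


def test_find_primer_sites_matches_bruteforce_scan():
    """Windowed search equals a naive all-window scan on random sequences."""

    def brute(seq, primer, mm_max):
        from honeytrace.reference_db import IUPAC

        out = []
        for pos in range(len(seq) - len(primer) + 1):
            mm = sum(
                1
                for pb, b in zip(primer, seq[pos : pos + len(primer)])
                if b == "N" or b not in IUPAC[pb]
            )
            if mm <= mm_max:
                out.append((pos, mm))
        return out

    rnd = random.Random(123)
    for _ in range(200):
        seq = _rand_seq(rnd, rnd.randint(30, 400))
        assert find_primer_sites(seq, PRIMERS.forward, 2) == brute(seq, PRIMERS.forward, 2)


def test_find_primer_sites_rejects_empty_primer():
    with pytest.raises(ValueError):
        find_primer_sites("ACGT", "", 0)


class TestExtractAmplicon:
    def test_planted_product(self):
        rnd = random.Random(1)
        insert = _rand_seq(rnd, 97)
        seq = _rand_seq(rnd, 30) + _product(insert) + _rand_seq(rnd, 30)
        rec = ReferenceRecord("A1", LINEAGE, seq)
        amp = extract_amplicon(rec, PRIMERS)
        assert amp is not None
        assert amp.strand == "+"
        assert len(amp.with_primers_sequence) == 139  # 21 + 97 + 21
        assert amp.insert_sequence == insert
        assert amp.end - amp.start == 139
        assert seq[amp.start : amp.end] == amp.with_primers_sequence

    def test_span_too_long_gives_none(self):
        rnd = random.Random(2)
        seq = FWD_SITE + _rand_seq(rnd, 258) + REV_RC  # span 300 > max 200
        assert extract_amplicon(ReferenceRecord("A1", LINEAGE, seq), PRIMERS) is None

    def test_strand_symmetry(self):
        rnd = random.Random(3)
        insert = _rand_seq(rnd, 97)
        seq = _rand_seq(rnd, 25) + _product(insert) + _rand_seq(rnd, 25)
        fwd = extract_amplicon(ReferenceRecord("A1", LINEAGE, seq), PRIMERS)
        rev = extract_amplicon(ReferenceRecord("A1", LINEAGE, revcomp(seq)), PRIMERS)
        assert fwd.insert_sequence == rev.insert_sequence == insert
        assert fwd.strand == "+" and rev.strand == "-"
        # coordinates are on the stored (+) sequence: the product read there
        # is the reverse complement of the amplified orientation
        assert revcomp(seq)[rev.start : rev.end] == revcomp(rev.with_primers_sequence)


class TestBuildDatabase:
    def _records(self, n_with_sites, n_without):
        rnd = random.Random(9)
        recs = []
        for i in range(n_with_sites):
            seq = _rand_seq(rnd, 20) + _product(_rand_seq(rnd, 97)) + _rand_seq(rnd, 20)
            recs.append(ReferenceRecord(f"R{i}", LINEAGE, seq))
        for i in range(n_without):
            recs.append(ReferenceRecord(f"X{i}", LINEAGE, _rand_seq(rnd, 300)))
        return recs

    def test_all_extractable(self):
        db = build_database(self._records(5, 0), PRIMERS)
        assert len(db.amplicons) == 5 and not db.excluded

    def test_exclusion_logged(self):
        db = build_database(self._records(4, 1), PRIMERS)
        assert len(db.amplicons) == 4
        assert db.excluded == [("X0", "no valid amplicon")]

    def test_zero_extractable_raises(self):
        with pytest.raises(EmptyDatabaseError):
            build_database(self._records(0, 3), PRIMERS)

    def test_serialization_deterministic(self, tmp_path):
        for d in ("a", "b"):
            db = build_database(self._records(5, 1), PRIMERS)
            db.to_files(tmp_path / f"{d}.json", tmp_path / f"{d}.fasta")
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()


def test_parse_header_and_host_flag():
    acc, lin = parse_header("AB1|Hemiptera|Sternorrhyncha|Aphididae|Aphis|Aphis gossypii")
    assert acc == "AB1" and lin.species == "Aphis gossypii" and not lin.is_host
    _, host = parse_header("H1|Hymenoptera|Apocrita|Apidae|Apis|Apis mellifera")
    assert host.is_host


class TestProjectHaplotypes:
    def _known(self, inserts_and_flanks, n_entries=None):
        rnd = random.Random(4)
        haps = []
        for i, (ins, flank_seed) in enumerate(inserts_and_flanks):
            fr = random.Random(flank_seed)
            full = _rand_seq(fr, 40) + _product(ins) + _rand_seq(fr, 40)
            n = n_entries[i] if n_entries else 1
            haps.append(KnownHaplotype(f"H{i + 1}", full, n))
        return KnownHaplotypeSet("Metcalfa pruinosa", tuple(haps))

    def test_constructed_collapse(self):
        rnd = random.Random(5)
        a, b = _rand_seq(rnd, 97), _rand_seq(rnd, 97)
        # three haplotypes share insert a (flanks differ), one carries b
        known = self._known([(a, 1), (a, 2), (a, 3), (b, 4)], [5, 5, 5, 2])
        classes = project_haplotypes(known, PRIMERS)
        assert len(classes) == 2
        assert classes[0].class_sequence == a  # 15 entries beats 2
        assert set(classes[0].member_haplotype_ids) == {"H1", "H2", "H3"}
        assert classes[0].total_n_db_entries == 15
        assert classes[1].member_haplotype_ids == ("H4",)

    def test_single_haplotype_identity(self):
        rnd = random.Random(6)
        known = self._known([(_rand_seq(rnd, 97), 1)])
        classes = project_haplotypes(known, PRIMERS)
        assert len(classes) == 1 and classes[0].member_haplotype_ids == ("H1",)

    def test_member_counts_sum_to_projectable_inputs(self):
        rnd = random.Random(7)
        inserts = [(_rand_seq(rnd, 97), i) for i in range(5)]
        known = self._known(inserts + [inserts[0]])
        classes = project_haplotypes(known, PRIMERS)
        assert sum(len(c.member_haplotype_ids) for c in classes) == 6


def test_primer_mismatch_report_ordering():
    """A host with planted primer mismatches scores strictly worse than a
    target with exact sites, mirroring lower amplification efficiency."""
    rnd = random.Random(8)
    insert = _rand_seq(rnd, 97)
    target_seq = _rand_seq(rnd, 20) + _product(insert) + _rand_seq(rnd, 20)
    fwd_3mm = "CCC" + FWD_SITE[3:]
    host_seq = _rand_seq(rnd, 20) + fwd_3mm + insert + REV_RC + _rand_seq(rnd, 20)
    host_lin = TaxonLineage(species="Apis mellifera", genus="Apis", family="Apidae",
                            order="Hymenoptera", is_host=True)
    db = build_database(
        [
            ReferenceRecord("T1", LINEAGE, target_seq),
            ReferenceRecord("H1", host_lin, host_seq),
        ],
        PrimerPair(max_mismatches=3),
    )
    report = primer_mismatch_report(db, PRIMERS).set_index("species")
    assert report.loc["Metcalfa pruinosa", "min_forward_mismatches"] == 0
    assert report.loc["Metcalfa pruinosa", "min_reverse_mismatches"] == 0
    assert report.loc["Apis mellifera", "min_forward_mismatches"] == 3
    assert (
        report.loc["Apis mellifera", "min_forward_mismatches"]
        > report.loc["Metcalfa pruinosa", "min_forward_mismatches"]
    )


def test_one_planted_forward_mismatch_reported():
    rnd = random.Random(10)
    insert = _rand_seq(rnd, 97)
    fwd_1mm = "A" + FWD_SITE[1:]  # site starts with T, so exactly 1 mismatch
    seq = _rand_seq(rnd, 20) + fwd_1mm + insert + REV_RC + _rand_seq(rnd, 20)
    db = build_database([ReferenceRecord("T1", LINEAGE, seq)], PrimerPair(max_mismatches=2))
    report = primer_mismatch_report(db, PRIMERS).set_index("species")
    assert report.loc["Metcalfa pruinosa", "min_forward_mismatches"] == 1
    assert report.loc["Metcalfa pruinosa", "min_reverse_mismatches"] == 0
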