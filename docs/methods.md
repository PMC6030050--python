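# Methods

## The measurement being modelled

A honey sample contains trace DNA of honeydew-producing Hemiptera alongside
a large excess of honey-bee (host) DNA. A degenerate primer pair designed in
conserved COI regions (forward `TGGAWCAGGAACAGGATGAAC`, reverse
`AAATGAARTTGATTGCTCCTA`, written 5′→3′ with the reverse on the antisense
strand) amplifies a 135–140 bp product across the main plant-sucking
families; single-end Ion-Torrent-style reads of the full product are then
assigned to taxa by alignment against an annotated COI reference set.
`honeytrace` reproduces this measurement chain computationally and adds the
statistics the survey design calls for: categorical abundance per library
and within-species mitotype frequencies with an error-robustness filter.

## In-silico PCR (reference_db)

Primer matching is IUPAC-aware Hamming matching — a degenerate code matches
any base of its expansion, an `N` in the subject matches nothing — with no
indels: references are assumed high-quality assemblies, and indel tolerance
belongs to read alignment, not site finding. Both strands are searched; a
product requires a forward site and, downstream, a site matching the
reverse complement of the reverse primer, with total span inside
[`min_amplicon_len`, `max_amplicon_len`] = [100, 200] bp. The 5′-most valid
product on the first productive strand wins; coordinates are 0-based
half-open on the stored (+) sequence with the product strand recorded
explicitly. The default mismatch budget for reference extraction is 2 per
primer; it is a parameter, since no canonical value exists for this primer
pair. Records without a product are excluded and logged, never silently
dropped.

The honey-bee lineage is a normal database record whose `order` field is
not Hemiptera; it is flagged `is_host` at parse time. Host reads are thus
*assigned* (and excluded from Hemiptera profiles) rather than left
unmatched, which reproduces the total-minus-Hemiptera host accounting used
in practice.

Known full-length haplotypes of a species are projected onto the amplicon
by extracting their insert region and grouping identical inserts: the class
keeps the union of member ids and the sum of their database-entry counts.
Because the amplicon is much shorter than the regions used in population
surveys, several long-region haplotypes typically land in one class.

## Read QC (read_qc)

Trimming interleaves two rules at the 3′ end until stable — drop a trailing
window (default 10 bp) whose mean phred is below 20, or a trailing base
below 20 — and mirrors the same rule once at the 5′ end. Interleaving makes
the trim a fixpoint, so filtering is idempotent. Primer stripping searches
the first/last 25 bases on both strands at ≤ 2 mismatches and reorients the
read to the forward strand when the primers determine orientation. A read
is retained iff, after trimming, length ≥ 50 bp and mean quality ≥ Q20.
"Quality ≥ Q20" is read as *mean* read quality (the common Ion Torrent
convention); it is exposed as a parameter, as is the window rule, since the
upstream tooling's exact 5′ trim settings are not standardized.

## Alignment and assignment (taxonomic_assignment)

Alignment is a banded overlap (free-end-gap) dynamic program with match +1,
mismatch −1, linear gap −2, implemented as a numba kernel. End gaps on
either sequence are free, so query ends hanging off the target are clipped
rather than penalized; identity is matches over alignment columns (gap
columns count against it, BLAST-like) and coverage is the aligned fraction
of the query, giving qcov semantics in which "95% to 100% coverage" is the
closed interval [0.95, 1.0] with 1.0 attainable. The band is centred on the
length-difference-corrected diagonal window
`[min(0, n−m) − band, max(0, n−m) + band]` (default band 16), so it
tolerates 16 net indels regardless of the query/target length difference —
far more than a 140 bp amplicon read accumulates. Ties in the DP and the
endpoint scan are broken by a fixed preference order, making results
deterministic. The scoring scheme is fixed and documented; decisions are
driven by the identity/coverage thresholds, which are robust to the scheme
at these divergences.

Candidates are gathered by shared 11-mers (both strands) from an index over
the with-primers amplicons; with no seed hit at all the read is aligned
against every accession. Among hits passing identity ≥ 0.97 and coverage
≥ 0.95, the maximum score wins. If two or more *species* tie within
`tie_margin` (default 0), the read is assigned the deepest rank shared by
the tied lineages — genus, else family, else unassigned — which is how
genus-level ("*Cinara* sp.") and family-level ("Aphididae spp.") rows arise
in a survey table. A tie involving the host resolves to host: an ambiguous
host/Hemiptera read must not inflate the Hemiptera profile.

## Abundance categories (community_summary)

Per-library fractions use the number of Hemiptera-assigned reads as
denominator, not all sequenced reads: with a large host background the
categorical labels are only meaningful relative to the Hemiptera signal
(the all-reads denominator is available as an option). Labels: high
> 30%, medium 5–30% with both boundaries included, low < 5%. The packaged
13-library survey count table, with every printed category label, is the
worked example: the computed label matches the printed one for all 86 rows,
which is also the empirical justification for the denominator choice.

## Mitotype calling (mitotype_caller)

Reads assigned to one species are aligned to that species' amplicon insert
on both strands; a read is *placed* when its best alignment is gapless and
(by default) covers the whole insert, and its aligned sequence is the
candidate key. A read with an indel against the reference is unplaced by
default: indels are the dominant Ion Torrent error mode, while real
mitotypes of these species differ by substitutions only, so a gapped read
is far more likely an error than a variant. Unplaced reads are counted
explicitly (`n_unplaced_reads`), keeping candidate counts + unplaced =
species reads in every run.

Reliability of a candidate follows the rule: **count ≥ 20 AND (known OR
fraction ≥ 5%)**, with fractions over placed (mitotypable) reads. The
20-read floor is the sequencing-error guard and always applies; the
alternative parse "(≥ 20 AND known) OR ≥ 5%" is available as
`MitotypeParams(rule="lenient")`. Known status is an exact sequence match
to a projected haplotype class — a single substitution breaks it, by
design. Reported mitotype frequencies are renormalized over reliable calls
only. Species eligibility across a set of libraries: the species with the
top overall read total, plus any species with ≥ 10 reads in at least two
libraries.

## The synthetic generator (synthetic_data)

The generator emulates the composition a real honey library shows: a
dominant planthopper species with a two-mitotype mixture, minor aphid
species, and a honey-bee background, with default community fractions
(0.65, 0.15, 0.08, 0.04, 0.04, 0.04), mitotype split 85/15 and host
fraction 0.7 in the default pipeline run. Reference fixtures plant one
concrete realization of the degenerate primer sites (a real template has
plain bases there) around species inserts derived from a common ancestor;
inter-species amplicon identity is verified < 0.97 (so species-level
assignment is well-posed at the 97% threshold) and within-species mitotypes
differ at 1–3 sites (identity ≥ 0.97). The default insert of 97 nt gives a
139 bp product, inside the 135–140 bp target range.

Reads cover the full product, primers included, as fragment-ligation
libraries of a short amplicon would; strand is randomized at 0.5. The error
model applies per-base substitutions (default 0.005) and per-base indels
(default 0.005) whose rate is multiplied (default ×3) inside homopolymer
runs ≥ 3 — the Ion-Torrent-like error mode. Defaults are this package's
choices of a realistic regime, not measured values from any particular run.
Per-base qualities are Normal(28, 3) clamped to [2, 40] and are independent
of the planted errors — a stated simplification: quality-aware trimming is
exercised by constructed reads in the tests, not by the simulator.
Everything draws from one `numpy.random.Generator`, so fixtures and whole
pipeline runs are bit-reproducible per seed.

What passing synthetic tests does *not* show about real data: no chimeras,
PCR duplicates, barcode/adapter artefacts, quality-correlated errors,
template-specific amplification bias, or incomplete reference databases —
the dominant real-world failure mode (a species missing from the reference
set) is out of the generator's scope by construction.

## Validation choices and problem sizes

The package's acceptance checks (tests/test_acceptance.py and
scripts/acceptance.py) run at sizes chosen to make sampling error small
while keeping the whole suite fast on one CPU: 500 random pairs ≤ 60 nt for
banded-vs-full-DP oracle agreement; 10,000 reads for the zero-error round
trip (100% species recovery, exact host partition) and for community
recovery at 1% substitution error (within 3 multinomial SE of the spec);
5,000 reads for the 85/15 mitotype mixture (within 3 SE of realized truth);
100 seeded replicates of 2,000 single-mitotype reads at 0.5% substitution
error for the reliability filter (≥ 95 replicates with zero spurious
reliable calls); and a 19-haplotype panel built with exactly 11 distinct
insert patterns for the projection check.

## Known limitations

- Identity counts gap columns as mismatches; tools that ignore end gaps or
  use affine gap costs will report slightly different identities near the
  97% threshold for indel-containing reads.
- The LCA tie-break only consults genus and family; ties across families
  are reported unassigned rather than at suborder/order rank.
- `primer_mismatch_report` is a computational analog of primer-efficiency
  ranking (minimum mismatch counts), not a thermodynamic or qPCR
  efficiency model.
- The count-table loader infers rank from name suffixes (" sp.", " spp."),
  which suits survey-style tables but not arbitrary taxonomies.
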