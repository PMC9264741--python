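# Methods

## Composition metrics and the NucleScore

All metrics operate on the raw tallies of a sequence set: counts of A, T,
G, C after uppercasing, a separate tally of every other non-whitespace
character ("ambiguous": N, IUPAC codes, U, gaps), and the total length
(unambiguous + ambiguous). Tallies are additive, so assembly-level
statistics are computed on merged counts and are invariant under any
re-partitioning of an assembly into records and any shuffling of
characters — composition is all that matters.

With A, T, G, C the unambiguous counts:

- **GC%** = (G+C)/(A+T+C+G) × 100. Ambiguous characters are excluded from
  numerator and denominator.
- **AT/GC** = (A+T)/(G+C); undefined when G+C = 0.
- **nuc%** = nuc/(A+T+C+G) × 100 for each base; the four values sum to 100.
- **Var** = variance of the four nuc% values. The four percentages are the
  entire population of interest, so the *population* variance (divisor 4)
  is used; the module constant `seqstats.VARIANCE_DDOF` flips this to the
  sample convention (divisor 3) if ever needed. For a perfectly uniform
  composition Var = 0.
- **NucleScore** = log2(Var × GC% × (AT/GC)³ / √length), with `length` the
  *total* assembly size including ambiguous characters — the score is a
  property of the whole assembly, and N-runs in scaffolded assemblies do
  contribute to its size term.

Two exact consequences used as test oracles: concatenating a sequence with
itself leaves every compositional term unchanged and doubles the length, so
the score drops by exactly log2(√2) = 0.5; and holding composition fixed,
the score strictly decreases with length.

Undefined values (AT/GC with G+C = 0; NucleScore when the ratio is undefined
or the log argument is ≤ 0, e.g. Var = 0) are carried as `None` and rendered
as `NA` in reports. The tool is report-oriented: one degenerate assembly in
a batch must not abort the batch. Reports print metrics to 3 decimals; full
precision is kept internally.

The score is deliberately simple and has known limits: compositionally
similar species (e.g. *Escherichia coli* vs *Salmonella enterica*) produce
overlapping bands, so it is a screening aid, not a classifier.

## Formats

FASTA and GenBank parsing is delegated to Biopython. FASTA *writing* is a
small local routine that emits `>` + the stored description verbatim and
wraps at a configurable width (default 70), which guarantees byte-exact
write→read→write round-trips — a property the tests rely on and that
generic writers (which re-derive the title from id + description) do not
provide. Gzip payloads are detected by magic bytes, not by file extension.

NCBI `assembly_summary.txt` files are parsed by locating the last `#`
comment line as the header and resolving columns **by name**, so the parser
survives column reordering and added trailing columns across NCBI releases.
Rows with unparsable release dates are kept with a null date (they are
excluded only by date filters); rows with `ftp_path` "na" are kept but
flagged non-downloadable.

GenBank metadata extraction reads only the header annotations, the
reference blocks (PubMed IDs, de-duplicated in first-seen order) and the
`source` feature's qualifiers. The isolation country is taken from
`/country`, falling back to `/geo_loc_name` — INSDC renamed the qualifier,
and files in the wild use either; `/country` wins when both are present.
Multi-entry files are summarized per assembly by taking the first defined
value of each single-valued field and the union of PubMed IDs.

## Query filtering and component separation

Index filters compose as a conjunction: case-insensitive substring match of
the species pattern against the organism name (an exact-match flag exists),
taxid matching either the strain-level or species-level taxid, an
*inclusive* minimum release date, and exact assembly-level match. Survivors
are stable-sorted by accession before truncation to the requested count, so
the same index always yields the same result set.

Records are classified from their FASTA headers by ordered, case-insensitive
keyword rules: `plasmid` → plasmid, else `chromosome` or `complete genome` →
chromosome, else other. The plasmid rule runs first because plasmid headers
routinely also contain "complete sequence"/"complete genome". Separation is
a partition: every record lands in exactly one class, order preserved, and
per-class FASTA files are written only for non-empty classes the caller
asked for. Classification from headers is a heuristic; headers that name
their molecule unconventionally land in "other" rather than being guessed.

## Alignment tools

Difference matrices compare uppercased characters literally, column by
column: a gap versus a base is one difference, as is any base mismatch —
counts are plain "differences in bp" with no evolutionary correction.
Percent identity is (columns − differences)/columns × 100, reported to 2
decimals. An optional mode excludes columns with a gap in either member of
a pair, in which case the identity denominator is the number of compared
columns (a pair with no gap-free columns reports 100). Column stripping
removes every column where the target character occurs in *any* record —
per-sequence deletion would break the alignment — making it an idempotent,
pure column projection whose output is free of the character.

## Repository access

All URL builders are pure functions over a single endpoint-configuration
record (NCBI genomes root, ENA browser/portal roots, SRA run-info root), so
mirrors can be substituted wholesale. The only operations that perform I/O
are the ENA filereport lookup and plan execution, and both go through an
injectable transport (default: urllib with a 60 s timeout, 3 retries,
exponential backoff). Downloads are written atomically (temp file + rename)
under destinations that are validated never to escape the output root.
FASTQ files are stored compressed as fetched; the package does not parse
FASTQ content. ERR, SRR and DRR run accessions are all accepted.

## Synthetic data

The fixture module generates every input the suite consumes. Sequences are
drawn i.i.d. from a target (A, C, G, T, N) composition; alignments are a
random reference plus copies mutated independently per column (substitution
always to a *different* base, so a rate of 1 guarantees a difference), with
optional gap columns. Fixture assemblies bundle a FASTA whose headers
invert the component classifier, a Biopython-written GenBank flat file with
planted provenance qualifiers (either geography dialect), and an index row
whose ftp_path points under a reserved `.invalid` host that the in-memory
stub transport serves.

The default study index holds ten assemblies with fixed organisms, levels
and release dates (only nucleotide content varies with the seed): four
*E. coli* (two Complete Genome ≥ 2019, one older, one Contig with no FTP
path), two *S. enterica*, two *K. pneumoniae*, one *S. aureus*, one
*B. subtilis*. Composition profiles roughly mirror each species' real GC
content. Record lengths default to 5 kb (tests use 0.4–2 kb) — orders of
magnitude below real genomes, chosen so the whole pipeline runs in seconds;
since every statistic is a pure function of counts, scale affects only the
sampling noise of the fixture compositions, not any code path.

What the synthetic data does *not* emulate: real genomic long-range
structure (repeats, skew along the replichore), realistic header zoo,
malformed index rows beyond the planted cases, and network behaviour
(latency, partial responses). Passing tests therefore demonstrate parser
and pipeline correctness and the metrics' mathematical properties, not
robustness to every artefact of live repository data.

## Numerical and design notes

- Sequences are uppercased; whitespace is ignored; `U` counts as ambiguous
  (this is a DNA tool).
- Tolerances: metric identities are asserted to 1e-9 relative; TSV output
  rounds to 3 decimals (identity matrices to 2).
- Dates on the command line are strictly ISO `YYYY-MM-DD`; the index's
  internal `YYYY/MM/DD` is normalized at parse time.
- Exit status 0 includes queries matching zero assemblies (a warning is
  logged) so shell scripts can distinguish "nothing matched" from failures.
- The live per-species score-band survey depends on assemblies currently in
  RefSeq, which change over time; scores are expected in or near the
  published bands, and the check allows a ±0.5 margin around them.
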