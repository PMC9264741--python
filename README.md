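# seqinfo

Retrieve genome assemblies and their metadata from public sequence
repositories, compute nucleotide composition statistics — including the
**NucleScore**, a composition-only species fingerprint — and post-process
multi-FASTA alignments.

`seqinfo` is aimed at microbiologists, students and database curators who
want a programmatic (or one-line shell) way to:

- query NCBI **GenBank**/**RefSeq** assembly indexes by species name, taxonomy
  ID, release date and assembly level, and download the matching genomic
  FASTA/GenBank files;
- fetch sequence records from **ENA** by accession and FASTQ files by run
  accession (ERR/SRR/DRR), and run-info tables from SRA;
- separate each assembly's **chromosomes from plasmids** (and everything
  else) into per-class folders based on FASTA header keywords;
- mine provenance metadata — country of isolation, host, isolation source,
  collection date, strain, PubMed IDs — from GenBank flat files, handling
  both the `/country` and the newer `/geo_loc_name` qualifier;
- build per-assembly **TSV/HTML reports** joining composition statistics
  with that metadata;
- compute pairwise **difference (bp) and percent-identity matrices** for a
  multi-FASTA alignment, and strip alignment columns containing a given
  character (e.g. `-` or `N`).

## The statistics

For a sequence set with unambiguous nucleotide counts A, T, G, C (ambiguous
characters such as N are tallied separately and excluded from compositional
ratios):

```
GC%      = (G + C) / (A + T + C + G) × 100
AT/GC    = (A + T) / (G + C)
nuc%     = nuc / (A + T + C + G) × 100          for each of A, T, G, C
Var      = population variance of the four nuc% values
NucleScore = log2( Var × GC% × (AT/GC)³ / √length )
```

`length` is the total assembly size in bases **including** ambiguous
characters. The NucleScore condenses compositional skew and genome size into
one number; assemblies of the same bacterial species tend to fall in a narrow
band, which makes the score usable as a quick plausibility/quality screen
without a reference genome. Undefined values (G+C = 0, or a non-positive log
argument) are reported as `NA` rather than aborting a batch.

## Worked example

```python
from seqinfo import count_nucleotides, composition_stats, nucle_score

counts = count_nucleotides("AATGC")
print(nucle_score(counts))          # 12.14467024010303
```

For the 5-mer `AATGC`: GC% = 2/5 × 100 = 40, AT/GC = 3/2 = 1.5,
nuc% = (40, 20, 20, 20), Var = 75, so
NucleScore = log2(75 × 40 × 1.5³ / √5) ≈ 12.145.

A realistic run (from `examples/composition_and_nuclescore.py`, a synthetic
55 kb assembly with a GC-rich chromosome and an AT-rich plasmid) prints:

```
total length : 55000 bp
GC content   : 54.480 %
AT/GC ratio  : 0.836
nuc%         : A=22.700, T=22.820, G=27.522, C=26.958
variance     : 5.059
NucleScore   : -0.545
```

The same metrics are available from the shell, one TSV row per FASTA file:

```bash
seqinfo nuclescore genome1.fasta genome2.fasta.gz
```

## Command-line interface

```bash
# E. coli complete genomes from RefSeq released since 2019, plasmids separated
seqinfo fetch -d refseq -k bacteria -s "Escherichia coli" \
    -level "Complete Genome" -date 2019-01-01 -n 50 -c plasmid -o ecoli_out

# ENA records and FASTQ runs
seqinfo fetch -ena GCA_000195955,BN000065 -o ena_out
seqinfo fetch -fastq SRR7693912,SRR7693877 -o fastq_out

# alignment tools and SRA run info
seqinfo count-differences alignment.fasta -o matrices/
seqinfo remove-char alignment.fasta - -o stripped.fasta
seqinfo sra-runinfo SRR7693877,SRR9850824 -o runinfo/
```

`fetch` writes `<out>/<accession>/{assembly.fna, assembly.gbff,
assembly_report.txt, components/<class>/<class>.fasta, report.tsv}` plus a
combined `report.tsv` and `report.html`. Every network call goes through an
injectable transport, so the whole pipeline is testable offline against the
synthetic repository in `seqinfo.fixtures` (see
`examples/fetch_pipeline_offline.py`).

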