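"""Survey NucleScores of live RefSeq assemblies against published bands.

NEEDS NETWORK ACCESS to the NCBI genomes FTP site.  Downloads one
reference assembly per species, computes the assembly-level NucleScore
and compares it with the per-species bands reported for 50-genome
samples.  Scores of current assemblies are expected to fall in or near
those bands; the assembly sets have changed since the bands were
measured, so small excursions are normal.
"""

import gzip
import io

from seqinfo.repo_client import UrllibTransport
from seqinfo.formats import read_fasta
from seqinfo.seqstats import composition_stats

BANDS = [
    ("Staphylococcus aureus NCTC 8325",
     "https://ftp.ncbi.nlm.nih.gov/genomes/all/GCF/000/013/425/"
     "GCF_000013425.1_ASM1342v1/GCF_000013425.1_ASM1342v1_genomic.fna.gz",
     4.655, 4.768),
    ("Klebsiella pneumoniae HS11286",
     "https://ftp.ncbi.nlm.nih.gov/genomes/all/GCF/000/240/185/"
     "GCF_000240185.1_ASM24018v2/GCF_000240185.1_ASM24018v2_genomic.fna.gz",
     0.140, 0.195),
    ("Escherichia coli K-12 MG1655",
     "https://ftp.ncbi.nlm.nih.gov/genomes/all/GCF/000/005/845/"
     "GCF_000005845.2_ASM584v2/GCF_000005845.2_ASM584v2_genomic.fna.gz",
     0.978, 1.125),
]

transport = UrllibTransport(timeout=60.0, retries=2)
for name, url, lo, hi in BANDS:
    payload = transport.fetch(url)
    records = read_fasta(io.BytesIO(gzip.decompress(payload)))
    stats = composition_stats(records)
    verdict = "in band" if lo <= stats.nucle_score <= hi else "outside band"
    print(
        f"{name}: NucleScore={stats.nucle_score:.3f} "
        f"(published band [{lo}, {hi}] -> {verdict}); "
        f"GC%={stats.gc_content:.2f}, length={stats.total_length} bp"
    )
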