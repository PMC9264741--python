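"""Compute composition statistics and the NucleScore for a small genome.

Builds a synthetic two-record assembly (a GC-skewed chromosome plus a
short plasmid), then prints the five composition metrics.  The
NucleScore condenses composition skew and genome size into one number:
assemblies of the same species tend to land in a narrow band.
"""

from seqinfo.fixtures import gen_sequence
from seqinfo.seqstats import composition_stats

# composition is (A, C, G, T, ambiguous): a GC-rich chromosome, an AT-rich plasmid
chromosome = gen_sequence(50_000, composition=(0.22, 0.28, 0.28, 0.22, 0.0), seed=42)
plasmid = gen_sequence(5_000, composition=(0.30, 0.20, 0.20, 0.30, 0.0), seed=43)

stats = composition_stats([chromosome, plasmid])

print(f"total length : {stats.total_length} bp")
print(f"GC content   : {stats.gc_content:.3f} %")
print(f"AT/GC ratio  : {stats.at_gc_ratio:.3f}")
print("nuc%         : " + ", ".join(
    f"{b}={p:.3f}" for b, p in zip("ATGC", stats.nuc_pct)
))
print(f"variance     : {stats.variance:.3f}")
print(f"NucleScore   : {stats.nucle_score:.3f}")
print()
print("GC% is the share of G+C among unambiguous bases; the variance is the")
print("spread of the four per-base percentages; the NucleScore is")
print("log2(Var * GC% * (AT/GC)^3 / sqrt(length)) — a composition-only")
print("species fingerprint (larger skew => larger score, longer genome =>")
print("slightly smaller score).")
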