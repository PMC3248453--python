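"""Aggregate a per-genome census table: group means and medians.

Uses the published functional-element counts of the eight Basidiomycota
genomes as a complete worked group."""

from ltrcensus import aggregate
from ltrcensus.census import BASIDIOMYCOTA_FUNCTIONAL_COUNTS, CensusRow

rows = [CensusRow(genome_id=g, phylum="Basidiomycota",
                  total_elements=n, functional_elements=n)
        for g, n in BASIDIOMYCOTA_FUNCTIONAL_COUNTS.items()]
(stats,) = aggregate(rows, column="functional_elements")

for g, n in BASIDIOMYCOTA_FUNCTIONAL_COUNTS.items():
    print(f"  {g:<32} {n:>5}")
print(f"n={stats.n_genomes}  mean={stats.mean:.1f}  median={stats.median:.1f}")
print("The mean (606.5) is pulled far above the median (277.5) by the "
      "Postia placenta expansion — the uneven-distribution signature that "
      "makes the median the better typical-genome summary.")
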