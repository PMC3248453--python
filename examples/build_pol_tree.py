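"""Concatenated pol-domain phylogeny of most-successful elements.

Aligns RT, INT, RH and AP across the winners of four simulated genomes,
trims gappy columns, concatenates, computes Poisson-corrected distances,
builds a neighbor-joining tree and roots it on the packaged Bel/Pao-like
outgroup."""

from ltrcensus import SimulationConfig, implant_elements
from ltrcensus.pipeline import (annotate_genome, build_pol_tree,
                                extract_domain_proteins, genome_census)

winners = {}
for seed in (1, 2, 3, 4):
    config = SimulationConfig(background_len=250_000, copies_per_template=4,
                              seed=seed)
    genome, _ = implant_elements(config)
    elements = annotate_genome(genome)
    _row, _fams, mse = genome_census(elements, genome_id=f"genome{seed}")
    if mse is None:
        continue
    winner = next(e for e in elements if e.element_id == mse.element_id)
    winners[f"genome{seed}"] = extract_domain_proteins(winner)

tree, msa = build_pol_tree(winners)
print(f"{len(winners)} ingroup winners + outgroup; concatenated alignment "
      f"of {msa.n_columns} columns over {len(msa.taxa)} taxa")
print(tree.newick())
print("The outgroup sits on its own side of the root; ingroup elements "
      "cluster by the template lineage their genome was invaded by.")
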