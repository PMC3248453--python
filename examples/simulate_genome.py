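"""Simulate a fungal-like genome with implanted LTR retrotransposons.

Generates a 300 kb background carrying intact copies of one Ty1/Copia and
one chromoviral Ty3/Gypsy template, then prints the ground truth that the
detector and classifier are later scored against.
"""

from ltrcensus import SimulationConfig, default_templates, implant_elements

config = SimulationConfig(background_len=300_000, copies_per_template=5, seed=1)
genome, truth = implant_elements(config)

contig = config.contig_name
print(f"genome: {len(genome[contig]):,} nt on one contig "
      f"({config.background_len:,} nt background + implants)")
print(f"{len(truth)} implanted copies:")
for r in truth[:6]:
    print(f"  {r.contig}:{r.start}-{r.end} {r.template_id:<12} "
          f"state={r.state} strand={r.strand}")
print("  ...")
print("Each row is one insertion: its exact span, source template, "
      "degradation state and strand — the detector must rediscover these "
      "coordinates from sequence alone.")
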