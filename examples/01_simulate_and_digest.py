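"""Simulate a viewpoint 3C locus and digest it in silico.

Builds the default 500 kb synthetic locus (viewpoint at the midpoint, three
planted loop partners at -184 kb, +50 kb and +146 kb), digests it with
EcoRI (G^AATTC), and shows where the viewpoint and loop partners landed.
"""

from ste3c import SimulationConfig, digest, simulate_locus

cfg = SimulationConfig(seed=1)
sequence, truth = simulate_locus(cfg)
fragments = digest(sequence, cfg.motif, cfg.cut_offset, cfg.chrom)

print(f"locus: {len(sequence):,} bp, {len(truth['motif_positions'])} EcoRI sites, "
      f"{len(fragments)} fragments")
print(f"viewpoint fragment: {truth['viewpoint']['fragment_id']}")
for loop in truth["loops"]:
    print(f"planted loop partner at {loop['position']:,} bp "
          f"(x{loop['enrichment']:.0f} enrichment) -> fragment {loop['fragment_id']}")

# Each planted partner sits on its own ~6 kb fragment, mirroring the few-kb
# tethering-element fragments a real screen would genotype; the remaining
# fragments form the 39-fragment screen panel.
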