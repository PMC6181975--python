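"""Test boundary colocalization and looping selectivity.

Do called loop anchors sit at chromatin-domain boundaries more often than
chance (permutation test), and is looping selective among the many
insulator-bound candidate sites (hypergeometric test)?
"""

from ste3c import SimulationConfig, classify_sites, coloc_permutation, digest, selectivity_test
from ste3c.simulate import simulate_locus

cfg = SimulationConfig(seed=1)
sequence, truth = simulate_locus(cfg)
fragments = digest(sequence, cfg.motif, cfg.cut_offset, cfg.chrom)
by_id = {f.id: f for f in fragments}

called_ids = [l["fragment_id"] for l in truth["loops"]]  # ground-truth loop fragments
anchors = [(by_id[i].start, by_id[i].end) for i in called_ids]
boundaries = truth["domain_boundaries"]["H3K9me3"]

res = coloc_permutation(anchors, boundaries, cfg.locus_length,
                        tolerance_bp=5_000, n_permutations=999, seed=1)
print(f"{res.observed_overlap}/{res.n_boundaries} boundaries carry a loop anchor "
      f"within {res.tolerance_bp / 1000:.0f} kb; null mean {res.null_mean:.2f}, "
      f"empirical p = {res.empirical_p:.3f}")

tested = [f for f in fragments if f.id != truth["viewpoint"]["fragment_id"]]
sel = selectivity_test(cfg.insulator_sites, set(called_ids), tested)
print(f"{sel.n_called_among_candidates} of {sel.n_candidate_sites} insulator-bound "
      f"tested fragments loop with the viewpoint "
      f"(of {sel.n_tested_fragments} tested): P[X >= k] = {sel.hypergeometric_p:.4f}")

for site in cfg.insulator_sites[:4]:
    print(f"site {site.start}-{site.end}: proteins {site.proteins} "
          f"-> class {sorted(classify_sites(site.proteins))}")
# A small p in both tests says anchors concentrate at boundaries, yet only a
# minority of similarly bound sites loop: binding alone does not determine looping.
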