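"""Plastid-transfer detection, HGT screening, and nuclear copies.

The recipient carries a 350 bp insert copied from its own plastome, a
700 bp tract copied from a foreign order's mitogenome, and has lost one
gene whose diverged copy sits in the nuclear genome.
"""

from mitoscreen import SimConfig, build_recipient_genome, \
    simulate_nuclear_genome, simulate_reference_set
from mitoscreen.transfers import (classify_transfer, intergenic_order_screen,
                                  nuclear_copy_search, place_region,
                                  plastid_hit_screen)

cfg = SimConfig(seed=19, genome_length_bp=15_000, n_genes=7,
                mtpt_spec=[("self_plastome", 350)],
                hgt_spec=[("Order_3", 700, False)],
                missing_genes=["nad7"],
                nuclear_copy_spec=[("nad7", 72.0, True)])
panel = simulate_reference_set(cfg)
genome, truth = build_recipient_genome(cfg, panel)

plastomes = {f"{o}_plastome": panel.plastome(o) for o in panel.orders}
own = panel.plastome(cfg.focal_order, label="recipient|plastome")
plastomes["own_plastome"] = own

regions = plastid_hit_screen(genome, list(plastomes.values()),
                             truth.gene_features)
for r in regions:
    seq = genome.sequence[r["start"]:r["end"]]
    placement = place_region(seq, plastomes, "own_plastome", seed=19)
    call = classify_transfer(r, placement, own, [], truth.gene_features,
                             mito=genome)
    print(f"plastome-hit region {r['start'] + 1}..{r['end']} "
          f"({r['length_bp']} bp, identity "
          f"{r['identity_range'][0]:.0f}-{r['identity_range'][1]:.0f}%) "
          f"-> {call.category}: {call.evidence[0]}")

refs = {o: [panel.ref_mitogenome(f"{o}|taxon_1")] for o in panel.orders}
tracks, cands, pct = intergenic_order_screen(genome, refs, cfg.focal_order)
print(f"\norder-level screen: {len(cands)} HGT candidate(s), "
      f"{pct:.2f}% of the genome")
for c in cands:
    print(f"  {c.region[0] + 1}..{c.region[1]} ({c.length_bp} bp): "
          f"{c.evidence[0]}")

nuclear = simulate_nuclear_genome(cfg, panel, truth)
missing = {g: panel.gene_sequences["Order_1|taxon_1"][g]
           for g in cfg.missing_genes}
for rec in nuclear_copy_search(missing, [nuclear]):
    print(f"\nnuclear copy of {rec['gene']}: found={rec['found']}, "
          f"{rec['copy_length_bp']} bp at "
          f"{rec['identity_percent']:.0f}% identity, "
          f"intact ORF: {rec['orf_intact']}")
# "intracellular" = own-lineage plastome-to-mitogenome transfer; an
# "HGT_candidate" tract is matched by a foreign order but not by the
# recipient's own order.
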