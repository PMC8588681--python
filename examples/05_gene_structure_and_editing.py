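"""Split-gene layout, trans-splicing read support, and C-to-U editing.

The recipient's ccmFc-like gene is split across three loci (a large 5'
portion of exon 1; the 3' end of exon 1; exon 2 on the opposite strand).
Transcript reads support splicing of the 3' exon-1 piece to exon 2 but
never join the two portions of exon 1.
"""

from mitoscreen import SimConfig, build_recipient_genome, \
    simulate_reference_set, simulate_transcript_reads
from mitoscreen.annotate import (GeneModel, detect_split_gene,
                                 junction_support, merge_edit_sites,
                                 observe_edit_sites, predict_edit_sites)
from mitoscreen.simulate import translate

cfg = SimConfig(seed=13, genome_length_bp=16_000, n_genes=8,
                gene_length_codons=(200, 350), subst_rate_per_branch=0.04,
                transsplice_gene="ccmFc", n_edit_sites=12,
                transcript_depth=40)
panel = simulate_reference_set(cfg)
genome, truth = build_recipient_genome(cfg, panel)

ref = panel.gene_sequences["Order_1|taxon_1"]["ccmFc"]
model = detect_split_gene("ccmFc", ref, genome, min_separation_bp=1500)
print("ccmFc pieces:", [(iv, s) for iv, s in model.exon_loci])
print("intron layout:", model.intron_layout, "|", "; ".join(model.notes))

reads = simulate_transcript_reads(genome, truth, cfg)
ts = truth.true_transsplice_layout
split_model = GeneModel(gene="ccmFc",
                        exon_loci=[(iv, s) for _, iv, s in ts["pieces"]],
                        intron_layout=["trans", "trans"],
                        completeness="fragmented")
for rec in junction_support(split_model, genome, reads):
    print(f"junction {rec['junction']}: {rec['n_pairs']} read pairs, "
          f"{rec['n_split_reads']} split reads")

gene = truth.provenance["edit_gene"]
feat = next(f for f in truth.gene_features if f.gene == gene)
homologs = [translate(panel.gene_sequences[t][gene])[:-1]
            for t in panel.taxa]
predicted = predict_edit_sites(feat.extract(genome), homologs, feature=feat)
em = GeneModel(gene=gene, exon_loci=[(feat.intervals[0], feat.strand)])
observed = observe_edit_sites(genome, em, reads)
merged = merge_edit_sites(predicted, observed)
both = sum(s.status == "both" for s in merged)
print(f"\nediting in {gene}: {len(truth.true_edit_sites)} sites planted, "
      f"{len(predicted)} predicted, {len(observed)} observed, "
      f"{both} supported by both")
# Junction 1 joins the two halves of exon 1 (no transcript should bridge
# it); junction 2 is the trans-spliced intron (read pairs should bridge it).
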