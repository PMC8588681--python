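"""Dispersed/tandem repeats and the long-read recombination proxy.

Plants one 700 bp repeat pair, simulates long reads in which 30% of the
repeat-spanning reads are crossover products, and estimates that fraction
back by phasing each spanning read's flanks to the repeat copies.
"""

from mitoscreen import SimConfig, build_recipient_genome, \
    simulate_long_reads, simulate_reference_set
from mitoscreen.repeats import (dispersed_repeats, long_repeats,
                                repeat_activity, repeat_content,
                                tandem_repeats)

cfg = SimConfig(seed=11, genome_length_bp=12_000, n_genes=4,
                include_rrn=False, repeat_spec=[(700, 96.0, 2)],
                recomb_fraction=0.30, spanning_reads_per_repeat=200)
panel = simulate_reference_set(cfg)
genome, truth = build_recipient_genome(cfg, panel)

pairs = dispersed_repeats(genome)
for rp in pairs:
    print(f"{rp.repeat_id}: {rp.length_bp} bp at "
          f"{rp.identity_percent:.1f}% identity, {rp.strand_relation}, "
          f"copies {rp.copy_a} / {rp.copy_b}")
print(f"dispersed repeat content: {repeat_content(pairs, genome):.2f}% "
      "(union of both copies over the genome)")
print(f"tandem arrays: {len(tandem_repeats(genome))}")

reads = simulate_long_reads(genome, truth, cfg)
(long_pair,) = long_repeats(pairs)
act = repeat_activity(long_pair, reads, genome, sample_cap=200, seed=11)
print(f"\nspanning reads: {act.n_spanning_reads}; sampled {act.n_sampled}")
print(f"congruent {act.n_congruent}, incongruent {act.n_incongruent}, "
      f"ambiguous {act.n_ambiguous}")
print(f"estimated recombinational activity: {act.activity_percent:.1f}% "
      f"(simulated crossover fraction was "
      f"{100 * cfg.recomb_fraction:.0f}%)")
# The activity percentage is the proportion of classified spanning reads
# whose two flanks phase with different repeat copies - the crossover proxy.
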