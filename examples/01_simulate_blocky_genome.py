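"""Simulate a patchwork genome: alternating AT-rich and GC-rich blocks.

Builds a two-chromosome, 4 Mb genome with the standard composition
(AT-rich blocks: peak GC 25%, mean ~25.7 kb, filled with RIP-mutated
nested repeats; GC-rich blocks: peak GC 52%, mean ~55.3 kb, carrying
genes and occasional MITEs) and prints what was planted.
"""

from patchwork import synthetic as syn

plan = syn.default_block_plan(n_chromosomes=2, genome_size=4_000_000, seed=0)
res = syn.generate_blocky_genome(plan, seed=0)

blocks = res.blocks
at = blocks[blocks["kind"] == "AT"]
gc = blocks[blocks["kind"] == "GC"]
print(f"genome: {res.genome.total_length():,} bp over {len(res.genome)} chromosomes")
print(f"AT blocks: {len(at)}, mean {((at['end'] - at['start']).mean() / 1e3):.1f} kb, "
      f"mean GC {at['realized_gc'].mean():.3f}")
print(f"GC blocks: {len(gc)}, mean {((gc['end'] - gc['start']).mean() / 1e3):.1f} kb, "
      f"mean GC {gc['realized_gc'].mean():.3f}")
print(f"repeat fragments: {len(res.repeats)} "
      f"({res.repeats['copy_id'].nunique()} copies, "
      f"{len(res.interruptions)} nested interruptions)")
print(f"genes: {len(res.genes)} (GC blocks only)")
mites = res.repeats[res.repeats["repeat_class"] == "MITE"]
print(f"MITE copies near genes: {len(mites)}")
# Realized GC tracks the per-block targets, repeats sit only in AT blocks,
# and the interruption log is the ground truth later stages must recover.
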