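"""RIP statistics, TpA masking, nesting and invasion dating.

The RIP index (CpA+TpG)/(ApC+GpT) quantifies repeat-induced point
mutation: C->T hypermutation at CpA leaves affected copies below ~0.9.
Terminal fork branch lengths (cherries) of a within-family tree estimate
time since each family last integrated a copy.
"""

from patchwork import synthetic as syn
from patchwork.io_formats import tree_from_string
from patchwork.rip import (
    family_medians,
    mask_tpa,
    nesting_interruptions,
    rip_profile,
    terminal_fork_lengths,
)

plan = syn.default_block_plan(n_chromosomes=2, genome_size=4_000_000, seed=0)
res = syn.generate_blocky_genome(plan, seed=0)

profile = rip_profile(res.repeats, res.genome, res.blocks)
copies = profile[profile["target_type"] == "copy"]
frac_ripped = (copies.loc[copies["defined"], "rip_index"] < 0.9).mean()
print(f"repeat copies with RIP index < 0.9: {frac_ripped:.1%} of {len(copies)}")
print("family median RIP indices:")
print(family_medians(profile).round(3).to_string())

edges = nesting_interruptions(res.repeats)
print(f"\nnested interruption events: {len(edges)} "
      f"(e.g. {edges.iloc[0]['interrupted_family']} interrupted by "
      f"{edges.iloc[0]['interrupting_family']})")

# TpA masking before tree estimation removes CpA->TpA RIP products
aln = {"copy1": "CATAGG-TA", "copy2": "CGTAGGATA"}
print("\nmasked alignment:", mask_tpa(aln))

# terminal forks: the cherry (A,B) dates the most recent duplication
tree = tree_from_string("((A:0.01,B:0.012):0.3,(C:0.25,D:0.31):0.05);")
forks = terminal_fork_lengths(tree)
print(f"terminal fork lengths: {sorted(float(x) for x in forks)} "
      "(short forks = recent integration)")
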