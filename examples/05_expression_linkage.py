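"""Linking genome architecture to expression.

Plants known signals — shared per-TAD expression effects, a gene class
2.32x as likely near AT blocks, MITEs threefold enriched near the most
up-regulated genes — and shows each statistic recovering its input.
"""

import numpy as np

from patchwork import linkage as lk
from patchwork import synthetic as syn

plan = syn.default_block_plan(n_chromosomes=4, genome_size=12_000_000, seed=5)
res = syn.generate_blocky_genome(plan, seed=5, mite_near_gene_rate=0.05)
gc_blocks = res.blocks[res.blocks["kind"] == "GC"].reset_index(drop=True)
tads = gc_blocks[["chrom", "start", "end"]].copy()
tads["tad_id"] = [f"{c}.{i}" for i, c in enumerate(tads["chrom"])]
mites = res.repeats[res.repeats["repeat_class"] == "MITE"]

# 1. TAD co-regulation: shared per-TAD effects of sd 0.6 LFC units
p = syn.ExpressionSimParams(tad_effect_sd=0.6, residual_sd=1.0, seed=5)
sim = syn.simulate_expression(res.genes, tads, None, p)
model = lk.tad_coregulation_model(sim.table, repeats=res.repeats, genome=res.genome)
est = model.table.set_index("tad_id")["estimate"]
common = est.index.intersection(sim.tad_effects.index)
r = np.corrcoef(est[common], sim.tad_effects[common])[0, 1]
print(f"TAD co-regulation: delta-AIC = {model.delta_aic:.1f} over "
      f"{model.n_genes} genes; planted-vs-estimated effect r = {r:.2f}")
print(f"TADs significant at FDR 0.01: {int(model.table['significant'].sum())}")

# 2. proximity odds ratio: class planted at OR 2.32 within 5 kb of AT blocks
labels = syn.plant_proximity_class(res.genes, res.blocks, odds_ratio=2.32,
                                   base_rate=0.12, seed=6)
orres = lk.proximity_odds_ratio(res.genes, (labels != "").to_numpy(), res.blocks)
print(f"\nproximity: OR = {orres.odds_ratio:.2f} "
      f"[{orres.ci_low:.2f}, {orres.ci_high:.2f}] (planted 2.32)")

# 3. MITEs planted threefold near the top-20% up-regulated genes
p2 = syn.ExpressionSimParams(residual_sd=1.0, n_de_fraction=0.2, mite_fold=3.0, seed=7)
sim2 = syn.simulate_expression(res.genes, None, mites, p2)
me = lk.mite_enrichment(mites, res.genes, sim2.table, top_fraction=0.2)
print(f"\nMITE within 2 kb: {me.frac_de:.1%} of top-20% genes vs "
      f"{me.frac_other:.1%} of others; pooled fold = {me.pooled_fold:.2f} (planted 3)")

# 4. 6mA: uniform-rate calls are evenly split between compartments
calls = syn.simulate_mod_calls(res.genome, res.blocks, seed=8)
m6a = lk.methylation_summary(calls, res.blocks, res.genes, res.genome)
f = m6a["fraction_modified"]
print(f"\n6mA: {f['AT']:.3%} of adenines in AT blocks, {f['GC']:.3%} in GC blocks")
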