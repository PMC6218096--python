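# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish.

## The genome model

The package targets genomes organised as alternating blocks of two
sequence classes: AT-rich blocks (peak GC ≈ 25%, mean length ≈ 25.7 kb,
sd ≈ 25.5 kb) that are almost entirely degenerate transposon copies, and
GC-rich blocks (peak GC ≈ 52%, mean length ≈ 55.3 kb, sd ≈ 74.7 kb) that
carry essentially all genes. These composition parameters are the defaults
of `synthetic.default_block_plan` and of every simulation in the test and
acceptance suites. Block lengths are drawn log-normal with the stated
mean/sd (only a mean and sd are available, and lengths must stay
positive); chromosomes begin and end with a GC block, mimicking gene-rich
subtelomeres.

Block sequences are composed with *exact* base counts for the GC target
(a random multiset permutation), so a block's realized GC equals its
target up to one base. AT blocks are filled to ~85% with repeat copies:
each copy is a family reference mutated by the RIP model at a per-copy
rate drawn uniformly from [0.4, 0.9], spliced into filler whose GC is
solved so that the whole block still lands on the composition target.
Insertions that land inside an earlier copy split it into linked
fragments and are logged; this log is the ground truth for the nesting
analysis. MITE copies are placed upstream of a configurable fraction of
genes in GC blocks and are not RIP-mutated, matching the observation that
short elements escape RIP.

## RIP

RIP is modelled as C→T at the target dinucleotide (default CpA) and,
independently at the same rate, G→A at its reverse complement (TpG) —
the two-strand symmetric version matching the symmetric index numerator.
Targets are located on the input sequence and mutated simultaneously, so a
mutation cannot create or destroy a target within one pass. The RIP index
is the dinucleotide ratio (CpA+TpG)/(ApC+GpT) with overlapping (step-1)
dinucleotide counting and N-containing dinucleotides excluded; an
all-zero denominator marks the record undefined rather than producing an
infinity. For copies fragmented by nested insertions the index is computed
by summing per-fragment counts, which concatenates the copy in genomic
order while excluding junction-spanning dinucleotides — those never
existed as contiguous sequence. An iid sequence has E[I] ≈ 1 regardless of
GC content, which is what makes the 0.9 threshold usable across
compartments; the RIP simulation drives I down through both the CpA→TpA
loss in the numerator and the GC→GT gain in the denominator.

TpA→NN masking scans each gap-stripped aligned sequence against its
*original* characters and maps hits back to alignment columns, so
overlapping TpAs cannot cascade and alignment length is preserved.

Terminal forks default to cherry mode: only tips whose sibling is also a
tip contribute (both branch lengths). An `all-tips` mode exists because
the term can be read either way; cherries are the stricter reading.

## Segmentation

Window GC (default 1 kb) is fitted with a two-component Gaussian mixture
(EM, three restarts); windows are classified at equal posterior and
same-class runs merged. Runs shorter than `min_block_len` (default 2 kb)
are flipped into their flanking class, shortest first — processing order
makes the AT-interval count monotone in `min_block_len`. Windows that are
mostly N are imputed with their chromosome's mean GC before fitting. If
the two component means are closer than `min_separation` (default 0.08,
about half the AT/GC peak gap) the distribution is treated as unimodal:
the whole genome is labelled GC and the result flagged rather than
inventing blocks. With 1 kb windows the two planted peaks are ~20 within-
window standard deviations apart, which is why planted-block recovery is
essentially perfect; the hard cases in real data are windows mixing both
classes at block edges, which is why boundary accuracy is only claimed to
one window.

## Hi-C

*Mappability.* A position is masked when the 80-mer starting there is not
unique in the genome (either strand), computed from 64-bit polynomial
k-mer hashes — collisions are astronomically unlikely rather than
impossible, a deliberate trade for linear-time masking without an aligner.
Positions too close to a chromosome end to start a full read are masked.

*Matrix.* Pairs with either end below MAPQ 30 or on a masked position are
dropped (the accounting input = kept + excluded is preserved in
`stats`); counts are accumulated symmetrically at 5 kb with self-bin pairs
on the diagonal once.

*Balancing.* Square-root iterative correction: each iteration divides
rows and columns by the square root of their mean-normalized marginal;
convergence is the coefficient of variation of nonzero marginals falling
below `tol` (default 1e-5). Zero-coverage bins are excluded from the
iteration and re-inserted as zeros. The balanced fixed point is unique up
to global scale, which is how the tests compare it against an explicit
50-iteration reference.

*Distance decay.* Mean contact per log-spaced distance bin (growth 1.2,
default range [2×bin, 1 Mb]) regressed on distance in log-log space. The
bin representative is computed self-consistently: x_b = (mean s^α)^(1/α)
with α re-estimated until fixed point, so an exactly power-law input is
recovered to machine precision instead of carrying a bin-centre bias
(~0.005 at α = −2 with 1.2× bins). When regions are supplied, only
regions > 100 kb contribute and only bins fully inside them; the fitted α
is range-dependent in principle, so recovery claims are made at the
simulator's planted exponents.

*Compartments.* Per chromosome, the cis map is transformed to
observed/expected by diagonal means, correlated (Pearson), and
decomposed; PC1 is sign-oriented so its correlation with per-bin AT
fraction is positive, with the flip recorded. A raw-counts mode exists.
Chromosomes with fewer than 10 informative bins are flagged undefined.

*TADs.* TopDom-style: the diamond mean across each candidate boundary is
minimised locally; candidate minima are screened by a one-sided
Mann-Whitney test of within-domain diamonds versus the boundary diamond,
Benjamini-Hochberg-controlled at α = 0.01. The default α is 0.01 rather
than 0.05 because at 0.05 a long uniform domain acquires a spurious
boundary roughly every 90 bins, while the 5:1 within:between contrast used
throughout the tests is still detected in ~97% of runs at 0.01. Domains
under 5 bins merge into the neighbour sharing more contact; all-zero runs
become gaps. Ranks make the caller invariant to global rescaling.

*Centromeres.* Iterated conditional maximisation: each chromosome's
candidate bin maximises summed trans contacts with the other chromosomes'
current candidates (±1 bin window) until a fixed point; ties break to the
lowest coordinate. The iteration is seeded from each chromosome's maximum
single trans cell — the centromere signal is point-like, and a row-sum
start can converge to a diffuse wrong fixed point. Significance comes from
permuting partner bins (200 draws); low-confidence calls are flagged, not
suppressed.

## Expression linkage

*TAD co-regulation.* OLS of per-gene log2 fold-change on TAD membership
(cell-means coding) plus centered covariates: number of other genes within
5 kb, gene GC fraction, and a TE-within-500 bp indicator. ΔAIC =
AIC(covariates-only) − AIC(full); positive values favour TAD-level shared
effects. Per-TAD estimates are tested against zero with BH control at FDR
0.01. TADs with fewer than 2 genes are dropped and reported; a single
populated TAD is unidentifiable and raises.

*Contact enrichment.* Genes map to the bin of their midpoint; the
statistic is the mean contact over all gene pairs of the set within each
fixed distance category (midpoint-to-midpoint, the ≥1 Mb category split
into cis and trans). The null is 1,000 uniform same-size redraws from the
eligible universe (unmatched sampling; chromosome-matched sampling is a
flag); "expected" is the permutation mean, the envelope the 2.5/97.5
percentiles, and the one-sided p uses the add-one Monte-Carlo correction,
which makes P(p ≤ 0.05) exactly 0.05 under exchangeability.

*Mantel control.* Distance matrices over AT blocks: 1/(1 + contacts)
(contacts averaged per bin pair) versus 1 − Jaccard of repeat-family
sets; two-sided permutation p, with full enumeration when feasible (≤8
regions or `exact=True`). Two aggregation choices matter and are
documented because both would silently bias the null positive: summed
contacts scale with block size, as does family count; and one-bin regions
couple zero-inflated contact estimates to family-set size. Hence the
default mean aggregation and the 15 kb minimum region length.

*Proximity odds ratio.* Genes within 5 kb of an AT block (interval gap,
0 if overlapping) cross-classified against a binary class; the logistic
fit's OR equals the 2×2 cross-product ratio whenever all cells are
nonzero, and the tests assert that equivalence to 1e-6. Empty cells fall
back to the Haldane-Anscombe +0.5 correction, flagged.

*MITE enrichment.* Per family, mean copies within 2 kb of the coding span
for the top-20% most up-regulated genes versus the rest; the positional
profile is strand-flipped and TSS-relative (negative = upstream), with
per-quantile folds taken against all genes outside that quantile.
Quantiles are rank-based, robust to ties.

*6mA.* Calls under mQV 20 are removed; denominators count adenines on
both strands (A and T in the reference); the ApX context reads the base 3'
of the adenine on the call's own strand. A call not on an adenine after
strand resolution is an error naming the position.

## Simulation scales and what passing shows

The test and acceptance runs use: a 35 Mb / 7-chromosome genome for
composition and segmentation; a large-block (250 kb AT / 400 kb GC)
genome with 10⁶ pairs for decay, compartments and centromeres — large
blocks are needed because decay fits filter regions ≤ 100 kb; and a 20 Mb
gene-dense genome (~5,200 genes) for the expression statistics. These
sizes recover all planted parameters comfortably on one CPU in about half
a minute.

The generators emulate the *statistical structure* the analyses assume —
bimodal composition, RIP dinucleotide erosion, power-law decay with
compartment affinity, TAD-shared expression effects, planted proximity
and MITE enrichments. They do not emulate read-level noise, ligation
chemistry or restriction-fragment geometry (pairs are positional),
alignment artefacts beyond the MAPQ/contaminant flags, unequal chromosome
arms, or correlated gene families. Passing therefore shows the estimators
are correct and calibrated under their assumed generative model, not that
real libraries are free of the upstream artefacts those non-modelled
processes can introduce.

## Known limitations

- The segmentation mixture is two-component by design; genomes with a
  third composition mode will fold it into the nearer class.
- Mappability is k-mer-exact, not aligner-faithful: a real aligner's
  mismatch tolerance can rescue positions the k-mer criterion masks.
- The decay exponent depends on the fitted distance range; comparisons
  are meaningful within one configuration.
- The centromere permutation test assumes a single dominant trans-contact
  focus per chromosome; diffuse or multiple foci yield low-confidence
  flags rather than multi-candidate output.
- `terminal_fork_lengths` dates integrations only for families with
  cherries; star-like trees return few or no forks.
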