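# Methods

## Records and coordinates

A `GenomeRecord` is a circular (occasionally linear) mitochondrial genome
with an ordered list of `GeneFeature`s in 1-based inclusive coordinates, the
convention of published annotation tables. Strand `H` is the reference
strand of the deposited sequence and `L` its complement; a feature whose
span crosses the origin carries `wraps_origin` and is written to GenBank as
a `join()` compound location. Feature length is `end − start + 1`
(`(L − start + 1) + end` across the origin) and the intergenic spacer
between consecutive features is `b.start − a.end − 1`, negative for
overlaps. Overlapping annotations — common in real mitogenomes, e.g. tRNAs
tucked into rRNA ends — are reported by `validate()` but never clipped.
Published tables occasionally print derived columns (sizes, intergenic
counts) inconsistent with their own coordinates; this package always
recomputes from coordinates and treats the printed derived columns as
display only. Gene-name dialects (COX1, rrnL, tRNA-Ser(UCN), …) are
normalized through an editable alias table
(`src/mitochar/data/gene_aliases.tsv`); the two serine and two leucine
tRNAs keep their 1/2 suffixes (S1 = AGN, S2 = UCN, L1 = CUN, L2 = UUR).

## Composition and skews

Counts exclude ambiguous bases (N) from all denominators. AT skew
= (A − T)/(A + T) and GC skew = (G − C)/(G + C) are computed from raw counts
when sequence is available; `skew_from_percent` recomputes them from printed
percentages purely to validate published tables. Partition composition
("whole", PCG, rRNA, tRNA) pools the *sense-strand* sequence of every
feature in the partition, while the whole-genome row uses the reference
strand; this is why a PCG partition mixing H- and L-strand genes can show
T > A while the whole genome shows A > T. Reported percentages are rounded
to 1 decimal and skews to 3 decimals, half away from zero, matching the
precision of published tables; full doubles are kept internally. A skew
with a zero denominator is NaN, never 0.

## Codon usage and RSCU

The genetic code defaults to NCBI translation table 5 (invertebrate
mitochondrial: ATA = Met, TGA = Trp, AGA/AGG = Ser), the standard code for
cephalopod mtDNA; it is a parameter everywhere. CDS extraction returns
sense-strand triplets with a trailing 1–2 nt codon retained and classified
`T--`/`TA-` (an incomplete stop completed to TAA by polyadenylation); an
in-frame stop before the annotated terminus raises a warning with its
position, since it signals a frame or annotation error. Alternative starts
(ATT/ATA) are accepted as annotated; there is no ORF re-calling. RSCU is
count/(family mean); within each synonymous family the values sum to the
family size, and six/eight-codon families are split by decoding tRNA
(L1/L2, S1/S2) to match mitogenome annotation practice. Stop codons and
incomplete terminal codons are never counted.

## Ka/Ks (NG86)

Site counts per codon: at each position the synonymous fraction is the
number of the three possible point mutations that preserve the amino acid,
divided by 3; mutations to stop codons count as nonsynonymous; S + N = 3 per
codon. Observed differences are averaged with equal weight over all k!
substitution pathways; pathways passing through a stop codon are excluded
and the average renormalized (if all paths hit stops they are all kept,
with stop-crossing steps counted as nonsynonymous). Sites are averaged over
the two sequences, proportions pS = Sd/S̄ and pN = Nd/N̄ are Jukes–Cantor
corrected, and p ≥ 3/4 raises a saturation error rather than returning a
number. Codons with gaps or ambiguity in either sequence are dropped
pairwise. Ka/Ks is undefined (NaN), not 0 or ∞, when Ks = 0. The per-gene
screen averages the defined pairwise ratios and labels regimes purifying
(< 1), neutral (= 1 ± 0.01) or positive (> 1).

Classic NG86 with equal pathway weights is unbiased when every point
mutation is equally likely; under transition-biased mutation it
underestimates dN/dS (transitions are disproportionately synonymous, so Ks
is inflated), e.g. a neutral gene evolved at ts/tv = 2 reads back at about
0.75. The estimator-validation simulations therefore propose mutations
without transition bias (ts/tv proposal ratio 0.5, all three target bases
equally likely), and `analysis/04_selection_screen.py` prints the biased
case alongside for reference. The per-gene comparison across 25
octopodiform species cannot be recomputed here (it needs the external
GenBank genome set); the screen's validity is instead established by exact
agreement with an exhaustive-enumeration reference implementation and by
recovery of known simulated dN/dS targets.

## Gene order, blocks, LNCRs, breakpoints

Gene orders are signed circular sequences of symbols (sign = strand),
compared equal under rotation; linearization rotates the order so an anchor
gene (default COIII, the first gene of both study annotations) comes first,
with tRNAs included or restricted to PCG+rRNA. tRNA runs between two
anchors are rendered as one-letter strings (trnK→K …), which yields the
KARNI and MCYWQG blocks. Conserved blocks are maximal runs contiguous with
consistent relative orientation in every input order; a block may match in
reverse-complement orientation, which is reported per taxon. Breakpoint
distance counts signed adjacencies — (a, b) identified with (−b, −a),
rotation-closed — present in one order and absent from the other; it is a
symmetric, rotation-invariant pseudo-metric and is reported instead of
sorting scenarios (inversion/DCJ distances are out of scope). LNCR
detection merges annotated intervals (overlaps unioned) and reports
unannotated gaps at or above a threshold, including the origin-spanning
gap. The default threshold of 500 bp separates control-region-scale gaps
(the 1109 bp and 1053 bp regions of *A. pelagicus*) from ordinary spacers
(≤ 212 bp in these genomes) and is flag-configurable.

## Phylogenetic stage

The concatenation step unifies taxa across per-gene alignments (gaps for
missing taxon × gene cells), fixes gene order by declaration so shuffled
input gives identical matrices, and emits a RAxML-style partition map.
Distances are K2P with pairwise deletion of gap/ambiguous columns;
log-domain violations raise a saturation error. Neighbor joining follows
Saitou–Nei agglomeration with Q-matrix ties broken by the lexicographic
order of the smallest leaf labels of the joined clusters, so results are
reproducible across platforms; negative branch-length estimates are clamped
to zero. Bootstrap resamples columns of the whole matrix with replacement
(per-partition resampling behind a flag), rebuilds each replicate with
K2P + NJ, and scores each internal bipartition of the full-matrix tree by
the percentage of replicates containing it. Robinson–Foulds distances and
monophyly checks (after rooting on a named outgroup) go through dendropy.

This stage deliberately replaces maximum-likelihood and Bayesian tree
inference: those require the 26-genome supermatrix and hours of search,
and their topology cannot be verified from first principles on the desk.
The claims made (and tested) here are therefore about *recovery*: on
6-taxon data simulated under K2P (5,000 sites, branch lengths 0.05–0.3,
ts/tv 2) the pipeline recovers the generating topology in ≥ 95 of 100
seeded replicates and assigns ≥ 95% bootstrap support to the deepest
simulated split. Alignment itself is out of scope; inputs are pre-aligned
per-gene FASTA (a > 50%-gap column mask is provided).

## Synthetic data generator

The generator is the package's data source in lieu of the deposited
sequences; its defaults encode the two study genomes. Templates are derived
from the published annotation tables: feature lengths, strands and
start/stop codon policies in annotated order, positive intergenic spacers
kept as non-coding entries (so the LNCR structure survives: one ~1.2 kb
region in the *J. diaphana* preset, the 1109/1053 bp pair in the
*A. pelagicus* preset) and overlaps collapsed to adjacency — which makes
the synthetic genomes slightly longer than the deposited ones (16,227 vs
16,111 bp; 17,488 vs 17,380 bp) while preserving every partition length sum.

Composition targeting solves a small linear program for one base
distribution per (partition, strand) class plus the non-coding class, such
that each partition's length-weighted sense-strand mixture equals its
published target exactly, reference-strand totals equal the whole-genome
target, and the largest departure of any class from its partition target is
minimized (spreading strand asymmetry over both strands, as in real
mitogenomes). A single pooled distribution per partition cannot satisfy
both the sense-strand partition rows and the reference-strand whole-genome
row simultaneously, which is why the per-strand solve exists; infeasible
targets raise an error rather than being approximated. Integer counts are
allocated by largest remainder and laid down by seeded shuffling, so
realized compositions sit within a few hundredths of a percentage point of
target. Within PCGs the free positions are split per codon position, with
third positions absorbing the A-over-T share of the class composition —
synonymous-site freedom concentrating the AT bias, which makes TTA (Leu,
UUR) the top pooled codon as in real AT-rich mitogenomes. Start/stop codons
follow the per-gene policy (incomplete `T--`/`TA-` supported); in-frame
internal stops are removed by swapping third-position bases within the
gene, which preserves both total and per-position counts exactly.

Sequence evolution is independent-site K2P along a Newick tree (branch
lengths = expected substitutions per site; closed-form transition
probabilities). CDS mode runs a proposal process (Poisson number of K2P
point-mutation proposals per branch) in which synonymous proposals are
always accepted, nonsynonymous ones with probability equal to the dN/dS
target, and stop-creating ones rejected. The rearrangement simulator
applies translocations, inversions, and duplication–random-loss events
(tandem segment duplication, then random loss of one copy of each
duplicated gene) with an explicit event log. Every generator is a pure
function of spec + seed (numpy `default_rng`, PCG64, so seeds are portable);
generation logs carry the injected ground truth for tests and are never
read by the analysis code.

What the generator does **not** emulate: homology between the two synthetic
genomes (their sequences are independent draws, so cross-genome Ka/Ks and
distances saturate, as the consolidated report states), realistic tRNA/rRNA
secondary structure, indels, within-partition composition heterogeneity
between genes, and codon-usage structure beyond the positional base model.
Passing tests on synthetic data therefore demonstrate correctness of the
statistics and estimators under known truth, not biological conclusions
about real sequences.

## Numerical and design choices

- Rounding for report output is half-away-from-zero (printed-table
  convention); Python's banker's rounding is never used for reported values.
- The LP uses scipy's HiGHS solver; class compositions are bounded to
  [0, 1] and the auxiliary objective keeps the solution interior rather
  than at a vertex.
- NJ tie-breaks and bootstrap resampling are seeded/deterministic;
  bootstrap replicates whose distance matrices saturate are skipped and
  support is normalized over the completed replicates.
- `kaks_pair` drops stop codons (full or incomplete) before counting;
  identical sequences give Ka = Ks = 0 with an undefined ratio.
- Problem sizes used by the test suite and the acceptance script — 30-codon
  pairs for oracle equivalence, 200–250-codon genes for selection recovery,
  6 taxa × 5,000 sites for topology recovery, 1,000 bootstrap replicates —
  are the package's chosen study conditions; they keep every quantity
  statistically decisive while the whole suite runs in well under a minute
  of simulation time.

## Known limitations

- Ka/Ks is counting-based NG86 only; no maximum-likelihood dN/dS, branch or
  site models.
- The phylogenetic stage is distance-based (K2P + NJ); no ML/BI tree
  search, model selection, or divergence dating.
- Gene-order analysis reports breakpoint distance, not rearrangement
  scenarios or ancestral order reconstruction.
- The published per-gene Ka/Ks range (0.07–1.17 with ND4 above 1) and the
  26-taxon clade structure depend on external genome sets and are outside
  what this package can recompute; the corresponding stages are validated
  by oracle equivalence and simulation recovery instead.
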