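# mitochar

Comparative characterization of annotated mitochondrial genomes, built around
the two deep-sea octopus mitogenomes of the family Amphitretidae —
*Japetella diaphana* (ON060363, 16,111 bp) and *Amphitretus pelagicus*
(ON060364, 17,380 bp). The package takes annotated circular mitogenome
records (feature-table TSV or GenBank) and produces the full analysis suite a
mitogenome paper reports:

- **Composition and strand skews** per partition (whole genome, 13 PCGs,
  rRNA, tRNA): AT skew = (A − T)/(A + T), GC skew = (G − C)/(G + C).
- **Codon usage**: strand-aware CDS extraction under the invertebrate
  mitochondrial code (NCBI table 5), start/stop classification including
  incomplete stops (`T--`, `TA-`, completed by polyadenylation), and RSCU
  (relative synonymous codon usage), per gene and pooled.
- **Selection screening**: pairwise Ka/Ks by Nei–Gojobori (1986) counting —
  fractional synonymous/nonsynonymous sites, equal-weight pathway averaging
  with stop-codon path exclusion, Jukes–Cantor correction
  K = −(3/4) ln(1 − 4p/3) — with purifying/neutral/positive classification.
- **Gene-order analysis**: linearization from an anchor gene (COIII),
  tRNA-block strings (the KARNI and MCYWQG runs), conserved-block mining
  across taxa, long non-coding region (LNCR) detection on the circle, and
  breakpoint distances between signed circular gene orders.
- **Desk-scale phylogenetics**: per-gene alignment concatenation into a
  partitioned supermatrix, Kimura two-parameter distances
  d = −½ ln((1 − 2P − Q)·√(1 − 2Q)), Saitou–Nei neighbor-joining with
  deterministic tie-breaking, nonparametric bootstrap, Robinson–Foulds
  distances and monophyly checks.
- **Synthetic data**: a generator producing annotated circular mitogenomes
  with controlled per-partition composition, codon policies and gene order;
  sequence evolution along trees (K2P, with a dN/dS-controlled CDS mode);
  and a translocation/inversion/duplication–random-loss rearrangement
  simulator. Every generator is a pure function of spec + seed.

The published annotation tables of the two genomes ship as package data and
drive the annotation-level analyses directly; the sequence-level analyses run
on synthetic genomes built to the published composition targets, since the
deposited sequences and the 25-genome comparison set are external downloads.

## Worked example

```sh
mitochar simulate genome --preset jdiaphana --seed 11 -o jd.gb
mitochar stats jd.gb
```

prints the per-partition composition of a synthetic *J. diaphana*-like
genome (tab-separated; skews at 3 decimals, percentages at 1):

```
partition  size_bp  A%    T%    C%    G%    A+T%  C+G%  AT_skew  GC_skew
whole      16227    40.6  36.3  15.4  7.7   76.9  23.1  0.056    -0.333
PCG        11152    31.9  43.5  11.0  13.5  75.5  24.5  -0.154   0.102
rRNA       2312     37.1  42.5  6.0   14.4  79.6  20.4  -0.067   0.411
tRNA       1462     37.9  40.6  8.1   13.4  78.5  21.5  -0.035   0.248
```

The whole-genome row reproduces the published values for *J. diaphana*
(AT skew +0.056, GC skew −0.333; A+T 76.9%); the PCG row shows the
sense-strand pooling signature (T > A) of genes split across both strands.
The numbered drivers under `analysis/` run each stage of the study in order
(annotation census, composition, codon usage, selection screen, gene order,
phylogeny) and write their tables under `results/`; for example
`python analysis/06_phylogeny.py` reports

```
topology recovery: 100/100 replicates exact (RF = 0)
bootstrap supports (1000 replicates): 100%, 100%, 100%
```

for 6-taxon alignments (5,000 sites) evolved on a known tree and rebuilt
with K2P + neighbor joining.

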