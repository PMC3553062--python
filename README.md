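# mircms

Small-RNA and degradome sequencing analysis for two-condition plant
experiments, built around the comparison of cytoplasmic male-sterile (CMS)
and maintainer-fertile (MF) floral tissue. The package covers the full
desk-side workflow:

1. **Read cleaning** — 3' adapter trimming, the 15–32 nt length window,
   junk-read removal, collapsing to unique counted tags, and the
   read-length profile.
2. **Known-miRNA annotation** — ungapped matching against a mature-miRNA
   catalog with isomiR nomenclature (`_L±n` / `_R±n` end shifts,
   `_NssPosRefObs` substitutions, `-p5`/`-p3` precursor-arm names).
3. **Novel miRNA discovery** — database exclusion, genomic precursor
   windows, exact maximum-base-pair hairpin folding, and arm/duplex
   acceptance rules (`PC-5p-N` / `PC-3p-N` candidates).
4. **Differential expression** — per-million normalization and a
   three-statistic consensus call at threshold 0.01.
5. **Degradome (PARE) target analysis** — t-plot construction, plant-style
   complementarity scoring, predicted cleavage opposite miRNA positions
   10–11, and the five-category cleavage classification.
6. **Synthetic data** — a seeded generator that plants hairpin precursors,
   fold changes, and degradome categories with recorded ground truth, so
   every stage runs and validates offline.

## The statistics at the core

For a tag with count *x* among *N₁* tags in library 1 (MF) and *y* among
*N₂* in library 2 (CMS), three tests are computed and a tag is called
differentially expressed only when **all three** give p ≤ α (default 0.01):

- **Audic–Claverie** point probability, computed in log space:

  p(y|x) = (N₂/N₁)^y · (x+y)! / ( x!·y!·(1+N₂/N₁)^(x+y+1) )

  which at N₁ = N₂ reduces to C(x+y, x)/2^(x+y+1).
- **Fisher's exact test**, two-sided by doubling the smaller one-sided
  hypergeometric tail of the 2×2 table [[x, N₁−x], [y, N₂−y]].
- **Pearson chi-square** on the same table, 1 df, no continuity correction.

Degradome cleavage positions are ranked by the five-tier scheme over the
positions of a transcript that carry signal: category 0 (unique maximum,
more than one read), 1 (tied maximum), 2 (above the median), 3 (at or below
the median), 4 (single read).

## Worked example

```
$ python examples/04_differential_expression.py
tested: 47  significant: 47  down: 25  up: 22
ath-miR156h_L+1: MF=14 CMS=47 AC=0.000005 Fisher=0.000027 chi2=0.000024 -> up
```

All 47 catalogued MF/CMS count pairs clear the three-test consensus at
0.01; 25 are lower and 22 higher in the male-sterile condition. The
`ath-miR156h_L+1` row shows the per-million counts and the three p-values
behind one "up" call (the name itself records a 5'-extended isomiR).

The other scripts in `examples/` each demonstrate one capability — read
cleaning and length profiles, isomiR naming, hairpin discovery on a
synthetic genome, and degradome target classification — and print a short
explanation with their output.

There is also a thin CLI:

```
mircms simulate demo --seed 5            # synthetic genome + two libraries
mircms run-all --reads-mf demo/MF.fastq --reads-cms demo/CMS.fastq \
    --genome demo/genome.fa --adapter TGGAATTCTCGGGTGCCAAGG --out demo/out
mircms fixtures demo/tables              # export the packaged study tables
```

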