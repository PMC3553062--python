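# Methods

This note documents the models, rules and numerical choices behind each
stage, the parameters worth knowing about, and what the synthetic-data
generator does and does not emulate.

## Read cleaning

Reads are 3'-adapter trimmed by exact prefix match: the leftmost position
where the adapter (or its prefix, down to a minimum overlap of 6 nt)
extends to the read end marks the insert boundary. Mismatch tolerance is a
parameter (default 0); untrimmed full-length reads are kept by default and
can be dropped. A cleaned read is retained iff its length is within
[15, 32] nt (inclusive) and it is not junk. *Junk* is defined here as a
read containing any `N` or with a single base composing more than 80% of
its length — the definition follows common vendor pipelines and is
deliberately explicit so it is testable; quality-based filtering exists on
the record type but is off by default. Filtering conserves counts per
rejection reason and is idempotent. Collapsing produces one tag per
distinct sequence with per-library raw counts; tag order is by descending
count, then sequence, so outputs are deterministic.

## IsomiR naming

Tags are aligned ungapped against every catalog mature at every 5'-end
offset within ±3 nt; an alignment is admissible when both end shifts are
within ±3 and at most 2 substitutions occur in the overlap. The best hit
minimizes (substitution count, total |shift|, catalog name) — the final
lexicographic key makes annotation deterministic. Names append, in order:
`_L±n` for the 5' end, `_R±n` for the 3' end (positive = tag longer than
the reference), and `_Nss` followed by `PosRefObs` blocks in ascending tag
position for substitutions (positions are 1-based on the observed tag).
The suffix tolerances cover the largest printed variants in the reference
catalog (2 substitutions, ±2 shifts) with margin; both are parameters.
Tags matching a precursor outside any annotated mature span are named
`<precursor>-p5` or `-p3` by comparing the match midpoint with the
precursor midpoint. Bases a tag gains beyond the reference are not encoded
in the suffix (they are genome-templated in real data); the reconstruction
property is therefore checked with the hit's own extension bases.

## Hairpin folding and novel-candidate calling

The built-in folder maximizes base-pair count (Watson–Crick + G:U, minimum
hairpin loop 3, no pseudoknots) by exact interval dynamic programming
(numba-compiled fill, deterministic traceback). Maximizing pairs instead of
free energy makes results bit-reproducible without a thermodynamics engine;
any external folder returning dot-bracket text can be plugged in through
the `folder` argument of `fold_window`/`discover`.

Discovery excludes tags occurring (on either strand) as exact substrings of
the mRNA/ncRNA/repeat catalogs and tags with total count below 5 (the
low-abundance cutoff is undocumented upstream; 5 is this package's default
and a parameter). Each remaining occurrence is extended into two asymmetric
windows (±160/20 nt, parameters), and each window is probed with a ladder
of nested sub-flanks (40, 80, 160 nt on either side). The ladder matters:
a global maximum-pairing structure of a 300+ nt random-flanked window
often buries the genuine mature:star duplex under scattered pairings, while
a tight window recovers it; the occurrence is accepted if any rung folds
acceptably, and reported once with its best-pairing structure.

A folded tag is accepted as a candidate iff

1. no base pair lies wholly inside the tag and every paired tag base has
   its partner strictly on one side — i.e. the tag sits on one arm and does
   not span the terminal loop;
2. at least 14 of its bases are paired (parameter);
3. the partners form a compact region: partner span at most tag length
   + 10 nt of bulge allowance. This is what separates real duplexes from
   chance pairings in shuffled decoys; without it, maximum-pairing folds of
   random windows pass rule 2 disturbingly often.

Candidates are named `PC-{5p|3p}-{serial}` in discovery order, which is
stable for a fixed input order. Organellar and nuclear copies of identical
precursors are reported as separate loci. Known limitation: an AT-rich,
partially self-complementary mature can fold onto itself in every window
and be missed (about 1 in 20 planted hairpins at the defaults); a
thermodynamic folder plugged into the hook mitigates this.

## Differential expression

Raw counts are normalized to a common total (default 10⁶, i.e. tags per
million) with integer rounding, and the three tests are run on the
normalized pairs with equal totals equal to the scale. The Audic–Claverie
statistic is the **point probability** p(y|x), not a tail sum — the
convention established by exact reproduction of the reference table — and
is computed via log-gamma so arbitrarily large counts are safe. Fisher is
two-sided by tail doubling (coincides with the probability-mass method at
equal totals, by symmetry); chi-square carries no Yates correction (with
one, the sparse reference pairs would not reproduce). In the regime
N ≫ counts all three depend essentially only on (x, y): across totals
10⁵–10⁷ the values move by under 1% and no call flips, though the sixth
decimal of the largest-count pairs can round either way. A tag is
*significant* iff all three p ≤ α (default 0.01); *direction* is the sign
of the normalized difference (condition 2 vs condition 1).

Caveat: running the tests on per-million-rescaled counts presumes
sequencing depth of that order. Rescaling a very shallow (toy) library to
10⁶ inflates the apparent evidence; for such inputs, pass the true totals
instead of rescaling.

## Degradome classification

Degradome tags are anchored by exact match of their first 20 nt (parameter)
to transcripts; each match adds the tag's raw count at the 1-based start
position, multi-transcript matches count in full everywhere. Target sites
are same-length transcript windows scored against the miRNA with the
plant-target ("Allen-style") scheme: mismatch 1.0, G:U 0.5, gap 2.0, all
doubled at miRNA positions 2–13, cutoff 7.0 (all parameters). The
predicted cleavage position is the transcript base opposite miRNA position
10 (cleavage falls between the bases opposite positions 10 and 11).

A signal-bearing position is categorized with the singleton rule first —
one raw read → category 4 — which resolves the corner case where the
transcript-wide maximum itself is 1. Otherwise: unique maximum → 0, tied
maximum → 1, above the median → 2, at or below it → 3. The maximum and
median are computed over raw counts at positions carrying at least one
read; including zero-signal positions would drive the median to 0 on long
transcripts and let category 2 swallow category 3. Classified sites report
per-library categories (the headline category comes from the library with
the strongest raw signal at the site) and per-million normalized read
support, labelled as such.

## Synthetic data

`make_genome` plants hairpin precursors — a random 21-nt mature, a loop of
8 nt, and the mature's full reverse complement on the other arm — and
decoy loci (shuffled precursors: same composition, destroyed pairing) at
evenly spaced positions in a random background (defaults: 20 + 20 loci in
100 kb). `simulate_libraries` assigns each planted mature and ~300
background tags (lengths drawn 21 > 24 > 22 > 20, the Dicer-typical
profile) exponential abundance weights scaled to the target depth, then
draws per-library counts negative-binomially with dispersion 0.1
(variance μ + 0.1μ²; dispersion 0 gives Poisson). Condition-2 means are
condition-1 means times the planted fold change. Reads carry the standard
small-RNA 3' adapter so cleaning is exercised. `simulate_degradome` works
backwards from the category definitions: dominant spike → 0, duplicated
spike → 1, above-noise-median count (with a separately planted maximum) →
2, at-median count → 3, singleton → 4, against uniform noise at 30
positions; requests that are unrealizable (category 0 with signal 1,
category 2 without noise to define a median) raise generation errors.
All randomness flows from one integer seed through `numpy.random.Generator`;
regeneration is bit-identical.

What the generator does **not** emulate: sequencing error and quality-score
profiles, multi-mapping ambiguity at genome scale, composition bias,
adapter dimers, or the full hairpin imperfection spectrum of real
precursors (planted duplexes are perfect). Passing the recovery tests
therefore demonstrates the correctness of the rules and statistics on data
satisfying their assumptions, not end-to-end performance on real libraries.

## Problem sizes and determinism

The shipped tests run the type-I simulation at 10,000 null pairs, the
category oracle at 1,000 random t-plots, folding-oracle equivalence at
~120 windows of ≤30 nt, power at 200 replicates, and discovery on 20–40 kb
toy genomes — sizes chosen so the whole suite completes in well under a
minute while keeping binomial error bars far from the asserted bounds.
Pipeline outputs use fixed sort orders and 6-decimal p-value formatting
(full precision in parallel columns), so re-runs are byte-identical.
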