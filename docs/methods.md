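# Methods

This note records the conventions, models and numerical choices behind
each module, and what the synthetic fixtures do and do not establish
about real data.

## Coordinates and architecture

All coordinates are 1-based inclusive, as in published mitogenome
annotation tables; conversion to 0-based slices happens only at sequence
extraction. The intergenic length attached to a feature is the gap to the
*next* feature in genomic order, `next.start − this.end − 1`; a negative
value is an overlap. On a circular genome the last feature closes onto
the first with `L − last.end + first.start − 1`. This convention
reproduces every value in the *L. langsoni* reference layout, including
the −7 bp atp8/atp6 overlap and the 99 bp closure spacer.

The overlap census counts every adjacency, including those involving the
replication origin OL and the control region; for the reference layout
this yields 11 overlaps and 18 positive spacers. (The accompanying prose
in the source publication says "13 intergenic spacers" while its own
table contains 18 positive values; the census reports what it computes.)

**PCG partition accounting.** The 13 printed gene lengths sum to
11,415 bp, yet the published composition table gives the PCG partition as
11,382 bp = 3 × 3794. These reconcile exactly when each gene's stop codon
is removed — 10 complete stops (30 bp) and 3 incomplete T- stops (3 bp).
The partition extractor therefore drops the annotated stop token from
every gene, and codon positions 1/2/3 are taken per gene on the stop-less
sequence, never across gene junctions (reading frame is a per-gene
property). Overlapping genes contribute their full spans independently,
with no double-count correction. Codon-usage extraction, by contrast,
*keeps* complete terminal stops (3804 codons = 11,382/3 + 10) and drops
only incomplete 1–2 bp tails.

## Composition and skews

Skews are computed on raw counts (equivalently percentages); ambiguity
codes are excluded from all counts and denominators. Reporting precision
follows the published tables: percentages to 2 decimals, skews to 4,
RSCU to 2, Hd/k̄ to 3, π to 4, Tajima's D to 4, all with half-up
rounding centralized in `mitochar.report`. Genome-level composition uses
the heavy-strand sequence as deposited; per-gene profiles use the
strand-corrected coding sequence with the stop retained. A zero skew
denominator raises by default; per-gene profiling relaxes this to a
missing value so an extreme synthetic gene (e.g. all-A) is representable.

## Codon usage

The genetic code is NCBI translation table 2 (via Biopython): stops
{UAA, UAG, AGA, AGG}, Met ∈ {AUA, AUG}, Trp ∈ {UGA, UGG}. Leu and Ser
are treated as single 6-codon families and the stops as one 4-codon
family; the published RSCU rows sum to 6/6/4 respectively, which fixes
this convention. Initiator codons are counted as written — a GTG start
contributes a GUG (Val) codon — since the published totals cannot
distinguish initiator recoding and counting-as-written is the simpler
rule. Codon-rank ties are broken alphabetically by codon, which places
AUU above GCC at their shared count of 145.

## Ka/Ks (Nei–Gojobori 1986 + JC69)

Sites: for each codon, the synonymous-site count is the sum over the
three positions of the fraction of single-base changes preserving the
amino acid, taken over changes that do not create a stop codon (the
standard refinement for coding sequences; under code 2 every position of
every sense codon retains at least one non-stop change, so the fraction
is always defined). Site counts are computed on both sequences and
averaged, so N + S = 3 × (number of codon pairs) identically.

Differences: pairs separated by 2–3 changes are averaged over all
minimal mutational pathways with equal weight; pathways passing through
a stop codon are excluded (with a flag to include them), falling back to
all pathways if every one is blocked. Proportions pN = nN/N and
pS = nS/S are corrected with JC69, `d = −(3/4)ln(1 − 4p/3)`, undefined
at p ≥ 3/4 (reported missing — note this makes Ks missing on degenerate
one-codon instances whose single difference is synonymous, since then
pS = nS/S ≥ 3/4 by construction). ω is missing when Ks = 0.

No attempt is made to match the published per-gene Ka/Ks bar values: the
model behind them is not identified in the source, so the qualitative
claim (all 13 genes under purifying selection, ω < 1) is the check, and
it is exercised on simulated pairs with known constraint. The estimator
itself is verified exactly against a brute-force pathway/site
enumeration oracle.

## Diversity statistics

Sites containing a gap or ambiguity code in any sequence are removed
before every statistic (complete deletion, the common DnaSP-style
default; the source is silent on this). Haplotypes are exact-identity
classes on retained sites. Hd uses the n/(n−1) unbiased correction —
(30/29)(1 − 0.6² − 0.4²) = 0.4966 reproduces the published 0.497 where
the uncorrected 0.480 does not. k̄ is the mean Hamming distance over all
C(n,2) pairs; π = k̄/L. Tajima's D uses the 1989 constants with the
per-locus k̄ (the per-locus convention reproduces the published 1.5078).
D is undefined at S = 0 or n < 4 and reported missing.

The 18:12 haplotype split of the published 30-sequence COI sample is
inferred, not printed: it is the unique two-class split of 30 whose
single-site configuration yields the published k̄ = 0.497
(2·18·12/870 = 216/435). All diversity fixtures use that configuration.

## Synthetic data

`make_genome` realizes a feature layout as an actual sequence:
start/stop tokens (including lone-T incomplete stops) are pinned at
their annotated positions first — overlapping pins are checked for
consistency, and in the reference layout all overlapping token pairs
(atp6/cox3 starts-on-stops, nad5/nad6 tail overlap) are mutually
compatible — then protein-coding genes are filled codon-by-codon in
coordinate order from the target composition, avoiding in-frame stops
and respecting bases already fixed by earlier overlapping genes; all
remaining positions are drawn i.i.d. from the composition target
(default: the deposited genome's A/T/G/C fractions, realized within
about ±1–2 percentage points). A codon fully constrained by an earlier
gene can occasionally be forced into a stop; generation then restarts
from the next RNG substream (bounded, deterministic under the seed).

`evolve_pair` is a mutation-filter model, not a full codon substitution
model: per sense codon, Poisson(t) candidate single-base changes;
synonymous candidates always accepted, amino-acid-changing ones with
probability ω_true, stop-creating ones rejected; non-coding positions
mutate neutrally at the matched per-base rate. Codons shared between
overlapping genes are frozen so the two genes' histories stay
independent (this guarantees Ka = 0 exactly when ω_true = 0). Estimated
ω from NG86 recovers the simulated acceptance ratio to first order and
is monotone in it.

`make_coalescent_sample` implements the single-locus neutral coalescent
(Hudson's algorithm): with k lineages the next coalescence is
exponential with rate k(k−1)/2 in units of 2N generations; mutations are
Poisson(θ·branch/2) per branch under infinite sites, each on a fresh
column. It is written in-package rather than through a general simulator
because the calibration tests need the θ-scaling explicit: E[S] = θ·a₁
with a₁ = Σ 1/i is asserted directly (±15% over 200 replicates), and the
mean of Tajima's D over replicates sits within ±0.3 of 0 — a loose
neutrality band, not a sharp test.

**What the fixtures do not show.** The generator draws bases i.i.d.
within the composition target: it has no strand-asymmetric mutational
spectrum, no codon-position-specific composition, no realistic tRNA/rRNA
secondary structure, and no recombination. Passing tests therefore
establish the *accounting* (lengths, gaps, frames, stop conventions,
estimator algebra) on genomes with the published architecture, not the
biological realism of the sequences themselves.

## Problem sizes and determinism

All fixtures are desk-scale: one 16.6 kb genome (~0.2 s to generate),
100 evolved pairs for the selection screen, 200 coalescent replicates at
n = 10, θ = 5. Every generator takes an explicit seed and a fresh
`numpy.random.Generator`; there is no hidden global RNG state, so every
report and fixture is byte-reproducible.

## Known limitations

* The NG86 implementation targets closely related in-frame orthologs;
  it does not align (upstream alignment is the caller's job) and has no
  transition/transversion or codon-frequency weighting.
* GenBank reading derives start/stop tokens from the annotated
  coordinates and sequence rather than `/transl_except` qualifiers.
* The Ka/Ks screen pairs genes by exact name; no synonym resolution
  (nad4l vs ND4L) is attempted.
* Wrapping (origin-spanning) features are supported in the data model
  and extraction, but the synthetic generator does not place genes
  across the origin.
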