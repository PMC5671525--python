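# Methods

This note documents the models, conventions and numerical choices behind
`prfscan`, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Genome annotation

A genome is annotated with the longest AUG-initiated, stop-terminated ORF
over the three forward frames (positive-sense genomes; a `--both-strands`
style reverse scan is deliberately absent from the default path). Within a
frame each stop codon closes the span opened by the first upstream AUG;
length ties break toward the smaller start coordinate, making the result
deterministic. Conventions, fixed once:

* coordinates are 0-based half-open internally, 1-based inclusive in GFF3;
* the ORF length **includes the stop codon**, so
  `utr5 + orf + utr3 = genome length` and the polyprotein has
  `orf/3 − 1` residues;
* the standard genetic code only — appropriate for flaviviruses.

If a deposited record's annotated CDS started at a later AUG than the first
AUG of the maximal span, the first-AUG rule — not the record — would be
wrong; the annotation should then be re-run with explicit coordinates
rather than silently overridden.

## Pairwise alignment and identity/similarity

Global Needleman–Wunsch with affine gaps (Biopython's `PairwiseAligner`
provides the DP; the test suite checks it against an independent exhaustive
enumeration of all gapped alignments on short pairs). Defaults: BLOSUM62,
gap open 10, gap extend 0.5 (a run of length L costs `10 + 0.5·(L−1)`),
end gaps penalized. Percent identity is identical columns over the full
alignment length (gap columns in the denominator); percent similarity
additionally counts columns whose substitution score is positive. Published
identity/similarity figures rarely state tool, matrix or denominator, so
all of these are configurable, and comparisons against published
percentages should allow a tolerance of a couple of points.

p-distances (1 − identity fraction) feed neighbor joining (scikit-bio),
with labels processed in lexicographic order for determinism and negative
branch lengths clamped to zero. NJ on p-distances is a deliberate
lightweight stand-in for full phylogenetic inference: the supported claims
are nearest-relative orderings, not clade posteriors.

## Slippery-site scan

The consensus `X_XXY_YYZ` is enforced literally: `XXX` three identical
nucleotides or a member of the exception list (default `{GGA, GGU}`; only
GGA is firmly established, the list is configurable and never silently
extended), `YYY ∈ {AAA, UUU}`, `Z ∈ {A, C, U}`. A site is *in frame* when
the heptamer starts at the third position of a zero-frame codon, so the
underscores coincide with codon boundaries; only in-frame sites are kept by
default (off-frame reporting is a flag).

The −1 frame ORF length is counted from the −1 frame codon whose first
nucleotide is the heptamer's **last** base — the first codon newly decoded
after tandem-slippage re-pairing — up to but excluding the first −1 frame
stop; if the genome ends first, the count is flagged truncated. The
counting origin is recorded in candidate metadata because published codon
counts do not state their convention; the alternative convention (one codon
later) is a one-line change and would shift every count by one.

## Stem-loop prediction

The stimulatory structure is modelled as a single hairpin — nested pairs
only, no pseudoknots — scored additively: G:C = 3, A:U = 2, G:U = 1, minus
`interior_penalty` (default 1) per unpaired interior nucleotide (bulges and
internal loops), hairpin loop ≥ 3 nt, at most `max_interior` (default 10)
unpaired nucleotides between consecutive pairs, fold window 80 nt starting
immediately after the heptamer. This is *not* a thermodynamic
nearest-neighbor model: what the analysis reports are pair counts and pair
identities (total bp, the consecutive Watson–Crick run at the stem base and
its G:C content), and a transparent additive scheme keeps the optimum
exactly checkable against brute-force enumeration (the test suite does so
for every window ≤ 16 nt). Wobble G:U pairs may occur in stems but never
count toward the Watson–Crick base run.

The optimum is found by DP over outermost pairs with a deterministic
tie-break (lowest start, then more pairs). A candidate's *spacer* is the
number of unpaired nucleotides between the heptamer end and the hairpin's
first paired base; candidates keep only spacers in [5, 9] by default, and
hairpins scoring below `min_score` (default 4) are discarded.

On real sequence the reported stem depends on this scoring scheme; a
thermodynamic folder can disagree in the fine structure of long stems
(bulge placement in particular), which is why the structural acceptance
surface is the base-run metrics rather than the full pairing list.

## Cross-species conservation

Two candidate sites are compared by anchoring their heptamers column-wise
and globally aligning the downstream spacer+hairpin stretch, both regions
cut at the common (larger) extent. Nucleotide alignment scores are match 2,
mismatch −1, gap open 10, gap extend 2 — gaps deliberately expensive so
that clustered substitutions in repeat-rich stems cannot outscore the
colinear alignment; gaps appear only for genuine indels. Each predicted
pair of species A is classified against species B's homologous nucleotides:

* `identical` — both positions unchanged;
* `compensatory` — both changed, B still forms a legal pair;
* `half-substitution` — one changed, pairing retained (wobble counts as
  retained by default; `strict_wc` restricts to Watson–Crick);
* `pairing-lost` — B's nucleotides no longer pair (or a gap interrupts).

Sites count as location-conserved when their heptamers sit within 50 ORF
codons of each other (configurable); homology is established by this local
anchored alignment, not genome-wide synteny — adequate at the desk scale of
two ~11 kb genomes.

## Synthetic genomes and what they do (not) show

The generator emits a uniform-composition genome (GC knob available) with a
planted architecture: UTR lengths, an ORF of sense codons with no internal
stop, a codon-anchored heptamer, a spacer, a stem of specified pair kinds,
a loop, and optionally an exact −1 frame stop position. Defaults mirror the
flavivirus case the package targets: 119/3450 codons/376, `G_GAU_UUU` at
mid-ORF (codon 1500, the NS2B neighbourhood), spacer 7, a 7-pair stem whose
base runs 7 Watson–Crick pairs with 4 G:C, and a six-codon −1 frame ORF.

Ground truth is kept *provably* unique: the 5′UTR is redrawn until no
upstream in-frame AUG could extend the ORF; chance in-frame compliant
heptamers elsewhere in the ORF are patched by flipping one `YYY` base (the
zero-frame codon stays sense for every legal `XXX` prefix); and all free
nucleotides inside the fold window are drawn from {A, C} with the last
spacer bases C and a purine on the 5′ side of the stem base, so that
outside the planted stem essentially nothing can pair and the planted
hairpin is the strict score optimum of its window. The generator then
re-runs annotation, the scan and the fold on its own emission and redraws
within a bounded retry budget until everything is recovered exactly;
genuinely impossible layouts (e.g. a −1 stop on top of an incompatible stem
cell) raise an explicit infeasibility error.

Consequently, passing the recovery tests shows the pipeline is *correct*
(it finds exactly what is there, under the stated conventions); it does
not show that real genomes are as clean. Real sequence folds everywhere,
carries multiple chance heptamers, and its background composition is not
uniform — which is precisely why candidate filtering (frame anchoring,
spacer bounds, score threshold) and cross-species conservation exist.

Sister genomes apply an exact substitution budget: compensatory edits
prefer pair-orientation flips (score-preserving), pairing-breaking edits go
to the innermost stem pairs so the stem base — and hence the measured
spacer — survives, and neutral edits avoid the site region while keeping
every zero-frame codon sense. Every edit is ledgered, and the sister is
re-scanned to confirm it still yields exactly one candidate at the planted
position. Because stem edits can overwrite the parent's planted −1 stop,
the sister's −1 ORF length is re-measured rather than inherited. No
realistic evolutionary process (codon models, indels, rate variation) is
simulated.

## Problem sizes

The default test and acceptance runs use full-size (~10.8 kb, 3450-codon)
genomes for recovery batteries (30–50 genomes), short random sequences
(≤ 5 aa, ≤ 16 nt) for the exhaustive-oracle equivalence batteries, and
4–8-taxon trees for NJ recovery — sizes at which the brute-force oracles
are exact and the whole suite runs in well under five minutes on one CPU.

## Known limitations

* The hairpin scorer is not thermodynamic; stems with near-tied structures
  may be reported differently than by an MFE folder.
* Pseudoknots — a known alternative −1 PRF stimulator — are out of scope.
* Identity/similarity percentages depend on alignment parameters that
  published figures usually leave unstated; exact reproduction to the
  integer is not guaranteed, orderings are robust.
* Mature-peptide (cleavage-site) annotation is not performed, so candidate
  sites are located by ORF coordinate, not protein-region name; a
  user-supplied region label can be attached to candidates.
* Remote fetching of deposited records is intentionally not part of any
  test or pipeline step; real-data checks activate only when the records
  are present locally (see `data/README.md`).
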