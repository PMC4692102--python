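# Methods

## Repeat model

A repeat family is described by a `RepeatPreset`: a set of exact seed
heptamers, a 7-character IUPAC degenerate unit, minimum unit and seed
counts, a minimum total length, and the length of the unit's leading
G-run used for quadruplex calling (`tract_prefix_length`).

Scanning is seed-anchored: every exact seed occurrence fixes a reading
frame, and the array is extended left and right in 7-base steps while
each adjacent window matches the degenerate unit.  Arrays are therefore
maximal by construction.  After extension, a terminal partial unit is
recorded when the next `tract_prefix_length` bases are exactly the
unit's leading G-run; partials never count toward the unit number
(keeping unit histograms integral) but do contribute one tract to
quadruplex calling, so three units plus a trailing G-tract — the minimal
G4-folding motif — is called capable.  Candidates failing the unit,
seed or length floors are dropped.  Overlapping same-strand candidates
(possible when seeds occur in different frames) are resolved
deterministically: more seed units first, then more units, then the
leftmost start.  Opposite-strand hits may overlap and are both kept.
Minus-strand scanning runs on the reverse complement and maps hits back
to forward coordinates; an `N` base never matches any pattern position.

Built-in presets: `xan` (seed `GGGAATC`, unit `GGGANTN`, ≥ 2 units,
≥ 1 seed, ≥ 14 bp) encodes the xanthomonad family — the degenerate
positions are 5 and 7, matching the observed per-position conservation
of the unit; `ana` (seeds `GGGGATT`/`GGGGACT`, unit `GGGGANT`, ≥ 2 seed
units) encodes the cyanobacterial family with position 6 degenerate.
`tract_prefix_length` is 3 for both: three stacked tetrads suffice for
a G4, so the fourth G of the `ana` unit is treated as surplus and a
mutation there does not break a tract.  For the `ana` family the
14 bp length floor is the repeat definition itself; reproducing a
quadruplex-constrained subset is done by composing with the PQS
scanner rather than by raising the floor.

Because the degenerate patterns fix the leading G-run, every unit
inside a scanned array carries an intact tract; units with G-tract
point mutations fall outside the array definition and terminate
extension.  `call_g4_capability` nevertheless implements the general
longest-run rule so custom presets with degenerate tract positions
behave correctly.

## PQS scan

A tract is a maximal run of ≥ `g_min` guanines (runs are never split;
`g_max` only filters out hits containing longer tracts).  Consecutive
tracts chain when separated by `loop_min`–`loop_max` bases; a hit is a
maximal chain of ≥ `min_tracts` tracts, reported greedily and
non-overlapping per strand.  Defaults G₃, L₁–₅, ≥ 4 tracts.  Where a
scanner convention was ambiguous (one hit per maximal chain vs. every
overlapping sub-motif) we chose the dominant regex-scanner convention
of one maximal hit; counts are therefore not comparable with tools
that enumerate overlapping motifs.

Both scanners accept a `circular` flag that appends a bounded prefix
copy so origin-spanning hits are found (reported with `end` past the
sequence length); it is off by default since linear replicon scanning
is the common case.

## Context annotation

Coordinates are 0-based half-open on the forward strand throughout;
1-based inclusive appears only in GFF3 I/O.  Any base overlap with an
annotated CDS makes a repeat intragenic (coding when repeat and ORF
strand agree); ties among overlapping ORFs go to the largest overlap,
then the smaller start.  Intergenic repeats are evaluated against both
flanking ORFs: the ORF's own orientation decides whether the repeat
lies upstream of its start codon or downstream of its stop codon, the
distance is the count of bases strictly between repeat boundary and
codon boundary (overlap/adjacency ⇒ 0), binned ≤ 50 / 51–100 / > 100 bp
with inclusive upper edges.  Orientation classes: both neighbors on one
strand ⇒ aligned (coding/noncoding by repeat strand), `+ −` ⇒
convergent, `− +` ⇒ divergent; a missing neighbor at a genome end is
reported as `undefined`, never dropped.

Inverted pairs are a plus-strand array whose end precedes a
minus-strand array's start by at most `max_gap` bases (default 100 bp —
the survey's "close proximity" was never quantified, so the flag is
exposed).  Matching is nearest-gap first, ties to the leftmost partner,
each array in at most one pair.

## Consensus statistics

The position-frequency matrix counts every full unit of every hit as
read on its G-rich strand (both strands pooled G-rich; trailing
partials excluded).  Information content per position is
2 + Σ f·log₂ f bits against a uniform background with 0·log 0 = 0 and
no small-sample correction — the standard logo convention.  The
canonical artifact is the PFM TSV; image rendering is left to external
logo tools.

## Conservation

A query region is the repeat-containing intergenic span plus both
flanking ORFs.  Alignment evidence is a 12-column tabular hit list
(query, subject, %identity, length, mismatches, gap opens, qstart,
qend, sstart, send, e-value, bitscore; `send < sstart` = minus strand);
query coordinates are taken on the query genome's forward strand, and
intervals are mapped across an alignment assuming collinearity.

Repeat presence: the best alignment covering ≥ 50 % of the repeat span
maps it to the subject; the mapped interval padded by `flank` (100 bp)
is re-scanned with the same preset — any qualifying hit ⇒ `conserved`,
none ⇒ `absent_or_mutated`, no covering alignment ⇒ `no_alignment`.

Region change: an ORF qualifies when a single alignment covers ≥ 80 %
of it at ≥ 80 % identity (both thresholds exposed).  Neither qualifies
⇒ `no_homology` (repeat presence then coerced to `no_alignment`);
exactly one ⇒ `flanking_change` (ORFs mapping to different subject
sequences are coerced here too, and logged); both ⇒ the change in
inter-ORF distance decides: ≥ +300 bp ⇒ `insertion`, ≤ −300 bp ⇒
`deletion`, else `no_change`.  This approximates a manual taxonomy that
distinguished gene deletions by inspection: loci whose flanking gene
vanished outright are routed to `flanking_change`, and `deletion` means
a large negative inter-ORF distance change.

Control sets draw from the pool of repeat-free intergenic regions with
two flanks: `random` samples without replacement; `position_matched`
greedily pairs each repeat region with the unused pool region of
nearest midpoint; `orientation_matched` reproduces the repeat set's
aligned/convergent/divergent composition by largest-remainder rounding.
All sampling is seeded and deterministic.

The one-sample t-test treats the five control frequencies of a category
as the sample and the repeat-group frequency as the reference:
t = (x̄ − μ₀)/(s/√n), df = n−1, two-sided p from the regularized
incomplete beta (cross-checked against an independent reference
implementation to 1e-9 in the tests).  Zero variance with mean equal to
the reference gives t = 0, p = 1; zero variance otherwise is a
degenerate-sample error rather than a silent ±∞.

## Transcript mapping

Repeats in coding regions are excluded; the rest split into a
G4-capable set and a control set of short/mutated arrays (both members
of an inverted pair kept individually).  Candidate transcripts overlap
the repeat by ≥ 1 base (or abut it exactly); the greatest overlap wins,
ties broken by expression, then length, then start — assembled
transcripts rarely tie, but the rule makes runs reproducible.
Classification: transcript 5' end inside the repeat ⇒ `start`; 3' end
inside the repeat or ≤ `max_after` (30 nt) past the repeat's 3'-most
boundary in the transcript's reading direction ⇒ `stop`; otherwise
`middle`.  `strand_content` records whether the transcript carries the
G-rich or C-rich strand.  Raising `max_after` can only move calls from
`middle` to `stop`.

## Synthetic data generator

`simulate_survey` emulates the surveyed chromosomes at desk scale: the
same repeat architecture at a higher density on a short sequence
(defaults: 40 repeats in 120 kb at 65 % GC, against roughly one repeat
per 25–30 kb on a real 5 Mb chromosome).  Unit counts follow a
distribution peaked at 4 (`{2: .20, 3: .15, 4: .40, 5: .15, 6: .06,
7: .04}`), matching the observed mode; strands are balanced; 30 % of
repeats form convergent inverted pairs with 40–90 bp gaps; the
orientation mix defaults to the observed intergenic/intragenic
composition (aligned 65 %, convergent 16 %, divergent 8 %, intragenic
11 %).  Degenerate unit positions mutate at 0.1 per position per unit
(with the preset's seed floor enforced by reverting mutated units);
G-tract point mutations (rate 0.05) are applied to terminal units,
which detaches them from the array — consistent with the scanner's
array definition — leaving the broken unit in the flanking sequence.

Backgrounds are drawn i.i.d. at the requested GC and rejection-scrubbed
so no seed heptamer (or its reverse complement) survives outside
planted loci; array flanks are additionally resampled so the in-frame
window before each array fails the degenerate pattern and the bases
after it are not a G-run.  Planted arrays are therefore exactly maximal
and the truth tables are complete: every scanner hit is planted and
every planted array is recovered verbatim, at any mutation rate.  What
the generator does **not** emulate: codon structure and GC skew inside
ORFs, operons, mobile elements, or repeat length/density gradients —
so passing tests demonstrate the correctness of the measurement
machinery, not biological claims about real genomes.

`simulate_ortholog` copies the survey genome and applies at most one
edit per intergenic region — intergenic insertion, intergenic deletion
(clipped to the space before the first repeat), scrambled right
flanking ORF, or scrambled whole locus — at configurable rates, with an
optional separate rate table for repeat-free background regions
(edits whose spans would collide are skipped).  Exact truth alignments
(100 % identity rows ≥ 30 bp) cover every unedited block, which makes
the conservation classifier's confusion matrix diagonal by
construction.  `simulate_transcripts` realizes an exact position-class
mix per intergenic repeat under the classifier's own rules, clipping
transcript extents so no transcript reaches a neighboring repeat; stop
offsets are drawn from 0–30 nt.

All generators are pure functions of (parameters, seed).

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on synthetic
data: scanner/oracle equivalence uses 110 motif-salted sequences of
0.5–20 kb; closed-loop surveys use 20–60 repeats on 80–220 kb genomes;
the t-test cross-check uses 1000 random samples of size 3–14.  These
sizes keep the full suite under ~10 s while exercising every rule
branch.  Fraction partitions are compared exactly where the generator
is deterministic and to 3 binomial standard errors where it is
stochastic; floating-point partition sums use a 1e-9 tolerance.

## Known limitations

* Alignment-based mapping assumes collinearity within one alignment row
  (gaps inside an alignment shift mapped subject coordinates slightly;
  with the default 100 bp flank this does not affect presence calls).
* The region classifier sees only the two flanking ORFs; rearrangements
  that preserve both ORFs and the inter-ORF distance are invisible.
* The PQS scanner reports maximal chains only and does not score
  thermodynamic stability.
* Circular scanning uses a bounded origin pad (512 bp for repeats,
  256 bp for PQS); arrays longer than the pad that span the origin
  would be truncated.
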