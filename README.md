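# g4reps

Bacterial genomes — notably *Xanthomonas* species and cyanobacteria such
as *Nostoc* — carry an unusually abundant class of G-rich heptameric
simple sequence repeats.  Tandem arrays of units like `GGGAATC` (or
`GGGGATT`/`GGGGACT`) supply one G-tract per unit, so an array of four or
more intact units can fold into a G-quadruplex (G4): four runs of
guanines held together by stacked G-tetrads.  These repeats concentrate
in intergenic regions close to start and stop codons, often occur as
convergent inverted pairs, and sit at unusually conserved genomic loci —
all of which suggests a regulatory rather than a mutagenic role.

`g4reps` is a tested, reusable pipeline for surveying this repeat class:

* **repeat scanning** — maximal tandem arrays of degenerate 7-mer units
  (IUPAC pattern, e.g. `GGGANTN`), seeded by at least one exact consensus
  heptamer, on both strands, with G4-capability calling;
* **PQS scanning** — a generic putative-quadruplex motif scan
  (≥ 4 G-tracts of ≥ G₃, loops L₁–₅ by default);
* **context annotation** — intragenic/intergenic classification,
  aligned/convergent/divergent orientation of flanking ORFs, distances to
  the nearest start/stop codon binned 0–50 / 50–100 / > 100 bp, and
  detection of convergent inverted repeat pairs;
* **consensus statistics** — position-frequency matrix of the heptamer
  unit with per-position information content, unit-count histograms,
  composition tables;
* **conservation analysis** — classification of repeat loci against an
  orthologous genome from 12-column local-alignment tables
  (no change / insertion / deletion / flanking change / no homology),
  control sets of repeat-free intergenic regions (random, position
  matched, orientation matched) and per-category one-sample t-tests;
* **transcript mapping** — position of each repeat on assembled
  transcripts (start / stop / middle / no transcript, with a 30 nt
  stop window) split into G4-capable and control sets;
* **synthetic data** — seeded generators of survey genomes, edited
  ortholog genomes with exact truth alignments, and transcript sets,
  with complete ground-truth tables, so every stage is testable offline.

## The core definitions

A repeat array is a maximal run of adjacent 7-mer windows, anchored on an
exact seed occurrence, in which every window matches the degenerate unit
pattern.  For the xanthomonad family the unit is `GGGANTN` with seed
`GGGAATC`, requiring ≥ 2 units (total length ≥ 14 bp) and ≥ 1 seed; for
the *Nostoc* family the unit is `GGGGANT` with seeds `GGGGATT`/`GGGGACT`
and ≥ 2 seed units.  A trailing `GGG` after the last unit is recorded as
a partial unit.  A unit contributes an intact G-tract when its first
three bases are all G; an array is **G4-capable** iff it contains a run
of ≥ 4 consecutive intact tracts — the minimal folding motif being
(GGGAATC)₃GGG.

The conservation t-test follows the survey design: for each region-change
category the five control-set frequencies form the sample and the
repeat-group frequency is the reference value,

t = (x̄ − μ₀) / (s/√n),  df = n − 1,

with the two-sided p-value from the regularized incomplete beta function.

## Worked example

Generate a small synthetic survey genome and produce the headline report:

```bash
g4reps simulate -o demo --seed 5 --n-repeats 20 --genome-length 80000
g4reps report demo/genome.fasta demo/orfs.gff3 -o demo/report.json
```

The report (abridged) reads:

```json
{
 "genome_id": "synthetic_survey",
 "genome_length": 80000,
 "repeat_count": 20,
 "g4_capable_count": 10,
 "unit_histogram": {"2": 6, "3": 4, "4": 6, "5": 3, "6": 1},
 "composition": {
  "strand": {"+": 0.6, "-": 0.4},
  "location": {"intergenic": 0.9, "intragenic": 0.1},
  "category": {"aligned_coding": 0.35, "aligned_noncoding": 0.4,
               "convergent": 0.1, "divergent": 0.05,
               "intragenic_coding": 0.05, "intragenic_noncoding": 0.05}
 },
 "inverted_pair_count": 3
}
```

All 20 planted arrays are recovered (`repeat_count` equals the truth
table in `demo/truth.json`); half are G4-capable (≥ 4 intact tracts);
90 % lie in intergenic regions; the unit histogram shows the expected
mode near 4 units.  `repeats.bed` holds the scanned coordinates (BED6,
0-based half-open), and `g4reps annotate` / `conserve` / `transcripts`
continue the analysis from these files.  Real genomes enter the same way:
a FASTA/GenBank sequence plus GFF3/GenBank CDS annotations.

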