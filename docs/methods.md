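# Methods

## Overview

`capq` analyses capture-release sequencing of RNA substrates of the queuine
tRNA ribosyltransferase (QTRT). The assay's chemistry converts enzyme binding
into a sequence-level signal: released substrates carry an abasic site at
anticodon position 34, which HIV reverse transcriptase converts into either a
thymidine misincorporation (a G→T transversion in read space) or a truncated
cDNA. The pipeline turns aligned reads into coverage regions, per-site
transversion ratios, filtered substrate records, and composition summaries;
a synthetic generator reproduces the assay's read-level signature so every
stage can be validated against ground truth.

## Coordinate and alphabet conventions

- Internal reference alphabet is RNA (U); FASTA is written as DNA. Reads and
  everything downstream of alignment (pileup, calls) live in DNA read space,
  which is why the diagnostic transversion is written G→T.
- Annotation tables are 1-based inclusive (human-readable); all internal
  interval arithmetic is 0-based half-open; BED output keeps the half-open
  convention and TSV reports 1-based positions. The converters in
  `references`/`signature` are the only crossing points.
- Reference sequences are stored as the genomic plus strand;
  `anticodon_start` indexes the transcript. A gene on the minus strand
  therefore shows its diagnostic site as C→A at the mirrored coordinate, and
  `transcript_position` maps a genomic site back to transcript numbering.
  This is deliberate: it makes the dual G→T / C→A rule arise from the data
  model rather than being special-cased.

## Substrate-recognition rules

A tRNA is a Q-family (GUN) substrate iff anticodon base 34 is G and base 35
is U (Tyr GUA, Asp GUC, His GUG, Asn GUU). Codon decoding pairs anticodon
bases 36/35 with codon positions 1/2 by Watson–Crick complementarity; at the
third codon position G34 wobble-pairs with C and U, giving the dual
synonymous NAU/NAC codons. The wobble extension is limited to G34 — no
inosine or other expanded wobble is modelled, because only G34 behaviour is
asserted by the recognition rule this package implements.

### Stem-loop folding

Designed oligos are folded with a deliberately structural, non-thermodynamic
model: a single hairpin with one contiguous stem of stacked Watson–Crick
pairs (G·U optional behind a flag, default off — the two reference 19-mers
fold identically either way), loop ≥ 3 nt, scored by stem length. Ties break
toward the most central loop, then the smallest loop start. The model class
is small enough to enumerate exhaustively, which is exactly what the test
oracle does; agreement is checked on every sequence ≤ 25 nt in the test set.
Substrate rule: loop length exactly 7 with loop positions 2–4 reading U-G-U
(tRNA positions 33–35); the anticodon is loop positions 3–5. A pair-count
objective rather than free energy is appropriate because the inputs are
short designed oligos where the structural question is only *which* hairpin
register forms, not its stability.

## Synthetic data generator

`simulate_capture` emulates, per molecule drawn from a Poisson abundance
model:

| parameter | default | meaning |
|---|---|---|
| `captured_fraction` | 0.85 (per GUN tRNA) | probability a molecule is a captured enzyme substrate |
| `p_readthrough_T` | 0.6 | RT reads through the abasic site inserting T |
| `p_readthrough_other` | 0.1 | read-through with a random non-T base |
| `p_terminate` | 0.3 | cDNA terminates at the abasic site |
| `p_backbone_cleave` | 0.0 | NaOH splits the molecule into 5′/3′ fragments |
| `seq_error_rate` | 0.005 /base | uniform substitution error |
| `read_length` | 65 | single-end cycle count |
| `contaminant_fraction` | 0.0 | reads drawn from the contaminant set |
| `cca_tail` | on | append CCA to mature tRNA molecules |

The three RT outcomes must sum to 1. The 0.6/0.1/0.3 split encodes
"read-through with thymidine in the majority of cases, termination in a
significant proportion" while leaving the ≥30% ratio filter clearly
attainable; it is an ordinary config field, not a constant. Truncation
places the cDNA 5′ end exactly at the base after the abasic site (optional
jitter parameter), so with `p_terminate > 0` mean coverage 3′ of the site
strictly exceeds 5′ coverage — the coverage-asymmetry pattern of real runs.
Backbone cleavage is exposed as a probability rather than fixed because the
assay chemistry does not pin down a rate.

The truth table has one row per emitted read (origin, interval, captured
flag, RT outcome, contaminant flag) and per-reference margins that must
equal the read counts exactly; outcome labels `cleaved_5p`/`cleaved_3p`/
`none` extend the three RT outcomes so the rows stay exhaustive.

What the generator does **not** emulate: ligation/PCR bias, duplicates,
quality-score structure, indels, splicing, partial degradation, and genomic
multi-mapping families (each gene is one reference). Passing recovery tests
therefore demonstrates the analysis logic is correct under the assay's
idealized signature, not that the wet-lab numbers would be reproduced from
raw reads.

## Pipeline stages and numerical choices

Fixed order: deplete → clip CCA → align (or ingest SAM) → pileup → regions →
calls → filter → quantify → classify → summarize, with per-stage read-count
conservation checks that raise on mismatch.

- **Depletion**: a read is a contaminant if an exact 12-mer seed extends to a
  full-length ungapped match with ≤ 2 mismatches (both strands). k=12/m=2
  keeps a 65-cycle read with two sequencing errors matchable; retained reads
  pass through byte-identical and in order.
- **CCA clipping**: exactly one full terminal CCA is removed; partial tails
  (CC/C) are kept because trimming them would erode genuine 3′ sequence.
- **Fixture aligner**: exhaustive ungapped scan of every reference window on
  both strands, best hit by (mismatches, plus strand first, reference order,
  position); ties flagged mapq=0 and counted once at the chosen locus. If a
  full-length read has no acceptable placement, up to 4 3′ bases are
  soft-clipped one at a time and the scan retried — reads that run a base or
  two into a partial CCA tail (molecule marginally longer than the cycle
  count) are otherwise unplaceable under full containment, while a spliced
  aligner would soft-clip them. The aligner is for synthetic panels; real
  data should arrive as SAM from any aligner, making the pipeline
  aligner-agnostic by contract.
- **Pileup/regions**: depth ≥ 10 (inclusive) defines coverage islands; runs
  are maximal and never merged across a failing position. No base-quality
  weighting is applied (the generator emits constant qualities and the
  filter is ratio-based).
- **Transversion calls**: only G→T and C→A are considered; sites with zero
  alt reads are not emitted. Minimum calling depth coincides with the region
  floor.
- **Filter**: region length strictly > 16; best-site ratio ≥ 0.30 and
  best-site depth ≥ 10 inclusive — mirroring the >16 / ≥30% / ≥10 symbols
  exactly. The ratio applies to the region's *best site* (ties: higher
  depth, then smaller position), because the mechanism predicts one abasic
  site per captured molecule; a region average would dilute the signal.
  Truncated reads contribute coverage only where they align; no stop-signal
  inference is attempted.
- **Quantification**: RPKM and TPM are computed over detected regions as
  transcript proxies, not gene bodies. Percentage denominators are a flag:
  `total_mapped` (reads outside regions appear as `unassigned`) or
  `in_regions` (the natural denominator when aggregating per-run region
  tables). Cytosolic tRNA is labelled GUN only when the annotated anticodon
  passes the Q-family rule; mitochondrial tRNA is reported jointly.

## Study-condition runs

`capq.studies` defines synthetic stand-ins for the three tissue runs the
assay was applied to, as captured-pool molecule fractions (GUN tRNA /
snoRNA / 45S / other): MDA-MB-231 ≈ 99.45/0.40/0.05/0.10, neonatal liver ≈
96.5/1.5/0.5/1.5, splenocytes 92.7/4.7/2.6/0 — the splenocyte snoRNA and
45S values at their reported levels with GUN tRNA as the remainder. Each run
draws 20 000 molecules over a 10-gene panel (4 cytosolic GUN, 1
mitochondrial GUN, 2 non-GUN tRNA, 2 snoRNA, 1 45S fragment) with a 2%
contaminant fraction. These sizes keep a full run at a few seconds on one
core while leaving per-category binomial errors well below the margins being
tested; they are the package's default study conditions, fixed before use
and not tuned per outcome. The acceptance script re-simulates and re-analyses
these runs from scratch and reports the recovered percentages.

## Known limitations

- The fixture aligner is O(reads × panel length) and unsuitable beyond small
  panels; it exists so tests need no external aligner.
- Single contiguous-stem hairpin model: no bulges, multiloops or pseudoknots;
  adequate for designed anticodon stem-loops, not general RNA folding.
- Multi-mapped reads are counted once at a deterministic primary placement;
  a `drop_mapq0` flag exists for sensitivity analysis, but locus-level
  disambiguation (e.g. mitochondrial tRNA lookalikes in nuclear genomes) is
  out of scope.
- The U33 requirement is enforced for stem-loop classification as part of
  the recognition motif; whether U33 is strictly necessary is not dissected
  by the classifier.
- Compositions recovered from synthetic runs validate the pipeline, not the
  underlying biology; real-run reproduction requires the original raw reads,
  which are not publicly deposited.
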