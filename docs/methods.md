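# Methods

## Overview

`ont16s` implements an identification pipeline for pure bacterial isolates
sequenced across the full-length (~1,500 bp) 16S rRNA gene with long,
error-prone reads, together with the supporting analyses used to validate
such a pipeline: consensus stability as a function of read count, and a
paired comparison of identification levels between the long-read arm and a
classical ~500 bp (V1–V3) Sanger-style arm.

The pipeline per sample:

1. **Quality filter.** Remove reads shorter than 20 nt or with an
   arithmetic mean Phred score below 7. Boundaries are inclusive on the
   keep side (length 20 and mean 7.0 pass). The mean is of integer Phred
   scores, not the Phred of the mean error probability — the simpler
   reading, and the two differ little at the scores involved.
2. **Dominant-genus screen.** Draw a uniform random subsample of 1,000
   passing reads (all reads when fewer), classify each read to the genus
   of its best reference hit, and continue only when one genus accounts
   for strictly more than 50% of the subsample. Reads whose best identity
   is below 80%, or whose best hits tie across genera, are *unassignable*:
   they join no genus but remain in the denominator, so low-quality reads
   can only make the stop rule more conservative, never less.
3. **Genus profile.** Align the genus's reference (centroid) sequences
   into a multiple alignment by center-star: the center is the centroid
   with the greatest summed pairwise alignment score; pairwise alignments
   to the center are merged under "once a gap, always a gap".
4. **Frequency matrix.** Align every QC-passing read (not just the
   subsample) to the profile's column-wise majority string, and tally per
   profile column the read bases and gaps. Reads below 80% identity to
   the profile are skipped and counted. Terminal indel runs of a read's
   alignment are treated as end gaps — the read does not cover those
   columns — and read insertions relative to the profile are dropped, so
   the consensus lives in the profile's coordinate system.
5. **Consensus call.** Per column with depth ≥ 5 reads: every symbol
   (four bases + gap) whose frequency is ≥ 40% joins the call set. One
   base → that base; several bases → their IUPAC ambiguity code; a gap
   that qualifies and strictly beats every qualifying base deletes the
   column, and a gap tying a base loses to it. Columns below the minimum
   depth are trimmed at the ends and masked as `N` internally. If no
   column reaches the minimum depth the sample has no consensus and the
   run fails with an explicit error.
6. **Database match and interpretation.** The consensus is compared to
   every centroid; the top five species are reported sorted by percent
   identity, then mismatches, then accession (a total, reproducible
   order). Hits with a matched span under 1,250 bp (long arm) or 400 bp
   (short arm) are excluded before interpretation.

## Interpretive ladder

Identification level follows MM18-style thresholds, all configurable:

| level   | rule (defaults)                                                  |
|---------|------------------------------------------------------------------|
| species | identity ≥ 99.0% (general), ≥ 99.6% (aerobic actinomycetes, plus separation > 0.4 percentage points to the next distinct species in standard mode), 100% (*Mycobacterium*) |
| genus   | identity ≥ 97.0%                                                 |
| family  | identity ≥ 95.0%                                                 |
| no ID   | below 95%                                                        |

The quoted thresholds for actinomycetes (99.6%, 0.4 pp) , *Mycobacterium*
(100%) and the family floor (95%) are the documented interpretive rules;
the 99.0%/97.0% general species/genus defaults are common practice and
deliberately surfaced as configuration rather than claimed as normative.
"Modified" mode waives the actinomycete separation clause: species at
≥ 99.6% regardless of the distance to the runner-up.

Two design choices were genuinely open:

* **Distance score.** "Separation to the next closest species" is the
  difference in percent identity between the top species and the best hit
  of a *different* species, compared strictly (> 0.4).
* **Exact ties.** When the top two kept hits are different species with
  identical percent identity *and* identical mismatch counts the data
  cannot name a species; the call demotes to genus in both modes. This is
  what makes the short arm report genus for species that are identical
  over the first 500 bp.

The organism group (general / actinomycete / mycobacterium) is an input,
normally derived from a genus→group map; it is never inferred from the
sequence. The reference carries no family field, so a family-level result
reports "family of <Genus>" unless a genus→family table is supplied.

A composite confidence score in [0, 1] accompanies species attributions:
a weighted mean (weights 0.4/0.2/0.2/0.2) of top identity rescaled from
[95, 100] to [0, 1], identity separation to the runner-up capped at 1
percentage point, the genus dominance fraction, and the fraction of
consensus positions that are unmasked plain bases. Each component is
monotone, so the score is monotone in each input.

## Alignment

The scored aligner is an affine-gap (Gotoh) dynamic program with free end
gaps on both sequences, row-vectorised in numpy, exact (no banding or
heuristics). Default scoring: match +2, mismatch −3, gap open −5, gap
extend −2; a gap of length L costs open + (L−1)·extend, and gaps open
from the match state only (no adjacent insertion/deletion switch). IUPAC
ambiguity codes match any base in their set, so consensus ambiguities are
not penalised against references. Identity accounting is BLAST-like: the
matched span runs from the first to the last aligned column; internal gap
columns count as mismatches and enter the denominator; end gaps do not.
Ties in the traceback prefer diagonal, then vertical, then horizontal
moves, making the alignment deterministic.

Per-read work (database prescreen, read classification, read-to-profile
placement) uses edlib's bit-parallel edit-distance alignment instead: at
thousands of 1.5 kb alignments per sample the exact scored DP is
uneconomical, and for ranking reads and placing them at an 80% identity
floor, unit-cost alignment is an adequate surrogate. Database ranking of
a consensus prescreens all records by edit distance, then re-aligns the
closest dozen (or 3k if larger) with the scored DP. The test suite checks
the scored aligner against a brute-force pure-python DP on 200 random
pairs and against an independent established aligner under a linear gap
penalty.

## Stability analysis

The expected consensus is built from all reads of a sample; prefix
subsets (the first 500 reads, 1,000, ... up to 20,500 by default) each
yield their own consensus, compared to the expected one by an
alignment-aware Hamming distance: equal-length sequences are compared
position-wise; unequal lengths are globally aligned and gap columns count
as mismatches. The distance is zero exactly when the sequences are
identical; `N` equals only `N`. The frequency matrix is accumulated
incrementally, so every read is aligned once regardless of the number of
subsets. The minimum stable read count is the smallest subset size from
which every curve stays within a tolerance (default 4 bp — differences
of that order do not change an identification) for all larger subsets;
this operationalises the visual "where the curve flattens" criterion
explicitly.

## Paired comparison

Identification levels of the two arms are cross-tabulated (4×4 over
no ID / family / genus / species). Whether the long-read arm reaches a
level significantly more often is tested with McNemar's exact test on the
discordant pair counts — the two-sided binomial tail of min(b, c) in
b + c trials at probability ½ (via statsmodels) — because discordant
counts in this setting are small (≤ 12); the continuity-corrected
chi-square form is exposed but never silently substituted. "Improvement
to at least level L" collapses the table to the paired binary "reached
≥ L". Concordance at a rank is counted among pairs where both arms
reached the rank; slash-group taxa ("X phocaicum/mucogenicum") are
concordant when any component matches.

## Synthetic data

The generator emulates exactly the structure the pipeline exercises:

* **Reference.** A root sequence drawn uniformly over {A,C,G,T}; per
  genus an ancestor mutated at the inter-genus divergence (default 10%,
  so realised pairwise inter-genus distances are well above the 5%
  screen margin); per species the ancestor mutated at the intra-genus
  divergence (default 1.5%, the typical congeneric 16S range of 0.5–3%).
  Default shape: 5 genera × 3 species, 1,500 bp.
* **Reads.** I.i.d. per-base substitution/deletion draws plus single-base
  insertions (defaults 3%/1%/1%, ~5% total — mid-accuracy nanopore
  chemistry), Phred qualities drawn normal (mean 12, sd 3) and clipped
  to [2, 41].
* **Short arm.** The template's first 500 bases (V1–V3 stand-in),
  optionally with a small substitution rate (default 0 — Sanger
  consensus traces are nearly error-free).
* **Challenge construction.** Congeneric species whose distinguishing
  substitutions are confined beyond position 500: identical over the
  short fragment, ~1% divergent over the full gene. This reproduces the
  directional effect that full-length sequencing resolves species the
  first 500 bp cannot.

What the generator does **not** model: rate heterogeneity along the gene
(real variable regions V1–V9), homopolymer-specific indel bias (the
dominant nanopore error mode), chimeras, quality–error correlation, and
mixed or contaminated cultures beyond simple two-genus mixtures. Passing
tests therefore demonstrate the pipeline's logic and its behaviour under
a clean error model, not clinical performance against a curated
full-scale database.

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; there is no global RNG state, and identical
inputs yield byte-identical outputs (consensus calling, profile
construction and ranking are fully deterministic, with documented
tie-breaks: alphabetical for majority bases, accession order for equal
hits, base-over-gap at gap ties).

## Problem sizes in tests and the acceptance script

Simulation-backed checks run at reduced but representative sizes chosen
as the package's own test conditions: consensus recovery at the stated
1,500 bp / 50-read depth over 10 replicates; dominance over 20 replicates
of 40–60 reads against the default 15-species reference (the dominance
fraction is depth-independent for a pure isolate); stability on a
2,000-read sample in 500-read increments. The published 153-isolate
paired-level table is carried as its 11 cell counts and re-expanded at
run time; its marginals and both McNemar bounds are recomputed, never
asserted as constants.

## Known limitations

* The reference here is a synthetic stand-in for a curated centroid
  database; per-isolate identities of the original study are not
  reproducible without it and are out of scope.
* Reads are placed against the profile's majority string rather than the
  full MSA or a profile HMM — an explicit approximation that preserves
  column bookkeeping at a fraction of the cost.
* The consensus cannot extend beyond the genus profile's coordinates;
  true insertions relative to every centroid of the genus are invisible.
* Family-level naming depends on an optional genus→family table.
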