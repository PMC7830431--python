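# Methods

This note documents the models and procedures implemented in `ytriage`,
the assumptions behind them, the defaults that matter, and what the
synthetic fixture study does and does not establish.

## Homology engine

Every homology step (triage, repeat masking, spliced transcript
alignment, boundary profiling, gametolog divergence, PAR ordering) runs
on one self-contained seeded local aligner (`ytriage.homology`):

* exact k-mer seeds (default k = 15, range 2–31) indexed over the
  reference with both strands retrievable; seeds containing N are
  excluded;
* seeds grouped per (target, strand) into diagonal bands with a
  tolerated drift of 30 bases and a maximum within-band seed gap of
  1,000 bases;
* each band extended ungapped with an x-drop rule (match +1,
  mismatch −2, drop-off 20);
* identity = matches / aligned columns, mismatches in the denominator,
  N never matching; hits below 50 aligned bases are dropped by default;
* equal-score hits ordered by (target id, target start) for determinism.

The engine targets substitution-dominated divergence. It performs no
gapped alignment and computes no E-values; acceptance is gated on
percent identity over a minimum aligned length instead of on alignment
statistics. Where a published protocol would gate a nucleotide search on
an E-value, the equivalent gate here is identity ≥ 0.80 over ≥ 100
bases — a deliberate divergence, documented because the two criteria
agree on the fixture regime (≥ 90% planted identity vs. i.i.d.
background) but are not interchangeable near the detection floor. The
test suite checks the engine against a full Smith–Waterman dynamic
programme on instances up to 2 kb (identity within half a point,
interval Jaccard ≥ 0.9).

With i.i.d. uniform background sequence, a spurious 15-mer match
appears roughly once per 10^9 query·target base pairs and never extends
past the 50-base length gate, so "no significant similarity" is a
clean, reproducible outcome on the fixture genomes.

## Spliced alignment and copy individuation

Transcript-to-contig alignment chains exon-candidate hits (identity
≥ 0.8, length ≥ 30) by colinearity in both transcript and contig
coordinates, within a maximum intron of 10 kb, separately per strand.
Chains are extracted by repeated best-chain dynamic programming with a
linear intron cost of 0.005 per base. That constant is load-bearing for
ampliconic arrays: it is large enough over an inter-copy distance
(≥ 2 kb ⇒ cost ≥ 10) to dominate per-copy identity noise (≲ 6 score
units between near-identical copies), so every exon pairs with its own
copy's partner rather than a neighbour's, yet small enough (10 kb intron
⇒ cost 50) never to outweigh a real exon. Blocks whose contig gap is
under 40 bases merge into one exon (x-drop overruns past an exon end are
bounded well below this); chains may overlap by up to 40 bases in
transcript coordinates for the same reason.

Each chain becomes one gene model. Two chains are distinct copies when
their contig footprints overlap by less than 20% of the shorter
footprint; otherwise the higher-coverage chain wins. Completeness:
FULL at ≥ 95% transcript coverage (all exons present near reference
length), FRAGMENT below 200 matched bases, TRUNCATED in between. Copy
totals count FULL + TRUNCATED; fragments are reported separately. Two
TRUNCATED models on different contigs whose transcript intervals are
disjoint (tolerance 30 bases) and jointly cover ≥ 90% of the transcript
merge into one SPLIT single-copy call; models that share exon 1 never
merge. Cross-species annotation mode relaxes identity to 0.75, shortens
seeds to k = 11, and assigns LOCATED to chains too weak for structure
(matched < 200 bases or identity below the standard gate) — the gene is
placed but its exon-intron structure is left unresolved.

ORFs are scanned in six frames; an ORF runs from the first ATG after
the previous in-frame stop to that stop (one maximal ORF per stop), with
stop-less ORFs reported as partial; the default floor is 100 residues.

## Triage

Gates: identity ≥ 0.95 (per hit) and union query coverage ≥ 0.25,
following the published significance convention for this analysis;
length threshold 8,034 bases — the mean long-read length of the emulated
study, taken as a fixed parameter because read data are out of scope.
Autosome/unplaced homology takes precedence over X homology
(contamination is removed before PAR assignment). Contigs that pass
coverage but sit within 2 identity points of the gate are flagged
near-threshold rather than silently classified. Short contigs
short-circuit: they are never homology-checked.

In-silico PCR matches primer sites with ≤ 2 substitutions and an exact
3'-terminal 3 bases, both primer orientations, product size 50–2,000 bp.
More than 3 products in the male genome is treated as a ladder-like,
ambiguous pattern (the threshold is a design choice; the phenomenon is
qualitative). A putative-MSY contig with at least one male-specific
marker is "validated MSY" in the pipeline summary.

## Boundary detection

The X-coverage profile uses 10 kb windows at 2 kb steps (window ≥ 1 kb
enforced; sub-window contigs collapse to one window). The changepoint
maximizes mean(left coverage) − mean(right coverage) with a guard flank
of 5 windows (shrunk proportionally on short profiles); a call requires
left mean ≥ 0.5 and right mean ≤ 0.1, otherwise the contig is uniform
and no boundary exists. Base-precision refinement re-aligns the two
windows around the transition and takes the rightmost X-homologous base
(identity ≥ 0.9). On fixtures the refined coordinate lands within a few
bases of the planted breakpoint; the documented tolerance is ±1,000.

PAR contigs are ordered by best-hit placement on a template X sequence;
overlapping placements resolve to the higher identity with the loser
flagged unplaced. The PAR coverage statistic reports the raw fraction,
the one-decimal percentage, and the round-half-up integer side by side:
3.74 Mb over a 7.0 Mb span is exactly 53.4%, while the figure printed in
the emulated study's style of reporting rounds to 54% — consistent with
an unrounded span estimate — so the report exposes both rather than
silently matching either.

## qPCR copy number

Single-animal design: there is no calibrator sample, so the two-sample
ΔΔCt collapses to a single ΔCt against the single-copy reference gene.
Per assay, ΔCt = mean Ct(target) − mean Ct(reference) and
fold = (1 + E)^(−ΔCt) with efficiency E = 1.0 by default (the parameter
is exposed but no dilution-series calibration is modelled). Duplicate
assays combine by geometric mean because fold changes are
multiplicative; dispersion is the square root of the mean per-assay
variance of per-replicate folds, reported as missing for single
replicates. The reference gene's own estimate is exactly 1 by
construction. Simulated tables (ΔCt noise sd 0.15 cycles, 2 assays × 3
replicates) recover true ratios 1–26 with median error within 10%.

## Neighbor joining

Uncorrected p-distance by default (columns with a gap or N in either
sequence excluded; a Jukes–Cantor correction is available behind a
flag, since "standard parameters" of distance-tree software leave the
model ambiguous). Classic Saitou–Nei agglomeration; ties in Q break to
the lowest (row, column) pair; negative branch lengths are clamped to
zero with the deficit moved to the sibling branch, preserving the
joined pair's path length. On additive matrices the output path-length
matrix equals the input to 1e−9 (tested to 12 taxa, and against an
independent NJ implementation for topology). Rooting: midpoint of the
longest leaf-to-leaf path, or on the branch separating a monophyletic
outgroup (non-monophyletic outgroups raise an error naming the smallest
containing split).

## Synthetic fixture study

The generator (`ytriage.synthetic_data`) is the package's study stand-in
and is itself first-class, tested code. Design choices:

* **Substitutions only.** Divergence is simulated as an exact count
  round(rate × length) of substitutions at uniform positions, each to a
  different base. Planted coordinates and identities are therefore
  exact, which makes the ground-truth manifest trivially checkable.
  Indel robustness is consequently *not* exercised by the fixtures; the
  aligner's gapless design is matched to this regime, and results on
  real, indel-containing data would require a gapped or chain-splitting
  treatment of the same interfaces.
* **i.i.d. uniform background.** Keeps spurious cross-identity far
  below the triage gates. Real genomes share repeat families between
  the Y and the autosomes — precisely the phenomenon that complicates
  real PCR validation — so fixture male-specificity results are cleaner
  than real ones; primer specificity on the fixtures demonstrates the
  logic, not field performance. Base composition is uniform (50% GC),
  so fixture GC values do not mimic the 33–45% range of real contigs.
* **The `paper` preset** plants the emulated study's architecture at
  its published coordinates: a 2-exon ampliconic gene in 26 copies
  (15 direct + 1 inverted / 9 direct / 1 on the boundary contig), a
  7-exon gene with an extra inverted copy truncated to exons 1–4, a
  28-exon single-copy gene split exons 1–16 / 17–28 across two contigs,
  3 full copies + 2 sub-200 bp fragments of a 4-exon gene, a 723-base
  single-exon coding gene (240-residue ORF), a location-only
  cross-species case, and a 307,557-base contig whose first 177,307
  bases derive from the X at 99.1% identity. PAR contigs sit at
  98.5–99.5% identity, contaminants at 96–97% (the emulated study gives
  only the ≥95% gate; the fixture values are free parameters),
  junk below 8,034 bases. Repeat targets per MSY contig: LINE 10%
  (3'-anchored truncated copies of a 3 kb consensus, 10% diverged),
  LTR 3%, SINE 1%, microsatellites 1%.
* **Scale.** X scaffold 320 kb, twelve MSY contigs of 12–70 kb, total
  ≈ 1.3 Mb — large enough that windows, arrays and split genes are
  non-trivial, small enough that the full study (generation, triage,
  annotation, boundary, qPCR, trees) runs in seconds. The `small`
  preset (≈ 0.3 Mb) backs the randomized property tests (20-seed label
  recovery, breakpoint recovery at random planted positions).
* Intron lengths default to 200–2,000 bases so spliced alignment is
  exercised while fixtures stay small; gene copies diverge 1% from
  their transcript; Ct noise sd 0.15 cycles.

Identical spec + seed give byte-identical outputs; all randomness flows
from one `numpy` generator.

## Reported problem sizes

The acceptance script regenerates the `paper`-preset fixture (21 Y
contigs, 766,557 bases), detects ampliconic copies across all of them,
refines the boundary on the 307,557-base contig with 10 kb/2 kb
windows, and estimates the 13-copy target from 2 assays × 3 replicates.
The test suite uses the same presets plus reduced randomized instances
(alignments ≤ 2 kb against the exhaustive DP oracle, trees ≤ 12 taxa,
200 simulated Ct tables per ratio).

## Known limitations

* No gapped alignment: indel-rich or low-identity (< ~75%) homology is
  invisible or fragmented; E-value semantics are not reproduced.
* Repeat masking is identity-gated consensus matching; it does not
  reproduce scoring-matrix or divergence-aware masking, so fractions on
  real data will differ from dedicated repeat annotators.
* The boundary detector assumes a single PAR/MSY transition per contig.
* qPCR efficiency is fixed at 1.0 unless supplied; no melting-curve or
  dilution-series modelling.
* Trees require pre-aligned input; no alignment or bootstrap support.
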