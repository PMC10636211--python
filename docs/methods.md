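# Methods

This note records the models behind each stage, the parameters that
matter (with defaults and rationale), what the synthetic data emulate and
do not, and the numerical choices made where the design was open.  It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Translated homology search

Viral protein queries are searched against all six reading frames of a
nucleotide genome, the standard approach for finding endogenized viral
fragments whose reading frames have decayed.

*Translation.*  Standard genetic code; codons containing N translate to
X; stop codons are emitted as `*` and retained so that alignments can
run through them.  Negative frames translate the reverse complement; each
frame carries an exact map from amino-acid positions back to
forward-strand nucleotide coordinates, and every emitted interval is
0-based half-open on the forward strand with strand stored separately.

*Scoring.*  BLOSUM62 with affine gaps, open 11 / extend 1 (a gap of
length L costs 11 + L).  These are the conventional translated-search
defaults; nothing in the protocol being reproduced specifies otherwise,
so they are stored in `ScoringScheme`/`PipelineConfig` and overridable.
`*` scores −4 against every residue, including itself: endogenized
fragments accumulate nonsense mutations, and treating stops as ordinary
mismatches lets one local alignment span them instead of fragmenting.

*Statistics.*  E = K·m·n·e^(−λS) with m the query length in residues and
n the total translated residues searched over all six frames of all
contigs; bit score (λS − ln K)/ln 2.  λ = 0.267 and K = 0.041, the
published gapped BLOSUM62-11-1 constants, fixed rather than empirically
recalibrated per search: at desk scale a deterministic, auditable
statistic is worth more than a per-run fit, and thresholds downstream
(1e−5, 1e−10, 1e−20) are orders of magnitude away from the regime where
the constants' second digit matters.

*Seeding and extension.*  Exact protein 4-mers (one-hit trigger), skipping
seed words containing X or `*`.  Each seed is extended ungapped with an
X-drop of 20 score units; extensions reaching 40 raw score units trigger
a gapped realignment: full affine Smith–Waterman of the query against a
subject window spanning the seed diagonal ± a band half-width of 32
residues.  The windowed score can never exceed the full per-frame
Smith–Waterman optimum, which gives the engine a testable dominance
property against the exhaustive oracle; the oracle itself is implemented
independently (same kernels, no seeding or windowing) and is additionally
cross-checked against a third-party pairwise aligner in the tests.
Hits are deduplicated by subject-interval containment (higher score
wins; among equal scores the smaller subject start is kept), and DP
traceback ties resolve diagonal > up > left, so outputs are
deterministic.  Frameshifted elements produce separate per-frame hits by
design; stitching them is the catalogue's job, not the aligner's.

*Trade-off.*  The one-hit 4-mer trigger with a 40-unit gapped threshold
recovers decayed homology down to ~60% amino-acid identity over ≥ 40
residues while triggering essentially no gapped work on random sequence
(the acceptance run reports zero catalogued loci on a 1-Mb implant-free
genome).  Much shorter or much more diverged fragments than the study's
own stringency floor (350 nt, e < 1e−10) are outside the intended regime.

## Locus catalogue

Hits with e-value < 1e−5 on the same contig and strand separated by at
most `max_gap_nt` are merged into loci spanning min(start)–max(end).
The merge distance is not specified by the protocol ("consecutive" hits);
the default is 1000 nt, large enough to bridge the 1–2 frameshifts per
element the decay model produces and small enough not to fuse separately
implanted loci (the generator spaces implants ≥ 3 kb apart).  Merging is
independent of input order and idempotent because locus identity derives
from the merged coordinates.  Opposite strands never merge — sense and
antisense elements are distinct.

Stringency (best member e < 1e−10 **and** length ≥ 350 nt) only flags
loci, never deletes them, so the permissive catalogue remains inspectable.
Both inequalities follow the printed wording: the e-value strictly below
the cutoff, the length at least the floor.

The reciprocal screen re-searches the locus sequence (translated, same
engine, roles swapped: panel proteins as queries, the locus as the
genome) against the union of the viral panel and a background "decoy"
proteome; the locus is kept iff the top bit score is viral, with
bit-score ties kept but flagged.  A supplied decoy set stands in for a
comprehensive protein database, and the acceptance rule is made explicit
because "eliminate false positives" is otherwise undefined.  An empty
decoy set keeps the locus with a warning (the screen is vacuous, not
failed).  Cognate-virus assignment is the best bit-score alignment
against the viral panel alone; the reported identity is that alignment's
own percent identity over its columns, which flank extension can dilute
relative to the implanted identity — this is a property of local
alignment, not an error.

ORF prediction extends the locus by 2000 nt on both sides (clipped at
contig bounds) and reports complete ATG→stop ORFs on both strands, the
longest ORF per stop codon, at a 300-nt floor — permissive relative to
the ~0.5–4.7 kb ORFs such elements can carry.  Intervals include the
stop codon; proteins exclude it.

## Synthetic data

The generators produce every pipeline input with recorded ground truth.
A single integer seed drives one named generator per simulator
(`SeedSequence([seed, stream])`), so adding a simulator never shifts
another's stream and all outputs are byte-reproducible.

- *Virus*: one genome segment with two non-overlapping intact ORFs whose
  translations are returned as CP (700 aa) and RdRp (900 aa) — the
  canonical totivirus organisation.
- *Implants*: protein fragments of 135–830 aa (405–2490 nt, all above the
  350-nt stringency floor) decayed in protein space to a target identity
  drawn from U(0.6, 1.0) by substituting uniformly chosen positions with
  uniformly chosen different residues, back-translated with uniform
  synonymous codons, optionally given 1–2 single-base indels
  (probability 0.5), and written onto either strand (half minus) of a
  1-Mb random host contig with ≥ 3 kb spacing.  Codon usage and
  transition/transversion structure are deliberately ignored: detection
  operates in protein space, and a uniform model keeps the truth table
  exact.  Fragment lengths were fixed once as representative of the
  0.4–10 kb range such elements span.
- *Reads*: for each individual and locus, read starts are uniform over
  [start − read_length + 1, end) with count Poisson(d·(L + rl − 1)/rl),
  giving expected interior depth d (30× present, 0× absent).  Reads are
  placements only — no sequences, no errors, no mapping ambiguity beyond
  an explicit multimap count.  The cohort is therefore *locus-targeted*:
  genome-wide individual QC is exercised on dense small-genome fixtures
  in the unit tests, and the population driver reports but does not
  enforce QC on the synthetic cohort.
- *Variants*: per individual and present locus, site counts are
  Poisson(density·L/1000) at uniform positions (default 6 /kb).
- *Orthologs*: gap-free three-row alignments mutated independently from a
  common ancestor with per-site probability m solved from
  2m(1−m) + (2/3)m² = r, so every row pair's expected p-distance equals
  the assigned class rate (5% at 0.4, 90% at 0.2, 5% at 0.05; 10 kb).
  Real ortholog alignments have gaps, rate variation along the gene and
  phylogenetic correlation; passing the recovery test shows the ranking
  machinery separates well-separated rate classes, not that 5% tails are
  biologically meaningful.
- *Small RNAs*: exact substrings of a transcript or its reverse
  complement with rounded-normal lengths clipped to [18, 30].

## Presence, QC and PCA

"Coverage higher than 50%" at locus level is interpreted as breadth of
coverage at depth ≥ 1 — the fraction of positions with any read — the
natural reading when per-base depth is the primitive; the alternative
(breadth at the profile's depth threshold) is noted as a possible
stricter variant.  All presence comparisons are strict (`>`), matching
"greater than"/"higher than", so a locus at mean depth exactly 5.0 is
absent under the strict profile.  Individual QC excludes genomes below
15.0× (strict) or 5.0× (relaxed), with the bar itself included, because
the excluded set is phrased as "less than".  Windowed depth uses
non-overlapping 100-bp tiles with the trailing partial tile at its
actual width, so width-weighted window sums conserve the per-base total
exactly.  PCA runs on the column-centered covered-fraction matrix via
SVD (deterministic sign convention); multi-mapped placements each count
once per placement, since multi-mapped reads are retained.

## Polymorphism and rate classes

The polymorphism level is defined here as distinct non-reference variant
positions per kb per individual — SNPs and indels each one position,
duplicate records at a position counted once.  The upstream protocol
cites a script rather than a formula, so this definition is the module's
own and is additive over interval partitions by construction.  Levels
are computed only for individual × locus pairs with > 50% breadth, since
polymorphism of an absent locus is undefined.  p-distance of a multi-row
alignment is the mean over row pairs of differences divided by columns
ungapped in both rows; alignments with > 10% gapped columns are dropped
(strictly more — 10% exactly is retained).  The FEG/SEG cut takes
floor(0.05·n) from each end of the descending ranking — validated by the
printed 73-of-1,462 — with ties broken by ortholog id; below n = 20 both
classes are empty with a warning rather than degenerate singletons from
noise.

## Expression, small RNAs, triage, enrichment

FPKM follows the standard formula and is invariant under joint scaling
of counts and library size.  A small-RNA read maps iff it is an exact
substring of the transcript or its reverse complement (perfect-match
mapping, strand of origin unknown), counted once per read.  The piRNA
flag — ≥ 50 mapped reads and ≥ 50% of mapped lengths in 24–29 nt — makes
the qualitative "abundant piRNA-sized reads" call explicit; both
thresholds are config-exposed, and the defaults are the package's own
substitutes for an unstated criterion.  Contig triage keeps candidates
with coverage > 20×, length > 2000 nt and best e-value < 1e−20, all
strict, and is monotone in each criterion.  The DEG filter
(|log₂ ratio| > 1, adjusted p < 0.05) is a plain table operation; the
differential model itself is out of scope.

The enrichment P-value is the inclusive upper tail Pr(X ≥ m) of
Hypergeom(N, M, n), exactly the 1 − Σ_{i<m} form, evaluated as a
log-sum-exp of log-gamma binomials so genome-scale N cannot overflow.
Raw P-values are the default output, mirroring the upstream protocol,
which does not state a correction; Benjamini–Hochberg adjustment is
available.  Note Pr(X ≥ m) equals 1 for all m at or below the support
floor max(0, n + M − N); strict monotonicity in m holds only above it.

## Numerical choices and degenerate inputs

Empty query sets, empty placement lists and zero-variant inputs return
empty-but-valid results; zero-length intervals, non-positive search
spaces and invariant-violating enrichment queries raise errors.
E-value filtering at the search stage uses ≤ (a cutoff of 0 yields an
empty set); the merge and stringency thresholds use < per their printed
wording.  All DP and ranking tie-breaks are deterministic, and pipeline
reruns at a fixed seed produce byte-identical output files.

## Problem sizes

The bundled study conditions (1-Mb genome, 20 implants, 10 individuals,
1,000 × 10-kb orthologs, 200-read sRNA libraries, 200 oracle-comparison
cases) were chosen as the smallest sizes at which every downstream
statistic is comfortably out of its small-sample regime; the full test
suite and the acceptance script each complete in a few minutes on one
core.

## Known limitations

- The search engine has no low-complexity masking or composition-based
  statistics; random-genome false positives are controlled only by the
  e-value thresholds (sufficient at these scales).
- Karlin–Altschul constants are fixed, not fitted; raw E-values on other
  scoring schemes require supplying matching λ and K.
- The reciprocal screen is only as good as the supplied decoy proteome.
- The synthetic cohort has no sequencing error, mapping bias, GC bias or
  population structure beyond the presence map; PCA separation on it
  demonstrates the mechanics, not population-genetic realism.
- Ortholog inference, multiple alignment, read mapping, variant calling
  and differential-expression model fitting are consumed as inputs, not
  reimplemented.
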