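# Methods

This note documents the models, parameter choices and numerical decisions
behind `siblingscaf`, and what the synthetic-data experiments do and do not
demonstrate.

## The synthetic sibling-genome study

Every stage is validated against a generator (`simdata`) that emulates the
data of a reference-guided assembly project for a satellite-rich genome:

- **Reference**: `n_chromosomes` i.i.d.-random ACGT chromosomes. Genes are
  placed one per equal-width slot (guaranteeing non-overlap; a
  configuration whose genes cannot fit raises a capacity error). Each gene
  carries one mRNA and five exon + five CDS children — a realistic
  multi-exon model, 12 annotation features per gene. N-gap runs are
  written into the emitted reference only; the truth record keeps the
  ungapped sequence, so simulated reads (drawn from the sibling) genuinely
  span the gaps.
- **Sibling**: substitutions at rate `divergence` (default 0.02, the
  coding-sequence-similar sibling-species regime), then insertions applied
  left-to-right with all coordinate shifts recorded: satellite arrays
  (one per entry of `array_lengths`; copies of a single random 166-bp
  monomer, each mutated at `satellite_copy_divergence`, default 0.005 —
  long *homogeneous* arrays) and TE copies (per-family random consensus,
  copies mutated at 5%, half reverse-complemented). Insertions avoid genes
  by a 100-bp margin so gene-level truth stays exact.
  `repeat_fraction` = planted (satellite+TE) bp / sibling bp.
- **Contigs**: breakpoints at long-array boundaries (arrays shorter than
  `isolate_min_bp` stay embedded) plus gene- and array-avoiding random
  breaks; contigs tile each chromosome exactly; a fraction are emitted
  reverse-complemented. Truth records source interval, orientation,
  contained features and satellite dominance (>50% of length).
- **Reads**: Normal(15 kb, 1.5 kb) lengths truncated at 1 kb,
  substitution-only errors at 0.1% (the long-accurate-read profile; no
  indels, which keeps alignment oracles exact), random strand, drawn per
  chromosome until the coverage target is met (total bases within a
  fraction of one read length of target).
- **Mitogenome contig**: a circular unit rotated once by a random offset,
  then 3 head-to-tail copies each mutated at 0.01% (the ~99.99%
  inter-copy identity regime); the "related species' mitogenome" is the
  unit mutated at `divergence` with a different origin.

What passing these tests does *not* show about real data: no indel
divergence or structural variation beyond insertions, no heterozygosity or
diploidy, no HiFi homopolymer errors, uniform base composition, and TE
length/copy spectra that are free parameters rather than calibrated to any
particular genome.

## K-mer spectrum estimators

Counting is canonical (lexicographic min of k-mer and reverse complement),
N-containing windows skipped, histogram capped at `max_multiplicity`
(default 15,000, mirroring full-scale practice; scaled-down simulations
pass a higher cap because a 1,200-copy monomer at 30× already exceeds
15,000). Mass conservation (Σ i·h_i = number of N-free windows) is
asserted against a string-level hash-set oracle.

Numerical choices:

- **Error threshold t**: first local minimum of the 3-point-smoothed
  histogram; the left edge is replicate-padded so index 1 is never dragged
  into a spurious minimum; a histogram with no minimum followed by signal
  raises an explicit "no error/signal separation" error.
- **λ**: located at the argmax of h_i above t, then refined as the mean
  multiplicity of the signal window (t, 2·argmax]. The mean is exact for a
  Poisson-shaped peak and stable where the raw argmax wanders ±3 across
  seeds on a broad peak. The distinct-k-mer peak (not the k-mer-mass peak)
  is used for location because on satellite-rich spectra the mass argmax
  sits on the high-multiplicity repeat cluster.
- **Repeat multiplier r = 2** (configurable): k-mers above r·λ count as
  repetitive. `peak` caps their mass at r·λ (repeat copies collapse);
  `repeat_aware` keeps full mass, hence `repeat_aware` ≥ `peak` on
  repeat-rich data. The repeat ratio is mass-based (share of signal k-mer
  instances above r·λ), one of two defensible definitions; distinct-k-mer
  based ratios would run lower.
- Presentation rounding is half-up (1 decimal for sizes/percent), matching
  how such tables are printed; `round()`'s banker's rounding would differ.

On the seeded ~1-Mb, 20%-satellite, 30× simulation the repeat-aware
estimator recovers genome size within ~1.5% and the repeat ratio within
~0.01 absolute; the residual ratio deficit is the mass of per-copy mutated
monomer k-mers, which are genuinely single-copy.

## Anchors, liftover, triage

One alignment engine serves the whole toolkit: (k=15, w=10) minimizers
with a mixed 64-bit hash, robust-minimizer tie handling, and a frequency
ceiling (default 10 occurrences) that drops repetitive anchors — this is
what stops satellite arrays from attracting chains. Candidate regions are
chained by longest colinear subsequence (LIS per relative strand) and
scored with edlib; identity = matches / alignment columns.

Liftover extends each chain by its unchained query overhangs so a feature
wholly contained in a contig is scored end to end (an exact copy reports
100/100 and exact coordinates). Accept thresholds default to 50% identity
and 50% coverage; all accepted copies are reported with a copy index, ties
broken by (score, contig id, position). A UMF count is the number of
*distinct* source features with an accepted lift — copies collapse, the
conservative reading of "uniquely mappable". Triage retains contigs with
count strictly greater than `min_umf` = 10; the boundary (11 retained, 10
discarded) is covered by a test.

## Gap filling

For each maximal N-run, 500-bp flanks are matched against donors
shortlisted by shared minimizers; a donor is accepted when both flanks
align colinearly on one strand at ≥80% identity (permissive, because the
donors come from a diverged species) within `max_span`. Best donor by
summed flank identity, then donor length, then id; the patch is inserted
verbatim (no polishing). Gaps are processed right-to-left per chromosome
so coordinates stay valid; filling is idempotent and never touches non-gap
bases. On the 1-Mb simulation all ten 200-bp gaps close with patches
≥99.5% identical to the sibling's homologous segment (the residual is read
error plus flank-boundary placement).

## Scaffolding

Per contig, one vote per distinct query minimizer per chromosome; the
best chromosome's vote share is the location confidence, the
majority-strand share within it the orientation confidence, and votes ×
k the matched span. Defaults (0.5 / 0.5 / 5 kb min span) are the
synthetic-scale analog of requiring a substantial unique match; satellite
contigs fail them because their anchors are frequency-dropped. Contigs
are ordered by median matched reference coordinate — a start projection
alone can invert adjacent contigs when insertions inflate one of them —
while implied gaps use the projected start/end, clamped to
[100, 100,000] bp (negative projections clamp to the minimum). Groups are
named `fLG<i>` in reference-chromosome order and round-trip through AGP
v2.1 byte-identically.

## Repeat annotation

Monomer/library hits: exact 11-mer seed matches vote for candidate
alignment starts per strand; vote clusters are verified by infix edlib
alignment; identity and query coverage must be *strictly* greater than
70% (a hit at exactly 70.0 is rejected); overlaps resolve greedily by
score. Arrays chain hits with inter-hit gaps ≤ 0.5 monomer lengths and
require ≥5 monomers — four tandem copies yield no array, five yield one.
On short targets the hit set is checked against a brute-force
all-positions alignment oracle. Low-complexity flagging (windowed entropy
< 1.0 bits/base over 64 bp) is a reporting aid outside the alignment
path, not a RepeatMasker emulation.

## Assembly statistics

N50 is the length of the sequence at which the cumulative descending sum
first reaches half the total (no interpolation), L50 its rank; verified
against a quadratic oracle on 1,000 random fixtures. GC excludes N from
the denominator. Fold coverage is total bases / genome size, half-up to
one decimal.

## Mitogenome extraction

Candidate contigs are ranked by minimizers shared with the reference unit
(with a raised occurrence ceiling, since tandem copies would otherwise
mask themselves), then scored by infix alignment of the full unit on both
strands. The tandem period is the smallest self-offset ≥1 kb whose
overlap alignment clears a 95% identity floor (margin below the ~99.99%
inter-copy identity of a freshly triplicated unit); copy count =
⌊length/period⌋. Rotation searches the anchor (by default, the first
~500 bp of the reference unit — a stand-in for its first annotated gene)
on the doubled unit so origin-crossing matches are found, flipping strand
if needed. Gene similarity aligns each annotated gene of one unit against
the doubled other unit on both strands; genes below a 50% floor are
reported missing rather than fatal.

## Pipeline

Stages run in dependency order with per-stage parameter blocks in a
single YAML (unknown keys rejected); a missing upstream output raises a
named dependency error. The report contains only quantities recomputable
from the stage outputs; re-running with the same configuration reproduces
it except for the timestamp. Problem sizes in the bundled demo (300-kb
reference, 20×) and the acceptance simulations (~1 Mb, 30×) were chosen
as the smallest scales at which every phenomenon of interest — a
separated error/signal/repeat spectrum, satellite-only contigs, >10-UMF
gene contigs, spanned gaps — is well expressed.

## Known limitations

Liftover is unspliced (features map as single blocks), so intron-scale
indel divergence would fragment them. Gap filling takes one best donor,
no consensus. Placement cannot split chimeric contigs or join across
reference chromosomes, and inherits the reference's large-scale structure
— true rearrangements in the query will be "corrected" toward the
reference. Satellite annotation reports monomer-resolution arrays but not
higher-order repeat structure. All estimators assume haploid,
substitution-dominated divergence.
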