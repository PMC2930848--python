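# Methods

This note records the model conventions, parameter semantics, numerical
choices and known limitations of the package, in the order the pipeline
applies them.

## Coordinates and orientation

All genomic coordinates are 0-based half-open. Promoter windows are
expressed in *transcript orientation*: index 0 is the most upstream base,
index `upstream_len` is the TSS base itself, and increasing index always
means downstream. Minus-strand windows are reverse-complemented at
extraction time; conservation and coding-mask arrays are reversed (not
complemented) alongside. Windows are truncated, never padded, at chromosome
edges, and the truncation is recorded on the object.

## TSS handling

Transcripts of a gene sharing a start position collapse into one TSS
record; records are indexed 5'→3' in gene orientation, so index 0 is the
*most distal* TSS (farthest from the gene body) and the highest index the
*most proximal* (core) one. CAGE refinement looks for the closest tag
cluster within 200 bp of the annotated TSS (distance to the cluster
interval, 0 if inside; equidistant clusters resolved by higher total tag
count), moves the TSS to the in-cluster position with the highest tag count
(ties to the most 5' position in gene orientation), and records the
cluster's maximum per-tissue TPM as promoter strength. With no cluster in
range the TPM sentinel −1 marks the absence of CAGE support.

Five selection modes pick which alternative promoters enter the analysis:
`all`, `most_distal`, `highest_tpm` (sentinel ranks below any real TPM;
if no TSS has CAGE support the mode falls back to `most_distal` with a
warning), and `with_cpg`/`without_cpg`, which partition on total CpG-island
length in the island window. Ties in `highest_tpm` resolve to the most
distal of the tied records.

## PWM scoring

Counts are converted to log₂-odds weights against a uniform 0.25 background
with the per-column pseudocount `p = sqrt(column total)` (the convention of
the classic Perl TFBS toolkit; a fixed numeric pseudocount can be
substituted). Matrix information content is computed from the smoothed
column frequencies. Scores are reported on the relative scale
`100·(raw − min)/(max − min)` with `min`/`max` the sums of column
minima/maxima; a degenerate matrix (`min == max`) scores 100 for any window
and triggers a warning. `N` bases take the column-minimum weight, so they
can only push a window below threshold, and they are excluded from the
G/C/CG tallies of the CpG module.

Scanning covers both strands; reverse-strand hits are reported at the
forward-orientation offset of their footprint. Ties at exactly the
threshold are included (`>=`), with an absolute epsilon of 1e-9 on the
0–100 scale to keep float round-off from dropping boundary windows. Window
scores accumulate column-by-column in ascending order, which makes the
vectorized scanner bit-identical to a naive left-to-right per-window sum —
the property the oracle-equivalence tests assert exactly rather than
approximately. Overlapping hits of one matrix are all reported; no greedy
masking. Each hit carries the mean conservation over its footprint and a
coding flag (true if any footprint base overlaps any exon of any
transcript, UTRs included).

## CpG islands

Islands are detected in a window 5 kb upstream to 10 kb downstream of each
TSS — deliberately the mirror image of the 10 kb/5 kb promoter scan window.
Frames of 200 bp (step 1 bp by default; a coarser step is available for
speed) are marked when GC > 50 % and CpG observed/expected
(`N_CG · L / (N_C · N_G)`) > 0.6, both strict. Overlapping qualifying
frames merge by footprint union, and a merged region is kept only when its
length exceeds 200 bp *and its own aggregate statistics still pass both
thresholds* — the re-validation prevents two barely-passing frames bridged
by AT-rich sequence from fusing into a spurious island. Per-TSS island
content is the summed length of detected islands; the genome-wide
distribution is the per-gene total over each gene's selected TSSs, with
island-free genes contributing 0 so the query/genome comparison stays on
one per-gene scale. The query is compared by a one-sided z-test of its mean
against the genome mean using the genome sample (n−1) standard deviation.

## Backgrounds and threshold calibration

Three background models estimate chance hit rates: 20 Mbp of uniform
random sequence (scaled down in tests), the concatenated oriented 200-bp
windows 5' of every gene start ("core"), and the concatenated maximal runs
of conservation strictly above 0.75 inside each gene's promoter window
("conserved", taken around the gene start to avoid double-counting
overlapping alternative-TSS windows). Each background is scanned once per
matrix at threshold 60; every window is assigned to the bucket of its
floored relative score (using the same 1e-9 epsilon as the scanner), and a
reverse cumulative sum yields both-strand hits per Mbp at every integer
threshold 60–100 — provably identical to rescanning at each threshold.
Rates are non-increasing in threshold by construction, and the table
asserts this on demand. The optimized threshold for a matrix is the
argmin of |rate − target| over 60–100, ties resolved toward the *higher*
(more restrictive) threshold — fewer false positives when the distance is
equal. Distance is absolute on the hits-per-Mbp scale; a log-scale distance
was considered and rejected as harder to document and reason about near
zero rates.

## Enrichment statistics

Per gene and matrix, hits pass five filters in order: footprint inside the
configured `[−upstream, +downstream)` window; coding mode (coding-only,
noncoding-only, or both); footprint-mean conservation at or above the
threshold; the top `top_percent` of survivors ranked by conservation
(count = ceiling of the fraction); and at most `max_conserved_tfbs`
highest-conservation hits per promoter (0 = unlimited) — the last filter
exists so that highly conserved promoters do not dominate simply by having
longer conserved stretches. Pooled hits from overlapping windows of one
gene are deduplicated by genomic footprint and strand, so one physical
site counts once per gene.

Effective length counts genomic bases surviving the *region-level* filters
(window, coding mode, conservation), union-deduplicated per gene. The rank
filters have no natural length and do not feed back into expectations —
this is the declared resolution of the method's largest interpretive gap.
Expected hits are `length/10⁶ × rate`; expected genes use a per-gene
Poisson model, `Σ_g (1 − exp(−λ_g))`. Folds (observed/expected, separately
for hits and genes) are standardized across the *entire* matrix repertoire
— the fold distribution is treated as Gaussian — with the sample (n−1)
standard deviation; at least 3 matrices are required, and a degenerate
all-equal distribution yields z = 0, p = 0.5. All p-values are one-sided
upper-tail (the tool reports overrepresentation only). The proportion
p-value is `min(1, expected/observed)`, 1 when nothing was observed. Raw
p-values are reported unadjusted, matching the method's convention; a
Bonferroni column is appended as a convenience. Result rows sort by hit
fold p ascending, ties by fold descending, then matrix id — fully
deterministic output.

## Synthetic data generator

The fixture generator emulates every input the engine consumes: genes on
both strands with 1–4 alternative TSSs (the first gene always has 4),
two-exon transcripts providing a coding mask, CpG-island blocks upstream of
half the TSSs, a conservation track with a low baseline (0.30 ± 0.05
noise) plus one highly conserved 500-bp stretch (≈0.90) in each proximal
promoter, and CAGE clusters (width 8, peak within ±2 bp of the annotated
TSS) at 70 % of TSSs. The background sequence draws i.i.d. bases at 45 % GC
and then depletes CG dinucleotides to a 0.20 survival fraction by C→T
substitution, mimicking the methyl-CpG deamination that makes real
vertebrate genomes CpG-poor; without this, an i.i.d. genome has CpG
obs/exp ≈ 1 and island detection saturates everywhere. Island blocks are
GC-rich (65 %) with forced CG dinucleotides, so they — and only they —
satisfy all three island criteria.

All randomness flows from a single seed through per-component seed
sequences (`[seed, component, index]`), so adding genes or planting motifs
never perturbs other components' sequences and bundles are byte-identical
across runs. Motif planting writes consensus (or PFM-sampled) words at
recorded TSS-relative offsets, marks their footprints as highly conserved
(0.95), refuses colliding placements, and returns a manifest.

The bundled planted-signal matrix is CRE-like with consensus `TGACGTGA`:
it keeps the TGACG half-site but is deliberately *not* the palindromic full
CRE, because a palindromic consensus necessarily produces strand-paired
double hits at every planted site, which would make "exactly k sites
planted, exactly k hits found" impossible to assert.

What the generator does **not** emulate: isochore structure, repeats,
realistic FANTOM tag-count distributions, dinucleotide composition beyond
CpG depletion, or genes with overlapping bodies. Passing tests therefore
demonstrate correctness of the machinery and calibration under idealized
composition, not performance on real mammalian promoters.

## Problem sizes and runtime choices

The validation experiments run at desk scale as the package's own choice of
test conditions: null calibration uses ten 50-gene fixtures with 30 decoy
matrices and 25-gene queries; power uses twenty 30-gene fixtures with 2
consensus sites planted per promoter in 20 query genes; analysis windows
are 1 kb upstream / 200 bp downstream with a 200 kb random background and a
tolerated random occurrence of 100 hits/Mbp. The full test suite and the
acceptance script each complete in under a minute on one CPU. Island
detection in batch contexts may use a 4-bp frame step; all published
constants (frame 200 bp, strict thresholds) are unchanged by the step.

## Known limitations

- Only uniform mononucleotide backgrounds for PWM scoring; no higher-order
  models or per-site p-values.
- The Gaussian assumption on the fold distribution is inherited from the
  method; with few matrices or heavy-tailed folds the z-derived p-values
  are approximate.
- Expected-genes uses a Poisson ≥1-hit model, which ignores overdispersion
  from clustered sites.
- The conserved background considers one promoter window per gene (around
  the gene start), not all alternative-TSS windows.
- Gene-ID resolution is exact-match against the annotation; microarray
  probe-set or symbol mapping is out of scope.
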