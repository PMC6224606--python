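# Methods

## Scope and model

`strascope` implements a transcriptome screen for multivalent RBP-decoy
transcripts and the downstream statistics used to test the sequestration
hypothesis. Alignment, assembly and quantification are upstream of the
package: it consumes transcript sequences (FASTA), transcript models (BED12 or
minimal GTF), a known-transcribed-exon track (BED6), a tandem-repeat track
(BED6), and a transcript × sample TPM matrix, and treats qRT-PCR-derived
per-cell copy numbers as constants.

## Motif scanning

Motifs are position probability matrices over {A, C, G, U}; DNA-alphabet input
is accepted with T read as U, and all sequence input is normalized the same
way at parse time (unknown letters become N). Scoring is classical log-odds:

* regularization p'_{b,i} = (p_{b,i} + α·q_b)/(1 + α) with a
  background-proportional pseudocount, α = 0.1 by default;
* s_{b,i} = log2(p'_{b,i}/q_b) in bits, with q the order-0 marginal of the
  background; the Markov-1 transitions are retained only for sequence
  simulation. The background estimator counts a single strand only and adds
  one pseudo-count per state and transition, so all frequencies are positive.

Exact p-values use the standard discretize-and-convolve dynamic program: each
column's four scores are rounded onto an integer grid (about 1000 levels
across the widest column), and the per-column score distributions under q are
convolved. Window scores are evaluated **on the same integer grid** (sum of
rounded column scores), which makes the tail lookup exact with respect to the
discretization; tests and the oracle comparisons allow the corresponding
±(w/2) bin rounding band at decision boundaries. With α = 0 a zero probability
gives a −∞ score; such entries are mapped to a sentinel level below every
all-finite sum, so finite-score p-values are unaffected.

A window is retained iff p < 0.001 and score/s_max ≥ 0.85. The 0.85 fraction
is computed on the log-odds scale (defined only for s_max > 0; an
information-free motif emits no hits, with a warning). A min–max
normalization, (score − s_min)/(s_max − s_min), is available as
`fraction_mode="minmax"` for sensitivity analyses; log-odds is the default
because the retention filter operates on the same scale as the reported
scores. Only the sense strand is scanned, windows containing N are skipped,
overlapping hits are allowed, and no q-values are computed.

## Enrichment screen

For every (transcript, motif) pair the retained-hit count and density
(hits per kilobase of spliced length; the unit is cosmetic — any constant
rescaling leaves Z unchanged) are standardized per motif across **all**
transcripts, zeros included, using the sample standard deviation (n−1). A
zero-variance motif gets Z = 0 everywhere rather than infinities. A
transcript is a candidate iff a single motif carries both Z_count ≥ 5 and
Z_density ≥ 5 — the stricter same-PWM reading of the dual threshold; the best
motif per transcript maximizes Z_count with lexicographic tie-break. A
structural consequence worth knowing when building fixtures: with k truly
multivalent transcripts among n, the planted Z cannot exceed ≈ √(n/k), so the
z ≥ 5 rule presupposes candidates are a small minority (k/n ≲ 1/26).

Class-wise enrichment comparisons use the two-sided Fisher exact test
(scipy's implementation; validated in the tests against exhaustive
hypergeometric enumeration). No multiple-testing correction is applied at the
screen stage.

## Filters and annotation

* **Known-transcription filter:** keep a transcript iff ≥ 1 nt of its *exons*
  overlaps a known exon on the same strand (split semantics — intron-only
  overlap does not count). A chromosome absent from the known track logs a
  warning and yields zero overlap.
* **Expression floor:** keep iff the median TPM across samples is ≥ 0.1
  (boundary inclusive; even sample counts use the mean of the middle two).
* **Intergenic class "u":** the transcript's genomic span overlaps no
  reference-locus span on either strand. This collapses the assembler's
  class-code taxonomy to the one code the screen uses; all other codes are
  "non-u".
* **Longest ORF:** sense strand, three frames, AUG→stop, length in codons
  from the AUG to the codon before the stop; unterminated frames are ignored.
* **STR content:** tandem-repeat intervals are merged strand-agnostically;
  per-transcript fraction = covered exonic nt / spliced length, and the
  aggregate percentage over a set is the length-weighted mean.
* **Tandem-repeat detector:** exact-copy periodicity only (units 2–12 nt,
  ≥ 3 copies, span ≥ 12 nt, partial last copy allowed, overlapping unit sizes
  merged). Homopolymers surface via their 2-nt unit. This utility exists so
  synthetic annotation needs no external tool; it intentionally does not
  reproduce a mismatch-tolerant repeat finder.

BED is 0-based half-open throughout; GTF exons are converted on read.

## Multivalency and sequestration

Degenerate patterns (IUPAC; Y = {C, U}) are matched at every start; a start
matching either of YUCUYY / YYUCUY counts once (union, the default — a shared
start is one physical site; per-pattern counting is available since the
alternative reading cannot be excluded). For a perfect (UC)ₖ array of length
L = 2k ≥ 6 every window start matches one of the two patterns, giving the
closed forms: total = L − 5 and non-overlapping = ⌊L/6⌋. The maximal
non-overlapping subset uses greedy earliest-end selection, provably optimal
for equal-width intervals. Capacity = 100·M·n_RNA/N_prot percent, capped at
100, assuming one protein per site, no cooperativity and no affinity
weighting.

## Imaging quantification

Maximum projections are per-pixel maxima. Particle analysis thresholds the
image (Otsu by default, value overridable and logged), labels connected
components at 8-connectivity (the common particle-analysis default) and
reports per-particle area and integrated intensity.

The per-nucleus estimator chain is designed so the copy number is insensitive
to the exact threshold: the total spot signal is integrated over the particle
mask dilated by 3 px (recovering sub-threshold Gaussian tails) after
subtracting the median intensity of non-spot nuclear pixels, and each
diffraction-limited particle's intensity (area ≤ 1.5× the median particle
area) is measured in a 4-px circular aperture. Copy number = total / median
single, so any residual truncation cancels to first order between numerator
and denominator. When Otsu's threshold falls within the noise band
(< median + 3 robust SD of the nuclear pixels) the image is declared
signal-free: Otsu always splits a histogram, even of pure noise. Compartment
dots — particles larger than 4× the median area — define the co-localization
footprint; the sequestered fraction is

    f = (coloc − b·A_coloc) / (nuclear − b·A_nuclear),  clamped to [0, 1]

with b the median cytoplasmic intensity. Note f counts *all* protein inside
the RNA-dot footprint, including the diffuse pool passing through it — that
is the co-localization quantity the imaging measures, and the synthetic
ground truth is defined identically. The KS test uses the asymptotic p-value
(the intended sample sizes are hundreds of nuclei); Pearson's r is the plain
product-moment correlation, raising on zero variance.

## Synthetic data

`generate_transcriptome` emulates the statistical structure the screen sees:

* **Background:** transcripts (default 500, lengths 600–1500 nt uniform) are
  drawn from a mildly AU-rich Markov-1 model; sporadic single consensus sites
  (CUCUCU, matching both patterns) are inserted at a Poisson rate of 0.2 per
  transcript so background hit counts are not degenerate zeros.
* **Planted:** 5 transcripts carry an exact (UC)₁₅₀ array in random flanks —
  a "normal-length" STR, no expansion; an optional mutation rate can degrade
  the array for robustness experiments. Planted loci get no reference span
  (class "u") but are covered by the known-exon track (EST-like evidence), so
  they pass the overlap filter while remaining intergenic.
* **Annotations:** every fifth background transcript is two-exon to exercise
  split-overlap semantics; a configurable subset lacks known-exon coverage
  (default 10) and another is expressed below the TPM floor (default 10), so
  both filters drop something by default. The STR track is produced by the
  exact-repeat detector on the emitted sequences. TPMs are log-normal
  (σ = 1.5); planted transcripts draw from a shifted distribution with median
  well above the floor.
* **Manifest self-audit:** every manifest quantity (motif counts, STR
  intervals, class flags, TPM medians) is re-derivable from the emitted files
  and is checked against the package's own scanners in the tests. All
  randomness flows from one seed; outputs are byte-identical per seed.

`generate_nuclei_images` emulates the two-channel quantification: disk nuclei
(radius 52 px in a 128-px frame), 1–2 compartment dots as flat-topped 6-px
disks (the footprint of an extended body is then nearly
threshold-independent — a Gaussian dot's segmented area would vary strongly
with the threshold), 40 molecules of unit flux of which 8 sit in the dots and
32 appear as σ = 1.5 px Gaussian spots with 10% multiplicative intensity
noise, over Poisson shot noise plus Gaussian read noise (SD 3). The protein
channel is cytoplasmic haze + nuclear diffuse signal + a dot-sequestered pool
sized so the co-localized fraction is exactly 8% before noise.

What the synthetic data does **not** model: real covariance of motif content
with GC/length, alignment/assembly artifacts, transcript-isoform ambiguity,
3-D optics, chromatic shift, uneven illumination, or autofluorescence.
Passing tests therefore demonstrate correctness of the estimators under the
stated noise models, not robustness to every property of real libraries and
microscopes.

## Problem sizes and numerical choices

Default test/demo sizes — 500 + 5 transcripts × 20 seeds for recovery, 200
random motif/sequence pairs for the scanner oracle, 1000 fuzz cases per
brute-force oracle, 50 nuclei for imaging recovery — were chosen as the
smallest populations at which the screened effects are stable across seeds.
Score discretization is 1000 bins per column (round-half-even via numpy
rounding); ties at the p threshold resolve through the discretized tail.
Degenerate inputs are defined rather than special-cased: sd = 0 → Z = 0,
s_max ≤ 0 → no hits, all-zero contingency table → p = 1 with a warning,
empty sequence → no windows.

## Pipeline configuration

`strascope run --config screen.toml --outdir out/` with:

```toml
[inputs]
fasta = "transcripts.fa"
bed12 = "transcripts.bed12"
known_exons = "known_exons.bed"
reference_spans = "reference_spans.bed"
strs = "strs.bed"
tpm = "tpm.tsv"
motifs = "motifs.meme"
motif_format = "meme"      # or "cisbp"

[thresholds]                # defaults shown
tpm_floor = 0.1
z_threshold = 5.0
alpha_p = 0.001
f_min = 0.85
pseudocount = 0.1
```

Outputs: `screen_report.tsv` (one row per input transcript), `hits.tsv`,
`candidates.bed`, `report.json` (stage counts, config hash, version). Exit
codes: 0 success (including an empty result), 2 input error, 3 config error.

## Known limitations

* The exact-repeat detector under-calls repeats with mismatches/indels.
* Single-molecule selection is area-based, not PSF-fitted; heavily clustered
  molecules bias the single-intensity median upward slightly (≲ 3% at the
  default density).
* The Z-score screen assumes motif counts are comparable across transcripts
  after density normalization; it does not model length- or GC-dependent
  null variation.
* Exact small-sample KS p-values are out of scope (asymptotic only).
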