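# Methods

This note documents the models behind `smtseq`, the defaults and why
they hold those values, the numerical choices that required a decision,
and what the simulations do and do not establish about real data.

## The assay being modelled

A flow cell carries covalently bound 60-nt capture probes (a 50-nt
specific region plus a dT10 linker). 70-nt single-stranded targets
hybridize to the probes; a non-cleavable anchor dye (Cy3) on each target
marks its position in the *template channel*. Sequencing proceeds in
cycles: one species of dye-labelled reversible terminator is flowed per
cycle in the fixed order G, C, T, A, so at most one base can add per
molecule per cycle, and a signal in the *incorporation channel* at cycle
`c` implies base `flow_order[(c - 1) % 4]`. With 19-30 cycles a molecule
yields a ~10-14 nt read. The package simulates this process and
implements the complete analysis path from raw two-channel images to
per-template consensus sequences and mutant-fraction estimates.

## Reference panel (`simcore.make_references`)

The panel emulates a drug-response target set: eight 70-nt templates,
six carrying a point mutation and two carrying short deletions of 15 nt
(5 codons) and 21 nt (7 codons). Template sequences are seeded-random
70-mers; the published panel's sequences are only available as a figure,
so synthetic stand-ins are generated instead and the panel is fully
reproducible from its seed.

Two constraints shape the generated sequences, both mirroring real
probe/panel design practice:

* **Variants sit in the first ten template positions**, so that ~10-nt
  reads span every variant site (the assay's probes were deliberately
  placed just upstream of the mutations for the same reason).
* **The first 16 bases contain no homopolymer and no period-2/3 tandem
  repeat.** A repeated base stalls the 4-base flow cycle for a full
  extra round, and short tandem repeats make indel placement ambiguous
  under local alignment - the same low-complexity exclusions that
  primer/probe design software applies. Without this constraint,
  deletion-bearing reads over repeat tracts realign gap-free with
  spurious mismatches and visibly bias the measured substitution rate.

Templates are stored in read space: the stored string is the base
sequence the instrument reports, read from position 0; the probe's
specific region is the reverse complement of template positions 20-69.
Probe quality is screened by GC fraction (pass within 0.20-0.80) and a
basic GC-count melting temperature, Tm = 64.9 + 41 (nGC - 16.4) / L,
pass above 65 degC; the assay names only the constraints, so the
simplest standard formula is used and is exposed in the probe report.

## Error model (`simcore.ErrorModel`)

Per due incorporation (flowed base equals the next template base):

| parameter | default | meaning |
| --- | --- | --- |
| `p_sub` | 0.0052 | wrong base recorded (uniform over the other three) |
| `p_del` | 0.040 | dark incorporation; the template base is skipped permanently |
| `p_ins` | 0.005 | per non-due cycle: spurious recorded event |

`p_sub` is the platform's published average substitution rate per base;
`p_del` and `p_ins` are set so the three rates total ~5% raw error per
base, consistent with deletion errors dominating and with ~95% consensus
accuracy at 1-fold coverage. A missed incorporation is modelled as a
permanent skip - no re-incorporation on a later matching flow - since
single molecules carry no population dephasing to rescue it.

The read-level simulator (`simulate_readset`) applies this process
directly and is vectorised over molecules; 6x10^5 reads simulate in
seconds. Under `p_del` alone the template pointer follows the noise-free
trajectory, so read length is exactly Binomial(K, 1 - p_del) with K the
noise-free extension length - a property the tests exploit.

## Field geometry and imaging (`simcore`, `imagesim`)

A field of view is 54.6 x 54.6 um on a 512 x 512 camera (tests and the
acceptance runs use smaller crops at the same pixel scale). Occupied
sites are Poisson with mean density x area (0.75 sites/um^2 ~ 2236 per
field, matching the observed 2200-2500 reads per field); each site holds
1, 2 or 3 molecules with fractions 0.38/0.36/0.26, the published surface
composition. Co-located molecules are jittered 0.6 px around the site
centre - closer than the diffraction limit but not coincident, which is
what lets the downstream cluster filter see inflated widths.

The PSF is an isotropic 2-D Gaussian, default sigma 1.0 px
(diffraction-limited for ~670 nm emission at 54.6 um / 512 px). The
camera model is Poisson shot noise on signal + background plus Gaussian
read noise; EM-gain excess noise is not modelled. The four 0.1-s
exposures per field are collapsed into one averaged frame by default
(Poisson of k-fold mean divided by k, read noise scaled by 1/sqrt(k)).
Stage drift is a per-cycle cumulative rigid translation; rotation is not
modelled. Photobleaching movies bleach each fluorophore at an
independent geometric time, so occupancy-k sites show k downward steps
unless two fluorophores bleach in the same frame (probability roughly
bleach_rate/2 per pair - an irreducible misclassification mode).

## Image processing (`imageproc`)

* **Registration.** Phase-only correlation: the inverse FFT of the
  unit-normalised cross-power spectrum peaks at the displacement;
  integer drifts are recovered exactly on noise-free frames and to the
  pixel at SNR >= 5. All cycles are aligned to cycle 1. Integer shifts
  are applied by exact roll, fractional ones by linear interpolation.
* **Detection.** The registered image is smoothed with a Gaussian
  kernel (sigma 1 px) and thresholded at median + 5 x robust scale,
  where the scale is 1.4826 x MAD of the smoothed image - on noise-free
  renders the scale falls back to 1% of the dynamic range. Thresholding
  runs on the smoothed image (the assay description leaves this open);
  8-connected components become candidates, components with several
  local maxima are split into one candidate per peak, and each is
  fitted on the *unsmoothed* image.
* **Fitting and cluster filter.** Isotropic 2-D Gaussian plus constant
  background by least squares. Non-convergent fits, non-positive
  amplitudes and escaped centroids are dropped; components larger than
  120 px or fits with sigma > 1.8 x PSF sigma are discarded as
  3+-molecule clusters. Unresolved *pairs* deliberately survive as
  single spots - the platform localises "single molecules or close
  pairs" and relies on photobleaching to tell them apart. Localization
  RMSE is < 0.2 px at 20x the noise scale (measured ~0.04 px).
* **Coincidence.** An incorporation-channel spot within 1.6 px of a
  template-channel anchor is a base-incorporation event; the nearest
  anchor wins, one spot per anchor per cycle, ties to the lower spot
  index. The 1.6 px radius is borrowed from the track radius; the
  colocalization radius itself is not published.

## Photobleaching classification (`photobleach`)

Traces are background-subtracted aperture sums. Step counting uses exact
penalized least-squares change-point segmentation (dynamic program over
piecewise-constant means, penalty = 4 sigma^2 log n per change point,
at most 7 segments). The noise sigma comes from the MAD of first
differences, taking the maximum of the whole-trace and early-window
estimates because shot noise makes post-bleach frames much quieter than
pre-bleach frames; a pooled estimate would under-penalize and shred the
bright segment into spurious steps. A trace is *single* with exactly one
significant downward step, *aggregated* with two to five, and
*unclassified* when it shows an upward step, residuals above 2.5x the
frame noise, more than five steps, or no step at all. On noiseless
movies the classifier is exact whenever bleach frames differ.

Composition recovery is validated on fields whose sites are mutually
resolvable; at realistic densities a few percent of sites fall within a
spot diameter of each other and would physically be detected as one
(aggregated-looking) spot, which is part of the phenomenon, not an
artifact.

## Base calling (`basecall`)

Tracks are anchored at template-channel positions (the anchor image
exists precisely to locate templates), not chained spot-to-spot.
Incorporation spots within 1.6 px of an anchor join its track; anchors
closer than twice the radius to a neighbour are ambiguous and excluded.
Decoding maps event cycles (1-based) through the flow order. On
noise-free, drift-free fields restricted to isolated single-occupancy
sites, the image path reproduces the read-level simulator's reads
string-for-string.

## Alignment, QC, consensus (`alignqc`)

Smith-Waterman with the platform scoring (+2 match, -2 substitution,
-1 for a deletion or insertion in the read, linear gaps), deterministic
tie-breaks (diagonal > up > left; first maximal cell in row-major
order). The jitted kernel aligns ~10^6 read-reference pairs per minute;
work is deduplicated over identical read strings.

Read QC applies, in order: length >= 5; exact-string multiplicity >= 4;
best score against any reference >= 10 (a perfect 5-mer) - the
alignability floor is a chosen operationalization of "could not be
aligned". Reads whose best score ties across templates are dropped from
pileups as ambiguous-origin.

Consensus is the most frequent symbol over {A, C, G, T, deletion} per
reference position, ties toward the reference base (switchable to
strict lexicographic). Identity counts covered positions only, and
consensus is called only where coverage reaches 5% of the maximum
position coverage: beyond the flow protocol's extension horizon the only
"coverage" comes from deletion-bearing or insertion-extended reads,
which carry no majority information.

### Boundary censoring and the error-rate estimators

A local aligner systematically censors errors at read boundaries: a
terminal substitution is either soft-clipped or, whenever the wrong base
equals an adjacent reference base, re-explained as a cheap gap plus a
shifted match (the -1 gap makes that profitable). Three measures make
`error_profile` an (empirically) unbiased estimator of the generative
rates:

1. reads are *realigned* for profiling under a gap-averse scheme
   (+2/-2/-4/-4, `PROFILING_SCORING`): at gap -4 the gap+match
   reinterpretation exactly ties the substitution and the
   diagonal-first tie-break restores the mismatch, while genuine indels
   still align as gaps;
2. each alignment is extended diagonally to the read ends (capped at
   2 bases - extending a long soft clip would fabricate mismatches) so
   boundary substitutions re-enter the pileup;
3. each read's first 2 and last 3 reference columns are excluded from
   the tallies, numerator and denominator alike, so rates are estimated
   from read-interior evidence only.

`ErrorProfile` reports both the unweighted mean-over-positions rates
(the conventional definition) and pooled rates (total events over total
profiled entries); binomial sampling theory applies to the pooled form,
which the recovery tests use. With the default model the pipeline
recovers the generative 0.52% substitution rate within its binomial
confidence interval at >= 10^5 profiled entries, and deletions remain
the largest error class. At the simulated scales the multiplicity
filter is omitted from profiling runs: with a few thousand reads per
template it removes genuine rare error strings wholesale (at production
scale every recurring error string clears four copies easily), which
would bias every rate estimate downward.

### Accuracy versus depth

`subsample_accuracy` draws exactly d pileup entries per position
(multivariate hypergeometric from the tally columns), matching the
"covered d times" reading of sampling-subsampling; a read-draw mode
(sample whole reads to mean coverage d) is available as an alternative.
Three refinements apply, all continuing the interior-evidence
principle: tallies use full-read extension (the depth-1 point should
reflect the raw error process, not the soft-clipped cores); the first
and last eligible positions are excluded (the template start and the
extension horizon see only boundary evidence - a deletion of the first
base or of a read's final base leaves no alignment trace); and a
position drawn at depth d is also wrong when more than half of its
drawn reads carry an insertion at that junction, since a low-depth
consensus inherits inserted bases (at full depth the rule is inert).
Under the defaults, depth-1 accuracy lands at ~95% and depth-5 rounds
to 100%, in line with a ~5% raw per-base error.

## Mutant detection (`mutdetect`)

Each read is assigned to the template (wild or mutant reference) with
the best score and classified by comparing its wild and mutant scores;
per the platform's literal rule, ties go to *mutant* (a documented
`tie_policy="drop"` switch exists, and an off-by-default span filter can
require the alignment to overlap the variant locus). The replicate unit
is the field of view; `simulate_readset` splits reads contiguously into
batches to emulate fields. Significance is a classic equal-variance
two-tailed Student t-test on per-batch mutant frequencies against a
pure wild-type control (Welch by flag). The "0.2 M effective reads" of
the published comparison is implemented as 2x10^5 reads per group in
300 batches.

Because errors masquerade as mutant evidence and non-discriminating
ties go to mutant, measured frequencies exceed the true fractions
(typically ~3% in the pure wild-type control, ~6% for a 3% mixture);
the platform reports the same upward bias and does not correct it, and
neither does this package. Detection works because the *contrast*
against the control is preserved: both the 10:1 and 97:3 mixtures are
significant at alpha = 0.05 and the smallest detected fraction is 3%.

## Problem sizes

The acceptance script and tests use: 12,000 reads (~1,500 per template)
for full-depth consensus; 16,000-48,000 reads for depth curves and error
profiling (>= 10^5 profiled pileup entries); 2x10^5 reads per group in
300 batches for the detection scan; fields of 60-120 sites on 128-200 px
crops for imaging and photobleaching. These scales reproduce the
platform's headline numbers in minutes on one CPU; all randomness is
seed-derived and every run is reproducible.

## What the simulations do not show

* Template sequences, hybridization efficiency and coverage
  non-uniformity are not taken from the real panel; coverage here is
  uniform across templates by construction, so the published
  per-template coverage variation (attributed to sequence-dependent
  hybridization and secondary structure) is out of scope.
* The camera model omits EM-gain excess noise and any chromatic offset
  between channels; the published 26% unclassified photobleaching
  fraction reflects real-trace messiness (blinking, drift, focus) that
  the geometric-bleaching model does not produce, so simulated fields
  classify more cleanly than real ones.
* The error model is homogeneous per base; real runs show
  position- and sequence-dependent error rates.
* Mixing ratios are treated as molecule-count ratios (10:1 means a
  mutant fraction of 1/11); whether the published ratios were molar or
  mass is not stated.
* The nucleotide spans of the two published deletions are inferred from
  their residue ranges (5 and 7 codons); both are configurable.
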