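# Methods

This note records the models, conventions, defaults, and known limits of
`chromtrace`, in the order the pipeline runs.

## Panel geometry and coordinates

Coordinates are 0-based half-open (BED convention) internally; 1-based
coordinates appear only in human-readable output. The default traced
region is chr15:23,500,000-25,600,000 (hg38). Published descriptions of
this experiment give a region end of 25,650,000 in one place (which would
tile into 43 segments of 50 kb) and "42 consecutive 50-kb segments /
2.1 Mb" in another; the two cannot both hold. We honor the segment count:
the default end is 25,600,000, so the panel is exactly 42 segments of
50 kb, and `partition_region` drops (and reports) any trailing remainder
shorter than one segment. Segment *i* is read out in round `i // 2` on
channel `647` (even *i*) or `560` (odd *i*); 42 segments over two channels
give 21 rounds. Round order follows genomic order; an optimized schedule
would only permute codebook rows.

## Probe design

Targeting sequences are 30-nt windows enumerated left-to-right with a
minimum offset gap (default 30 nt, i.e. non-overlapping); windows with
non-ACGT characters are skipped. Composition defaults follow common
oligo-FISH practice — GC fraction in [0.30, 0.70], homopolymer runs of at
most 6 — and are configurable; neither value is prescribed by the source
experiment. Repetitive-sequence screening is exact sub-k-mer counting
(default k = 17, at most 1 genome-wide hit for every window of the
candidate) against the supplied genome, a deterministic, oracle-testable
stand-in for a BLAST screen of the repetitive genome; a brute-force string
scan reproduces its decisions on toy genomes. Per segment, 500 candidates
are selected (the published per-segment pool size) by even spacing over
the offset-sorted candidate list — indices `floor(i·(m−1)/(n−1))` — which
is deterministic, spreads probes across the segment, and breaks ties
leftmost; it approximates, without exactly solving, max-min-gap placement.

Template oligos concatenate, 5'→3': 20-nt forward primer, 20-nt readout
site, the 30-nt target, two more 20-nt readout sites, and the reverse
complement of the 20-nt reverse primer — 130 nt under the
(20, 20, 30, 20, 20, 20) grammar. All oligos of one segment share the same
three readout sites. Adapters are 60 nt: the reverse complement of the
segment's first readout site plus two identical copies of the channel's
common readout-binding 20-mer. Primer/readout sequences are drawn from a
seeded random pool with pairwise (and reverse-complement) Hamming distance
at least 8; the experiment's actual sequences are not reproduced.
Thermodynamic scoring (Tm, secondary structure) is out of scope.

## Synthetic ground truth

The polymer is an ideal Gaussian chain: locus positions are cumulative
sums of isotropic Gaussian steps with per-axis standard deviation
`scale · step_sigma` (default step_sigma = 120 nm per 50-kb step), so
`E[d²(i,j)] = 3 (scale·step_sigma)² |i−j|`. A `sub_block = (lo, hi, s)`
override rescales the steps between loci `lo..hi−1`, which rescales all
block-internal distances exactly — this plants the locally reversed
compaction contrast (a sub-region more compact in AS than PWS) that the
fold-change analysis must recover. The chain is not self-avoiding and has
no loop extrusion; a crude confinement hook (rescaling overflowing chains)
exists but is off by default. Contact matrices are the fraction of traces
with `d(i,j)` below a capture radius (default 150 nm), the ground-truth
analog of a binned proximity-ligation map.

Each simulated nucleus (radius 6 µm, centers on a disjoint grid) carries
exactly one traceable allele, matching hemizygous-deletion fibroblasts;
`expected_traces_per_nucleus` in the linker can be raised to stress
multi-allele assignment. The observation model applies, per round: a rigid
drift uniform in ±300 nm per axis (round 0 defines the reference frame and
has zero drift), a (60, 40, 0) nm chromatic offset on the 560-nm channel,
localization jitter (σ_xy = 50 nm, σ_z = 100 nm; fiducials at 0.2× that),
detection with probability 0.9, and Poisson(3) spurious foci uniform in
the nucleus per round split across channels. Intensities are lognormal
(median 1000, σ = 0.5 for true foci; median 500 for spurious). Fiducial
beads (20 per field) appear every round in the 488-nm channel; a
two-channel bead table supports chromatic calibration. None of these
magnitudes are reported by the source experiment; they are chosen to be
realistic yet desk-solvable and are all configurable. Optional raster
mode renders foci as 3D Gaussians on a (108, 108, 200) nm voxel grid
(axial pitch from the 200-nm z-stepping; lateral pitch a typical sCMOS
back-projected pixel) with Poisson shot noise.

What passing tests show — and don't: the simulator reproduces the
geometry, registration, decoding, and statistics of the experiment, so the
tests validate the *computation*. It does not model self-avoidance,
nuclear environment, optical aberrations beyond a rigid chromatic offset,
or segmentation errors, so the tests do not certify performance on real
image data.

## Registration

Order of corrections is chromatic first (within round), then drift
(across rounds). Chromatic correction maps the 560-nm frame onto the
647-nm reference frame; the default model is a pure translation estimated
by least squares over mutual-nearest-neighbor bead pairs (gate 500 nm),
with an affine mode behind a flag (≥ 4 non-coplanar pairs required).
Drift per round is the mean matched fiducial displacement against round 0;
a robust variant trims the worst 20 % of matches. In the noiseless limit
both estimators are exact, and applying the corrections returns simulated
foci to the planted coordinates identically — the end-to-end identity the
acceptance suite asserts. Nucleus segmentation is Otsu thresholding plus
connected components (min-volume filtered) in raster mode, or a
pass-through of declared center+radius masks in vector mode. Spot fitting
refines local maxima by least-squares 3D Gaussians with an
intensity-weighted centroid fallback, flagged in `fit_quality`; vector
mode filters simulator localizations by intensity threshold and mask
containment, keeping sub-threshold in-mask detections as the refit pool.

## Trace linking

This panel reads one segment per (round, channel), so a focus is a
candidate for exactly one locus and decoding is not combinatorial. Per
nucleus, trace centers are seeded at density peaks (most neighbors within
`r_max`; ties to higher intensity, then input order), then a few
assignment/centroid passes run. Per locus, candidate foci within
`r_max` (default 1500 nm) of the evolving center compete by cost
`distance − intensity_weight · log(intensity)`; ties break to higher
intensity, then lower round. For a single trace the cost is separable
across loci, so per-locus minimization attains the exhaustive global
minimum — verified against brute-force enumeration on 200 random
instances. With multiple seeded traces, per-locus contention is resolved
by exact Hungarian assignment. Missing loci are refit: the expected
position is linearly interpolated (extrapolated at chain ends) between the
nearest assigned loci, and the nearest same-readout candidate within
`refit_radius` (500 nm) at a relaxed threshold (factor 0.5) is adopted and
flagged; assigned loci are never overwritten, so refitting can only raise
completeness. Traces below 50 % completeness are dropped and counted.
Defaults are implementation choices; the source experiment specifies none
of them.

## Statistics

Median distance matrices are pairwise-complete (a trace missing either
locus is skipped for that entry); entries with fewer than `min_pairs`
(default 10) observations are reported missing rather than noisy, and
even-count medians use the midpoint. Fold-change maps are entrywise
`log2(D_num/D_den)`, antisymmetric under swapping conditions, missing
where either input is missing or a denominator is zero (warned, never
pseudocounted). Compaction summaries (radius of gyration, median all-pairs
distance) use a seeded 1000-resample percentile bootstrap over traces.
Distance-contact concordance pairs matched (chrom, start, end) bins,
excludes the diagonal and optionally near-diagonal pairs
(`min_separation`, default 1), and supports Pearson or Spearman on raw or
log-transformed values; zeros are excluded and counted under log
transforms. Constant vectors yield an explicitly `undefined` result. The
published correlation for the real experiment does not state its method or
transform, so both are exposed; the pipeline default is Spearman on raw
values, which is monotone-invariant and the natural choice when contact
frequency decays nonlinearly with distance.

## Problem sizes and determinism

All randomness flows from one top-level seed through named CRC32-derived
substreams per stage, so identical configs produce byte-identical
artifacts. Test and acceptance runs use 150-1000 traces over 6-42 loci —
sizes at which the Monte-Carlo error of a median-of-medians log2
fold-change is well under the ±0.05 recovery tolerance (relative SE of a
per-entry median ≈ 1.25·0.42/√n). Localization noise inflates short-range
distances slightly more in the compact condition, biasing the recovered
log2 fold change toward zero by ~0.01-0.02 at these settings; the bias is
second-order for the median over all 861 entries and is visible in tests
only as a margin, not a failure.

## Known limitations

Gaussian-chain ground truth (no excluded volume, no TADs/loops); rigid
per-round transforms (no field-dependent distortion or illumination
models); translation-only chromatic default; single-FOV simulation; no
error-correcting barcodes (the panel is one-segment-per-slot by design);
contact-map input limited to text dumps at the panel's bin width.
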