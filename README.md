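# chromtrace

Chromatin tracing resolves the 3D fold of a genomic region allele by
allele: the region is tiled into consecutive segments, each segment is
labeled with a pool of primary oligonucleotide probes, and sequential
rounds of secondary hybridization light up one segment per dye channel per
round. Localizing each segment's focus in 3D and linking the localizations
yields a polymer trace per allele, from which median pairwise spatial
distances, condition contrasts, and concordance with Hi-C contact maps
follow.

`chromtrace` implements that computation end to end for the imprinted
human 15q11.2-q13 domain (the Prader-Willi/Angelman region): 42
consecutive 50-kb segments spanning the 2.1-Mb interval
chr15:23,500,000-25,600,000 (hg38), read out in 21 two-color rounds.
Because patient fibroblasts carry a hemizygous deletion of the domain
(paternal in PWS, maternal in AS), each nucleus exposes exactly one
traceable allele. The package is aimed at imaging-genomics researchers who
want a tested, seedable reference implementation of the analysis chain —
and a ground-truth simulator to validate it against.

## What it does

- **`panel_design`** — tile a region into fixed-length segments; enumerate
  30-nt genome-targeting sequences; screen them for repetitive sub-17-mers
  against the supplied genome; select 500 evenly spaced probes per
  segment; assemble 130-nt template oligos under the
  (20, 20, 30, 20, 20, 20) grammar (forward primer, readout site, target,
  two readout sites, reverse-primer site) and 60-nt adapters; build the
  round x channel codebook.
- **`synthetic_data`** — Gaussian-chain conformations with a per-condition
  compaction scale `s` (inter-locus distance obeys
  `E[d²(i,j)] = 3 (s·σ_step)² |i−j|`), an optional sub-block with its own
  scale, matched contact matrices, and a full observation model: per-round
  rigid drift, chromatic offset on the 560-nm channel, localization
  jitter, detection dropout, spurious foci, fiducial beads, nucleus masks,
  optional z-stack rendering at 200-nm steps.
- **`registration`** — chromatic correction from two-color bead images,
  per-round drift from fiducials, nucleus segmentation (Otsu + labeling in
  raster mode), 3D Gaussian spot fitting restricted to nuclei.
- **`trace_linking`** — per-nucleus assembly of registered foci into
  traces by spatial clustering with per-locus minimum-cost assignment, and
  refitting of missing loci from relaxed-threshold detections near the
  interpolated trace position.
- **`distance_stats`** — pairwise-complete median spatial-distance
  matrices, log2 fold-change maps between conditions, radius of gyration
  and detection QC.
- **`hic_concordance`** — plain-text contact-matrix I/O, bin alignment,
  and the distance-versus-contact correlation (Pearson/Spearman, optional
  log transforms).
- **`pipeline` / CLI** — one-seed reproducible orchestration of all of
  the above; verbs `panel`, `simulate`, `register`, `link`, `distmat`,
  `foldchange`, `concord`, `run-all`, `report`.

## Worked example

Run the full two-condition pipeline (maternal-deletion "PWS" allele
simulated 20 % more compact than the paternal-deletion "AS" allele, with
a reversed sub-block at loci 16-22):

```sh
chromtrace run-all --seed 7 --out run7
```

Abridged report (`run7/report.json`):

```json
{
  "stages": {
    "panel": {"n_segments": 42, "n_rounds": 21, "span_bp": 2100000},
    "condition:PWS": {"n_foci": 15149, "n_traces_kept": 150,
                      "mean_completeness": 0.902,
                      "concordance": {"r": -0.894, "method": "spearman"}},
    "condition:AS":  {"n_foci": 15074, "n_traces_kept": 150,
                      "mean_completeness": 0.896,
                      "concordance": {"r": -0.853, "method": "spearman"}}
  },
  "fold_change": {
    "median_log2fc": -0.139,
    "region_summary": {"inside_fraction_positive": 1.0,
                       "outside_fraction_negative": 0.874}
  }
}
```

Reading the numbers: the 2.1-Mb region tiles into 42 segments imaged in 21
rounds; ~15,000 simulated foci per condition reconstruct into 150 traces
with ~90 % locus completeness. Median spatial distance anti-correlates
strongly with simulated contact frequency (Spearman r ≈ −0.85 to −0.89
over the 861 locus pairs), the regime reported for real tracing-vs-Hi-C
comparisons. The global median log2 fold change PWS/AS is negative (the
PWS allele is more compact), while every entry inside the reversed
sub-block is positive — the planted direction reversal is recovered. With
a pure scaling contrast (no sub-block) the median log2 fold change
recovers log2(0.8) ≈ −0.32 to within ±0.05.

Per-condition artifacts land under `run7/conditions/<name>/`: foci,
fiducial and trace TSVs, median-distance and contact matrices (TSV +
heatmap PNG), concordance JSON, and QC counters.

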