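# tkde

Genome-wide identification of **constitutive protein binding sites** from
ChIP-seq peak calls pooled over many cell lines.

A transcription factor such as CTCF binds some loci in essentially every cell
type. When peak calls for the same factor are available from many cell lines,
the centers of the peaks at such a locus pile up within a few tens of base
pairs of each other. `tkde` finds these pile-ups directly from the 1-D peak
centers, with no motif model and no access to the underlying reads, so it
works equally for factors that bind DNA indirectly or lack a known motif.

## Method

For every peak interval `[start, end)` the center is `(start + end)/2`. Per
chromosome, the pipeline runs three stages:

1. **Binary range tree.** The sorted centers are split recursively at the
   midrange `m = (min + max)/2` (left: `x < m`, right: `x ≥ m`). A split is
   refused — making the node terminal — as soon as either prospective child
   would cover too few of the cell lines in the manifest (fraction not above
   the coverage cutoff, default 0.90). This keeps every terminal node
   representative of nearly the whole panel while reducing the
   `O(N log₂ N)` density work on `N` centers to `Σᵢ O(Nᵢ log₂ Nᵢ)` over small
   nodes.
2. **Kernel density estimation.** Within each terminal node the center
   density is the equal-weight Gaussian mixture
   `f̂(x) = (1/(N·h)) Σᵢ K((x − xᵢ)/h)` with `K(u) = (2π)^(−1/2) e^(−u²/2)`
   and bandwidth `h` (default 100 bp; 100–400 bp suits factors with narrow
   peaks).
3. **Mode finding.** From every peak center a mean-shift hill-climb
   (`x ← Σᵢ xᵢ wᵢ / Σᵢ wᵢ`, `wᵢ = K((x − xᵢ)/h)`) converges to a stationary
   point, which Newton steps on the gradient polish and a second-derivative
   test classifies. Each local maximum is a candidate **binding site**; the
   local minima between maxima delimit **modal regions**, and every center is
   assigned to the region whose basin contains it (single-center regions have
   width zero).

A modal region becomes a binding-site call when at least one cell line
contributes centers from ≥ 2 distinct replicate datasets (configurable). The
site is **constitutive** when the fraction of cell lines with such replicate
support strictly exceeds the constitutive cutoff (default: more than 90% of
all cell lines in the manifest).

The package also ships the classical fixed-width **binning** baseline (default
400 bp bins, optionally tiled outward from per-chromosome centromeres), which
suffers boundary-split and amalgamation artifacts the KDE approach avoids, and
a **synthetic catalog generator** that plants constitutive loci,
cell-line-specific loci and background noise with known ground truth.

## Worked example

```
$ cat sim.yaml
n_constitutive_loci: 8
n_specific_loci: 4
noise_peaks_per_dataset: 20
seed: 5

$ tkde simulate --config sim.yaml --out-dir sim
12 loci, 20 datasets, 10 cell lines -> sim

$ tkde call --manifest sim/manifest.tsv --out sites.bed
14 sites (8 constitutive) -> sites.bed

$ tkde compare --dir sim --out-prefix cmp
tkde: recall=1.000 precision=1.000 median |summit-locus|=1.4 bp
binning: recall=0.125 precision=0.143 median |summit-locus|=44.4 bp
wrote cmp.metrics.tsv and cmp.distance_cdf.tsv
```

The simulated panel is 10 cell lines × 2 replicates. `tkde call` recovers all
8 planted constitutive loci (loci present in every cell line) as constitutive
sites plus 6 non-constitutive sites from the cell-line-specific loci; the
median distance between a called summit and its planted locus is 1.4 bp.
The 400 bp binning baseline on the same input finds only 1 of the 8 loci
(boundary splitting disperses replicate support across adjacent bins) and
mislocates sites by tens of bp, since a bin's summit can sit no closer than
the bin midpoint.

`sites.bed` is BED6+4: chrom, region start/end, `site_<k>`,
`score = 1000 × cell-line fraction`, strand `.`, then summit coordinate,
number of supporting cell lines, number of member peak centers, and a 0/1
constitutive flag, preceded by `#` provenance headers. A
`sites.bed.summary.tsv` gives per-chromosome totals.

Real data: point the manifest's `file_path` column at BED3+/narrowPeak peak
files, one per dataset, with `cell_line` and `replicate` columns describing
the panel. Re-labelling datasets lets the same machinery find multi-factor
"hot spots": give each factor's datasets a common pseudo-cell-line and run
`tkde call` on the merged manifest.

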