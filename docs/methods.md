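# Methods

## Model

The observable is the set of ChIP-seq peak centers for one protein, pooled
over every dataset in a manifest of cell lines × replicates. Peak centers are
`(start + end)/2` of the called interval, kept at half-integer resolution:
the downstream density estimate is continuous, so rounding would only discard
information (BED output is floored at write time). If a locus is bound in a
cell line, each of that line's datasets contributes, with some probability,
one peak whose center scatters around the locus by the peak caller's
localization noise. Binding sites are therefore local concentrations of
centers, and a site bound in (essentially) all cell lines shows replicate
support from nearly the whole panel within one concentration.

Within a terminal node of `N` centers the density is the equal-weight
Gaussian mixture

    f̂(x) = 1/(N·h) · Σᵢ K((x − xᵢ)/h),   K(u) = (2π)^(−1/2) exp(−u²/2).

Every local maximum of `f̂` is a candidate binding site; its modal region is
the set of centers in the maximum's basin, bounded by the adjacent antimodes
(local minima). Since the mixture has at most as many maxima as components,
hill-climbing from every sample point visits every populated basin.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `bandwidth` (h) | 100 | bp | kernel SD; 100–400 bp suits narrow-peak factors. Larger h merges nearby modes (mode count is non-increasing in h for Gaussian kernels); the constitutive count is insensitive to h in this range while total modal regions shrink. |
| `coverage_cutoff` | 0.90 | fraction | range-tree stopping rule (below). |
| `constitutive_cutoff` | 0.90 | fraction | a call is constitutive when its supported cell-line fraction **strictly** exceeds this ("more than 90%"). The denominator is always the full manifest cell-line count: absence of peaks is evidence of non-binding, not missing data. |
| `min_replicates` | 2 | datasets | distinct datasets of one cell line needed for that line to support a region; capped at the line's dataset count so single-dataset lines remain usable; 1 disables the binding-site filter. |
| `bin_width` | 400 | bp | binning baseline only. |

Both 0.90 cutoffs are deliberately separate knobs; they play different roles
(partitioning vs calling) even though they share a default.

## Binary range tree

Centers are sorted per chromosome and split recursively at the midrange
(mean of min and max); ties go right (`x ≥ m`). A split is refused, making
the node terminal, when either prospective child would cover too few cell
lines, where a child "covers" a cell line as soon as any one of its datasets
contributes a single center (the stricter replicate rule belongs to calling,
not partitioning). Forced stops: ≤ 1 distinct position, or an empty child
(all positions tied).

**Boundary rule.** A child is acceptable only when its covered fraction
*strictly exceeds* `coverage_cutoff`, or the child covers every cell line
(the exception keeps `coverage_cutoff = 1.0` meaningful). With 55 cell lines
and cutoff 0.9 the threshold 49.5 is not an integer, so "strictly above" and
"at least" coincide and the rule is simply "a child with 49 lines refuses
the split". The readings differ only when `cutoff × n_cell_lines` is an
integer — e.g. 10 cell lines, threshold 9 — and there the strict rule is the
right one: a child landing exactly on the boundary means the split is already
eroding coverage, which is the signature of a midrange that fell *inside* a
binding-site cluster rather than between clusters. Allowing such splits can
cut a genuinely constitutive cluster into two halves that each fail the
replicate rule; refusing them is what makes the tree a pure speed device
whose calls match the tree-free computation.

The tree reduces the density/mode-finding cost from `O(N log₂ N)` on a whole
chromosome to a sum of small per-node costs. `disable_tree` runs the whole
chromosome as one node and exists as the oracle the tree is tested against.

## Mode finding

From every distinct sample point, the mean-shift fixed point iteration
`x ← Σ xᵢ wᵢ / Σ wᵢ`, `wᵢ = K((x − xᵢ)/h)`, runs until the step is below
`10⁻³·h` (at most 500 iterations; non-convergence is logged and the current
point is used). Mean-shift is used first because it ascends the density and
converges for Gaussian kernels from any start, where raw Newton can diverge.
Newton steps on the gradient (capped at `h` per step, at most 60 steps,
gradient tolerance `10⁻¹⁰/(N·h²)`) then polish the stationary point to
near machine precision, and the second derivative classifies it; curvature
within `10⁻⁹/(N·h³)` of zero counts as a (flat-topped) maximum, which
resolves the degenerate equal-pair-at-exactly-2h case to a single midpoint
mode. Converged maxima closer than `10⁻²·h` are deduplicated (keeping the
denser); true modes of a bandwidth-h mixture cannot be that close without an
intervening dip below numerical resolution. One antimode is then located
between each adjacent pair of maxima by Brent root finding on the gradient;
if the gradient signs at the bracket ends are inconclusive (flat valleys,
far-separated modes where intermediate weights underflow), a 257-point scan
of the bracket finds the dip instead, and a pair with no genuine dip at all
is merged. The result strictly alternates max/min/…/max.

Basin assignment is by interval: the antimodes partition the axis, a center
exactly on an antimode goes to the left region (deterministic tie-break),
region bounds are min/max member positions (singletons have width zero), and
a summit that numerical polish left marginally outside its member span is
clamped to it.

## Binning baseline

Equal bins tile each chromosome from origin 0, or outward along both arms
when a centromere table is supplied; bins are half-open `[lo, hi)` with
boundary points belonging to the right bin on either arm (deterministic and
BED-consistent; the bin-phase choice only matters relative to locus
positions). The support and constitutive rules are byte-identical to the KDE
pipeline's, with the bin as the region and the bin midpoint as the summit.
The baseline exists to demonstrate its two failure modes: replicate support
split across a bin boundary (missed sites, worse for narrow bins) and
several adjacent loci amalgamated into one wide bin (spuriously constitutive
calls, worse for wide bins).

## Synthetic data

The generator emulates the multi-cell-line structure the method consumes:
constitutive loci present in every cell line, specific loci present in a
per-locus Bernoulli subset of lines, and uniform background noise peaks per
dataset. Defaults: 10 cell lines × 2 replicates, 20 bp center jitter
(Gaussian, clipped at ±5σ so loci stay separable), peak widths uniform in
150–350 bp, ≥ 2 kb locus spacing on a 1 Mb chromosome, no dropout. A
specific locus whose Bernoulli draw comes out as the full universe is
redrawn: a locus present everywhere *is* constitutive, which would
contradict its planted label (after 100 failed redraws — only reachable with
presence probability ≈ 1 — one arbitrary line is removed instead).

What the generator does **not** emulate: correlated replicate failures,
cell-line lineage structure, peak-width/signal dependence, mappability gaps,
copy-number effects, and clustered or heavy-tailed localization noise.
Passing tests therefore demonstrate the algorithm's correctness and its
robustness properties under the stated noise model, not performance on any
particular real dataset.

Recovery scoring matches constitutive calls to planted constitutive loci
greedily, nearest pair first, one-to-one within a match radius (default
50 bp) — simple, deterministic and adequate for well-spaced loci.

## Problem sizes

The shipped tests and the acceptance script run on catalogs of ~3,300 peak
centers (10 cell lines × 2 replicates; 50 constitutive + 30 specific loci +
100 noise peaks/dataset on a 1 Mb chromosome), chosen so the full pipeline —
including the deliberately slow tree-free oracle runs — completes in seconds
while every planted-structure effect (recovery, bandwidth robustness,
binning artifacts) is still resolvable. The mode-finder oracle comparison
uses 200 random instances of ≤ 50 points at a grid step of `h/1000`.

## Known limitations

* One dimension per chromosome; no joint multi-factor mode beyond manifest
  relabeling.
* No automatic bandwidth selection; `h` is a user choice.
* Tree and tree-free summits can differ by a few bp for *non-planted*
  dense noise neighbourhoods when a node boundary reassigns a distant,
  low-weight center between adjacent basins; planted well-separated loci are
  unaffected.
* With very few cell lines the constitutive label is statistically weak
  regardless of the algorithm; the package computes it but cannot make it
  biologically trustworthy.
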