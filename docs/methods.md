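# Methods

This note records the models, defaults and design choices behind
fishcoder, and what the simulation-based validation does and does not
establish.

## Probe design

Targeting sites are all sliding 28-nt windows of the transcript
(5'→3').  "Off-target homology" is operationalized as an exact shared
substring of length ≥ 17 nt between a site and any background sequence
or its reverse complement; since a shared substring of length ≥ k
exists iff a shared k-mer exists, the screen is decided exactly by a
both-strand 17-mer hash index.  This is deterministic and slightly
stricter than an alignment-based screen (no mismatches are forgiven).
Site selection packs non-overlapping windows greedily left-to-right —
which is provably maximal for interval packing — and thins evenly to
the 32-probe cap when more survive.  Genes that cannot reach 17 probes
are emitted with a `below_minimum` flag rather than dropped, so panel
curation stays a user decision.

No GC or melting-temperature filter is applied to targeting regions by
default (an optional GC window exists but is off); the GC constraint
[0.40, 0.60] applies to readout sequences, which are rejection-sampled
(seeded, deterministic) under three k-mer constraints at k = 10:
against the background (both strands), against previously accepted
readouts (both strands), and implicitly against themselves through the
accepted-k-mer index.  Readout placement on the oligo
(primer|RO|RO|target|RO|RO|primer) follows common practice for
four-readout encoding probes.  Primer flanks default to two arbitrary
fixed 20-mers and are user-replaceable.

## Codebook

Barcodes are unordered 4-subsets of the R × C pseudocolor grid.  The
packer shuffles all C(R·C, 4) subsets with a seeded generator and
accepts a subset iff none of its four 3-subsets has been used — this
enforces pairwise intersection ≤ 2 and, equivalently, bijectivity of
the 3-subset → gene lookup.  On the 44-slot default grid the greedy
capacity is ≈ 2700 (the counting bound is C(44,3)/4 ≈ 3311), i.e.
~2.5× the 1085-gene panel.  No attempt is made at Hamming-optimal or
channel-balanced codes; those are out of scope.

## Simulator

The simulator emulates one field of view of a hydrogel-cleared tissue
section imaged over R rounds × C channels:

- **Geometry.** `n_cells` disc nuclei placed by dart throwing with
  disjoint cytoplasm discs (nucleus radius × 1.6).  Transcripts are
  uniform in the cytoplasm disc; counts per cell and gene are Poisson.
- **Expression.** Default per-cell means are log-spaced over 0.2–5
  copies/cell across the panel, the classical range for transcription
  factor mRNAs (median ≈ 1); the panel-wide mean is ≈ 1.6 copies/cell.
- **Optics.** Isotropic Gaussian PSF, σ = 1.3 px.  Spot amplitude is
  lognormal with mean 500 photons and CV 0.2 over a background of 20
  photons, giving peak-pixel SNR ≈ 10 under shot noise — bright but
  realistic for dye-amplified readout chemistry.
- **Artifacts.** Per-round rigid drift (random walk, σ = 0.8 px/round,
  or an explicit list); multiplicative low-frequency illumination bias
  (±15%, 100-px scale); Poisson shot noise; additive Gaussian read
  noise (σ = 2); per-barcode-position dropout (default 0.1); spurious
  spots (Poisson, default 0.05/plane).
- **Truth.** The generator records every transcript, the per-plane spot
  list after dropout, the planted drifts and the nucleus label image,
  so recall/precision/localization can be scored exactly.

Not emulated: 3-D stacks, chromatic aberration, channel bleed-through,
photobleaching, cell-shape irregularity, autofluorescent structure.
Passing tests therefore demonstrate correctness of the algorithms under
a favorable but honest noise model, not performance on real tissue.

## Image chain

Registration is translation-only (the acquisition corrects horizontal
shift; rotation/scale are out of scope), estimated on the nuclear
reference by unnormalized phase cross-correlation with 1/20-px
upsampling — the unnormalized variant is markedly more robust on
smooth, sparse nuclear images than the phase-normalized one.  The
estimated correction is applied to both channels of the round by cubic
spline interpolation with reflective boundaries.

Tophat uses a 7-px disc (≈ 5× the PSF σ).  ROF denoising is Chambolle's
dual projection with the plane normalized to unit peak so the weight
(default 0.05) is scale-free; the projection conserves the mean.
Richardson–Lucy runs 25 iterations with a Gaussian PSF matched to the
simulator's σ.  25 (not a smaller count) is the default because the
extra sharpening measurably separates crowded same-plane spot pairs;
the cost is mild ringing, handled downstream.  All three parameters are
config-exposed and were chosen on simulation — the acquisition they
would need to be re-tuned for does not publish its values.

## Spot calling

Peaks are strict local maxima above a robust per-plane threshold,
median + 6·MAD.  Two artifact guards, both config-exposed:

- a 10-px border exclusion, because reflective-padding rims from
  tophat/RL concentrate false maxima at plane edges and those rims
  co-occur across planes (so they would decode);
- a ring filter that drops a peak lying within 3 px of a ≥ 3× brighter
  same-plane peak — RL sidelobes; genuine neighboring transcripts
  rarely differ 3× in brightness (lognormal CV 0.2 puts that at ≈ 5σ).

Sub-pixel refinement is a gradient-line radial-symmetry estimator in a
7×7 window: intensity gradients on the mid-pixel lattice define lines
that all pass near the center of a radially symmetric spot; the
estimator returns the weighted least-squares intersection point
(weights: squared gradient magnitude over distance to the gradient
centroid).  On noise-free Gaussians it is exact to < 0.01 px; peaks too
close to the border fall back to an intensity centroid and carry a
flag.  Coordinates are 0-based with pixel centers at integers,
x = column, y = row.

## Decoding

The decoder follows the seeded nearest-neighbor scheme: per seed and
candidate gene, the nearest spot within an inclusive 2.5-px radius in
each of the other three barcode positions; viability at ≥ 3 of 4
positions; the most complete candidate wins, with total seed-companion
distance breaking ties and exact cross-gene ties dropping the seed.
Three choices where the procedure is underdetermined:

- **Completeness before distance.**  Ranking by raw distance sums lets
  a 3-position wrong-gene candidate (a smaller sum by construction)
  beat the correct 4-position one; preferring complete matches reflects
  the rule that a combination matching a single full barcode is
  accepted directly, and removed ~10% of recall loss on simulation.
- **Iterative extraction.**  Same-gene candidates sharing spots are
  grouped; the best candidate claims its spots and the remainder is
  re-evaluated, so two overlapping transcripts of one gene yield two
  calls instead of collapsing.
- **Global conflict resolution.**  A spot claimed by calls of different
  genes goes to the more complete / nearer call (deterministic
  tie-break by gene id); losers are re-validated and dropped below 3
  positions.  Iterated to a fixed point, guaranteeing each spot ends in
  at most one call.

The result is invariant to input row order and global translation; the
consensus call position is the intensity-weighted mean of constituent
spots.  The implementation (KD-trees, union-find) is checked for exact
equality against a brute-force nested-loop oracle on randomized ≤
50-spot fields across 50 seeds.

## Cells and counting

Nuclear segmentation is classical — Gaussian smoothing, Otsu, distance
transform, peak markers (min separation 10 px), watershed, minimum area
50 px² — standing in for a trained segmentation network, which is out
of scope; the watershed finalization matches standard practice.  Calls
are assigned by containment in labels expanded 5 px (non-overlapping
expansion, so cells never merge); counts conserve exactly
(assigned + unassigned = calls).  Per-gene *relative* expression is
recovered faithfully (per-gene truth correlation ≥ 0.99 on the default
simulation); *absolute* per-cell means are biased low by the end-to-end
detection efficiency (≈ 0.83 at default difficulty), as in any real
FISH experiment — comparisons across genes or cells should use the
matrix as-is, absolute copy-number claims require an efficiency
correction.

## Pipeline and reproducibility

A single YAML config drives all seven stages; per-stage seeds derive
from the global seed by fixed offsets (decoupling stage RNG streams),
every output embeds the config hash, and the manifest records per-stage
timings and output hashes.  A stage whose input is supplied externally
(probe TSV, codebook CSV, stack directory, spot CSV) is skipped.
Reruns of the same config are byte-identical.  Default problem sizes
(512×512 field, 30 cells, 40 genes, 22 rounds) complete in under a
minute on one CPU; the 1085-gene codebook and probe design for a panel
that size each take seconds.

## Known limitations

- The decoder is spot-based; pixel-vector decoding and
  intensity-weighted barcode scoring are out of scope.
- Registration is translation-only; rotation or chromatic offsets
  between channels are not corrected.
- The simulator's noise model is plausible rather than fitted to a real
  instrument; thresholds proven here (e.g. recall ≥ 0.8 at 10% dropout)
  are properties of this artifact's conditions, not claims about any
  particular microscope.
- Segmentation assumes roughly convex, well-separated nuclei.
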