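# fishcoder

An in-silico toolkit for combinatorial sequential FISH (seqFISH-style)
spatial transcriptomics.  It covers the full computational arc of a
multi-round barcoding experiment — hybridization probe design, codebook
construction, image preprocessing, sub-pixel spot calling, barcode
decoding, and per-cell counting — together with a ground-truth image
simulator, so every stage can be developed, validated and benchmarked
without microscope data.

## Who this is for

Groups building or analyzing image-based spatial transcriptomics
(seqFISH, MERFISH and relatives) who need a transparent, testable
reference implementation of the decoding pipeline, and a simulator with
known truth to measure recall/precision of design choices before
committing to an experiment.

## The method

**Barcoding.** Each gene *g* is assigned a barcode
*B(g) ⊂ {0, …, R·C − 1}* with |*B(g)*| = 4 — an unordered set of four
*pseudocolors*, where a pseudocolor is one (hybridization round,
fluorescence channel) slot of an *R* = 22 round × *C* = 2 channel
acquisition (44 slots).  Barcodes are packed greedily under the
constraint |*B(g) ∩ B(h)*| ≤ 2 for all gene pairs, which makes every
3-subset of every barcode unique — a transcript missing one of its four
signals still decodes unambiguously.  The greedy packer accommodates
well over the 1085 genes of a genome-scale transcription-factor panel.

**Probe design.** An encoding probe is
`fwd_primer | RO1 | RO2 | revcomp(target28) | RO3 | RO4 | rev_primer`:
a 28-nt mRNA-complementary targeting region flanked by four 18-nt
readout sequences and two PCR primers.  Targeting regions sharing an
exact substring of ≥ 17 nt with any background transcript (either
strand) are discarded; each gene keeps 17–32 non-overlapping sites.
Readout sequences are rejection-sampled with GC ∈ [40%, 60%] and no
shared ≥ 10-mer with the background or each other.

**Image chain.** Per round, the nuclear reference is registered to
round 0 by phase cross-correlation (translation, sub-pixel); each
fluorescence plane then passes white tophat (illumination flattening),
Rudin–Osher–Fatemi total-variation denoising, and Richardson–Lucy
deconvolution with a Gaussian PSF.  Spots are local maxima above a
robust per-plane threshold (median + 6·MAD), refined to sub-pixel
positions by the radial center of the local gradient field.

**Decoding.** Every spot seeds a search: for each gene whose barcode
contains the seed's pseudocolor, the nearest spot within **2.5 px** is
collected in each of the other three barcode positions.  Candidates
covering ≥ 3 of 4 positions are viable; the most complete,
minimum-total-distance candidate wins, exact ties drop the seed as
ambiguous.  Seeding repeats from every position, same-gene candidates
sharing spots are reconciled, cross-gene claims on a spot are resolved
by minimum distance, and each spot ends in at most one validated call.
Calls are assigned to watershed-segmented, morphologically expanded
nuclei, yielding a gene × cell count matrix (MatrixMarket on disk).

## Worked example

`examples/03_simulate_and_decode.py` simulates a 256×256 field (10
cells, 10 genes, 8 rounds × 2 channels, 10% dropout, drift,
illumination bias, shot noise), runs the full chain and scores it
against the simulator's truth:

```
simulated 297 transcripts in 10 cells; 1092 spot placements after 10% dropout
per-round drift corrections (first 4): [(0.0, 0.0), (0.25, 1.95), (-1.05, 1.0), (-0.9, 0.3)]
detected 1508 spots across 16 planes
decoded 211 gene calls: recall 0.710, precision 1.000, positional RMSE 0.55 px
segmented 10 nuclei; count matrix total 203 (8 calls outside expanded cells)
```

The drift corrections undo the planted random-walk drift to ~0.1 px;
precision is ~1 because random spot triples essentially never match a
barcode when pairwise sharing is capped at 2, while recall is bounded by
dropout (P[≥ 3 of 4 positions present] = 0.948 at 10%) minus detection
losses in crowded cytoplasm.  The other examples show probe design
attrition (`01`), codebook capacity (`02`), and the one-command
pipeline with its reproducibility manifest (`04`).

A thin CLI wraps the same library calls:

```bash
fishcoder run --config run.yaml        # full pipeline
fishcoder design --transcripts t.fa --background bg.fa --out dir/
fishcoder codebook --genes genes.txt --rounds 22 --channels 2 --seed 0 --out cb.csv
```

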