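"""Nuclei segmentation, transcript-to-cell assignment, and counting.

Segmentation is classical: Gaussian smoothing, Otsu threshold, distance
transform, peak markers, watershed.  Decoded calls are assigned by
containment in labels morphologically expanded by a few pixels to
approximate the cytoplasm; the result is a gene x cell count matrix
written as MatrixMarket with genes.tsv / cells.tsv sidecars.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation
from skimage.feature import peak_local_max


@dataclass
class SegmentConfig:
    smooth_sigma: float = 2.0
    marker_dist: int = 10
    min_area: int = 50


def segment_nuclei(reference_plane: np.ndarray, cfg: SegmentConfig | None = None) -> np.ndarray:
    """Watershed-based nuclear segmentation of the reference plane.

    Returns a label image (0 = background, labels contiguous from 1).
    A blank image yields zero labels with a warning.
    """
    cfg = cfg or SegmentConfig()
    smooth = ndimage.gaussian_filter(reference_plane.astype(float), cfg.smooth_sigma)
    if smooth.max() <= smooth.min():
        warnings.warn("blank reference plane: no nuclei found")
        return np.zeros(reference_plane.shape, dtype=np.int32)
    thr = filters.threshold_otsu(smooth)
    mask = smooth > thr
    mask = morphology.remove_small_objects(mask, max_size=cfg.min_area - 1)
    if not mask.any():
        warnings.warn("no foreground after thresholding: no nuclei found")
        return np.zeros(reference_plane.shape, dtype=np.int32)
    dist = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(
        dist, min_distance=cfg.marker_dist, labels=mask, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for k, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = k
    labels = segmentation.watershed(-dist, markers, mask=mask)
    labels = morphology.remove_small_objects(labels, max_size=cfg.min_area - 1)
    relabeled, _, _ = segmentation.relabel_sequential(labels)
    return relabeled.astype(np.int32)


@dataclass
class CountMatrix:
    """Gene x cell integer counts with cell centroids."""

    matrix: np.ndarray  # (n_genes, n_cells)
    gene_ids: list[str]
    cell_ids: list[int]
    cell_centroids: pd.DataFrame  # cell_id, y, x, area
    n_unassigned: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=self.gene_ids, columns=self.cell_ids
        )

    def save(self, outdir) -> None:
        from scipy import io as sio
        from scipy.sparse import csr_matrix

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sio.mmwrite(str(outdir / "matrix.mtx"), csr_matrix(self.matrix))
        pd.Series(self.gene_ids).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
        self.cell_centroids.to_csv(outdir / "cells.tsv", sep="\t", index=False)


def assign_and_count(
    calls,
    labels: np.ndarray,
    gene_ids: list[str] | None = None,
    expand_px: int = 5,
) -> CountMatrix:
    """Assign decoded calls to expanded cell labels and count.

    Expansion is non-overlapping (nearest label wins at boundaries, so
    two cells never merge).  Calls landing on background after expansion
    stay unassigned; matrix grand total equals the number of assigned
    calls.
    """
    expanded = segmentation.expand_labels(labels, distance=expand_px) if expand_px else labels
    cell_ids = [int(k) for k in np.unique(labels) if k != 0]
    if gene_ids is None:
        gene_ids = sorted({c.gene_id for c in calls})
    gi = {g: i for i, g in enumerate(gene_ids)}
    ci = {k: j for j, k in enumerate(cell_ids)}
    mat = np.zeros((len(gene_ids), len(cell_ids)), dtype=np.int64)
    H, W = labels.shape
    unassigned = 0
    for c in calls:
        r, col = int(round(c.y)), int(round(c.x))
        if not (0 <= r < H and 0 <= col < W):
            unassigned += 1
            continue
        lab = int(expanded[r, col])
        if lab == 0 or c.gene_id not in gi:
            unassigned += 1
            continue
        mat[gi[c.gene_id], ci[lab]] += 1

    props = measure.regionprops(labels)
    cent = pd.DataFrame(
        [
            {
                "cell_id": p.label,
                "y": p.centroid[0],
                "x": p.centroid[1],
                "area": p.area,
            }
            for p in props
        ],
        columns=["cell_id", "y", "x", "area"],
    )
    return CountMatrix(mat, list(gene_ids), cell_ids, cent, unassigned)
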