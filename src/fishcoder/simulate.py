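"""Ground-truth field simulation and image-stack rendering.

The simulator emulates one field of view of a multi-round combinatorial
FISH acquisition: nuclei scattered in the field, per-cell transcript
counts drawn from Poisson means, and a (round, channel) image series in
which every transcript appears as a diffraction-limited Gaussian spot in
the four planes named by its gene's barcode.  Acquisition artifacts —
per-round rigid drift, multiplicative low-frequency illumination bias,
Poisson shot noise, additive read noise, per-position dropout, and
spurious spots — are all parameterized and seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .codebook import Codebook


def default_expression_means(gene_ids: list[str], lo: float = 0.2, hi: float = 5.0) -> dict[str, float]:
    """Log-spaced per-cell Poisson means for a transcription-factor panel.

    TF mRNAs are classically low-copy (median around one molecule per
    cell, a handful for the most abundant); the default spans 0.2-5
    copies per cell across the panel.
    """
    means = np.geomspace(lo, hi, num=len(gene_ids))
    return {g: float(m) for g, m in zip(gene_ids, means)}


@dataclass
class FieldSpec:
    """Geometry and expression of one simulated tissue field."""

    height: int = 512
    width: int = 512
    n_cells: int = 30
    cell_radius_range: tuple[float, float] = (10.0, 16.0)
    expression_means: dict[str, float] = field(default_factory=dict)
    # transcripts are scattered in a disc this factor larger than the
    # nucleus, a proxy for the cytoplasm
    cytoplasm_scale: float = 1.6

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.expression_means.values()):
            raise ValueError("expression means must be >= 0")
        rmax = self.cell_radius_range[1] * self.cytoplasm_scale
        if 2 * rmax > min(self.height, self.width):
            raise ValueError("cells do not fit in the field")


@dataclass
class AcquisitionSpec:
    """Imaging and noise model for stack rendering.

    Amplitude units are photons; ``spot_amplitude`` is (mean, CV) of a
    lognormal per-spot brightness.  ``drift_per_round`` is either an
    explicit list of (dy, dx) per round or None, in which case a random
    walk with per-round step ``drift_sigma`` px is drawn.
    """

    psf_sigma: float = 1.3
    spot_amplitude: tuple[float, float] = (500.0, 0.2)
    background_level: float = 20.0
    illumination_amplitude: float = 0.15
    illumination_scale_px: float = 100.0
    drift_per_round: list[tuple[float, float]] | None = None
    drift_sigma: float = 0.8
    dropout_rate: float = 0.1
    false_spot_rate: float = 0.05
    read_noise_sigma: float = 2.0
    shot_noise: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")


@dataclass
class GroundTruth:
    """Everything the simulator knows: use it to score the pipeline.

    ``transcripts`` columns: transcript_id, gene_id, x, y, cell_id
    (0 = extracellular).  ``plane_spots`` columns: transcript_id,
    gene_id, pseudocolor, round, channel, x, y — true spot positions per
    plane *after* dropout, in undrifted (round-0) coordinates.
    """

    transcripts: pd.DataFrame
    cell_labels: np.ndarray
    cell_centers: pd.DataFrame
    drifts: list[tuple[float, float]] = field(default_factory=list)
    plane_spots: pd.DataFrame | None = None


def simulate_field(
    fieldspec: FieldSpec, codebook: Codebook, rng_seed: int = 0
) -> GroundTruth:
    """Place nuclei and scatter transcripts; deterministic per seed.

    Nuclei are placed by dart throwing with a retry cap and never
    overlap; per-cell, per-gene transcript counts are Poisson with the
    field's expression means; transcript positions are uniform in the
    cytoplasm disc.
    """
    missing = set(codebook.genes()) - set(fieldspec.expression_means)
    if missing:
        raise ValueError(f"expression_means missing genes: {sorted(missing)[:5]}...")
    rng = np.random.default_rng(rng_seed)
    H, W = fieldspec.height, fieldspec.width
    rlo, rhi = fieldspec.cell_radius_range

    centers: list[tuple[float, float, float]] = []  # (y, x, r)
    tries = 0
    while len(centers) < fieldspec.n_cells:
        if tries > 200 * max(fieldspec.n_cells, 1):
            raise RuntimeError(
                f"placed only {len(centers)}/{fieldspec.n_cells} nuclei; "
                "lower n_cells or the radius range"
            )
        tries += 1
        r = rng.uniform(rlo, rhi)
        margin = r * fieldspec.cytoplasm_scale + 1
        y = rng.uniform(margin, H - margin)
        x = rng.uniform(margin, W - margin)
        # keep cytoplasm discs disjoint so per-cell assignment is unambiguous
        if all(
            np.hypot(y - cy, x - cx)
            > (r + cr) * fieldspec.cytoplasm_scale + 2
            for cy, cx, cr in centers
        ):
            centers.append((y, x, r))

    yy, xx = np.mgrid[0:H, 0:W]
    labels = np.zeros((H, W), dtype=np.int32)
    for k, (cy, cx, r) in enumerate(centers, start=1):
        labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = k

    genes = codebook.genes()
    rows = []
    tid = 0
    for k, (cy, cx, r) in enumerate(centers, start=1):
        rc = r * fieldspec.cytoplasm_scale
        for g in genes:
            n = rng.poisson(fieldspec.expression_means[g])
            for _ in range(n):
                # uniform in disc
                theta = rng.uniform(0, 2 * np.pi)
                rad = rc * np.sqrt(rng.uniform())
                rows.append(
                    {
                        "transcript_id": tid,
                        "gene_id": g,
                        "x": cx + rad * np.cos(theta),
                        "y": cy + rad * np.sin(theta),
                        "cell_id": k,
                    }
                )
                tid += 1
    transcripts = pd.DataFrame(
        rows, columns=["transcript_id", "gene_id", "x", "y", "cell_id"]
    )
    cell_centers = pd.DataFrame(
        [{"cell_id": k, "y": cy, "x": cx, "radius": r} for k, (cy, cx, r) in enumerate(centers, 1)]
    )
    return GroundTruth(transcripts, labels, cell_centers)


def _illumination_field(
    shape: tuple[int, int], amplitude: float, scale_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth multiplicative bias field with mean ~1."""
    if amplitude == 0:
        return np.ones(shape)
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=scale_px, mode="reflect")
    smooth /= np.abs(smooth).max() + 1e-12
    return 1.0 + amplitude * smooth


def _add_gaussian_spots(
    plane: np.ndarray,
    ys: np.ndarray,
    xs: np.ndarray,
    amps: np.ndarray,
    sigma: float,
) -> None:
    """Accumulate unit-mass 2-D Gaussians (times amplitude) in place."""
    H, W = plane.shape
    halfw = int(np.ceil(4 * sigma))
    for y, x, a in zip(ys, xs, amps):
        iy, ix = int(round(y)), int(round(x))
        y0, y1 = max(iy - halfw, 0), min(iy + halfw + 1, H)
        x0, x1 = max(ix - halfw, 0), min(ix + halfw + 1, W)
        if y0 >= y1 or x0 >= x1:
            continue
        gy = np.arange(y0, y1) - y
        gx = np.arange(x0, x1) - x
        g = np.exp(-(gy[:, None] ** 2 + gx[None, :] ** 2) / (2 * sigma**2))
        plane[y0:y1, x0:x1] += a * g / (2 * np.pi * sigma**2)


def render_stack(
    truth: GroundTruth, codebook: Codebook, acq: AcquisitionSpec
) -> "ImageStack":
    """Render the (round, channel) image series plus nuclear references.

    Every non-dropped transcript contributes a Gaussian spot in each of
    its barcode's four planes at its drift-shifted position; spurious
    spots, illumination bias, shot noise and read noise are layered on
    top.  The per-plane true spot table (after dropout) is written back
    onto ``truth.plane_spots``.
    """
    from .stack import ImageStack

    genes = set(truth.transcripts["gene_id"]) if len(truth.transcripts) else set()
    unknown = genes - set(codebook.genes())
    if unknown:
        raise ValueError(f"truth genes not in codebook: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(acq.rng_seed)
    nR, nC = codebook.n_rounds, codebook.n_channels
    H, W = truth.cell_labels.shape

    if acq.drift_per_round is not None:
        drifts = [tuple(map(float, d)) for d in acq.drift_per_round]
        if len(drifts) != nR:
            raise ValueError("drift_per_round length must equal n_rounds")
    else:
        steps = rng.normal(0, acq.drift_sigma, size=(nR, 2))
        steps[0] = 0.0
        drifts = [tuple(d) for d in np.cumsum(steps, axis=0)]
    truth.drifts = drifts

    # per-transcript-position dropout
    spot_rows = []
    barcode_of = {g: sorted(codebook.barcodes[g].pseudocolors) for g in codebook.genes()}
    for rec in truth.transcripts.itertuples(index=False):
        for pc in barcode_of[rec.gene_id]:
            if rng.uniform() < acq.dropout_rate:
                continue
            r, c = divmod(pc, nC)
            spot_rows.append(
                {
                    "transcript_id": rec.transcript_id,
                    "gene_id": rec.gene_id,
                    "pseudocolor": pc,
                    "round": r,
                    "channel": c,
                    "x": rec.x,
                    "y": rec.y,
                }
            )
    plane_spots = pd.DataFrame(
        spot_rows,
        columns=["transcript_id", "gene_id", "pseudocolor", "round", "channel", "x", "y"],
    )
    truth.plane_spots = plane_spots

    amp_mean, amp_cv = acq.spot_amplitude
    illum = _illumination_field(
        (H, W), acq.illumination_amplitude, acq.illumination_scale_px, rng
    )

    planes = np.zeros((nR, nC, H, W))
    for r in range(nR):
        dy, dx = drifts[r]
        for c in range(nC):
            pc = r * nC + c
            plane = np.zeros((H, W))
            sel = plane_spots[plane_spots["pseudocolor"] == pc]
            n_true = len(sel)
            if n_true:
                if amp_cv > 0:
                    s = np.sqrt(np.log(1 + amp_cv**2))
                    amps = rng.lognormal(np.log(amp_mean) - s**2 / 2, s, n_true)
                else:
                    amps = np.full(n_true, amp_mean)
                _add_gaussian_spots(
                    plane, sel["y"].to_numpy() + dy, sel["x"].to_numpy() + dx,
                    amps, acq.psf_sigma,
                )
            n_false = rng.poisson(acq.false_spot_rate)
            if n_false:
                fy = rng.uniform(0, H - 1, n_false)
                fx = rng.uniform(0, W - 1, n_false)
                famps = np.full(n_false, amp_mean)
                _add_gaussian_spots(plane, fy, fx, famps, acq.psf_sigma)
            plane = plane * illum + acq.background_level
            if acq.shot_noise:
                plane = rng.poisson(plane).astype(np.float64)
            if acq.read_noise_sigma > 0:
                plane = plane + rng.normal(0, acq.read_noise_sigma, plane.shape)
            planes[r, c] = np.clip(plane, 0, None)

    # nuclear reference: smoothed discs, drift-shifted, mild noise
    base = 50.0 * ndimage.gaussian_filter((truth.cell_labels > 0).astype(float), 2.0)
    ref = np.zeros((nR, H, W))
    for r in range(nR):
        dy, dx = drifts[r]
        shifted = ndimage.shift(base, (dy, dx), order=3, mode="constant")
        shifted = shifted + 5.0
        if acq.shot_noise:
            shifted = rng.poisson(np.clip(shifted, 0, None)).astype(np.float64)
        if acq.read_noise_sigma > 0:
            shifted = shifted + rng.normal(0, acq.read_noise_sigma, shifted.shape)
        ref[r] = np.clip(shifted, 0, None)

    return ImageStack(planes, ref, registered=False)


# ----------------------------------------------------------------------
# truth table I/O

def write_truth(truth: GroundTruth, outdir) -> None:
    from pathlib import Path
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.transcripts.to_csv(outdir / "truth_transcripts.csv", index=False)
    truth.cell_centers.to_csv(outdir / "truth_cells.csv", index=False)
    if truth.plane_spots is not None:
        truth.plane_spots.to_csv(outdir / "truth_plane_spots.csv", index=False)
    tifffile.imwrite(outdir / "truth_labels.tif", truth.cell_labels.astype(np.int32))
    pd.DataFrame(truth.drifts, columns=["dy", "dx"]).to_csv(
        outdir / "truth_drifts.csv", index=False
    )
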