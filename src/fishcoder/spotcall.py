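"""Spot detection and sub-pixel localization.

Candidate transcript signals are local maxima above a per-plane
threshold (absolute, or robust median + k*MAD); each peak is refined to
sub-pixel precision with the radial center of the local intensity
distribution — the point that the intensity-gradient lines in a small
window most nearly pass through.

Coordinate convention: 0-based, pixel centers at integers, x = column,
y = row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import peak_local_max

from .stack import ImageStack


@dataclass
class ThresholdSpec:
    """Either an absolute intensity cutoff or robust median + k*MAD."""

    mode: str = "robust"  # "robust" | "absolute"
    k_mad: float = 6.0
    absolute: float = 0.0

    def evaluate(self, plane: np.ndarray) -> float:
        if self.mode == "absolute":
            return self.absolute
        med = float(np.median(plane))
        mad = float(np.median(np.abs(plane - med)))
        return med + self.k_mad * mad


@dataclass
class SpotCallConfig:
    threshold: ThresholdSpec = None  # type: ignore[assignment]
    min_distance: int = 1
    window: int = 7
    # reflective-padding artifacts from tophat/deconvolution concentrate
    # in a thin border rim; peaks there are rejected
    exclude_border: int = 10
    # deconvolution ringing: a peak within ring_radius of a >= ring_ratio
    # brighter peak in the same plane is discarded as a sidelobe
    ring_radius: float = 3.0
    ring_ratio: float = 3.0

    def __post_init__(self) -> None:
        if self.threshold is None:
            self.threshold = ThresholdSpec()
        if self.window % 2 == 0:
            raise ValueError("window must be odd")


def detect_spots(
    plane: np.ndarray,
    threshold_spec: ThresholdSpec | None = None,
    min_distance: int = 3,
    exclude_border: int = 0,
) -> np.ndarray:
    """Pixel-level peaks: local maxima over a (2*min_distance+1)^2
    neighborhood, above the threshold.  Returns an (n, 2) array of
    (row, col) sorted by descending intensity."""
    threshold_spec = threshold_spec or ThresholdSpec()
    thr = threshold_spec.evaluate(plane)
    if thr <= 0:
        thr = np.finfo(float).tiny
    peaks = peak_local_max(
        plane,
        min_distance=min_distance,
        threshold_abs=thr,
        exclude_border=exclude_border if exclude_border else False,
    )
    return peaks


def refine_radial_center(
    plane: np.ndarray, peak: tuple[int, int], window: int = 7
) -> tuple[float, float, str]:
    """Sub-pixel (x, y) via the gradient-line radial-symmetry estimator.

    Intensity gradients around a radially symmetric spot all point at
    its center; the estimator finds the least-squares intersection of
    the gradient lines computed on the mid-pixel lattice of the window,
    weighting each line by gradient magnitude squared over distance to
    the rough centroid.

    Returns (x, y, flag) with flag in {"ok", "border_centroid",
    "degenerate"}.  A peak closer than window//2 to the border falls
    back to an intensity centroid; a zero-gradient window returns the
    peak itself.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    h = window // 2
    r0, c0 = int(peak[0]), int(peak[1])
    H, W = plane.shape
    if r0 < h or c0 < h or r0 >= H - h or c0 >= W - h:
        y0, y1 = max(r0 - h, 0), min(r0 + h + 1, H)
        x0, x1 = max(c0 - h, 0), min(c0 + h + 1, W)
        win = plane[y0:y1, x0:x1].astype(float)
        tot = win.sum()
        if tot <= 0:
            return float(c0), float(r0), "degenerate"
        ys, xs = np.mgrid[y0:y1, x0:x1]
        return float((xs * win).sum() / tot), float((ys * win).sum() / tot), "border_centroid"

    win = plane[r0 - h : r0 + h + 1, c0 - h : c0 + h + 1].astype(float)
    # gradients on the (window-1)^2 mid-pixel lattice, 45-degree pairs
    dI_du = win[:-1, 1:] - win[1:, :-1]
    dI_dv = win[:-1, :-1] - win[1:, 1:]
    # 3x3 boxcar smoothing stabilizes against pixel noise
    kernel = np.ones((3, 3)) / 9.0
    from scipy.signal import convolve2d

    du = convolve2d(dI_du, kernel, mode="same", boundary="symm")
    dv = convolve2d(dI_dv, kernel, mode="same", boundary="symm")
    mag2 = du**2 + dv**2
    if mag2.max() <= 0:
        return float(c0), float(r0), "degenerate"

    # mid-pixel coordinates relative to window center
    m = window - 1
    grid = np.arange(m) - (m - 1) / 2.0
    xm = np.tile(grid, (m, 1))
    ym = xm.T
    # gradient slope in (x, y): rotate the 45-degree derivatives back
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = -(du + dv) / (du - dv)
    infs = ~np.isfinite(slope)

    # rough centroid for distance weighting
    tot = mag2.sum()
    xc = (xm * mag2).sum() / tot
    yc = (ym * mag2).sum() / tot
    dist = np.sqrt((xm - xc) ** 2 + (ym - yc) ** 2)
    w = mag2 / (dist + 1e-9)

    # least-squares point minimizing weighted distance to lines
    # y - ym = slope (x - xm); for vertical lines (infinite slope) the
    # line is x = xm.
    mm = np.where(infs, 0.0, slope)
    denom = mm**2 + 1.0
    # distance^2 from (x,y) to line through (xm,ym) with slope mm:
    # (mm*x - y + (ym - mm*xm))^2 / (mm^2+1); vertical: (x - xm)^2
    A11 = np.where(infs, w, w * mm**2 / denom).sum()
    A12 = np.where(infs, 0.0, -w * mm / denom).sum()
    A22 = np.where(infs, 0.0, w / denom).sum()
    b = np.where(infs, 0.0, ym - mm * xm)
    b1 = np.where(infs, w * xm, w * mm * (-b) / denom).sum()
    b2 = np.where(infs, 0.0, w * b / denom).sum()
    A = np.array([[A11, A12], [A12, A22]])
    rhs = np.array([b1, b2])
    det = np.linalg.det(A)
    if abs(det) < 1e-12:
        return float(c0), float(r0), "degenerate"
    xs, ys = np.linalg.solve(A, rhs)
    # clamp pathological solutions to the window
    if abs(xs) > h or abs(ys) > h:
        xs = float(np.clip(xs, -h, h))
        ys = float(np.clip(ys, -h, h))
    return float(c0 + xs), float(r0 + ys), "ok"


@dataclass
class SpotTable:
    """All spots of a stack, sorted by (pseudocolor, y, x)."""

    spots: pd.DataFrame
    provenance: dict | None = None

    def __len__(self) -> int:
        return len(self.spots)

    def to_csv(self, path) -> None:
        header = ""
        if self.provenance:
            header = "".join(f"# {k}={v}\n" for k, v in self.provenance.items())
        with open(path, "w") as fh:
            fh.write(header)
            self.spots.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpotTable":
        prov = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                k, _, v = line.lstrip("# ").partition("=")
                prov[k.strip()] = v.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh)
        return cls(df, prov or None)


def suppress_ring_artifacts(
    df: pd.DataFrame, radius: float = 3.0, ratio: float = 3.0
) -> pd.DataFrame:
    """Drop peaks that sit within ``radius`` px of a >= ``ratio`` times
    brighter peak of the same plane (deconvolution sidelobes).  Genuine
    neighboring transcripts rarely differ that much in brightness."""
    from scipy.spatial import cKDTree

    keep = np.ones(len(df), dtype=bool)
    for _, sub in df.groupby("pseudocolor"):
        xy = sub[["x", "y"]].to_numpy()
        inten = sub["intensity"].to_numpy()
        if len(sub) < 2:
            continue
        tree = cKDTree(xy)
        for a, b in tree.query_pairs(radius):
            if inten[a] >= ratio * inten[b]:
                keep[sub.index[b]] = False
            elif inten[b] >= ratio * inten[a]:
                keep[sub.index[a]] = False
    return df[keep].reset_index(drop=True)


def call_spots(stack: ImageStack, cfg: SpotCallConfig | None = None) -> SpotTable:
    """Detect and refine spots on every (round, channel) plane."""
    if not stack.registered:
        raise ValueError("stack must be registered before spot calling")
    cfg = cfg or SpotCallConfig()
    rows = []
    for r in range(stack.n_rounds):
        for c in range(stack.n_channels):
            plane = stack.planes[r, c]
            pc = r * stack.n_channels + c
            for peak in detect_spots(plane, cfg.threshold, cfg.min_distance, cfg.exclude_border):
                x, y, flag = refine_radial_center(plane, tuple(peak), cfg.window)
                rows.append(
                    {
                        "pseudocolor": pc,
                        "round": r,
                        "channel": c,
                        "x": x,
                        "y": y,
                        "intensity": float(plane[peak[0], peak[1]]),
                        "flag": flag,
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=["pseudocolor", "round", "channel", "x", "y", "intensity", "flag"],
    )
    if cfg.ring_radius > 0:
        df = suppress_ring_artifacts(df, cfg.ring_radius, cfg.ring_ratio)
    df = df.sort_values(["pseudocolor", "y", "x"], kind="mergesort").reset_index(drop=True)
    df.insert(0, "spot_id", np.arange(len(df)))
    return SpotTable(df)
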