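"""Multi-round, multi-channel image stack container with TIFF I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class ImageStack:
    """Planes indexed by (round, channel) plus a per-round nuclear reference.

    ``planes`` has shape (n_rounds, n_channels, H, W) and
    ``nuclear_reference`` shape (n_rounds, H, W).  ``shifts`` holds the
    per-round (dy, dx) translations estimated during registration;
    shifts[0] is (0, 0) once registered.
    """

    planes: np.ndarray
    nuclear_reference: np.ndarray
    registered: bool = False
    shifts: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.planes.ndim != 4:
            raise ValueError("planes must be (rounds, channels, H, W)")
        if self.nuclear_reference.ndim != 3:
            raise ValueError("nuclear_reference must be (rounds, H, W)")
        if self.planes.shape[0] != self.nuclear_reference.shape[0]:
            raise ValueError("round count mismatch between planes and reference")
        if self.planes.shape[2:] != self.nuclear_reference.shape[1:]:
            raise ValueError("plane dimensions mismatch")
        if np.any(self.planes < 0):
            raise ValueError("plane intensities must be nonnegative")

    @property
    def n_rounds(self) -> int:
        return self.planes.shape[0]

    @property
    def n_channels(self) -> int:
        return self.planes.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[2:]

    def plane(self, round: int, channel: int) -> np.ndarray:
        return self.planes[round, channel]

    def flat_plane(self, pseudocolor: int) -> np.ndarray:
        r, c = divmod(pseudocolor, self.n_channels)
        return self.planes[r, c]

    # ------------------------------------------------------------------
    def save(self, outdir) -> None:
        """Write one multi-page TIFF per channel (pages = rounds) plus the
        nuclear reference TIFF and a shifts CSV."""
        import tifffile

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for c in range(self.n_channels):
            tifffile.imwrite(
                outdir / f"channel_{c}.tif", self.planes[:, c].astype(np.float32)
            )
        tifffile.imwrite(
            outdir / "nuclear_reference.tif",
            self.nuclear_reference.astype(np.float32),
        )
        with open(outdir / "shifts.csv", "w") as fh:
            fh.write("round,dy,dx,registered\n")
            shifts = self.shifts or [(0.0, 0.0)] * self.n_rounds
            for r, (dy, dx) in enumerate(shifts):
                fh.write(f"{r},{dy},{dx},{int(self.registered)}\n")

    @classmethod
    def load(cls, indir) -> "ImageStack":
        import tifffile

        indir = Path(indir)
        channels = sorted(indir.glob("channel_*.tif"))
        if not channels:
            raise FileNotFoundError(f"no channel_*.tif under {indir}")
        planes = np.stack([tifffile.imread(p) for p in channels], axis=1)
        ref = tifffile.imread(indir / "nuclear_reference.tif")
        registered = False
        shifts: list[tuple[float, float]] = []
        shifts_path = indir / "shifts.csv"
        if shifts_path.exists():
            with open(shifts_path) as fh:
                next(fh)
                for line in fh:
                    _, dy, dx, reg = line.strip().split(",")
                    shifts.append((float(dy), float(dx)))
                    registered = bool(int(reg))
        return cls(planes.astype(np.float64), ref.astype(np.float64), registered, shifts)
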