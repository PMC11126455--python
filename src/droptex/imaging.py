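"""Loading, masking, time-normalisation and stage labelling of droplet image series.

A droplet movie is an ordered stack of 8-bit grayscale frames sharing one
binary region-of-interest (ROI) mask — the droplet interior, which stays
fixed because the contact line is pinned.  Normalised time is frame index
divided by the last index, so the first frame sits at 0 and the last at 1,
and the drying process is segmented into three stages (initial, middle,
final) by two breakpoints on that normalised axis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize

logger = logging.getLogger(__name__)

CLASS_LABELS = ("0x", "0.25x", "0.5x", "0.75x", "1x")

#: default normalised-time breakpoints separating initial/middle/final stages
DEFAULT_BREAKPOINTS = (0.40, 0.75)

STAGES = ("initial", "middle", "final")


@dataclass
class DropletSeries:
    """Time-ordered masked frames of a single drying droplet.

    Attributes
    ----------
    frames : np.ndarray
        ``(n_frames, h, w)`` uint8 stack.
    mask : np.ndarray
        ``(h, w)`` boolean ROI; True inside the droplet.
    times_norm : np.ndarray
        Per-frame normalised time, strictly increasing from 0 to 1.
    stages : np.ndarray
        Per-frame stage label in ``{"initial", "middle", "final"}``.
    label : str
        Droplet class (initial buffer concentration), e.g. ``"0.5x"``.
    droplet_id : str
        Free-form identifier.
    """

    frames: np.ndarray
    mask: np.ndarray
    times_norm: np.ndarray
    stages: np.ndarray
    label: str
    droplet_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.uint8)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.times_norm = np.asarray(self.times_norm, dtype=float)
        self.stages = np.asarray(self.stages, dtype=object)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) stack")
        if self.frames.shape[1:] != self.mask.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match frame shape "
                f"{self.frames.shape[1:]}"
            )
        n = len(self.frames)
        if len(self.times_norm) != n or len(self.stages) != n:
            raise ValueError("times_norm and stages must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def stage_indices(self, stage: str) -> np.ndarray:
        """Frame indices belonging to one stage."""
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
        return np.flatnonzero(self.stages == stage)


@dataclass(frozen=True)
class QuantizedROI:
    """Gray-level-binned ROI underlying every texture matrix.

    ``levels`` holds consecutive bin indices 1..N_g on mask pixels and 0
    outside the mask; ``bin_centers[k]`` is the representative raw intensity
    of level ``k+1`` (kept for intensity-weighted features, though matrix
    features use the consecutive indices themselves).
    """

    levels: np.ndarray
    mask: np.ndarray
    n_p: int
    n_g: int
    bin_width: int
    bin_centers: np.ndarray = field(default=None)  # type: ignore[assignment]


def circular_mask(shape: tuple[int, int], radius_fraction: float = 0.9) -> np.ndarray:
    """Centered disk mask at ``radius_fraction`` of the half-width.

    The default mask when none is supplied: the droplet is pinned and
    circular, so the ROI is the largest inscribed centered disk scaled by
    ``radius_fraction``.
    """
    h, w = shape
    r = radius_fraction * min(h, w) / 2.0
    yy, xx = np.ogrid[:h, :w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def normalized_times(n_frames: int) -> np.ndarray:
    if n_frames < 2:
        raise ValueError("need at least 2 frames to normalise time")
    return np.arange(n_frames, dtype=float) / (n_frames - 1)


def stage_of(t: float, breakpoints: tuple[float, float] = DEFAULT_BREAKPOINTS) -> str:
    """Stage label for one normalised time.

    Left-closed/right-open intervals except the final stage, which is closed
    at 1, so every frame receives exactly one stage.
    """
    b1, b2 = breakpoints
    if not (0.0 < b1 < b2 < 1.0):
        raise ValueError(f"breakpoints must satisfy 0 < b1 < b2 < 1, got {breakpoints}")
    if t < b1:
        return "initial"
    if t < b2:
        return "middle"
    return "final"


def assign_stages(
    series: DropletSeries, breakpoints: tuple[float, float] = DEFAULT_BREAKPOINTS
) -> DropletSeries:
    """Return a copy of ``series`` with stages recomputed from ``breakpoints``."""
    stages = np.array([stage_of(t, breakpoints) for t in series.times_norm], dtype=object)
    return replace(series, stages=stages)


def _to_uint8_gray(img: np.ndarray) -> np.ndarray:
    """Collapse colour channels and rescale to the 8-bit range."""
    img = np.asarray(img)
    if img.ndim == 3:
        if img.shape[2] == 4:  # drop alpha
            img = img[:, :, :3]
        # ITU-R 601 luma
        img = img @ np.array([0.299, 0.587, 0.114])
    img = img.astype(float)
    if img.max() > 255:  # 16-bit input
        img = img * (255.0 / img.max())
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def load_series(
    directory: str | Path,
    mask_path: str | Path | None,
    label: str,
    *,
    size: int = 150,
    breakpoints: tuple[float, float] = DEFAULT_BREAKPOINTS,
    radius_fraction: float = 0.9,
    droplet_id: str | None = None,
) -> DropletSeries:
    """Load a droplet movie from a directory of image files.

    Files are sorted by name, converted to 8-bit grayscale and resized to
    ``size``×``size`` (bilinear, rounded back to integers); the mask is
    resized by nearest neighbour.  Non-image files are skipped with a
    warning.  When ``mask_path`` is None a centered disk mask is used.
    """
    directory = Path(directory)
    if mask_path is None and (directory / "mask.png").exists():
        mask_path = directory / "mask.png"  # sidecar convention of save_series
    mask_resolved = Path(mask_path).resolve() if mask_path is not None else None
    paths = sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.resolve() != mask_resolved
    )
    frames = []
    for p in paths:
        try:
            img = iio.imread(p)
        except Exception:
            logger.warning("skipping unreadable file %s", p)
            continue
        img = _to_uint8_gray(img)
        if img.shape != (size, size):
            img = resize(img.astype(float), (size, size), order=1, anti_aliasing=False)
            img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        frames.append(img)
    if len(frames) < 2:
        raise ValueError(f"{directory} contains fewer than 2 readable images")

    if mask_path is None:
        mask = circular_mask((size, size), radius_fraction)
    else:
        m = iio.imread(mask_path)
        if m.ndim == 3:
            m = m[..., 0]
        if m.shape != (size, size):
            m = resize(m.astype(float), (size, size), order=0, anti_aliasing=False)
        mask = np.asarray(m) > 0
    if mask.shape != (size, size):
        raise ValueError("mask shape does not match frame shape after resize")

    times = normalized_times(len(frames))
    stages = np.array([stage_of(t, breakpoints) for t in times], dtype=object)
    return DropletSeries(
        frames=np.stack(frames),
        mask=mask,
        times_norm=times,
        stages=stages,
        label=label,
        droplet_id=droplet_id or directory.name,
    )


def quantize(frame: np.ndarray, mask: np.ndarray, bin_width: int = 25) -> QuantizedROI:
    """Bin ROI intensities into discrete gray levels.

    Bin index before remapping is ``floor(intensity / bin_width)``; occupied
    bins are then remapped to consecutive levels 1..N_g (matrix rows), with
    the original bin centers retained.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask selects no pixels")
    frame = np.asarray(frame)
    raw_bins = frame.astype(np.int64) // bin_width
    occupied = np.unique(raw_bins[mask])
    levels = np.zeros(frame.shape, dtype=np.int64)
    levels[mask] = np.searchsorted(occupied, raw_bins[mask]) + 1
    centers = occupied * bin_width + (bin_width - 1) / 2.0
    return QuantizedROI(
        levels=levels,
        mask=mask,
        n_p=int(mask.sum()),
        n_g=len(occupied),
        bin_width=bin_width,
        bin_centers=centers,
    )


def save_series(series: DropletSeries, out_dir: str | Path) -> Path:
    """Write frames as zero-padded 8-bit PNGs plus mask and JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(series.n_frames - 1)))
    for i, frame in enumerate(series.frames):
        iio.imwrite(out_dir / f"frame_{i:0{width}d}.png", frame)
    iio.imwrite(out_dir / "mask.png", (series.mask * 255).astype(np.uint8))
    meta = {
        "label": series.label,
        "droplet_id": series.droplet_id,
        "n_frames": int(series.n_frames),
        "stages": [str(s) for s in series.stages],
    }
    (out_dir / "meta.json").write_text(json.dumps(meta, indent=2))
    return out_dir
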