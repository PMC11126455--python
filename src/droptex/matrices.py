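"""Gray-level texture matrices on a quantized ROI.

Four count matrices underpin the second- and higher-order texture features:

* GLCM — joint frequency of level pairs at offset (delta, theta);
* GLRLM — maximal same-level pixel runs by level and length, per angle;
* GLSZM — connected same-level zones by level and size (rotation free);
* GLDM — per-pixel count of neighbours within Chebyshev distance delta
  whose level differs from the centre by at most alpha.

All builders operate on :class:`~droptex.imaging.QuantizedROI`, whose
``levels`` array holds consecutive indices 1..N_g inside the mask and 0
outside; level 0 never participates in a pair, run, zone or dependency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import QuantizedROI

GLCM_ANGLES = (0, 45, 90, 135)

# unit offsets (drow, dcol); sign is immaterial under symmetric accumulation
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class CooccurrenceMatrix:
    """Per-angle GLCM counts plus the settings that produced them."""

    counts: dict[int, np.ndarray]  # angle -> (N_g, N_g) pair counts
    n_g: int
    delta: int
    symmetric: bool

    def total(self, angle: int) -> float:
        return float(self.counts[angle].sum())

    def is_degenerate(self, angle: int) -> bool:
        """True when no valid pixel pair exists at this angle."""
        return self.counts[angle].sum() == 0

    def p(self, angle: int) -> np.ndarray:
        """Normalised co-occurrence matrix for one angle."""
        c = self.counts[angle]
        s = c.sum()
        if s == 0:
            raise ValueError(f"degenerate GLCM at angle {angle}: no pixel pairs")
        return c / s


@dataclass
class RunLengthMatrix:
    """Run counts P(i, j | theta): level i (rows, 1..N_g), length j (cols, 1..)."""

    counts: np.ndarray
    theta: int
    n_g: int

    @property
    def n_r(self) -> int:
        return int(self.counts.sum())

    def p(self) -> np.ndarray:
        return self.counts / self.counts.sum()


@dataclass
class SizeZoneMatrix:
    """Zone counts P(i, j): level i (rows, 1..N_g), zone size j (cols, 1..)."""

    counts: np.ndarray
    connectivity: int
    n_g: int

    @property
    def n_z(self) -> int:
        return int(self.counts.sum())

    @property
    def n_s(self) -> int:
        """Number of distinct zone sizes present."""
        return int((self.counts.sum(axis=0) > 0).sum())

    def p(self) -> np.ndarray:
        return self.counts / self.counts.sum()


@dataclass
class DependenceMatrix:
    """Dependence counts P(i, d): level i (rows, 1..N_g), count d (cols, 0..)."""

    counts: np.ndarray
    alpha: int
    delta: int
    n_g: int

    @property
    def n_dep(self) -> int:
        return int(self.counts.sum())  # equals N_p: one entry per ROI pixel

    def p(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def _offset_pairs(levels: np.ndarray, dr: int, dc: int) -> tuple[np.ndarray, np.ndarray]:
    """Levels of all in-bounds pixel pairs at offset (dr, dc)."""
    h, w = levels.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    a = levels[r0:r1, c0:c1]
    b = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    ok = (a > 0) & (b > 0)
    return a[ok], b[ok]


def build_glcm(
    roi: QuantizedROI,
    delta: int = 1,
    angles: tuple[int, ...] = GLCM_ANGLES,
    symmetric: bool = True,
) -> CooccurrenceMatrix:
    """Gray level co-occurrence matrix for each requested angle.

    Both pixels of a pair must lie inside the mask.  In symmetric mode each
    pair is accumulated in both orders, so the matrix equals its transpose.
    """
    if delta < 1:
        raise ValueError("delta must be >= 1")
    n_g = roi.n_g
    counts: dict[int, np.ndarray] = {}
    for angle in angles:
        dr, dc = _ANGLE_OFFSETS[angle]
        a, b = _offset_pairs(roi.levels, dr * delta, dc * delta)
        flat = np.bincount((a - 1) * n_g + (b - 1), minlength=n_g * n_g)
        m = flat.reshape(n_g, n_g).astype(np.int64)
        if symmetric:
            m = m + m.T
        counts[angle] = m
    return CooccurrenceMatrix(counts=counts, n_g=n_g, delta=delta, symmetric=symmetric)


def _run_lengths(line_stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Values and lengths of maximal constant runs in a 1D array."""
    arr = line_stack
    if arr.size == 0:
        return arr, arr
    change = np.flatnonzero(arr[1:] != arr[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [arr.size]))
    return arr[starts], ends - starts


def _lines_along(levels: np.ndarray, theta: int) -> list[np.ndarray]:
    """Lattice lines of the level image along one of the four angles."""
    h, w = levels.shape
    if theta == 0:
        return [levels[r] for r in range(h)]
    if theta == 90:
        return [levels[:, c] for c in range(w)]
    if theta == 135:  # main diagonals (down-right)
        return [np.diagonal(levels, off) for off in range(-(h - 1), w)]
    if theta == 45:  # anti-diagonals (up-right)
        fl = np.fliplr(levels)
        return [np.diagonal(fl, off) for off in range(-(h - 1), w)]
    raise ValueError(f"theta must be one of {GLCM_ANGLES}, got {theta}")


def build_glrlm(roi: QuantizedROI, theta: int) -> RunLengthMatrix:
    """Gray level run length matrix along one angle.

    Masked-out pixels (level 0) break runs; every ROI pixel belongs to
    exactly one run per angle, so sum(j * P(i, j)) = N_p.
    """
    lines = _lines_along(roi.levels, theta)
    # join lines with a single 0 separator; level-0 runs are discarded below
    joined = np.concatenate(
        [np.concatenate((ln, [0])) for ln in lines]
    ) if lines else np.empty(0, dtype=np.int64)
    vals, lens = _run_lengths(joined)
    keep = vals > 0
    vals, lens = vals[keep], lens[keep]
    max_len = int(lens.max()) if lens.size else 1
    counts = np.zeros((roi.n_g, max_len), dtype=np.int64)
    np.add.at(counts, (vals - 1, lens - 1), 1)
    return RunLengthMatrix(counts=counts, theta=theta, n_g=roi.n_g)


_STRUCT4 = ndimage.generate_binary_structure(2, 1)
_STRUCT8 = ndimage.generate_binary_structure(2, 2)


def build_glszm(roi: QuantizedROI, connectivity: int = 8) -> SizeZoneMatrix:
    """Gray level size zone matrix: connected equal-level components in the mask.

    Zones partition the ROI, so sum(j * P(i, j)) = N_p for any connectivity.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    struct = _STRUCT8 if connectivity == 8 else _STRUCT4
    n_g = roi.n_g
    level_sizes: list[tuple[np.ndarray, np.ndarray]] = []
    max_size = 1
    for lvl in range(1, n_g + 1):
        lab, n_lab = ndimage.label(roi.levels == lvl, structure=struct)
        if n_lab == 0:
            level_sizes.append((np.empty(0, int), np.empty(0, int)))
            continue
        sizes = np.bincount(lab.ravel())[1:]
        level_sizes.append((np.full(n_lab, lvl), sizes))
        max_size = max(max_size, int(sizes.max()))
    counts = np.zeros((n_g, max_size), dtype=np.int64)
    for lvls, sizes in level_sizes:
        if lvls.size:
            np.add.at(counts, (lvls - 1, sizes - 1), 1)
    return SizeZoneMatrix(counts=counts, connectivity=connectivity, n_g=n_g)


def build_gldm(roi: QuantizedROI, alpha: int = 0, delta: int = 1) -> DependenceMatrix:
    """Gray level dependence matrix.

    For each ROI pixel, the dependence d is the number of in-mask neighbours
    within Chebyshev distance ``delta`` (centre excluded) whose level differs
    by at most ``alpha``; P(i, d) counts pixels of level i with dependence d.
    """
    if alpha < 0 or delta < 1:
        raise ValueError("alpha must be >= 0 and delta >= 1")
    levels = roi.levels
    h, w = levels.shape
    dep = np.zeros((h, w), dtype=np.int64)
    for dr in range(-delta, delta + 1):
        for dc in range(-delta, delta + 1):
            if dr == 0 and dc == 0:
                continue
            r0, r1 = max(0, -dr), min(h, h - dr)
            c0, c1 = max(0, -dc), min(w, w - dc)
            if r0 >= r1 or c0 >= c1:
                continue
            a = levels[r0:r1, c0:c1]
            b = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
            hit = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
            dep[r0:r1, c0:c1] += hit
    in_roi = levels > 0
    d_vals = dep[in_roi]
    l_vals = levels[in_roi]
    counts = np.zeros((roi.n_g, int(d_vals.max()) + 1 if d_vals.size else 1), dtype=np.int64)
    np.add.at(counts, (l_vals - 1, d_vals), 1)
    return DependenceMatrix(counts=counts, alpha=alpha, delta=delta, n_g=roi.n_g)
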