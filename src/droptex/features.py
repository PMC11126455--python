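"""The thirty gray-level texture features extracted per frame.

Eight first-order statistics (FOS) of the raw ROI intensity histogram, eight
gray level co-occurrence (GLCM) features averaged over four angles, four run
length (GLRLM) features averaged over four angles, five size zone (GLSZM)
features and five dependence (GLDM) features.  Entropies are base-2 with a
fixed epsilon of 2.2e-16 inside the logarithm; conventions for degenerate
(constant-intensity) regions keep every feature finite: skewness and
kurtosis are 0 and GLCM correlation is 1 on zero-variance input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import DropletSeries, quantize
from .matrices import (
    GLCM_ANGLES,
    CooccurrenceMatrix,
    DependenceMatrix,
    RunLengthMatrix,
    SizeZoneMatrix,
    build_glcm,
    build_gldm,
    build_glrlm,
    build_glszm,
)

EPS = 2.2e-16

FOS_NAMES = (
    "Mean", "Variance", "Skewness", "Kurtosis",
    "RootMeanSquared", "Uniformity", "Entropy", "Energy",
)
GLCM_NAMES = (
    "Contrast", "Correlation", "IDM", "MaximumProbability",
    "DifferenceAverage", "DifferenceVariance", "SumEntropy", "DifferenceEntropy",
)
GLRLM_NAMES = ("GrayLevelNonUniformity", "GrayLevelVariance", "RunVariance", "RunEntropy")
GLSZM_NAMES = (
    "GrayLevelNonUniformity", "SizeZoneNonUniformity",
    "GrayLevelVariance", "ZoneVariance", "ZoneEntropy",
)
GLDM_NAMES = (
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "GrayLevelVariance", "DependenceVariance", "DependenceEntropy",
)

#: stable column order of the 30-feature vector
FEATURE_COLUMNS = (
    *(f"fos_{n}" for n in FOS_NAMES),
    *(f"glcm_{n}" for n in GLCM_NAMES),
    *(f"glrlm_{n}" for n in GLRLM_NAMES),
    *(f"glszm_{n}" for n in GLSZM_NAMES),
    *(f"gldm_{n}" for n in GLDM_NAMES),
)

META_COLUMNS = ("droplet_id", "label", "t_norm", "stage")


@dataclass(frozen=True)
class FeatureSettings:
    """Extraction settings; matrix features use quantized levels, FOS raw 8-bit."""

    matrix_bin_width: int = 25
    glcm_delta: int = 1
    glcm_angles: tuple[int, ...] = GLCM_ANGLES
    glcm_symmetric: bool = True
    glrlm_angles: tuple[int, ...] = GLCM_ANGLES
    glszm_connectivity: int = 8
    gldm_alpha: int = 0
    gldm_delta: int = 1
    fos_shift: float = 0.0

    def to_dict(self) -> dict:
        return {
            "matrix_bin_width": self.matrix_bin_width,
            "glcm_delta": self.glcm_delta,
            "glcm_angles": list(self.glcm_angles),
            "glcm_symmetric": self.glcm_symmetric,
            "glrlm_angles": list(self.glrlm_angles),
            "glszm_connectivity": self.glszm_connectivity,
            "gldm_alpha": self.gldm_alpha,
            "gldm_delta": self.gldm_delta,
            "fos_shift": self.fos_shift,
        }


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy, base 2, with the fixed epsilon guard."""
    p = np.asarray(p, dtype=float)
    return float(-np.sum(p * np.log2(p + EPS)))


def fos_features(x: np.ndarray, c: float = 0.0) -> dict[str, float]:
    """First-order statistics of the raw ROI intensities.

    ``x`` is the flat list of N_p intensities; the histogram runs over the
    N_g distinct values present.  ``c`` shifts intensities in Energy and RMS
    (guards against negative input; 0 for 8-bit data).
    """
    x = np.asarray(x, dtype=float).ravel()
    n_p = x.size
    if n_p < 1:
        raise ValueError("empty ROI")
    mean = float(x.mean())
    var = float(np.mean((x - mean) ** 2))
    if var > 0:
        sd = np.sqrt(var)
        skew = float(np.mean((x - mean) ** 3) / sd**3)
        kurt = float(np.mean((x - mean) ** 4) / var**2)
    else:
        skew = 0.0
        kurt = 0.0
    _, counts = np.unique(x, return_counts=True)
    p = counts / n_p
    return {
        "Mean": mean,
        "Variance": var,
        "Skewness": skew,
        "Kurtosis": kurt,
        "RootMeanSquared": float(np.sqrt(np.mean((x + c) ** 2))),
        "Uniformity": float(np.sum(p**2)),
        "Entropy": _entropy(p),
        "Energy": float(np.sum((x + c) ** 2)),
    }


def _glcm_angle_features(p: np.ndarray) -> dict[str, float]:
    n_g = p.shape[0]
    i = np.arange(1, n_g + 1)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(px @ i)
    mu_y = float(py @ i)
    sig_x = float(np.sqrt(px @ (i - mu_x) ** 2))
    sig_y = float(np.sqrt(py @ (i - mu_y) ** 2))
    ii, jj = np.meshgrid(i, i, indexing="ij")
    k_diff = np.arange(0, n_g)
    p_diff = np.bincount(np.abs(ii - jj).ravel(), weights=p.ravel(), minlength=n_g)
    k_sum = np.arange(2, 2 * n_g + 1)
    p_sum = np.bincount((ii + jj).ravel(), weights=p.ravel(), minlength=2 * n_g + 1)[2:]
    da = float(k_diff @ p_diff)
    if sig_x > 0 and sig_y > 0:
        corr = float(np.sum(p * (ii * jj - mu_x * mu_y)) / (sig_x * sig_y))
    else:
        corr = 1.0  # constant region: perfectly dependent by convention
    return {
        "Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "Correlation": corr,
        "IDM": float(np.sum(p_diff / (1.0 + k_diff**2))),
        "MaximumProbability": float(p.max()),
        "DifferenceAverage": da,
        "DifferenceVariance": float((k_diff - da) ** 2 @ p_diff),
        "SumEntropy": _entropy(p_sum),
        "DifferenceEntropy": _entropy(p_diff),
    }


def glcm_features(m: CooccurrenceMatrix) -> dict[str, float]:
    """Eight GLCM features, computed per angle then arithmetically averaged."""
    per_angle = []
    for angle in m.counts:
        if m.is_degenerate(angle):
            continue
        per_angle.append(_glcm_angle_features(m.p(angle)))
    if not per_angle:
        raise ValueError("GLCM degenerate for every angle (single-pixel ROI?)")
    return {k: float(np.mean([f[k] for f in per_angle])) for k in GLCM_NAMES}


def _glrlm_angle_features(mat: RunLengthMatrix) -> dict[str, float]:
    p = mat.p()
    n_g, max_j = p.shape
    i = np.arange(1, n_g + 1)
    j = np.arange(1, max_j + 1)
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float(pi @ i)
    mu_j = float(pj @ j)
    row_sums = mat.counts.sum(axis=1).astype(float)
    return {
        "GrayLevelNonUniformity": float(np.sum(row_sums**2) / mat.n_r),
        "GrayLevelVariance": float(pi @ (i - mu_i) ** 2),
        "RunVariance": float(pj @ (j - mu_j) ** 2),
        "RunEntropy": _entropy(p.ravel()),
    }


def glrlm_features(matrices: dict[int, RunLengthMatrix]) -> dict[str, float]:
    """Four GLRLM features, per angle then averaged."""
    per_angle = [_glrlm_angle_features(m) for m in matrices.values() if m.n_r > 0]
    if not per_angle:
        raise ValueError("GLRLM degenerate: no runs in any direction")
    return {k: float(np.mean([f[k] for f in per_angle])) for k in GLRLM_NAMES}


def glszm_features(m: SizeZoneMatrix) -> dict[str, float]:
    """Five GLSZM features."""
    if m.n_z < 1:
        raise ValueError("GLSZM degenerate: no zones")
    p = m.p()
    n_g, max_j = p.shape
    i = np.arange(1, n_g + 1)
    j = np.arange(1, max_j + 1)
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float(pi @ i)
    mu_j = float(pj @ j)
    row_sums = m.counts.sum(axis=1).astype(float)
    col_sums = m.counts.sum(axis=0).astype(float)
    return {
        "GrayLevelNonUniformity": float(np.sum(row_sums**2) / m.n_z),
        "SizeZoneNonUniformity": float(np.sum(col_sums**2) / m.n_z),
        "GrayLevelVariance": float(pi @ (i - mu_i) ** 2),
        "ZoneVariance": float(pj @ (j - mu_j) ** 2),
        "ZoneEntropy": _entropy(p.ravel()),
    }


def gldm_features(m: DependenceMatrix) -> dict[str, float]:
    """Five GLDM features; dependence columns are raw neighbour counts d >= 0."""
    if m.counts.sum() < 1:
        raise ValueError("GLDM degenerate: empty ROI")
    p = m.p()
    n_g, n_cols = p.shape
    i = np.arange(1, n_g + 1)
    d = np.arange(0, n_cols)
    pi = p.sum(axis=1)
    pd_ = p.sum(axis=0)
    mu_i = float(pi @ i)
    mu_d = float(pd_ @ d)
    row_sums = m.counts.sum(axis=1).astype(float)
    col_sums = m.counts.sum(axis=0).astype(float)
    total = float(m.counts.sum())
    return {
        "GrayLevelNonUniformity": float(np.sum(row_sums**2) / total),
        "DependenceNonUniformity": float(np.sum(col_sums**2) / total),
        "GrayLevelVariance": float(pi @ (i - mu_i) ** 2),
        "DependenceVariance": float(pd_ @ (d - mu_d) ** 2),
        "DependenceEntropy": _entropy(p.ravel()),
    }


def frame_features(
    frame: np.ndarray, mask: np.ndarray, settings: FeatureSettings = FeatureSettings()
) -> dict[str, float]:
    """All 30 features of a single masked frame, keyed by prefixed name."""
    out: dict[str, float] = {}
    x = np.asarray(frame)[np.asarray(mask, dtype=bool)]
    for k, v in fos_features(x, c=settings.fos_shift).items():
        out[f"fos_{k}"] = v
    roi = quantize(frame, mask, settings.matrix_bin_width)
    glcm = build_glcm(
        roi, delta=settings.glcm_delta, angles=settings.glcm_angles,
        symmetric=settings.glcm_symmetric,
    )
    for k, v in glcm_features(glcm).items():
        out[f"glcm_{k}"] = v
    rlms = {a: build_glrlm(roi, a) for a in settings.glrlm_angles}
    for k, v in glrlm_features(rlms).items():
        out[f"glrlm_{k}"] = v
    for k, v in glszm_features(build_glszm(roi, settings.glszm_connectivity)).items():
        out[f"glszm_{k}"] = v
    gldm = build_gldm(roi, alpha=settings.gldm_alpha, delta=settings.gldm_delta)
    for k, v in gldm_features(gldm).items():
        out[f"gldm_{k}"] = v
    return out


def extract_feature_table(
    series: DropletSeries, settings: FeatureSettings = FeatureSettings()
) -> pd.DataFrame:
    """One row per frame: metadata columns plus the 30 texture features.

    Column order is fixed: droplet_id, label, t_norm, stage, then
    :data:`FEATURE_COLUMNS`.
    """
    rows = []
    for idx in range(series.n_frames):
        try:
            feats = frame_features(series.frames[idx], series.mask, settings)
        except ValueError as exc:
            raise ValueError(f"frame {idx}: {exc}") from exc
        rows.append(
            {
                "droplet_id": series.droplet_id,
                "label": series.label,
                "t_norm": float(series.times_norm[idx]),
                "stage": str(series.stages[idx]),
                **feats,
            }
        )
    return pd.DataFrame(rows, columns=list(META_COLUMNS) + list(FEATURE_COLUMNS))


def write_features_csv(table: pd.DataFrame, path) -> None:
    """Write a feature table with full float precision (17 significant
    digits) so reloaded tables reproduce downstream fits exactly."""
    table.to_csv(path, index=False, float_format="%.17g")
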