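"""K-means clustering and 2D principal-component separability of feature tables.

For each slice of the drying process the scaled 30-feature table is
clustered with k-means (k = 5 classes, best of 25 restarts by within-cluster
sum of squares) and projected onto its two leading principal components.
Class separability is summarised three ways:

* explained variance of the two leading components;
* an adjusted-for-chance agreement index (adjusted Rand) between cluster
  assignments and the true class labels;
* pairwise overlap of per-class concentration ellipses, measured as the
  Bhattacharyya coefficient exp(-D_B) between the 2D Gaussians fitted to
  each class's projected scatter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from .features import FEATURE_COLUMNS


def _feature_matrix(table: pd.DataFrame) -> np.ndarray:
    cols = [c for c in FEATURE_COLUMNS if c in table.columns]
    if not cols:
        cols = [c for c in table.columns if table[c].dtype.kind in "fc"]
    return table[cols].to_numpy(dtype=float)


@dataclass
class ClusterResult:
    """Best-of-restarts k-means outcome."""

    assignments: np.ndarray  # per-row cluster id, 1..k
    centers: np.ndarray  # (k, n_features)
    wcss: float
    restart_wcss: np.ndarray  # WCSS of every individual restart
    best_restart_index: int
    seed: int

    @property
    def k(self) -> int:
        return len(self.centers)


def kmeans_fit(
    table: pd.DataFrame | np.ndarray,
    k: int = 5,
    n_restarts: int = 25,
    seed: int = 0,
) -> ClusterResult:
    """Lloyd k-means from k-means++ starts, retaining the restart with the
    smallest within-cluster sum of squares.

    Each restart runs to its assignment fixpoint (or 300 iterations).  Rows
    must number at least ``k``.
    """
    X = _feature_matrix(table) if isinstance(table, pd.DataFrame) else np.asarray(table, float)
    if len(X) < k:
        raise ValueError(f"need at least k={k} rows, got {len(X)}")
    rng = np.random.default_rng(seed)
    restart_seeds = rng.integers(0, 2**31 - 1, size=n_restarts)
    best = None
    wcss_all = np.empty(n_restarts)
    for r, s in enumerate(restart_seeds):
        km = KMeans(n_clusters=k, n_init=1, init="k-means++", max_iter=300, random_state=int(s))
        km.fit(X)
        wcss_all[r] = km.inertia_
        if best is None or km.inertia_ < best[1].inertia_:
            best = (r, km)
    r_best, km_best = best
    return ClusterResult(
        assignments=km_best.labels_ + 1,
        centers=km_best.cluster_centers_,
        wcss=float(km_best.inertia_),
        restart_wcss=wcss_all,
        best_restart_index=r_best,
        seed=seed,
    )


@dataclass
class ProjectionSummary:
    """2D principal-component view of one slice plus separability metrics."""

    coordinates: np.ndarray  # (n, 2) scores
    explained_ratio: tuple[float, float]
    class_labels: list[str] = field(default_factory=list)
    class_means: dict[str, np.ndarray] = field(default_factory=dict)
    class_covs: dict[str, np.ndarray] = field(default_factory=dict)
    overlap: pd.DataFrame | None = None
    agreement: float | None = None

    @property
    def mean_offdiag_overlap(self) -> float:
        """Mean pairwise class overlap (excluding the diagonal)."""
        m = self.overlap.to_numpy()
        n = m.shape[0]
        return float((m.sum() - np.trace(m)) / (n * (n - 1)))


def project_2d(table: pd.DataFrame | np.ndarray) -> ProjectionSummary:
    """Scores and variance fractions of the two leading principal axes."""
    X = _feature_matrix(table) if isinstance(table, pd.DataFrame) else np.asarray(table, float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows for a 2D projection")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features for a 2D projection")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X)
    r1, r2 = (float(v) for v in pca.explained_variance_ratio_)
    return ProjectionSummary(coordinates=coords, explained_ratio=(r1, r2))


def _bhattacharyya_overlap(
    m1: np.ndarray, c1: np.ndarray, m2: np.ndarray, c2: np.ndarray
) -> float:
    """exp(-D_B) for two Gaussians; 1 when identical, -> 0 when far apart."""
    c = 0.5 * (c1 + c2)
    diff = m1 - m2
    sign, logdet_c = np.linalg.slogdet(c)
    _, logdet_1 = np.linalg.slogdet(c1)
    _, logdet_2 = np.linalg.slogdet(c2)
    d_b = 0.125 * diff @ np.linalg.solve(c, diff) + 0.5 * (
        logdet_c - 0.5 * (logdet_1 + logdet_2)
    )
    return float(np.exp(-d_b))


def class_overlap(
    coordinates: np.ndarray, labels: np.ndarray | list[str]
) -> tuple[pd.DataFrame, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-class 2D Gaussian fits and their pairwise Bhattacharyya overlap.

    Returns the symmetric overlap matrix (diagonal 1) plus the per-class
    means and covariances from which 95% concentration ellipses can be drawn.
    Singular class covariances get a 1e-8 ridge.
    """
    coords = np.asarray(coordinates, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    means: dict[str, np.ndarray] = {}
    covs: dict[str, np.ndarray] = {}
    for cl in classes:
        pts = coords[labels == cl]
        if len(pts) < 3:
            raise ValueError(f"class {cl!r} has fewer than 3 points")
        means[cl] = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False)
        if np.linalg.det(cov) <= 0:
            cov = cov + 1e-8 * np.eye(2)
        covs[cl] = cov
    n = len(classes)
    m = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            ov = _bhattacharyya_overlap(
                means[classes[a]], covs[classes[a]], means[classes[b]], covs[classes[b]]
            )
            m[a, b] = m[b, a] = min(max(ov, 0.0), 1.0)
    return pd.DataFrame(m, index=classes, columns=classes), means, covs


def ellipse_points(
    mean: np.ndarray, cov: np.ndarray, level: float = 0.95, n: int = 100
) -> np.ndarray:
    """Boundary of the ``level`` concentration ellipse, for plotting."""
    from scipy.stats import chi2

    r2 = chi2.ppf(level, df=2)
    vals, vecs = np.linalg.eigh(cov)
    t = np.linspace(0, 2 * np.pi, n)
    circle = np.stack([np.cos(t), np.sin(t)])
    return (vecs @ (np.sqrt(np.clip(vals, 0, None) * r2)[:, None] * circle)).T + mean


def agreement_index(assignments: np.ndarray, labels: np.ndarray | list[str]) -> float:
    """Adjusted-for-chance pair-counting agreement (adjusted Rand index)."""
    return float(adjusted_rand_score(np.asarray(labels), np.asarray(assignments)))


def summarize_slice(
    table: pd.DataFrame,
    k: int = 5,
    n_restarts: int = 25,
    seed: int = 0,
    scale: bool = True,
) -> tuple[ProjectionSummary, ClusterResult]:
    """Cluster + project one slice and attach all separability metrics.

    The slice is z-scored on its own rows first (``scale=False`` if the
    caller already scaled it); without scaling the extensive features such
    as Energy dominate every distance.
    """
    if scale:
        from .gam import scale_table

        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            table = scale_table(table)
    clus = kmeans_fit(table, k=k, n_restarts=n_restarts, seed=seed)
    proj = project_2d(table)
    labels = table["label"].to_numpy()
    overlap, means, covs = class_overlap(proj.coordinates, labels)
    proj.class_labels = sorted(set(labels.tolist()))
    proj.class_means = means
    proj.class_covs = covs
    proj.overlap = overlap
    proj.agreement = agreement_index(clus.assignments, labels)
    return proj, clus


def plot_clusters(
    proj: ProjectionSummary,
    labels,
    path,
    title: str | None = None,
) -> None:
    """Scatter of the 2D scores coloured by class, with 95% concentration
    ellipses, written to ``path`` (PNG/SVG by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(6, 5))
    for cl in sorted(set(labels.tolist())):
        pts = proj.coordinates[labels == cl]
        (line,) = ax.plot(pts[:, 0], pts[:, 1], ".", ms=4, label=str(cl))
        if cl in proj.class_means:
            ell = ellipse_points(proj.class_means[cl], proj.class_covs[cl])
            ax.plot(ell[:, 0], ell[:, 1], "-", lw=1, color=line.get_color())
    r1, r2 = proj.explained_ratio
    ax.set_xlabel(f"PC1 ({100 * r1:.0f}%)")
    ax.set_ylabel(f"PC2 ({100 * r2:.0f}%)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def stage_separability_report(
    tables: dict[str, pd.DataFrame],
    k: int = 5,
    n_restarts: int = 25,
    seed: int = 0,
) -> dict[str, dict]:
    """Per-slice clustering/projection summaries plus separability rankings.

    The report orders slices by mean off-diagonal overlap (ascending) and by
    agreement (descending); per-slice failures are recorded and the rest
    proceed.
    """
    summaries: dict[str, tuple[ProjectionSummary, ClusterResult]] = {}
    failures: dict[str, str] = {}
    for name, tbl in tables.items():
        try:
            summaries[name] = summarize_slice(tbl, k=k, n_restarts=n_restarts, seed=seed)
        except (ValueError, KeyError) as exc:
            failures[name] = str(exc)
    if not summaries:
        raise ValueError("no slice could be summarised")
    by_overlap = sorted(summaries, key=lambda s: summaries[s][0].mean_offdiag_overlap)
    by_agreement = sorted(summaries, key=lambda s: -summaries[s][0].agreement)
    return {
        "slices": summaries,
        "order_by_overlap": by_overlap,
        "order_by_agreement": by_agreement,
        "failures": failures,
    }
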