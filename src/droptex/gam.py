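"""Additive model of droplet class on smoothed texture features.

The droplet class (initial buffer concentration) is encoded as a numeric
response (0x -> 0 .. 1x -> 1) and regressed on a smooth function of each of
the 30 texture features:

    y ~ s(f_1) + s(f_2) + ... + s(f_30)

Each smooth is a fixed-degrees-of-freedom natural cubic spline with knots at
predictor quantiles; with the default ``smooth_df = 4`` each term carries 3
basis columns (one linear plus two curvature), so every term is tested on
3 degrees of freedom.  Per-term significance is a drop-one F test comparing
the residual deviance of the full Gaussian fit against the fit without that
term's columns.  AIC from the Gaussian log-likelihood compares how well the
same model explains different slices of the drying process (all frames, or
the initial / middle / final stage only); the slice with the lowest AIC is
the one in which texture most sharply determines the droplet class.

Usage follows the model/results pattern::

    model = TextureGAM.from_feature_table(table)
    res = model.fit()
    print(res.summary())
    comparison = compare_stages(slice_tables(table))
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_COLUMNS

DEFAULT_RESPONSE_ENCODING = {"0x": 0.0, "0.25x": 0.25, "0.5x": 0.5, "0.75x": 0.75, "1x": 1.0}

SLICES = ("all", "initial", "middle", "final")


@dataclass(frozen=True)
class AdditiveModelSpec:
    """Specification of the additive texture model.

    ``smooth_df`` is the nominal degrees of freedom of each smooth term; the
    per-term basis has ``smooth_df - 1`` columns (the shared intercept
    accounts for the remaining one).  ``smooth_df = 2`` therefore degenerates
    to ordinary multiple linear regression.
    """

    response_encoding: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESPONSE_ENCODING)
    )
    smooth_df: int = 4
    scale_predictors: bool = True
    features: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.smooth_df < 2:
            raise ValueError("smooth_df must be >= 2")
        enc = self.response_encoding
        if len(set(enc.values())) != len(enc):
            raise ValueError("response encoding must be injective")


def scale_table(table: pd.DataFrame, columns: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Z-score the feature columns (mean 0, sample sd 1).

    Constant columns are set to 0 with a warning so downstream fits never
    see NaNs.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 rows to scale")
    out = table.copy()
    cols = columns or [c for c in FEATURE_COLUMNS if c in table.columns]
    for c in cols:
        x = out[c].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            warnings.warn(f"constant feature column {c!r} scaled to zeros", stacklevel=2)
            out[c] = 0.0
        else:
            out[c] = (x - x.mean()) / sd
    return out


def natural_spline_basis(x: np.ndarray, df: int) -> np.ndarray:
    """Natural cubic spline basis of ``df - 1`` columns, knots at quantiles.

    Columns are the linear term plus ``df - 2`` curvature functions of the
    truncated-power natural-spline construction with ``df`` knots.  Degenerate
    predictors (too few distinct values for the requested knots) fall back to
    whatever columns the distinct values support, down to the bare linear
    column.
    """
    x = np.asarray(x, dtype=float)
    n_knots = df
    knots = np.unique(np.quantile(x, np.linspace(0, 1, n_knots)))
    cols = [x]
    k = len(knots)
    if k >= 3:
        xi_k = knots[-1]
        xi_km1 = knots[-2]

        def d(xi: float) -> np.ndarray:
            return (
                np.clip(x - xi, 0, None) ** 3 - np.clip(x - xi_k, 0, None) ** 3
            ) / (xi_k - xi)

        d_last = d(xi_km1)
        for xi in knots[:-2]:
            cols.append(d(xi) - d_last)
    return np.column_stack(cols)


@dataclass
class TermFit:
    """Drop-one test of one smooth term."""

    feature: str
    df: int
    f_statistic: float
    p_value: float


class TextureGAMResults:
    """Fitted additive texture model: deviances, per-term F tests and AIC."""

    def __init__(
        self,
        model: "TextureGAM",
        params: np.ndarray,
        per_term: list[TermFit],
        null_deviance: float,
        df_null: int,
        residual_deviance: float,
        df_resid: int,
        rank: int,
        n_obs: int,
    ) -> None:
        self.model = model
        self.params = params
        self.per_term = per_term
        self.null_deviance = null_deviance
        self.df_null = df_null
        self.residual_deviance = residual_deviance
        self.df_resid = df_resid
        self.rank = rank
        self.n_obs = n_obs

    @property
    def aic(self) -> float:
        """Gaussian AIC: -2 loglik + 2 * (number of mean parameters)."""
        n = self.n_obs
        sigma2 = max(self.residual_deviance / n, np.finfo(float).tiny)
        llf = -0.5 * n * (np.log(2 * np.pi) + np.log(sigma2) + 1.0)
        return float(-2.0 * llf + 2.0 * self.rank)

    @property
    def deviance_explained(self) -> float:
        return 1.0 - self.residual_deviance / self.null_deviance

    def terms_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"feature": t.feature, "df": t.df, "F": t.f_statistic, "p": t.p_value}
                for t in self.per_term
            ]
        )

    def summary(self) -> str:
        """Plain-text report mirroring the usual additive-model summary."""
        lines = [
            "Additive texture model (Gaussian, natural cubic spline terms)",
            f"n_obs = {self.n_obs}, terms = {len(self.per_term)}, rank = {self.rank}",
            f"Null deviance:     {self.null_deviance:.4f} on {self.df_null} df",
            f"Residual deviance: {self.residual_deviance:.4f} on {self.df_resid} df",
            f"AIC: {self.aic:.2f}",
            "",
            f"{'term':<34}{'Df':>4}{'F':>12}{'p':>12}",
        ]
        for t in self.per_term:
            p_str = f"{t.p_value:.5f}" if t.p_value >= 1e-5 else "<0.00001"
            lines.append(f"s({t.feature:<30}){t.df:>4}{t.f_statistic:>12.3f}{p_str:>12}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_obs": self.n_obs,
            "rank": self.rank,
            "null_deviance": self.null_deviance,
            "df_null": self.df_null,
            "residual_deviance": self.residual_deviance,
            "df_resid": self.df_resid,
            "aic": self.aic,
            "per_term": [
                {"feature": t.feature, "df": t.df, "F": t.f_statistic, "p": t.p_value}
                for t in self.per_term
            ],
        }


class TextureGAM:
    """Additive model of encoded droplet class on spline-expanded features.

    Parameters
    ----------
    endog : array-like
        Numeric response (encoded class).
    exog : pd.DataFrame
        Feature columns (already scaled if desired).
    spec : AdditiveModelSpec
        Basis and encoding settings.
    """

    def __init__(self, endog, exog: pd.DataFrame, spec: AdditiveModelSpec | None = None):
        self.spec = spec or AdditiveModelSpec()
        self.endog = np.asarray(endog, dtype=float)
        self.exog = exog
        self.feature_names = list(exog.columns)
        if len(self.endog) != len(exog):
            raise ValueError("endog and exog lengths differ")
        self._build_design()

    @classmethod
    def from_feature_table(
        cls, table: pd.DataFrame, spec: AdditiveModelSpec | None = None
    ) -> "TextureGAM":
        """Build the model from a feature table with a ``label`` column."""
        spec = spec or AdditiveModelSpec()
        enc = spec.response_encoding
        unknown = set(table["label"]) - set(enc)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} missing from response encoding")
        y = table["label"].map(enc).to_numpy(dtype=float)
        feats = list(spec.features) if spec.features else [
            c for c in FEATURE_COLUMNS if c in table.columns
        ]
        X = table[feats]
        if spec.scale_predictors:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                X = scale_table(X, tuple(feats))
        return cls(y, X, spec)

    def _build_design(self) -> None:
        n = len(self.endog)
        blocks: list[np.ndarray] = []
        self.term_slices: dict[str, slice] = {}
        start = 1  # column 0 is the intercept
        for name in self.feature_names:
            b = natural_spline_basis(self.exog[name].to_numpy(dtype=float), self.spec.smooth_df)
            blocks.append(b)
            self.term_slices[name] = slice(start, start + b.shape[1])
            start += b.shape[1]
        self.design = np.column_stack([np.ones(n)] + blocks)
        if n <= self.design.shape[1]:
            raise ValueError(
                f"n_obs = {n} must exceed the total basis dimension "
                f"{self.design.shape[1]}"
            )

    @staticmethod
    def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int, np.ndarray]:
        """Least-squares residual sum of squares, rank, coefficients."""
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid), int(rank), beta

    def fit(self) -> TextureGAMResults:
        """Fit by least squares; per-term F from drop-one deviance comparison."""
        y = self.endog
        n = len(y)
        X = self.design
        rss_full, rank_full, beta = self._rss(X, y)
        if rank_full < X.shape[1]:
            warnings.warn(
                f"design is rank deficient ({rank_full} < {X.shape[1]}); "
                "collinear basis columns are implicitly dropped",
                stacklevel=2,
            )
        df_resid = n - rank_full
        null_dev = float(np.sum((y - y.mean()) ** 2))
        per_term: list[TermFit] = []
        scale = rss_full / df_resid if df_resid > 0 else np.nan
        for name in self.feature_names:
            sl = self.term_slices[name]
            keep = np.ones(X.shape[1], dtype=bool)
            keep[sl] = False
            rss_red, rank_red, _ = self._rss(X[:, keep], y)
            df_term = rank_full - rank_red
            if df_term <= 0 or not np.isfinite(scale) or scale <= 0:
                per_term.append(TermFit(name, max(df_term, 0), np.nan, np.nan))
                continue
            f_stat = ((rss_red - rss_full) / df_term) / scale
            f_stat = max(f_stat, 0.0)
            p = float(stats.f.sf(f_stat, df_term, df_resid))
            per_term.append(TermFit(name, df_term, float(f_stat), p))
        return TextureGAMResults(
            model=self,
            params=beta,
            per_term=per_term,
            null_deviance=null_dev,
            df_null=n - 1,
            residual_deviance=rss_full,
            df_resid=df_resid,
            rank=rank_full,
            n_obs=n,
        )


def fit_additive_model(
    table: pd.DataFrame, spec: AdditiveModelSpec | None = None
) -> TextureGAMResults:
    """Convenience wrapper: build and fit in one call."""
    return TextureGAM.from_feature_table(table, spec).fit()


def slice_tables(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """The four analysis slices: all rows plus one table per drying stage."""
    out = {"all": table}
    for stage in ("initial", "middle", "final"):
        out[stage] = table[table["stage"] == stage].reset_index(drop=True)
    return out


@dataclass
class StageComparison:
    """AIC comparison of the additive model across drying-process slices."""

    aic_by_slice: dict[str, float]
    best_slice: str
    fits: dict[str, TextureGAMResults]
    failures: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "aic_by_slice": self.aic_by_slice,
            "best_slice": self.best_slice,
            "failures": self.failures,
        }


def compare_stages(
    tables: dict[str, pd.DataFrame], spec: AdditiveModelSpec | None = None
) -> StageComparison:
    """Fit the additive model independently on each slice and rank by AIC.

    Each slice is scaled on its own rows.  Unfittable slices are reported
    and the comparison proceeds over the remainder.
    """
    fits: dict[str, TextureGAMResults] = {}
    failures: dict[str, str] = {}
    for name, tbl in tables.items():
        try:
            fits[name] = fit_additive_model(tbl, spec)
        except (ValueError, KeyError) as exc:
            warnings.warn(f"slice {name!r} unfittable: {exc}", stacklevel=2)
            failures[name] = str(exc)
    if not fits:
        raise ValueError("no slice could be fitted")
    aic = {name: res.aic for name, res in fits.items()}
    best = min(aic, key=aic.get)
    return StageComparison(aic_by_slice=aic, best_slice=best, fits=fits, failures=failures)
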