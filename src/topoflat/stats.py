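"""Statistical layer: flatmap clustering and topography regressions.

Clustering follows the map-comparison recipe: each normalized flatmap is
smoothed with a 5x5 Gaussian kernel (sigma 1.5 bins), pairwise Pearson
correlations between flatmaps are computed over the in-region bins, and the
rows of the correlation matrix are k-means clustered; the number of clusters
is read off the within- to between-cluster variance-ratio elbow.

Topography is quantified by multiple linear regression of each center-of-mass
coordinate on the normalized injection coordinates (rc, dv) and age in days.
A model with the three main effects and all two-way interactions is fitted by
least squares; the non-significant interaction with the smallest standardized
beta is removed and the model refitted, repeating until only main effects and
significant interactions remain. Coefficients are reported unstandardized
with 95% confidence intervals; collinearity is checked by pairwise predictor
correlations (|r| < 0.70) and variance inflation factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cluster import KMeans

from .labels import FIELDS, ExperimentLabelMap

MAIN_PREDICTORS = ("rc", "dv", "age")
INTERACTIONS = (("rc", "dv"), ("rc", "age"), ("dv", "age"))


# ---------------------------------------------------------------------------
# flatmap smoothing and correlation
# ---------------------------------------------------------------------------

def gaussian_kernel(size: int = 5, sigma: float = 1.5) -> np.ndarray:
    """Square 2D Gaussian kernel, normalized to sum 1."""
    r = (size - 1) / 2
    ax = np.arange(size) - r
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
    return k / k.sum()


def smooth_grid(
    values: np.ndarray, mask: np.ndarray, size: int = 5, sigma: float = 1.5
) -> np.ndarray:
    """Normalized convolution of a masked grid with a Gaussian kernel.

    At every bin the kernel is renormalized over the in-region support, so
    out-of-region bins contribute nothing and a constant map stays constant.
    """
    from scipy.ndimage import convolve

    k = gaussian_kernel(size, sigma)
    m = mask.astype(float)
    num = convolve(values * m, k, mode="constant", cval=0.0)
    den = convolve(m, k, mode="constant", cval=0.0)
    out = np.zeros_like(values, dtype=float)
    valid = mask & (den > 0)
    out[valid] = num[valid] / den[valid]
    return out


def smooth_flatmap(
    label_map: ExperimentLabelMap, size: int = 5, sigma: float = 1.5
) -> ExperimentLabelMap:
    """Gaussian-smooth every subdivision grid of a flatmap."""
    out = label_map.copy()
    for sub, spec in out.specs.items():
        mask = spec.mask()
        dense = smooth_grid(out.dense(sub), mask, size, sigma)
        out.grids[sub] = [dense[i, : c] for i, c in enumerate(spec.bin_counts)]
    return out


def _vectorize(label_map: ExperimentLabelMap) -> np.ndarray:
    return np.concatenate(
        [row for sub in sorted(label_map.grids) for row in label_map.grids[sub]]
    )


def flatmap_correlations(maps: list[ExperimentLabelMap]) -> pd.DataFrame:
    """Pairwise Pearson correlations over the vectorized in-region bins."""
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    vecs = np.vstack([_vectorize(m) for m in maps])
    sd = vecs.std(axis=1)
    bad = [maps[i].experiment_id for i in np.nonzero(sd == 0)[0]]
    if bad:
        raise ValueError(
            "zero-variance flatmap(s), correlation undefined: " + ", ".join(bad)
        )
    corr = np.corrcoef(vecs)
    ids = [m.experiment_id for m in maps]
    return pd.DataFrame(corr, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """K-means clustering of the flatmap correlation matrix."""

    chosen_k: int
    labels: np.ndarray  # 1-based cluster labels
    ratio_curve: dict[int, float]  # k -> SSW/SSB
    corr: pd.DataFrame
    degenerate: bool = False
    labels_by_k: dict[int, np.ndarray] = field(default_factory=dict)


def cluster_experiments(
    corr: pd.DataFrame,
    k_range=range(2, 8),
    n_restarts: int = 50,
    seed: int = 0,
    elbow_threshold: float = 0.1,
    k_override: int | None = None,
) -> ClusterResult:
    """Cluster experiments by k-means on correlation-matrix rows.

    For each candidate k the within- to between-cluster variance ratio
    (SSW/SSB) is recorded; the chosen k is the smallest where adding one more
    cluster no longer decreases the ratio substantially — by less than
    ``elbow_threshold`` of the curve's initial value (normalizing by the
    curve scale keeps the criterion meaningful once the ratio is near zero).
    The elbow choice is heuristic and can be overridden with ``k_override``.
    """
    X = corr.to_numpy(dtype=float)
    n = X.shape[0]
    ks = [k for k in k_range]
    if any(k >= n for k in ks):
        raise ValueError("k must be smaller than the number of experiments")
    total_ss = float(((X - X.mean(axis=0)) ** 2).sum())
    if total_ss == 0:
        return ClusterResult(
            chosen_k=1,
            labels=np.ones(n, dtype=int),
            ratio_curve={},
            corr=corr,
            degenerate=True,
        )

    ratio_curve: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        lab = km.fit_predict(X)
        ssw = float(km.inertia_)
        ssb = total_ss - ssw
        ratio_curve[k] = ssw / ssb if ssb > 0 else np.inf
        labels_by_k[k] = lab + 1

    if k_override is not None:
        chosen = int(k_override)
        if chosen not in labels_by_k:
            raise ValueError("k_override outside k_range")
    else:
        chosen = ks[-1]
        scale = ratio_curve[ks[0]]
        for a, b in zip(ks[:-1], ks[1:]):
            ra, rb = ratio_curve[a], ratio_curve[b]
            if ra <= 0 or scale <= 0:
                chosen = a
                break
            if (ra - rb) / scale < elbow_threshold:
                chosen = a
                break
    return ClusterResult(
        chosen_k=chosen,
        labels=labels_by_k[chosen],
        ratio_curve=ratio_curve,
        corr=corr,
        labels_by_k=labels_by_k,
    )


class FlatmapKMeans(BaseEstimator):
    """Estimator form of the flatmap cluster analysis.

    Smooths each map (5x5 Gaussian, sigma 1.5 by default), correlates all
    pairs and k-means clusters the correlation matrix rows.

    Attributes
    ----------
    labels_ : 1-based cluster labels per experiment
    chosen_k_ : elbow-selected number of clusters
    ratio_curve_ : dict k -> SSW/SSB
    corr_ : correlation matrix used
    """

    def __init__(
        self,
        k_range=range(2, 8),
        n_restarts: int = 50,
        random_state: int = 0,
        elbow_threshold: float = 0.1,
        smoothing_size: int = 5,
        smoothing_sigma: float = 1.5,
        k_override: int | None = None,
    ):
        self.k_range = k_range
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.elbow_threshold = elbow_threshold
        self.smoothing_size = smoothing_size
        self.smoothing_sigma = smoothing_sigma
        self.k_override = k_override

    def fit(self, X, y=None):
        """Fit from a list of normalized ExperimentLabelMaps."""
        smoothed = [
            smooth_flatmap(m, self.smoothing_size, self.smoothing_sigma) for m in X
        ]
        self.corr_ = flatmap_correlations(smoothed)
        res = cluster_experiments(
            self.corr_,
            k_range=self.k_range,
            n_restarts=self.n_restarts,
            seed=self.random_state,
            elbow_threshold=self.elbow_threshold,
            k_override=self.k_override,
        )
        self.result_ = res
        self.labels_ = res.labels
        self.chosen_k_ = res.chosen_k
        self.ratio_curve_ = res.ratio_curve
        return self


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    """A fitted topography regression after backward elimination."""

    outcome: str
    n: int
    df_resid: int
    params: pd.DataFrame  # index: term; columns: beta, se, ci_low, ci_high,
    #                                t, p, std_beta
    trace: list[dict]  # one entry per eliminated interaction
    predictors: list[str]
    design: pd.DataFrame = field(repr=False)
    y: np.ndarray = field(repr=False)

    @property
    def terms(self) -> list[str]:
        return [t for t in self.params.index if t != "const"]


def _interaction_name(a: str, b: str) -> str:
    return f"{a}:{b}"


def _build_design(df: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            X[t] = df[a] * df[b]
        else:
            X[t] = df[t]
    return sm.add_constant(X, has_constant="add")


def _check_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # name the aliased columns via the null space of the design
        _, s, vt = np.linalg.svd(A, full_matrices=False)
        null = vt[s < s.max() * 1e-10 * max(A.shape)]
        aliased = sorted(
            {X.columns[j] for row in null for j in np.nonzero(np.abs(row) > 1e-8)[0]}
        )
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")


def _fit_ols(X: pd.DataFrame, y: np.ndarray):
    return sm.OLS(y, X).fit()


def _summarize(res, X: pd.DataFrame, y: np.ndarray) -> pd.DataFrame:
    ci = res.conf_int(alpha=0.05)
    sd_y = np.std(y, ddof=1)
    rows = {}
    for term in X.columns:
        sd_x = np.std(X[term].to_numpy(), ddof=1)
        rows[term] = {
            "beta": res.params[term],
            "se": res.bse[term],
            "ci_low": ci.loc[term, 0],
            "ci_high": ci.loc[term, 1],
            "t": res.tvalues[term],
            "p": res.pvalues[term],
            "std_beta": (
                res.params[term] * sd_x / sd_y if term != "const" else np.nan
            ),
        }
    return pd.DataFrame(rows).T


def backward_eliminate(
    df: pd.DataFrame,
    y: np.ndarray,
    main: list[str],
    interactions: list[tuple[str, str]],
    alpha: float = 0.05,
    outcome: str = "y",
) -> RegressionResult:
    """Backward elimination of two-way interactions from a least-squares fit.

    Starting from main effects plus all listed interactions, the interaction
    with the smallest absolute standardized beta among those not significant
    (two-sided t-test, p >= alpha) is removed and the model refitted, until
    every remaining interaction is significant or none remain. Main effects
    are never removed.
    """
    terms = list(main) + [_interaction_name(a, b) for a, b in interactions]
    trace: list[dict] = []
    while True:
        X = _build_design(df, terms)
        _check_rank(X)
        res = _fit_ols(X, y)
        table = _summarize(res, X, y)
        inter_terms = [t for t in terms if ":" in t]
        candidates = [t for t in inter_terms if table.loc[t, "p"] >= alpha]
        if not candidates:
            break
        drop = min(candidates, key=lambda t: abs(table.loc[t, "std_beta"]))
        trace.append(
            {
                "step": len(trace) + 1,
                "dropped": drop,
                "p": float(table.loc[drop, "p"]),
                "std_beta": float(table.loc[drop, "std_beta"]),
            }
        )
        terms.remove(drop)
    return RegressionResult(
        outcome=outcome,
        n=len(y),
        df_resid=int(res.df_resid),
        params=table,
        trace=trace,
        predictors=terms,
        design=X,
        y=np.asarray(y, dtype=float),
    )


class TopographyRegression(BaseEstimator, RegressorMixin):
    """Center-of-mass topography regression with interaction elimination.

    Regresses a center-of-mass coordinate on the normalized injection
    coordinates and age: ``y ~ rc + dv + age + rc:dv + rc:age + dv:age``,
    backward-eliminating non-significant interactions.

    Parameters
    ----------
    alpha : float
        Two-sided significance level for retaining an interaction.
    age_max : float or None
        Experiments in animals older than this (days) are excluded before
        fitting (the study design leaves an age gap above this point).
    dichotomize_at : float or None
        If set, age is replaced by the indicator ``age >= dichotomize_at``
        (age-group check, e.g. younger vs older than one week).

    Attributes
    ----------
    result_ : RegressionResult
    """

    def __init__(
        self,
        alpha: float = 0.05,
        age_max: float | None = 19,
        dichotomize_at: float | None = None,
        min_rows: int = 10,
        outcome_name: str = "y",
    ):
        self.alpha = alpha
        self.age_max = age_max
        self.dichotomize_at = dichotomize_at
        self.min_rows = min_rows
        self.outcome_name = outcome_name

    def _prepare(self, X: pd.DataFrame, y) -> tuple[pd.DataFrame, np.ndarray]:
        df = X[["rc", "dv", "age"]].copy()
        yv = np.asarray(y, dtype=float)
        keep = ~np.isnan(yv)
        if self.age_max is not None:
            keep &= df["age"].to_numpy() <= self.age_max
        df = df.loc[keep].reset_index(drop=True)
        yv = yv[keep]
        if self.dichotomize_at is not None:
            ind = (df["age"] >= self.dichotomize_at).astype(float)
            if ind.nunique() < 2:
                raise ValueError(
                    "age dichotomization leaves one group empty "
                    f"(cut at {self.dichotomize_at})"
                )
            df["age"] = ind
        if len(df) < self.min_rows:
            raise ValueError(
                f"too few rows with a defined outcome ({len(df)} < {self.min_rows})"
            )
        return df, yv

    def fit(self, X: pd.DataFrame, y):
        df, yv = self._prepare(X, y)
        self.result_ = backward_eliminate(
            df,
            yv,
            main=list(MAIN_PREDICTORS),
            interactions=list(INTERACTIONS),
            alpha=self.alpha,
            outcome=self.outcome_name,
        )
        self.n_excluded_ = len(X) - len(df)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "result_"):
            raise RuntimeError("TopographyRegression is not fitted")
        df = X[["rc", "dv", "age"]].copy()
        if self.dichotomize_at is not None:
            df["age"] = (df["age"] >= self.dichotomize_at).astype(float)
        Xd = _build_design(df, self.result_.predictors)
        beta = self.result_.params["beta"].reindex(Xd.columns)
        return Xd.to_numpy() @ beta.to_numpy()


def fit_topography(
    com_table: pd.DataFrame,
    outcome: str,
    alpha: float = 0.05,
    age_max: float | None = 19,
) -> RegressionResult:
    """Fit one topography regression from a center-of-mass table.

    ``com_table`` needs columns rc, dv, age and the outcome column (e.g.
    ``"PrS_LI_III:dv"``); rows with an undefined outcome (experiments without
    labeling in the field) or age above ``age_max`` are excluded.
    """
    est = TopographyRegression(alpha=alpha, age_max=age_max, outcome_name=outcome)
    est.fit(com_table, com_table[outcome])
    return est.result_


def fit_age_dichotomized(
    com_table: pd.DataFrame,
    outcome: str,
    cut: float = 7,
    alpha: float = 0.05,
    age_max: float | None = 19,
) -> RegressionResult:
    """As :func:`fit_topography` with age replaced by ``age >= cut``."""
    est = TopographyRegression(
        alpha=alpha, age_max=age_max, dichotomize_at=cut, outcome_name=outcome
    )
    est.fit(com_table, com_table[outcome])
    return est.result_


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticsReport:
    """Collinearity and residual diagnostics for a fitted regression."""

    predictor_corr: pd.DataFrame
    collinearity_ok: bool
    vif: pd.Series
    std_residuals: np.ndarray
    std_predictions: np.ndarray
    residual_hist: tuple[np.ndarray, np.ndarray]
    qq: pd.DataFrame  # theoretical vs sample quantiles


def regression_diagnostics(
    result: RegressionResult, corr_limit: float = 0.70
) -> DiagnosticsReport:
    """Collinearity (pairwise r, VIF) and residual diagnostics.

    VIF of each retained term is 1/(1-R^2) from an auxiliary regression of
    that term on the other terms; pairwise Pearson correlations among the
    main predictors are flagged when |r| >= ``corr_limit``. A perfectly
    collinear term yields an infinite VIF.
    """
    X = result.design
    main_cols = [c for c in X.columns if c in MAIN_PREDICTORS]
    pred_corr = X[main_cols].corr()
    off = pred_corr.to_numpy()[~np.eye(len(main_cols), dtype=bool)]
    ok = bool(np.all(np.abs(off) < corr_limit))

    vif = {}
    terms = [c for c in X.columns if c != "const"]
    for t in terms:
        others = [c for c in X.columns if c != t]
        aux = sm.OLS(X[t].to_numpy(), X[others].to_numpy()).fit()
        r2 = min(aux.rsquared, 1.0)
        vif[t] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    vif = pd.Series(vif, name="VIF")

    beta = result.params["beta"].reindex(X.columns).to_numpy()
    fitted = X.to_numpy() @ beta
    resid = result.y - fitted

    def _standardize(v):
        s = v.std(ddof=1)
        return (v - v.mean()) / s if s > 0 else np.zeros_like(v)

    std_res = _standardize(resid)
    std_pred = _standardize(fitted)
    hist = np.histogram(std_res, bins=10)
    order = np.sort(std_res)
    theo = sps.norm.ppf((np.arange(len(order)) + 0.5) / len(order))
    qq = pd.DataFrame({"theoretical": theo, "sample": order})
    return DiagnosticsReport(
        predictor_corr=pred_corr,
        collinearity_ok=ok,
        vif=vif,
        std_residuals=std_res,
        std_predictions=std_pred,
        residual_hist=hist,
        qq=qq,
    )
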