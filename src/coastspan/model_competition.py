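"""All-subsets OLS competition with AICc, Akaike weights and RVI.

The response (total non-native range, km) is regressed on every subset of
the candidate predictors, including the null (intercept-only) model. Models
are ranked by the small-sample-corrected Akaike criterion

    AICc = n ln(RSS/n) + 2p + 2p(p+1)/(n - p - 1),   p = k + 2,

where k is the number of slope coefficients (intercept and error variance
are counted in p) and the Gaussian log-likelihood constant n ln(2*pi) + n is
omitted — differences, weights and RVI are invariant to that convention, but
absolute AICc values are only comparable within one convention.

Akaike weights w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2) quantify
relative model support. Relative variable importance (RVI) is the sum of
weights over models containing a variable, computed on the best 40 models
with weights renormalized within that subset.

Predictors and response are z-scored (sample SD) before fitting, so the
reported coefficients are standardized betas, comparable across variables
including 0/1-coded categorical traits.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

DEFAULT_R_CLUSTER = 0.9
DEFAULT_R_REP = 0.7
DEFAULT_TOP_K = 40
#: spring values are forced cluster representatives: spring is the spawning
#: peak for broadcast-spawning invertebrates, when currents and temperature
#: most influence larval transport
DEFAULT_FORCED = frozenset({"current_speed_spring_mean", "temperature_spring_mean"})


# ---------------------------------------------------------------------------
# covariate pruning


@dataclass
class PruneReport:
    selected: list[str]
    clusters: list[dict]
    dropped_constant: list[str]
    r_cluster: float
    r_rep: float


def correlation_prune(
    candidates: pd.DataFrame,
    r_cluster: float = DEFAULT_R_CLUSTER,
    r_rep: float = DEFAULT_R_REP,
    forced: frozenset = DEFAULT_FORCED,
) -> PruneReport:
    """Collapse clusters of highly correlated candidates to representatives.

    Connected components of the |Pearson r| > ``r_cluster`` graph define
    clusters; each cluster then absorbs any variable correlated above
    ``r_rep`` with one of its members (overlapping clusters merge). One
    representative survives per cluster: a forced variable if the cluster
    contains one, otherwise the member with the highest mean |r| to the rest
    of its cluster. Constant columns are excluded up front (their correlation
    is undefined).
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 rows to compute correlations")
    cols = list(candidates.columns)
    sd = candidates.std(ddof=1)
    dropped_constant = [c for c in cols if not np.isfinite(sd[c]) or sd[c] == 0.0]
    if dropped_constant:
        warnings.warn(f"constant columns excluded from pruning: {dropped_constant}")
    cols = [c for c in cols if c not in dropped_constant]
    corr = candidates[cols].corr().abs()

    # components at the tight threshold
    parent = {c: c for c in cols}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for a, b in itertools.combinations(cols, 2):
        if corr.loc[a, b] > r_cluster:
            union(a, b)
    # absorb moderately correlated variables into existing clusters
    clustered = {c for c in cols if any(
        corr.loc[c, d] > r_cluster for d in cols if d != c)}
    for a in cols:
        if a in clustered:
            continue
        for b in sorted(clustered):
            if corr.loc[a, b] > r_rep:
                union(a, b)
                break

    groups: dict[str, list[str]] = {}
    for c in cols:
        groups.setdefault(find(c), []).append(c)

    selected: list[str] = []
    clusters: list[dict] = []
    for members in sorted(groups.values(), key=lambda m: m[0]):
        if len(members) == 1:
            selected.append(members[0])
            continue
        forced_here = sorted(set(members) & set(forced))
        if forced_here:
            reps = forced_here
        else:
            mean_r = {
                m: corr.loc[m, [x for x in members if x != m]].mean()
                for m in members
            }
            best = max(mean_r.values())
            reps = [sorted(m for m, v in mean_r.items() if v >= best - 1e-12)[0]]
        selected.extend(reps)
        clusters.append({"members": sorted(members), "representatives": reps})
    return PruneReport(sorted(selected), clusters, dropped_constant,
                       r_cluster, r_rep)


# ---------------------------------------------------------------------------
# standardization and OLS


def standardize(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score every column (sample SD); returns (z, scales).

    ``scales`` has one row per column with its mean and SD, for
    back-transformation of standardized coefficients.
    """
    means = df.mean()
    sds = df.std(ddof=1)
    zero = [c for c in df.columns if sds[c] == 0.0 or not np.isfinite(sds[c])]
    if zero:
        raise ValueError(f"zero-variance column(s): {zero}")
    z = (df - means) / sds
    scales = pd.DataFrame({"mean": means, "sd": sds})
    return z, scales


@dataclass
class OLSFit:
    variables: tuple[str, ...]
    params: dict[str, float]  # includes "intercept"
    rss: float
    tss: float
    r2: float
    pvalues: dict[str, float]
    n: int
    k: int


def fit_ols(y, X: pd.DataFrame | None = None) -> OLSFit:
    """Ordinary least squares through statsmodels (QR/pinv based).

    ``X`` columns are the predictors (an intercept is always added); ``X``
    of None or zero columns fits the intercept-only model. Raises on
    rank-deficient designs, naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if X is None or X.shape[1] == 0:
        names: list[str] = []
        design = np.ones((n, 1))
    else:
        names = list(X.columns)
        design = np.column_stack([np.ones(n), np.asarray(X, dtype=float)])
    k = len(names)
    if n <= k + 2:
        raise ValueError(f"n={n} too small for k={k} predictors")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        _, r = np.linalg.qr(design)
        bad = [names[i - 1] for i in range(1, design.shape[1])
               if abs(r[i, i]) < 1e-8 * abs(r[0, 0])]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    res = sm.OLS(y, design).fit()
    params = {"intercept": float(res.params[0])}
    pvalues = {"intercept": float(res.pvalues[0])}
    for i, name in enumerate(names, start=1):
        params[name] = float(res.params[i])
        pvalues[name] = float(res.pvalues[i])
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = float(res.ssr)
    r2 = 0.0 if tss == 0.0 else 1.0 - rss / tss
    return OLSFit(tuple(names), params, rss, tss, r2, pvalues, n, k)


def simple_regression(x, y) -> dict[str, float]:
    """Raw-scale single-predictor regression: slope, intercept, R², p."""
    X = pd.DataFrame({"x": np.asarray(x, dtype=float)})
    fit = fit_ols(y, X)
    return {
        "slope": fit.params["x"],
        "intercept": fit.params["intercept"],
        "r2": fit.r2,
        "p": fit.pvalues["x"],
        "n": fit.n,
    }


# ---------------------------------------------------------------------------
# information criteria


def aicc(rss: float, n: int, k: int) -> float:
    """Small-sample corrected AIC of a Gaussian OLS fit.

    ``k`` counts slope coefficients; p = k + 2 adds the intercept and error
    variance. The additive constant n ln(2*pi) + n is omitted.
    """
    p = k + 2
    if n <= p + 1:
        raise ValueError("insufficient sample for correction (n <= p + 1)")
    if rss <= 0.0:
        raise ValueError("RSS must be positive (exact fits have no finite AICc)")
    aic = n * np.log(rss / n) + 2.0 * p
    return float(aic + 2.0 * p * (p + 1) / (n - p - 1))


def akaike_weights(values) -> np.ndarray:
    """exp(-Delta/2) weights, normalized to sum to 1 over the compared set."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one model")
    delta = v - v.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


# ---------------------------------------------------------------------------
# the competition


@dataclass
class ModelFit:
    variables: tuple[str, ...]
    betas: dict[str, float]
    pvalues: dict[str, float]
    r2: float
    rss: float
    k: int
    aicc: float
    delta: float = np.nan
    weight: float = np.nan


@dataclass
class CompetitionResult:
    fits: list[ModelFit]  # sorted by AICc ascending
    predictors: list[str]
    n: int
    top_k: int
    rvi: dict[str, float]
    residual_diagnostics: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, f in enumerate(self.fits, start=1):
            row = {
                "rank": rank,
                "n_variables": f.k,
                "variables": "+".join(f.variables) if f.variables else "(null)",
                "r2": f.r2,
                "aicc": f.aicc,
                "delta_aicc": f.delta,
                "weight": f.weight,
            }
            for v in self.predictors:
                row[f"beta_{v}"] = f.betas.get(v, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)

    def table1(self, max_size: int = 7, per_size: int = 4,
               renormalize: bool = True) -> pd.DataFrame:
        """Summary in the style of a model-selection table: the best
        ``per_size`` models for each size up to ``max_size`` variables, plus
        the null model, with weights renormalized across the shown set."""
        chosen: list[ModelFit] = []
        for size in range(1, max_size + 1):
            of_size = [f for f in self.fits if f.k == size]
            chosen.extend(of_size[:per_size])
        null = [f for f in self.fits if f.k == 0]
        chosen.extend(null)
        chosen.sort(key=lambda f: f.aicc)
        w = akaike_weights([f.aicc for f in chosen]) if renormalize else np.array(
            [f.weight for f in chosen])
        rows = []
        for f, wi in zip(chosen, w):
            row = {
                "variables": "+".join(f.variables) if f.variables else "(null)",
                "n_variables": f.k,
                "r2": f.r2,
                "aicc": f.aicc,
                "delta_aicc": f.delta,
                "weight": float(wi),
            }
            for v in self.predictors:
                beta = f.betas.get(v, np.nan)
                row[f"beta_{v}"] = beta
                row[f"sig_{v}"] = (
                    bool(f.pvalues.get(v, 1.0) < 0.05) if v in f.betas else False
                )
            rows.append(row)
        return pd.DataFrame(rows)


def rvi(
    fits: list[ModelFit],
    variable: str,
    top_k: int = DEFAULT_TOP_K,
    renormalize: bool = True,
) -> float:
    """Relative variable importance over the ``top_k`` lowest-AICc models.

    Weights are (by default) recomputed within the top-k subset so they sum
    to 1 there; AICc ties at the boundary widen the subset.
    """
    ranked = sorted(fits, key=lambda f: f.aicc)
    if top_k > len(ranked):
        warnings.warn(
            f"top_k={top_k} exceeds the {len(ranked)} fitted models; using all"
        )
        top = ranked
    else:
        cutoff = ranked[top_k - 1].aicc
        top = [f for f in ranked if f.aicc <= cutoff + 1e-12]
    if renormalize:
        w = akaike_weights([f.aicc for f in top])
    else:
        w = np.array([f.weight for f in top])
    return float(sum(wi for f, wi in zip(top, w) if variable in f.variables))


def run_competition(
    table: pd.DataFrame,
    response: str,
    predictors: list[str],
    top_k: int = DEFAULT_TOP_K,
    max_predictors: int = 20,
    allow_large: bool = False,
) -> CompetitionResult:
    """Fit all 2^V predictor subsets (V predictors + the null model).

    ``table`` must be complete cases. Response and predictors are z-scored,
    so coefficients are standardized betas. Models are ranked by AICc;
    Delta-AICc and Akaike weights are computed over the full set and RVI per
    variable over the best ``top_k`` models. Residual skewness/kurtosis of
    the best model are reported as a normality diagnostic (no automatic
    transformation is applied).
    """
    V = len(predictors)
    if V > max_predictors and not allow_large:
        raise ValueError(
            f"{V} predictors implies 2^{V} models; pass allow_large=True to force"
        )
    data = table[[response] + list(predictors)]
    if data.isna().any().any():
        raise ValueError("table contains missing values; drop incomplete cases first")
    z, _ = standardize(data)
    y = z[response].to_numpy()
    n = len(z)

    fits: list[ModelFit] = []
    # canonical subset order: ranking must not depend on enumeration order
    for size in range(V + 1):
        for combo in itertools.combinations(sorted(predictors), size):
            f = fit_ols(y, z[list(combo)] if combo else None)
            crit = aicc(f.rss, n, f.k)
            betas = {v: f.params[v] for v in combo}
            pvals = {v: f.pvalues[v] for v in combo}
            fits.append(ModelFit(combo, betas, pvals, f.r2, f.rss, f.k, crit))
    fits.sort(key=lambda f: (f.aicc, f.variables))
    w = akaike_weights([f.aicc for f in fits])
    for f, (delta, wi) in zip(fits, zip(
            np.array([f.aicc for f in fits]) - fits[0].aicc, w)):
        f.delta = float(delta)
        f.weight = float(wi)

    importance = {v: rvi(fits, v, top_k=top_k) for v in predictors}

    best = fits[0]
    Xb = z[list(best.variables)] if best.variables else None
    bf = fit_ols(y, Xb)
    resid = y - (bf.params["intercept"] + (
        np.asarray(Xb) @ np.array([bf.params[v] for v in best.variables])
        if best.variables else 0.0))
    diagnostics = {
        "residual_skewness": float(sps.skew(resid)),
        "residual_kurtosis": float(sps.kurtosis(resid)),
    }
    return CompetitionResult(fits, list(predictors), n, top_k, importance,
                             diagnostics)
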