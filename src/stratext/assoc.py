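"""Proxy–biodiversity association models.

Bed-level design matrices of geochemical proxies are screened for
pairwise correlation and collinearity (variance inflation factors),
then related to species richness with log-link Poisson GLMs and to
assemblage composition with partial distance-based redundancy analysis
(dbRDA, the capscale approach) on Jaccard distances, with permutation
inference.  Also: the proxy-variance versus extinction-rate screen and
a quadratic trend fit for body-size-versus-proxy scatters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm


# ---------------------------------------------------------------- screening

def correlation_screen(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pearson and Spearman r with two-sided p for every column pair.

    Zero-variance columns yield NaN entries for their pairs (the
    correlation is undefined).
    """
    if len(matrix) < 3:
        raise ValueError("correlation screen needs >= 3 complete rows")
    cols = list(matrix.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            xa, xb = matrix[a].to_numpy(float), matrix[b].to_numpy(float)
            if np.std(xa) == 0 or np.std(xb) == 0:
                rows.append((a, b, np.nan, np.nan, np.nan, np.nan))
                continue
            pr = scipy.stats.pearsonr(xa, xb)
            sr = scipy.stats.spearmanr(xa, xb)
            rows.append((a, b, pr.statistic, pr.pvalue, sr.statistic, sr.pvalue))
    return pd.DataFrame(
        rows, columns=["var1", "var2", "pearson_r", "pearson_p", "spearman_r", "spearman_p"]
    )


def vif(matrix: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column: 1 / (1 - R²_j).

    R²_j comes from regressing column j on the remaining columns (with
    intercept).  Perfect collinearity is reported as ``inf``.
    """
    if matrix.shape[1] < 2:
        raise ValueError("VIF needs >= 2 columns")
    if matrix.shape[0] <= matrix.shape[1]:
        raise ValueError("VIF needs more rows than columns")
    out = {}
    X = matrix.to_numpy(float)
    for j, col in enumerate(matrix.columns):
        y = X[:, j]
        others = np.column_stack([np.ones(len(y)), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        sst = float(np.sum((y - y.mean()) ** 2))
        if sst == 0:
            out[col] = np.nan
            continue
        r2 = 1.0 - float(resid @ resid) / sst
        out[col] = np.inf if r2 > 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def drop_collinear(
    matrix: pd.DataFrame,
    vif_threshold: float = 10.0,
    forced_drops: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, list[dict]]:
    """Successively drop the highest-VIF column above the threshold.

    *forced_drops* are removed first regardless of VIF (e.g. a proxy
    excluded for low sampling resolution).  Returns the reduced matrix
    and an audit trail of every drop with the VIF that triggered it.
    """
    audit: list[dict] = []
    work = matrix.copy()
    for col in forced_drops:
        if col in work.columns:
            work = work.drop(columns=col)
            audit.append({"column": col, "vif": None, "reason": "forced"})
    while work.shape[1] >= 2:
        v = vif(work)
        vmax = v.max()
        if not (vmax > vif_threshold):
            break
        # ties (e.g. duplicated columns) drop the later column, keeping the original
        worst = v[v == vmax].index[-1]
        audit.append({"column": worst, "vif": float(vmax), "reason": "vif"})
        work = work.drop(columns=worst)
    return work, audit


# --------------------------------------------------------------------- GLM

@dataclass
class GlmResult:
    """A fitted log-link Poisson GLM of richness on proxies."""

    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    null_deviance: float
    deviance: float
    aic: float
    converged: bool
    predictors: list[str]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params, "se": self.bse, "z": self.zvalues, "p": self.pvalues}
        )


def fit_poisson_glm(response, matrix: pd.DataFrame | None = None) -> GlmResult:
    """Log-link Poisson regression of count response on proxy columns.

    Fit by iteratively reweighted least squares (statsmodels GLM) to
    tolerance 1e-8; *matrix* may be None or empty for the intercept-only
    model.  Non-convergence (e.g. separation) is flagged, not raised.
    """
    y = np.asarray(response, dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("Poisson response must be non-negative integers")
    if matrix is not None and len(matrix.columns) > 0:
        if len(matrix) != len(y):
            raise ValueError("response and design matrix row counts differ")
        X = sm.add_constant(matrix.astype(float), has_constant="add")
        predictors = list(matrix.columns)
    else:
        X = pd.DataFrame({"const": np.ones(len(y))})
        predictors = []
    model = sm.GLM(y, X, family=sm.families.Poisson())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(tol=1e-8, maxiter=200)
    return GlmResult(
        params=res.params,
        bse=res.bse,
        zvalues=res.tvalues,
        pvalues=res.pvalues,
        null_deviance=float(res.null_deviance),
        deviance=float(res.deviance),
        aic=float(res.aic),
        converged=bool(res.converged),
        predictors=predictors,
    )


def run_glm_pair(
    response,
    matrix: pd.DataFrame,
    focal_a: str = "d18O_apatite",
    focal_b: str = "d114_110Cd",
) -> dict:
    """The paired GLMs for two mutually collinear focal proxies.

    When two proxies are too correlated to share one model (here the
    paleotemperature and primary-productivity isotopes), two GLMs are
    run on the same post-VIF column set: model A keeps *focal_a* and
    excludes *focal_b*, model B vice versa.  The AIC comparison of the
    pair is reported.
    """
    for col in (focal_a, focal_b):
        if col not in matrix.columns:
            raise ValueError(f"focal proxy {col!r} missing from the design matrix")
    model_a = fit_poisson_glm(response, matrix.drop(columns=focal_b))
    model_b = fit_poisson_glm(response, matrix.drop(columns=focal_a))
    return {
        "model_a": model_a,
        "model_b": model_b,
        "focal_a": focal_a,
        "focal_b": focal_b,
        "aic_a": model_a.aic,
        "aic_b": model_b.aic,
        "preferred": "model_a" if model_a.aic <= model_b.aic else "model_b",
    }


# ------------------------------------------------------------------- dbRDA

def jaccard_distances(incidence: pd.DataFrame) -> pd.DataFrame:
    """Bed-by-bed Jaccard distance from a taxa × beds 0/1 matrix.

    d(a, b) = 1 - |A ∩ B| / |A ∪ B| over taxa present in either bed.
    Two beds with no taxa at all get distance 0 with a warning.
    """
    if incidence.shape[1] < 2:
        raise ValueError("need >= 2 beds for a distance matrix")
    B = (incidence.to_numpy() > 0).astype(float)
    inter = B.T @ B
    sums = B.sum(axis=0)
    union = sums[:, None] + sums[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    empty = sums == 0
    if np.any(empty):
        warnings.warn(
            f"{int(empty.sum())} bed(s) with all-zero incidence; "
            "their mutual distances are set to 0",
            stacklevel=2,
        )
        ee = np.ix_(empty, empty)
        d[ee] = 0.0
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=incidence.columns, columns=incidence.columns)


@dataclass
class DbrdaResult:
    """Partial dbRDA decomposition of a distance matrix."""

    constrained_eigenvalues: np.ndarray
    unconstrained_eigenvalues: np.ndarray
    site_scores: pd.DataFrame  # beds × constrained axes
    biplot_scores: pd.DataFrame  # constraints × constrained axes
    constrained_inertia: float
    total_inertia: float
    proportion_constrained: float
    constraint_names: list[str]
    condition_names: list[str]
    overall_p: float | None = None
    term_p: pd.Series | None = None
    # matrices retained for permutation inference
    _G: np.ndarray = field(default=None, repr=False)
    _X: np.ndarray = field(default=None, repr=False)
    _resid_df: float = field(default=0.0, repr=False)


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    A = -0.5 * d**2
    C = np.eye(n) - np.ones((n, n)) / n
    return C @ A @ C


def _hat_project(M: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Trace-free helper: returns H @ M @ H for the hat matrix of X."""
    Q, _ = np.linalg.qr(X)
    # drop dependent columns (zero diagonal of R handled by rank)
    r = np.linalg.matrix_rank(X)
    Q = Q[:, :r]
    return Q @ (Q.T @ M @ Q) @ Q.T


def partial_dbrda(
    dist: pd.DataFrame,
    constraints: pd.DataFrame | None = None,
    condition: pd.DataFrame | None = None,
    sqrt_correction: bool = False,
) -> DbrdaResult:
    """Constrained ordination of a distance matrix (capscale approach).

    The Gower-centered matrix G of -d²/2 is residualized on the
    conditioning variables, projected onto the span of the constraint
    columns, and both the constrained and residual parts are
    eigendecomposed.  Negative eigenvalues (non-Euclidean distances)
    are reported as-is; *sqrt_correction* takes the square root of the
    distances first, which makes Jaccard distances Euclidean-embeddable.
    With no constraints and no condition this reduces to classical
    principal coordinates analysis.
    """
    d = dist.to_numpy(float) if isinstance(dist, pd.DataFrame) else np.asarray(dist, float)
    labels = list(dist.index) if isinstance(dist, pd.DataFrame) else list(range(len(d)))
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    if sqrt_correction:
        d = np.sqrt(d)
    n = d.shape[0]
    G = _gower_center(d)

    cond_names: list[str] = []
    r_cond = 0
    if condition is not None and condition.shape[1] > 0:
        cond_names = list(condition.columns)
        Z = condition.to_numpy(float) - condition.to_numpy(float).mean(axis=0)
        Qz, _ = np.linalg.qr(Z)
        Qz = Qz[:, : np.linalg.matrix_rank(Z)]
        r_cond = Qz.shape[1]
        P = np.eye(n) - Qz @ Qz.T
        G = P @ G @ P
    else:
        P = np.eye(n)

    total_inertia = float(np.trace(G))

    if constraints is None or constraints.shape[1] == 0:
        vals, vecs = np.linalg.eigh(G)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        keep = np.abs(vals) > 1e-10
        pos = vals > 1e-10
        scores = vecs[:, pos] * np.sqrt(vals[pos])
        return DbrdaResult(
            constrained_eigenvalues=np.array([]),
            unconstrained_eigenvalues=vals[keep],
            site_scores=pd.DataFrame(
                scores, index=labels, columns=[f"MDS{i+1}" for i in range(scores.shape[1])]
            ),
            biplot_scores=pd.DataFrame(index=[]),
            constrained_inertia=0.0,
            total_inertia=total_inertia,
            proportion_constrained=0.0,
            constraint_names=[],
            condition_names=cond_names,
            _G=G,
            _X=np.empty((n, 0)),
            _resid_df=n - r_cond - 1,
        )

    names = list(constraints.columns)
    X = constraints.to_numpy(float)
    X = P @ (X - X.mean(axis=0))
    q = int(np.linalg.matrix_rank(X))
    if q + r_cond >= n - 1:
        raise ValueError("saturated model: constraint plus condition rank >= n - 1")

    HGH = _hat_project(G, X)
    vals_c, vecs_c = np.linalg.eigh(HGH)
    order = np.argsort(vals_c)[::-1]
    vals_c, vecs_c = vals_c[order], vecs_c[:, order]
    keep_c = np.abs(vals_c) > 1e-10
    vals_c = vals_c[keep_c][: q]
    vecs_c = vecs_c[:, keep_c][:, : q]
    pos = vals_c > 1e-10
    scores = vecs_c[:, pos] * np.sqrt(vals_c[pos])
    axes = [f"CAP{i+1}" for i in range(scores.shape[1])]

    R = G - HGH  # residual part: (I-H) G (I-H) since G is already in the residual space
    Q, _ = np.linalg.qr(X)
    Q = Q[:, :q]
    R = R - Q @ (Q.T @ R) - (R @ Q) @ Q.T + Q @ (Q.T @ R @ Q) @ Q.T
    vals_u = np.linalg.eigvalsh(R)[::-1]
    vals_u = vals_u[np.abs(vals_u) > 1e-10]

    constrained_inertia = float(np.trace(HGH))
    if scores.shape[1] > 0:
        bip = np.zeros((len(names), scores.shape[1]))
        for i in range(len(names)):
            xi = X[:, i]
            if np.std(xi) > 0:
                for j in range(scores.shape[1]):
                    sj = scores[:, j]
                    bip[i, j] = np.corrcoef(xi, sj)[0, 1] if np.std(sj) > 0 else 0.0
        biplot = pd.DataFrame(bip, index=names, columns=axes)
    else:
        biplot = pd.DataFrame(index=names)

    return DbrdaResult(
        constrained_eigenvalues=vals_c,
        unconstrained_eigenvalues=vals_u,
        site_scores=pd.DataFrame(scores, index=labels, columns=axes),
        biplot_scores=biplot,
        constrained_inertia=constrained_inertia,
        total_inertia=total_inertia,
        proportion_constrained=(
            constrained_inertia / total_inertia if total_inertia > 0 else 0.0
        ),
        constraint_names=names,
        condition_names=cond_names,
        _G=G,
        _X=X,
        _resid_df=n - q - r_cond - 1,
    )


def _pseudo_f(ci, total, q, df_res):
    ci = np.asarray(ci, dtype=float)
    resid = np.asarray(total - ci, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(resid > 1e-12 * max(total, 1e-12), (ci / q) / (resid / df_res), np.inf)


def _constrained_trace(G: np.ndarray, X: np.ndarray) -> float:
    r = np.linalg.matrix_rank(X)
    if r == 0:
        return 0.0
    Q, _ = np.linalg.qr(X)
    Q = Q[:, :r]
    return float(np.einsum("ij,ij->", Q, G @ Q))


def permutation_test_dbrda(
    result: DbrdaResult, n_perm: int = 199, seed: int = 0
) -> DbrdaResult:
    """Permutation pseudo-F tests for the dbRDA constraints.

    Rows of the (residualized) constraint matrix are permuted and the
    constrained-inertia pseudo-F recomputed; with conditioning variables
    this is residual permutation, since both G and X already live in
    the condition's orthogonal complement.  The overall p-value is
    (1 + #{F_perm >= F_obs}) / (1 + n_perm); per-term marginal tests
    use the drop-one constrained-inertia difference under the same
    permutation scheme.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    G, X = result._G, result._X
    if X.shape[1] == 0:
        raise ValueError("no constraints to test")
    rng = np.random.default_rng(seed)
    n = G.shape[0]
    q = int(np.linalg.matrix_rank(X))
    df_res = result._resid_df
    total = result.total_inertia

    ci_obs = _constrained_trace(G, X)
    f_obs = float(_pseudo_f(ci_obs, total, q, df_res))

    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    if X.shape[1] == 1:
        # vectorized fast path: tr(HG) = x'Gx / x'x for a single column
        Xp = X[perms[:, :], 0].T  # (n, n_perm)
        num = np.einsum("ip,ip->p", Xp, G @ Xp)
        den = np.einsum("ip,ip->p", Xp, Xp)
        ci_perm = num / den
        f_perm = _pseudo_f(ci_perm, total, q, df_res)
    else:
        f_perm = np.empty(n_perm)
        for b in range(n_perm):
            ci = _constrained_trace(G, X[perms[b]])
            f_perm[b] = _pseudo_f(ci, total, q, df_res)
    overall_p = (1.0 + np.sum(f_perm >= f_obs - 1e-12)) / (1.0 + n_perm)

    term_p = {}
    if X.shape[1] > 1:
        resid_ms = (total - ci_obs) / df_res
        for j, name in enumerate(result.constraint_names):
            Xmj = np.delete(X, j, axis=1)
            stat_obs = (ci_obs - _constrained_trace(G, Xmj)) / resid_ms
            stat_perm = np.empty(n_perm)
            for b in range(n_perm):
                Xb = X[perms[b]]
                cib = _constrained_trace(G, Xb)
                stat_perm[b] = (cib - _constrained_trace(G, np.delete(Xb, j, axis=1))) / (
                    (total - cib) / df_res
                )
            term_p[name] = (1.0 + np.sum(stat_perm >= stat_obs - 1e-12)) / (1.0 + n_perm)
    else:
        term_p[result.constraint_names[0]] = overall_p

    result.overall_p = float(overall_p)
    result.term_p = pd.Series(term_p, name="p")
    return result


# ------------------------------------------------- variance & trend checks

def variance_vs_extinction_rate(
    per_bed_variance: pd.DataFrame, rates: pd.Series
) -> pd.DataFrame:
    """Spearman screen of within-bed proxy variance against extinction rate.

    *per_bed_variance* holds one column per proxy of within-bed sample
    variances (NaN where a bed has < 2 samples); the analysis is
    pairwise-complete.  Proxies with constant (or undefined) variance
    series are reported with NaN correlation.
    """
    if len(per_bed_variance) < 4:
        raise ValueError("need >= 4 beds")
    rows = []
    r = rates.to_numpy(float)
    for proxy in per_bed_variance.columns:
        v = per_bed_variance[proxy].to_numpy(float)
        ok = np.isfinite(v) & np.isfinite(r)
        if ok.sum() < 4 or np.std(v[ok]) == 0 or np.std(r[ok]) == 0:
            rows.append((proxy, int(ok.sum()), np.nan, np.nan))
            continue
        sr = scipy.stats.spearmanr(v[ok], r[ok])
        rows.append((proxy, int(ok.sum()), sr.statistic, sr.pvalue))
    return pd.DataFrame(rows, columns=["proxy", "n", "spearman_r", "spearman_p"])


@dataclass
class PolyTrend:
    """Least-squares polynomial trend (ascending coefficients) with R²."""

    coefficients: np.ndarray  # c0 + c1 x + c2 x² + ...
    r_squared: float
    degree: int

    def predict(self, x) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(x, float), self.coefficients)


def fit_polynomial_trend(x, y, degree: int = 2) -> PolyTrend:
    """Polynomial least squares, default order 2 (quadratic trend line)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < degree + 2:
        raise ValueError(f"need >= {degree + 2} points for degree {degree}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: all values equal")
    coefs = np.polynomial.polynomial.polyfit(x, y, degree)
    pred = np.polynomial.polynomial.polyval(x, coefs)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - float(np.sum((y - pred) ** 2)) / sst
    return PolyTrend(coefficients=coefs, r_squared=r2, degree=degree)
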