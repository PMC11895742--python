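"""Continuous piecewise-linear (segmented) regression.

Used for two things: detecting state-shifts in geochemical proxy series
(a breakpoint is a persistent change in trend) and as the imputation
curve for proxy values at unsampled beds.  The mean function is

    E[y] = b0 + b1*x + sum_j d_j * (x - psi_j)_+

with breakpoints psi_1 < ... < psi_k estimated by Muggeo-style
iterative linearization: at each iteration the model is refit with the
hinge terms U_j = (x - psi_j)_+ and indicator terms V_j = -1{x > psi_j},
and each breakpoint is updated by psi_j += gamma_j / d_j where gamma_j
is the V_j coefficient.  Multi-start (quantile-spaced plus a coarse
grid-seeded start) guards against local optima.  Breakpoint count is
selected by BIC.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class SegmentedFit:
    """A fitted continuous piecewise-linear model."""

    n_breakpoints: int
    breakpoints: np.ndarray  # strictly increasing, inside the data span
    intercept: float
    slope: float  # slope of the first segment
    slope_changes: np.ndarray  # d_j, change in slope at each breakpoint
    sse: float
    sigma2: float
    bic: float
    converged: bool
    n_obs: int
    span: tuple[float, float]
    bic_trace: dict[int, float] = field(default_factory=dict)

    @property
    def segment_slopes(self) -> np.ndarray:
        """Slope of each of the k+1 segments, bottom-up."""
        return self.slope + np.concatenate([[0.0], np.cumsum(self.slope_changes)])

    def to_dict(self) -> dict:
        return {
            "n_breakpoints": self.n_breakpoints,
            "breakpoints": list(map(float, self.breakpoints)),
            "intercept": self.intercept,
            "slope": self.slope,
            "slope_changes": list(map(float, self.slope_changes)),
            "segment_slopes": list(map(float, self.segment_slopes)),
            "sse": self.sse,
            "bic": self.bic,
            "converged": self.converged,
            "bic_trace": {str(k): v for k, v in self.bic_trace.items()},
        }


@dataclass
class AnomalyFlags:
    """Per-sample spike flags from segmented-fit residuals."""

    flags: np.ndarray  # boolean
    residuals: np.ndarray
    scale: float
    threshold: float


MIN_SEGMENT_POINTS = 3  # identifiability floor per segment


def _design(x: np.ndarray, psi: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(x), x] + [np.clip(x - p, 0.0, None) for p in psi]
    return np.column_stack(cols)


def _ols_sse(x: np.ndarray, y: np.ndarray, psi: np.ndarray):
    X = _design(x, psi)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), beta


def _occupancy_ok(x: np.ndarray, psi: np.ndarray) -> bool:
    edges = np.concatenate([[-np.inf], psi, [np.inf]])
    counts = np.histogram(x, bins=edges)[0]
    return bool(np.all(counts >= MIN_SEGMENT_POINTS))


def _bic(n: int, sse: float, k: int, y_scale: float = 1.0) -> float:
    # parameters: intercept, base slope, k slope changes, k breakpoints.
    # SSE is floored at numerical precision relative to the data scale so
    # that exactly-interpolating fits compare by parameter count, not by
    # floating-point noise in a zero residual.
    p = 2 + 2 * k
    floor = n * (1e-9 * max(y_scale, 1e-12)) ** 2
    return n * np.log(max(sse, floor) / n) + p * np.log(n)


def _grid_candidates(x: np.ndarray, k: int, n_cand: int = 15) -> np.ndarray:
    qs = np.linspace(0.05, 0.95, n_cand)
    cand = np.unique(np.quantile(x, qs))
    return cand if len(cand) >= k else np.unique(x)[1:-1]


def _grid_best(x: np.ndarray, y: np.ndarray, k: int):
    """Best exact piecewise-OLS over a coarse breakpoint grid."""
    cand = _grid_candidates(x, k)
    best = (np.inf, None)
    for combo in itertools.combinations(cand, k):
        psi = np.array(combo)
        if not _occupancy_ok(x, psi):
            continue
        sse, _ = _ols_sse(x, y, psi)
        if sse < best[0]:
            best = (sse, psi)
    return best


def fit_segmented(
    x: np.ndarray,
    y: np.ndarray,
    k: int,
    starts: list[np.ndarray] | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
    seed: int = 0,
    n_starts: int = 10,
) -> SegmentedFit:
    """Least-squares continuous piecewise-linear fit with k breakpoints.

    For k = 0 this is the ordinary least-squares line.  For k >= 1 the
    breakpoints are estimated by iterative linearization restarted from
    quantile-spaced initial values plus the best coarse-grid placement;
    the lowest-SSE solution is kept.  ``converged`` is False when every
    start exhausted ``max_iter`` without the breakpoints settling.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D and equal length")
    n = len(x)
    if n < 2 * k + 4:
        raise ValueError(f"need at least {2 * k + 4} points for k={k}, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: all values equal")
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    span = (float(x[0]), float(x[-1]))

    if k == 0:
        X = np.column_stack([np.ones(n), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sse = float(resid @ resid)
        return SegmentedFit(
            n_breakpoints=0,
            breakpoints=np.array([]),
            intercept=float(beta[0]),
            slope=float(beta[1]),
            slope_changes=np.array([]),
            sse=sse,
            sigma2=sse / max(n - 2, 1),
            bic=_bic(n, sse, 0, float(np.ptp(y))),
            converged=True,
            n_obs=n,
            span=span,
        )

    rng = np.random.default_rng(seed)
    lo, hi = np.quantile(x, [0.05, 0.95])
    if starts is None:
        starts = [np.linspace(lo, hi, k + 2)[1:-1]]
        for _ in range(n_starts - 1):
            starts.append(np.sort(rng.uniform(lo, hi, size=k)))
        g_sse, g_psi = _grid_best(x, y, k)
        if g_psi is not None:
            starts.append(g_psi)

    x_span = span[1] - span[0]
    best_sse, best_psi, best_beta, any_converged = np.inf, None, None, False
    for psi0 in starts:
        psi = np.sort(np.asarray(psi0, dtype=float))
        converged = False
        for _ in range(max_iter):
            U = np.column_stack([np.clip(x - p, 0.0, None) for p in psi])
            V = np.column_stack([-(x > p).astype(float) for p in psi])
            X = np.column_stack([np.ones(n), x, U, V])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            delta = beta[2 : 2 + k]
            gamma = beta[2 + k :]
            with np.errstate(divide="ignore", invalid="ignore"):
                step = np.where(np.abs(delta) > 1e-12, gamma / delta, 0.0)
            new_psi = np.sort(np.clip(psi + step, span[0] + 1e-9, span[1] - 1e-9))
            shift = np.max(np.abs(new_psi - psi)) if k else 0.0
            psi = new_psi
            if shift < tol * x_span:
                converged = True
                break
        if not _occupancy_ok(x, psi):
            continue
        sse, beta_final = _ols_sse(x, y, psi)
        if sse < best_sse - 1e-12 or (sse < best_sse + 1e-12 and not any_converged):
            best_sse, best_psi, best_beta = sse, psi, beta_final
            any_converged = any_converged or converged

    if best_psi is None:
        # every start violated segment occupancy: fall back to grid optimum
        g_sse, g_psi = _grid_best(x, y, k)
        if g_psi is None:
            raise ValueError(f"cannot place {k} breakpoints with occupied segments")
        best_sse, best_psi = g_sse, g_psi
        _, best_beta = _ols_sse(x, y, best_psi)
        any_converged = False

    return SegmentedFit(
        n_breakpoints=k,
        breakpoints=best_psi,
        intercept=float(best_beta[0]),
        slope=float(best_beta[1]),
        slope_changes=np.asarray(best_beta[2:], dtype=float),
        sse=best_sse,
        sigma2=best_sse / max(n - (2 + 2 * k), 1),
        bic=_bic(n, best_sse, k, float(np.ptp(y))),
        converged=any_converged,
        n_obs=n,
        span=span,
    )


def select_segmented(
    x: np.ndarray, y: np.ndarray, K_max: int = 3, seed: int = 0, **kwargs
) -> SegmentedFit:
    """Fit k = 0..K_max breakpoints and select by BIC.

    The selected fit carries the full BIC trace so the decision is
    auditable.
    """
    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    x = np.asarray(x, dtype=float)
    fits: dict[int, SegmentedFit] = {}
    trace: dict[int, float] = {}
    for k in range(K_max + 1):
        if len(x) < 2 * k + 4:
            break
        try:
            fits[k] = fit_segmented(x, y, k, seed=seed, **kwargs)
        except ValueError:
            continue
        trace[k] = fits[k].bic
    if not fits:
        raise ValueError("no breakpoint count could be fitted")
    k_best = min(trace, key=trace.get)
    best = fits[k_best]
    best.bic_trace = trace
    return best


def predict_segmented(fit: SegmentedFit, x_new: np.ndarray) -> np.ndarray:
    """Evaluate the fitted piecewise-linear mean; warns on extrapolation."""
    x_new = np.atleast_1d(np.asarray(x_new, dtype=float))
    if np.any(x_new < fit.span[0]) or np.any(x_new > fit.span[1]):
        warnings.warn("predicting outside the fitted span (extrapolation)", stacklevel=2)
    out = fit.intercept + fit.slope * x_new
    for psi, d in zip(fit.breakpoints, fit.slope_changes):
        out = out + d * np.clip(x_new - psi, 0.0, None)
    return out


def flag_anomalies(
    x: np.ndarray, y: np.ndarray, fit: SegmentedFit, threshold: float = 3.0
) -> AnomalyFlags:
    """Flag transient spikes: residuals beyond threshold robust scales.

    Spike-type proxies (volcanism tracers such as Hg/TOC, Zn and Os
    isotopes) show anomalies, not trend shifts; a residual is flagged
    when it exceeds ``threshold`` times the MAD-based robust scale of
    the residuals.  If the MAD degenerates to zero but residuals are
    not all zero (one spike on an otherwise perfect fit) the residual
    standard deviation is used instead; identically-zero residuals
    yield no flags.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    resid = y - predict_segmented(fit, x)
    med = np.median(resid)
    scale = 1.4826 * np.median(np.abs(resid - med))
    if scale == 0.0:
        scale = float(np.std(resid))
    if scale == 0.0:
        flags = np.zeros_like(resid, dtype=bool)
    else:
        flags = np.abs(resid - med) > threshold * scale
    return AnomalyFlags(flags=flags, residuals=resid, scale=float(scale), threshold=threshold)
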