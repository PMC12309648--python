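"""Weighted additive model of MPA features on conservation performance.

Conservation performance (the annual biomass log response ratio of no-take
MPAs for targeted species) is modelled as a sum of smooth functions of the
eight MPA features -- age, size, habitat diversity, habitat richness,
proportion rock, pre-implementation landings, ecosystem-specific and total
larval settlement -- plus a cyclic cubic spline in survey year that
absorbs periodic temporal trends.  Observations are weighted by the
random-effects meta-analytic weights w = 1/(v + tau2), with tau2 taken
from the network-level pool of the same stratum.

The fit is penalized weighted least squares with a Gaussian response:
cubic B-spline bases with second-derivative penalties for the feature
smooths (statsmodels' ``BSplines``/``CyclicCubicSplines`` supply basis and
penalty matrices), smoothing parameters chosen by minimizing the
generalized cross-validation score

    GCV = n * RSS_w / (n - EDF_total)^2,

where RSS_w is the weighted residual sum of squares and EDF the trace of
the hat matrix.  Model terms are chosen by greedy forward selection on
GCV, starting from intercept + year: at each step the candidate smooth
whose addition most reduces GCV is added, stopping when no candidate
improves GCV by more than a relative tolerance.

Weights are normalised to mean 1 internally, so rescaling all weights by
a constant leaves the fit (including the selected smoothing) unchanged.
Term p-values are approximate Wald tests on the penalized coefficients
with rank rounded from the term's effective degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from statsmodels.gam.smooth_basis import BSplines, CyclicCubicSplines

from .effects import most_recent_filter
from .exceptions import IllPosedError, InvalidArgumentError
from .pooling import pooled_effect

__all__ = [
    "FEATURES",
    "FeatureModelFit",
    "build_model_frame",
    "fit_weighted_gam",
    "forward_select_gcv",
]

#: The eight candidate MPA features, in their conventional order.
FEATURES = (
    "age",
    "size_km2",
    "habitat_diversity",
    "habitat_richness",
    "prop_rock",
    "pre_landings",
    "settlement_ecosystem",
    "settlement_total",
)

DEFAULT_BASIS_DIM = 5
DEFAULT_REL_TOL = 1e-2  # minimum relative GCV improvement to accept a term
_RIDGE = 1e-9  # tiny stabilising ridge on the penalized normal equations
_RHO_BOUND = 15.0  # |log lambda| search bound


# ---------------------------------------------------------------------------
# model frame

def build_model_frame(
    effects_annual: pd.DataFrame,
    features: pd.DataFrame,
    *,
    tau2: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the GAM input: annual no-take, targeted effects + features.

    Rows are annual effect sizes (year enters the model, so the
    most-recent-year filter is NOT applied) restricted to no-take MPAs and
    targeted species.  Weights are w = 1/(v + tau2); when ``tau2`` is not
    given it is estimated from the network-level pool of the most-recent
    effects in the same stratum.  Rows with any missing feature are
    dropped and returned separately.

    Returns ``(frame, dropped)``.
    """
    sel = effects_annual[
        (effects_annual["protection"] == "no_take")
        & (effects_annual["status"] == "targeted")
    ].copy()
    if sel.empty:
        raise InvalidArgumentError("no no-take, targeted effect sizes to model")

    if tau2 is None:
        recent = most_recent_filter(sel)
        tau2 = pooled_effect(
            recent["Y"].to_numpy(), recent["v"].to_numpy()
        ).tau2

    feat_cols = [c for c in FEATURES if c != "age"]
    frame = sel.merge(
        features[["mpa_id", "implementation_year"] + feat_cols],
        on="mpa_id",
        how="left",
    )
    frame["age"] = frame["year"] - frame["implementation_year"]
    ok = frame[list(FEATURES)].notna().all(axis=1)
    dropped = frame.loc[~ok].copy()
    dropped["reason"] = "missing_feature"
    frame = frame.loc[ok].copy()
    if frame.empty:
        raise InvalidArgumentError("model frame empty after dropping missing features")
    frame["w"] = 1.0 / (frame["v"] + tau2)
    frame.attrs["tau2"] = float(tau2)
    return frame.reset_index(drop=True), dropped


# ---------------------------------------------------------------------------
# smooth construction

class _Smooth:
    """One smooth term: centered basis, penalty, and prediction transform."""

    def __init__(self, name: str, x: np.ndarray, basis_dim: int, cyclic: bool):
        self.name = name
        self.cyclic = cyclic
        x = np.asarray(x, dtype=float)
        n_distinct = np.unique(x).size
        if cyclic:
            df = int(min(basis_dim, max(n_distinct - 1, 1)))
            if n_distinct < 3 or df < 3:
                # too few distinct values for a cyclic basis: linear fallback
                self._linear_mean = x.mean()
                self._sm = None
                basis = (x - self._linear_mean).reshape(-1, 1)
                self.penalty = np.zeros((1, 1))
            else:
                self._sm = CyclicCubicSplines(x.reshape(-1, 1), df=[df])
                # the cyclic basis sums to one; drop a column for identifiability
                basis = self._sm.basis[:, :-1]
                self.penalty = self._sm.penalty_matrices[0][:-1, :-1]
        else:
            df = int(min(basis_dim, n_distinct - 1))
            if df < 4:  # cubic B-splines need df >= 4; fall back to linear
                self._linear_mean = x.mean()
                self._sm = None
                basis = (x - self._linear_mean).reshape(-1, 1)
                self.penalty = np.zeros((1, 1))
            else:
                self._sm = BSplines(
                    x.reshape(-1, 1), df=[df], degree=[3], include_intercept=False
                )
                basis = self._sm.basis
                self.penalty = self._sm.penalty_matrices[0]
        self.center = basis.mean(axis=0)
        self.basis = basis - self.center
        self.ncol = self.basis.shape[1]

    def transform(self, x_new: np.ndarray) -> np.ndarray:
        x_new = np.asarray(x_new, dtype=float)
        if self._sm is None:
            return (x_new - self._linear_mean).reshape(-1, 1)
        b = self._sm.transform(x_new.reshape(-1, 1))
        if self.cyclic:
            b = b[:, :-1]
        return b - self.center


@dataclass
class FeatureModelFit:
    """Result of one weighted additive model fit."""

    included_terms: list[str]
    edf: dict[str, float]
    term_p: dict[str, float]
    gcv: float
    r2_adj: float
    fitted: np.ndarray = field(repr=False)
    partials: dict[str, pd.DataFrame] = field(repr=False)
    lambdas: dict[str, float]
    edf_total: float
    sigma2: float
    n: int
    coefficients: np.ndarray = field(repr=False)


def _assemble(frame, terms, basis_dim, y_col, weight_col, year_col):
    y = frame[y_col].to_numpy(dtype=float)
    w = frame[weight_col].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise InvalidArgumentError("weights must be positive")
    w = w / w.mean()  # scale invariance of the fit and of GCV

    smooths = [_Smooth("year", frame[year_col].to_numpy(), basis_dim, cyclic=True)]
    for t in terms:
        smooths.append(_Smooth(t, frame[t].to_numpy(), basis_dim, cyclic=False))

    blocks, start = [], 1
    cols = [np.ones((len(frame), 1))]
    for sm in smooths:
        cols.append(sm.basis)
        blocks.append(slice(start, start + sm.ncol))
        start += sm.ncol
    X = np.hstack(cols)
    if X.shape[1] >= len(frame):
        raise IllPosedError(
            f"{X.shape[1]} basis columns for {len(frame)} observations"
        )
    return y, w, X, smooths, blocks


def _penalty_full(p, smooths, blocks, rho):
    S = np.zeros((p, p))
    for sm, blk, r in zip(smooths, blocks, rho):
        S[blk, blk] += np.exp(r) * sm.penalty
    return S


def _gcv_quantities(rho, XtWX, XtWy, ytWy, smooths, blocks, n):
    p = XtWX.shape[0]
    A = XtWX + _penalty_full(p, smooths, blocks, rho)
    A[np.diag_indices_from(A)] += _RIDGE * (1.0 + np.trace(XtWX) / p)
    try:
        c, low = linalg.cho_factor(A)
        beta = linalg.cho_solve((c, low), XtWy)
        F = linalg.cho_solve((c, low), XtWX)  # edf matrix
    except linalg.LinAlgError:
        beta = linalg.lstsq(A, XtWy)[0]
        F = linalg.lstsq(A, XtWX)[0]
    rss = float(ytWy - 2 * beta @ XtWy + beta @ XtWX @ beta)
    rss = max(rss, 1e-300)
    edf = float(np.trace(F))
    gcv = n * rss / (n - edf) ** 2 if edf < n else np.inf
    return gcv, beta, F, rss, edf, A


def fit_weighted_gam(
    frame: pd.DataFrame,
    terms: list[str],
    *,
    basis_dim: int = DEFAULT_BASIS_DIM,
    y_col: str = "Y",
    weight_col: str = "w",
    year_col: str = "year",
    lambdas: np.ndarray | None = None,
    grid_points: int = 100,
) -> FeatureModelFit:
    """Fit the weighted penalized additive model for a given set of terms.

    The cyclic year smooth is always included alongside the intercept;
    ``terms`` lists the feature smooths.  Smoothing parameters minimise
    GCV unless ``lambdas`` (one per smooth, year first) fixes them.
    """
    unknown = set(terms) - set(FEATURES)
    if unknown:
        raise InvalidArgumentError(f"unknown model terms: {sorted(unknown)}")
    y, w, X, smooths, blocks = _assemble(
        frame, terms, basis_dim, y_col, weight_col, year_col
    )
    n = len(y)
    XtWX = X.T @ (w[:, None] * X)
    XtWy = X.T @ (w * y)
    ytWy = float(y @ (w * y))

    d = len(smooths)
    if lambdas is not None:
        rho = np.log(np.asarray(lambdas, dtype=float))
    else:
        def objective(r):
            r = np.clip(r, -_RHO_BOUND, _RHO_BOUND)
            return _gcv_quantities(r, XtWX, XtWy, ytWy, smooths, blocks, n)[0]

        best = None
        for start in (np.zeros(d), np.full(d, 4.0)):
            res = optimize.minimize(
                objective, start, method="Nelder-Mead",
                options={"maxiter": 200 * d, "xatol": 1e-3, "fatol": 1e-9},
            )
            if best is None or res.fun < best.fun:
                best = res
        rho = np.clip(best.x, -_RHO_BOUND, _RHO_BOUND)

    gcv, beta, F, rss, edf_total, A = _gcv_quantities(
        rho, XtWX, XtWy, ytWy, smooths, blocks, n
    )
    sigma2 = rss / max(n - edf_total, 1.0)
    Vb = linalg.inv(A) * sigma2  # Bayesian covariance of the coefficients

    ybar = float(np.sum(w * y) / np.sum(w))
    tss = float(np.sum(w * (y - ybar) ** 2))
    r2_adj = 1.0 - (rss / max(n - edf_total, 1.0)) / (tss / (n - 1))

    edf, term_p, partials, lam = {}, {}, {}, {}
    diagF = np.diag(F)
    for sm, blk, r in zip(smooths, blocks, rho):
        edf[sm.name] = float(diagF[blk].sum())
        lam[sm.name] = float(np.exp(r))
        b = beta[blk]
        Vbb = Vb[blk, blk]
        rank = max(1, int(round(edf[sm.name])))
        stat = float(b @ linalg.pinvh(Vbb) @ b)
        term_p[sm.name] = float(stats.chi2.sf(stat, rank))
        # partial-effect curve on a grid over the observed range
        xobs = (
            frame[year_col] if sm.name == "year" else frame[sm.name]
        ).to_numpy(dtype=float)
        grid = np.linspace(xobs.min(), xobs.max(), grid_points)
        Bg = sm.transform(grid)
        est = Bg @ b
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Bg, Vbb, Bg), 0.0))
        partials[sm.name] = pd.DataFrame(
            {"x": grid, "estimate": est, "lo": est - 1.96 * se, "hi": est + 1.96 * se}
        )

    return FeatureModelFit(
        included_terms=list(terms),
        edf=edf,
        term_p=term_p,
        gcv=gcv,
        r2_adj=r2_adj,
        fitted=X @ beta,
        partials=partials,
        lambdas=lam,
        edf_total=edf_total,
        sigma2=sigma2,
        n=n,
        coefficients=beta,
    )


def forward_select_gcv(
    frame: pd.DataFrame,
    candidates: list[str] | tuple[str, ...] = FEATURES,
    *,
    basis_dim: int = DEFAULT_BASIS_DIM,
    rel_tol: float = DEFAULT_REL_TOL,
    **fit_kwargs,
) -> tuple[FeatureModelFit, pd.DataFrame]:
    """Greedy forward selection of feature smooths by GCV.

    Starts from intercept + cyclic year; at each step refits with each
    remaining candidate added and keeps the one that most reduces GCV,
    stopping when the best addition improves GCV by less than ``rel_tol``
    relative to the current score.  Returns the selected fit and a trace
    of the GCV path (one row per accepted step, step 0 = year-only model).
    """
    if not candidates:
        raise InvalidArgumentError("need at least one candidate term")
    current: list[str] = []
    fit = fit_weighted_gam(frame, current, basis_dim=basis_dim, **fit_kwargs)
    trace = [{"step": 0, "term_added": None, "gcv": fit.gcv}]
    remaining = list(candidates)
    while remaining:
        trials = []
        for t in remaining:
            f = fit_weighted_gam(frame, current + [t], basis_dim=basis_dim, **fit_kwargs)
            trials.append((f.gcv, t, f))
        best_gcv, best_term, best_fit = min(trials, key=lambda r: r[0])
        if fit.gcv - best_gcv <= rel_tol * fit.gcv:
            break
        current.append(best_term)
        fit = best_fit
        remaining.remove(best_term)
        trace.append({"step": len(current), "term_added": best_term, "gcv": fit.gcv})
    return fit, pd.DataFrame(trace)
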