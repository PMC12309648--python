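"""Random-effects pooling of log response ratios at four spatial scales.

The pooled conservation performance of a group of ecosystem-MPA effect
sizes is a weighted mean

    R_bar = sum(w_i * Y_i) / sum(w_i),    w_i = 1 / (v_i + tau2),

where ``v_i`` is the within-study variance of each effect and ``tau2`` the
between-study variance component, estimated from the heterogeneity
statistic

    Q = sum(w_i * (Y_i - R_bar_w)^2),     tau2 = max(0, (Q - (k-1)) / (k-1)).

Because the weights, Q and tau2 are mutually defined, the estimator is
evaluated in the conventional two-pass order: Q is computed under
fixed-effect weights 1/v, tau2 follows from Q, and the random-effects
weights 1/(v + tau2) then produce the pooled mean.  Note the tau2
denominator is k - 1 (the number of pooled effects minus one), not the
DerSimonian-Laird constant ``sum(w) - sum(w^2)/sum(w)``.

Groups are formed at four scales -- individual MPA (pooling its
ecosystems), ecosystem, region, and the whole network -- always stratified
by species target status and protection level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidArgumentError

__all__ = [
    "PooledEffect",
    "heterogeneity_Q",
    "tau_squared",
    "apply_variance_floor",
    "pooled_effect",
    "pool_at_scale",
    "SCALES",
]

SCALES = ("mpa", "ecosystem", "region", "network")

#: Fraction of the smallest positive variance in a pooling group assigned
#: to zero-variance effects so that no single effect gets infinite weight.
VARIANCE_FLOOR_FACTOR = 0.1

#: Fallback variance when every effect in a group has zero variance.
DEGENERATE_VARIANCE = 1e-6


@dataclass
class PooledEffect:
    """One pooled group: weighted mean effect with heterogeneity statistics."""

    scale: str
    group_key: str
    status: str
    protection: str
    k: int
    Q: float
    tau2: float
    R_bar: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    weights: np.ndarray = field(repr=False)
    single_study: bool = False
    tau2_truncated: bool = False
    n_floored: int = 0


def heterogeneity_Q(y, w) -> float:
    """Weighted sum of squared deviations around the weighted mean.

    ``w`` should be fixed-effect weights (1/v) when used to estimate tau2.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if y.size == 0:
        raise InvalidArgumentError("heterogeneity_Q requires at least one effect")
    if np.any(w <= 0):
        raise InvalidArgumentError("weights must be positive")
    r_bar = np.sum(w * y) / np.sum(w)
    return float(np.sum(w * (y - r_bar) ** 2))


def tau_squared(Q: float, k: int) -> tuple[float, bool]:
    """Between-study variance from Q with c = k - 1; truncated at zero.

    Returns ``(tau2, truncated)`` where ``truncated`` records whether the
    raw estimate was negative.  A single study carries no between-study
    information, so k = 1 yields 0.
    """
    if k < 1:
        raise InvalidArgumentError(f"k must be >= 1, got {k}")
    if k == 1:
        return 0.0, False
    raw = (Q - (k - 1)) / (k - 1)
    return max(0.0, raw), raw < 0


def apply_variance_floor(v, factor: float = VARIANCE_FLOOR_FACTOR):
    """Replace zero variances by ``factor`` times the group's smallest positive one.

    Returns ``(v_floored, n_floored)``.  If the group has no positive
    variance at all, a small fixed fallback is used.
    """
    v = np.asarray(v, dtype=float).copy()
    zero = v <= 0
    if zero.any():
        positive = v[~zero]
        floor = factor * positive.min() if positive.size else DEGENERATE_VARIANCE
        v[zero] = floor
    return v, int(zero.sum())


def pooled_effect(
    y,
    v,
    *,
    scale: str = "network",
    group_key: str = "all",
    status: str = "targeted",
    protection: str = "no_take",
    alpha: float = 0.05,
    use_t: bool = False,
) -> PooledEffect:
    """Pool effect sizes into a single random-effects summary.

    Sequence: fixed-effect weights give Q; tau2 from Q; random-effects
    weights 1/(v + tau2) give the pooled mean, its standard error
    sqrt(1 / sum(w)), the (1 - alpha) confidence interval and a two-sided
    p-value from the normal reference (or Student t with k - 1 df when
    ``use_t``).
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    if y.size == 0:
        raise InvalidArgumentError("cannot pool an empty group")
    if y.shape != v.shape:
        raise InvalidArgumentError("y and v must have the same length")
    k = y.size
    v, n_floored = apply_variance_floor(v)

    if k == 1:
        r_bar = float(y[0])
        se = float(np.sqrt(v[0]))
        q, tau2, truncated = 0.0, 0.0, False
        w = np.array([1.0 / v[0]])
        single = True
    else:
        w_fe = 1.0 / v
        q = heterogeneity_Q(y, w_fe)
        tau2, truncated = tau_squared(q, k)
        w = 1.0 / (v + tau2)
        r_bar = float(np.sum(w * y) / np.sum(w))
        se = float(np.sqrt(1.0 / np.sum(w)))
        single = False

    z = r_bar / se if se > 0 else np.inf * np.sign(r_bar)
    if use_t and k > 1:
        crit = stats.t.ppf(1 - alpha / 2, df=k - 1)
        p = 2 * stats.t.sf(abs(z), df=k - 1)
    else:
        crit = stats.norm.ppf(1 - alpha / 2)
        p = 2 * stats.norm.sf(abs(z))
    return PooledEffect(
        scale=scale,
        group_key=group_key,
        status=status,
        protection=protection,
        k=k,
        Q=q,
        tau2=tau2,
        R_bar=r_bar,
        se=se,
        ci_low=r_bar - crit * se,
        ci_high=r_bar + crit * se,
        p=float(min(p, 1.0)),
        weights=w,
        single_study=single,
        tau2_truncated=truncated,
        n_floored=n_floored,
    )


_GROUP_COLS = {
    "mpa": ["mpa_id"],
    "ecosystem": ["ecosystem"],
    "region": ["region"],
    "network": [],
}


def pool_at_scale(
    effects: pd.DataFrame,
    scale: str,
    *,
    within_region: bool = False,
    alpha: float = 0.05,
    use_t: bool = False,
) -> pd.DataFrame:
    """Pool an effects table at one spatial scale, stratified by status x protection.

    ``effects`` needs columns mpa_id, ecosystem, region, status, protection,
    Y, v (typically the most-recent-year effects).  ``within_region`` adds
    region to the ecosystem-scale grouping (region-by-ecosystem rows).
    Groups with no effects simply do not appear.
    """
    if scale not in _GROUP_COLS:
        raise InvalidArgumentError(
            f"unknown scale {scale!r}; expected one of {SCALES}"
        )
    group_cols = list(_GROUP_COLS[scale])
    if scale == "ecosystem" and within_region:
        group_cols = ["region"] + group_cols
    strat = group_cols + ["status", "protection"]

    rows = []
    for key, grp in effects.groupby(strat, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        labels = dict(zip(strat, key))
        group_key = (
            "|".join(str(labels[c]) for c in group_cols) if group_cols else "all"
        )
        pe = pooled_effect(
            grp["Y"].to_numpy(),
            grp["v"].to_numpy(),
            scale=scale,
            group_key=group_key,
            status=labels["status"],
            protection=labels["protection"],
            alpha=alpha,
            use_t=use_t,
        )
        row = {
            "scale": scale,
            "group_key": group_key,
            "status": pe.status,
            "protection": pe.protection,
            "k": pe.k,
            "Q": pe.Q,
            "tau2": pe.tau2,
            "R_bar": pe.R_bar,
            "se": pe.se,
            "ci_low": pe.ci_low,
            "ci_high": pe.ci_high,
            "p": pe.p,
            "significant": pe.p < alpha,
            "single_study": pe.single_study,
            "n_floored": pe.n_floored,
        }
        for c in group_cols:
            row[c] = labels[c]
        rows.append(row)
    return pd.DataFrame(rows)
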