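"""Log response ratio effect sizes and their within-study variances.

The effect of protection for MPA j in year i is the log response ratio

    Y_ji = ln( Xbar_inside_ji / Xbar_outside_ji ),

where the Xbar are mean biomass (or richness/diversity) across replicate
units on each side of the MPA boundary.  Reference sites occasionally have
all-zero samples, which would leave Y undefined, so before taking ratios a
small constant -- 10% of the mean of all values in the (ecosystem, year,
protection level, side) stratum -- is added to both members of any pair
containing a zero.

The within-study variance attached to one ecosystem-MPA effect is, in the
form the meta-analysis uses it (``as_printed``),

    v = sd_in^2 / (n_in * Xbar_in) + sd_out^2 / (n_out * Xbar_out),

with first-power means in the denominators.  That form is not invariant to
the measurement scale; the standard delta-method variance of a log ratio,

    v = sd_in^2 / (n_in * Xbar_in^2) + sd_out^2 / (n_out * Xbar_out^2),

is available as method ``"delta"`` and is the one with nominal coverage
properties.  The method used is recorded alongside every variance.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .exceptions import (
    InsufficientReplicationError,
    InvalidArgumentError,
    UndefinedRatioError,
)

__all__ = [
    "zero_adjust",
    "log_response_ratio",
    "within_study_variance",
    "compute_effects",
    "most_recent_filter",
    "ZERO_ADJUST_FRACTION",
]

#: Stratum constant = this fraction of the stratum mean.
ZERO_ADJUST_FRACTION = 0.10

VARIANCE_METHODS = ("as_printed", "delta")


def zero_adjust(
    pairs: pd.DataFrame,
    *,
    mode: str = "zero_pairs",
    fraction: float = ZERO_ADJUST_FRACTION,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Add stratum constants to inside/outside pairs that contain a zero.

    ``pairs`` needs columns mpa_id, ecosystem, year, status, protection,
    mean_inside, mean_outside.  For each (ecosystem, year, protection,
    side) stratum the constant is ``fraction`` times the mean of all of
    that stratum's values (all MPAs and statuses together).  Each member
    of an affected pair receives the constant of its own side's stratum;
    adding to one side only would bias the ratio.

    mode ``"zero_pairs"`` (default) adjusts only pairs where either member
    is zero; ``"stratum_wide"`` adds the constants to every pair, for
    sensitivity analysis.

    Returns ``(adjusted, constants, exclusions)``.  Pairs that still
    contain a zero after adjustment (their stratum was all zeros, so the
    constant is zero) go to the exclusion table, not the output.
    """
    if mode not in ("zero_pairs", "stratum_wide"):
        raise InvalidArgumentError(f"unknown zero-adjust mode {mode!r}")
    required = {"ecosystem", "year", "protection", "mean_inside", "mean_outside"}
    missing = required - set(pairs.columns)
    if missing:
        raise InvalidArgumentError(f"pairs table missing columns: {sorted(missing)}")
    if (pairs[["mean_inside", "mean_outside"]] < 0).any().any():
        raise InvalidArgumentError("means must be nonnegative before zero-adjustment")

    strat = ["ecosystem", "year", "protection"]
    # biomass is computed per target status, so status-specific metrics get
    # status-specific strata; diversity tables carry a single pooled status
    if "status" in pairs.columns and pairs["status"].nunique() > 1:
        strat.append("status")
    const_in = pairs.groupby(strat)["mean_inside"].mean() * fraction
    const_out = pairs.groupby(strat)["mean_outside"].mean() * fraction

    constants = pd.concat(
        [
            const_in.rename("constant").reset_index().assign(side="inside"),
            const_out.rename("constant").reset_index().assign(side="outside"),
        ],
        ignore_index=True,
    )

    out = pairs.copy()
    key = pd.MultiIndex.from_frame(out[strat])
    c_in = const_in.reindex(key).to_numpy()
    c_out = const_out.reindex(key).to_numpy()
    has_zero = (out["mean_inside"] == 0) | (out["mean_outside"] == 0)
    adjust = (
        has_zero if mode == "zero_pairs" else pd.Series(True, index=out.index)
    )
    out["adj_mean_inside"] = np.where(
        adjust, out["mean_inside"] + c_in, out["mean_inside"]
    )
    out["adj_mean_outside"] = np.where(
        adjust, out["mean_outside"] + c_out, out["mean_outside"]
    )
    out["zero_adjusted"] = adjust.to_numpy()

    undefined = (out["adj_mean_inside"] <= 0) | (out["adj_mean_outside"] <= 0)
    exclusions = out.loc[undefined, list(pairs.columns)].copy()
    exclusions["reason"] = "undefined_ratio_all_zero_stratum"
    return out.loc[~undefined].copy(), constants, exclusions


def log_response_ratio(mean_inside: float, mean_outside: float) -> float:
    """ln(inside / outside); natural log, positive when biomass is higher inside."""
    if mean_inside <= 0 or mean_outside <= 0:
        raise UndefinedRatioError(
            f"log response ratio undefined for means "
            f"({mean_inside}, {mean_outside}); apply zero adjustment first"
        )
    return math.log(mean_inside / mean_outside)


def within_study_variance(
    sd_inside: float,
    n_inside: int,
    mean_inside: float,
    sd_outside: float,
    n_outside: int,
    mean_outside: float,
    method: str = "as_printed",
) -> float:
    """Sampling variance of one ecosystem-MPA log response ratio."""
    if method not in VARIANCE_METHODS:
        raise InvalidArgumentError(f"unknown variance method {method!r}")
    if n_inside < 2 or n_outside < 2:
        raise InsufficientReplicationError(
            f"need >= 2 replicates per side, got ({n_inside}, {n_outside})"
        )
    if mean_inside <= 0 or mean_outside <= 0:
        raise InvalidArgumentError("means must be positive")
    power = 1 if method == "as_printed" else 2
    return sd_inside**2 / (n_inside * mean_inside**power) + sd_outside**2 / (
        n_outside * mean_outside**power
    )


def compute_effects(
    adjusted_pairs: pd.DataFrame,
    *,
    method: str = "as_printed",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Turn zero-adjusted paired summaries into an effect-size table.

    Expects the output of :func:`zero_adjust` joined with sd_inside,
    sd_outside, n_inside, n_outside (and region).  Y and v both use the
    adjusted means.  Rows with fewer than 2 replicates on a side are
    excluded with a reason rather than raising.  Returns
    ``(effects, exclusions)``.
    """
    ok = (adjusted_pairs["n_inside"] >= 2) & (adjusted_pairs["n_outside"] >= 2)
    exclusions = adjusted_pairs.loc[~ok].copy()
    exclusions["reason"] = "insufficient_replication"
    kept = adjusted_pairs.loc[ok]

    mi = kept["adj_mean_inside"].to_numpy(dtype=float)
    mo = kept["adj_mean_outside"].to_numpy(dtype=float)
    power = 1 if method == "as_printed" else 2
    v = kept["sd_inside"].to_numpy() ** 2 / (
        kept["n_inside"].to_numpy() * mi**power
    ) + kept["sd_outside"].to_numpy() ** 2 / (
        kept["n_outside"].to_numpy() * mo**power
    )

    cols = ["mpa_id", "ecosystem", "year", "status", "protection"]
    if "region" in kept.columns:
        cols.append("region")
    effects = kept[cols].copy()
    effects["Y"] = np.log(mi / mo)
    effects["v"] = v
    effects["variance_method"] = method
    effects["zero_variance"] = v == 0
    return effects.reset_index(drop=True), exclusions


def most_recent_filter(effects: pd.DataFrame) -> pd.DataFrame:
    """Keep, per (mpa_id, ecosystem, status), only the most recent year.

    Reflects the longest duration of protection when an MPA was surveyed
    repeatedly over time.
    """
    if effects.empty:
        return effects.copy()
    idx = effects.groupby(["mpa_id", "ecosystem", "status"])["year"].idxmax()
    return effects.loc[sorted(idx)].reset_index(drop=True)
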