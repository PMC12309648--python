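"""MPA-level species richness and Shannon diversity, and their inside/outside tests.

Richness and diversity are computed at the MPA level (abundances summed
across all replicate units of a given MPA, ecosystem, year and side)
because sampling is depth-stratified and replicate-level composition is
not comparable across units.  Each metric's inside/outside contrast is a
log response ratio with the same stratified zero-adjustment used for
biomass, and per-ecosystem significance comes from a two-tailed one-sample
t-test of the ratios against zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .effects import zero_adjust
from .exceptions import InsufficientReplicationError, InvalidArgumentError

__all__ = [
    "shannon",
    "mpa_level_metrics",
    "diversity_response",
    "ecosystem_ttest",
    "all_ecosystem_ttests",
]

METRICS = ("richness", "shannon")


def shannon(abundances) -> float:
    """Shannon diversity H = -sum(p_i * ln(p_i)) over species proportions."""
    a = np.asarray(abundances, dtype=float)
    a = a[a > 0]
    if a.size == 0:
        return 0.0
    return float(stats.entropy(a))  # normalises to proportions, natural log


def mpa_level_metrics(observations: pd.DataFrame) -> pd.DataFrame:
    """Richness and Shannon diversity per (mpa, ecosystem, year, side).

    Abundances are summed across replicates before computing the metrics.
    A side with zero total abundance gets richness 0 and H 0, flagged.
    """
    if observations.empty:
        raise InvalidArgumentError("observations table is empty")
    keys = ["mpa_id", "ecosystem", "year", "side"]
    totals = (
        observations.groupby(keys + ["species_id"])["count"].sum().reset_index()
    )
    grp = totals.groupby(keys)
    group_sum = grp["count"].transform("sum").to_numpy(dtype=float)
    counts = totals["count"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(group_sum > 0, counts / group_sum, 0.0)
        plogp = np.where(p > 0, -p * np.log(p), 0.0)
    totals["_plogp"] = plogp
    totals["_present"] = counts > 0
    out = totals.groupby(keys).agg(
        richness=("_present", "sum"), shannon=("_plogp", "sum"), total=("count", "sum")
    ).reset_index()
    out["richness"] = out["richness"].astype(int)
    out["empty"] = out["total"] <= 0
    return out.drop(columns="total")


def diversity_response(
    records: pd.DataFrame,
    protection: pd.DataFrame,
    *,
    zero_adjust_mode: str = "zero_pairs",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log response ratios of richness and diversity per MPA, ecosystem, year.

    ``records`` is the output of :func:`mpa_level_metrics`; ``protection``
    maps (mpa_id, ecosystem) or mpa_id to a protection level, needed for
    the zero-adjustment strata.  Returns ``(responses, exclusions)`` in
    long form with a ``metric`` column.
    """
    if "ecosystem" in protection.columns:
        rec = records.merge(protection, on=["mpa_id", "ecosystem"], how="left")
    else:
        rec = records.merge(protection, on="mpa_id", how="left")
    if rec["protection"].isna().any():
        missing = rec.loc[rec["protection"].isna(), "mpa_id"].unique().tolist()
        raise InvalidArgumentError(f"no protection level for MPAs: {missing}")

    keys = ["mpa_id", "ecosystem", "year", "protection"]
    responses, exclusions = [], []
    for metric in METRICS:
        wide = rec.pivot_table(
            index=keys, columns="side", values=metric, aggfunc="first"
        ).reset_index()
        wide = wide.dropna(subset=["inside", "outside"])
        pairs = wide.rename(
            columns={"inside": "mean_inside", "outside": "mean_outside"}
        )
        pairs["status"] = "all"  # diversity is not split by target status
        adjusted, _, excl = zero_adjust(pairs, mode=zero_adjust_mode)
        resp = adjusted[keys].copy()
        resp["metric"] = metric
        resp["Y"] = np.log(
            adjusted["adj_mean_inside"] / adjusted["adj_mean_outside"]
        )
        responses.append(resp)
        if not excl.empty:
            e = excl[keys].copy()
            e["metric"] = metric
            e["reason"] = excl["reason"].to_numpy()
            exclusions.append(e)
    out = pd.concat(responses, ignore_index=True)
    excl_out = (
        pd.concat(exclusions, ignore_index=True)
        if exclusions
        else pd.DataFrame(columns=keys + ["metric", "reason"])
    )
    return out, excl_out


def ecosystem_ttest(
    responses: pd.DataFrame,
    metric: str,
    ecosystem: str,
    *,
    most_recent_only: bool = True,
) -> dict:
    """Two-tailed one-sample t-test of one ecosystem's log response ratios.

    ``most_recent_only`` keeps one response per MPA (its latest surveyed
    year) to avoid pseudo-replication from repeated surveys.  A group with
    zero variance is flagged degenerate (t undefined) rather than raising.
    """
    grp = responses[
        (responses["metric"] == metric) & (responses["ecosystem"] == ecosystem)
    ]
    if most_recent_only and not grp.empty:
        idx = grp.groupby("mpa_id")["year"].idxmax()
        grp = grp.loc[sorted(idx)]
    y = grp["Y"].to_numpy(dtype=float)
    if y.size < 2:
        raise InsufficientReplicationError(
            f"need >= 2 responses for {metric}/{ecosystem}, got {y.size}"
        )
    degenerate = float(np.std(y, ddof=1)) == 0.0
    if degenerate:
        t, p = np.nan, np.nan
    else:
        t, p = stats.ttest_1samp(y, 0.0)
    return {
        "metric": metric,
        "ecosystem": ecosystem,
        "n": int(y.size),
        "mean_Y": float(np.mean(y)),
        "t": float(t),
        "df": int(y.size - 1),
        "p": float(p),
        "degenerate": degenerate,
    }


def all_ecosystem_ttests(
    responses: pd.DataFrame, *, most_recent_only: bool = True
) -> pd.DataFrame:
    """Run the per-ecosystem t-test for every metric x ecosystem with data."""
    rows = []
    for metric in METRICS:
        for eco in sorted(responses["ecosystem"].unique()):
            sub = responses[
                (responses["metric"] == metric) & (responses["ecosystem"] == eco)
            ]
            if len(sub) < 2:
                continue
            try:
                rows.append(
                    ecosystem_ttest(
                        responses, metric, eco, most_recent_only=most_recent_only
                    )
                )
            except InsufficientReplicationError:
                continue
    return pd.DataFrame(rows)
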