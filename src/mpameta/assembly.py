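"""Survey ingestion, species/protection classification, and biomass assembly.

Raw monitoring records arrive as one row per species within a replicate
sampling unit (a seine haul in the surf zone, a transect on kelp forest or
deep reef, a hook-and-line fishing cell on shallow reef), tagged by MPA,
ecosystem, year and side (inside the MPA or at its paired reference site).
This module

* classifies each species as targeted or nontargeted from fisheries catch
  volumes (two stages: any positive catch means targeted, then low-volume
  bycatch is reclassified nontargeted, then explicit overrides -- e.g.
  cryptic species that fishers target but catch records miss -- win);
* classifies each MPA x ecosystem as no-take or partial-take, treating an
  MPA as de facto no-take for an ecosystem when its allowed take cannot
  affect that ecosystem's resident species;
* converts fish lengths to weights with the allometric law W = a * L^b;
* aggregates biomass per replicate unit and target status, writing
  explicit zero rows so that replicate means include true zeros;
* summarises each (MPA, ecosystem, year, status) into paired inside /
  outside means, sample standard deviations (n - 1 denominator) and
  replicate counts.

Expected CSV schemas are documented in the reader functions.
"""

from __future__ import annotations

from collections.abc import Mapping
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError, MissingDataError

__all__ = [
    "classify_target_status",
    "classify_protection",
    "classify_protection_table",
    "length_to_weight",
    "parse_lengths",
    "encode_lengths",
    "aggregate_replicate_biomass",
    "summarize_pairs",
    "read_surveys",
    "read_species",
    "read_mpas",
    "read_regulations",
]

ECOSYSTEMS = ("surf_zone", "kelp_forest", "shallow_reef", "deep_reef")
SIDES = ("inside", "outside")
STATUSES = ("targeted", "nontargeted")


# ---------------------------------------------------------------------------
# readers

def read_surveys(path: str | Path) -> pd.DataFrame:
    """surveys.csv: mpa_id, ecosystem, year, side, replicate_id, species_id,
    count, lengths (semicolon-separated cm values, empty when not recorded)."""
    df = pd.read_csv(path, dtype={"lengths": "string"})
    df["lengths"] = df["lengths"].fillna("")
    return df


def read_species(path: str | Path) -> pd.DataFrame:
    """species.csv: species_id, lw_a, lw_b, mean_length_cm, annual_catch, ..."""
    return pd.read_csv(path)


def read_mpas(path: str | Path) -> pd.DataFrame:
    """mpas.csv: mpa_id, region, protection, implementation_year and the
    eight feature columns."""
    return pd.read_csv(path)


def read_regulations(path: str | Path) -> pd.DataFrame:
    """regulations.csv: mpa_id, ecosystem, allows_take, take_affects_ecosystem."""
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# classification

def classify_target_status(
    catch: pd.DataFrame | Mapping[str, float],
    bycatch_threshold: float = 0.0,
    overrides: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Two-stage target-status classification from fisheries catch volumes.

    Species with positive catch are targeted unless their volume is at or
    below ``bycatch_threshold`` (low-volume bycatch, reclassified
    nontargeted).  ``overrides`` are applied last and win, which is how
    cryptic targeted species absent from catch records are re-included.
    """
    if isinstance(catch, Mapping):
        catch = pd.DataFrame(
            {"species_id": list(catch), "annual_catch": list(catch.values())}
        )
    if (catch["annual_catch"] < 0).any():
        bad = catch.loc[catch["annual_catch"] < 0, "species_id"].tolist()
        raise InvalidArgumentError(f"negative annual catch for species: {bad}")
    status = {
        str(row.species_id): (
            "targeted" if row.annual_catch > bycatch_threshold else "nontargeted"
        )
        for row in catch.itertuples()
    }
    for sid, st in (overrides or {}).items():
        if st not in STATUSES:
            raise InvalidArgumentError(f"override status {st!r} for {sid}")
        status[str(sid)] = st
    return status


def classify_protection(
    mpa_id: str, ecosystem: str, regulations: pd.DataFrame
) -> str:
    """Protection level of one MPA for one ecosystem: no_take or partial_take.

    Formal no-take designations (no take allowed at all) are no_take.  An
    MPA that allows some take is still treated as de facto no_take for an
    ecosystem when that take is flagged as not affecting the ecosystem's
    resident species (e.g. salmon take does not touch reef residents).
    """
    row = regulations[
        (regulations["mpa_id"] == mpa_id) & (regulations["ecosystem"] == ecosystem)
    ]
    if row.empty:
        raise MissingDataError(
            f"no regulation row for MPA {mpa_id!r} x ecosystem {ecosystem!r}"
        )
    row = row.iloc[0]
    if not bool(row["allows_take"]):
        return "no_take"
    return "no_take" if not bool(row["take_affects_ecosystem"]) else "partial_take"


def classify_protection_table(regulations: pd.DataFrame) -> pd.DataFrame:
    """Vectorised protection classification for a whole regulations table."""
    out = regulations[["mpa_id", "ecosystem"]].copy()
    allows = regulations["allows_take"].astype(bool)
    affects = regulations["take_affects_ecosystem"].astype(bool)
    out["protection"] = np.where(allows & affects, "partial_take", "no_take")
    return out


# ---------------------------------------------------------------------------
# biomass

def length_to_weight(length_cm, lw_a, lw_b):
    """Allometric length-weight conversion W = a * L^b (grams for cm input)."""
    length_cm = np.asarray(length_cm, dtype=float)
    lw_a = np.asarray(lw_a, dtype=float)
    lw_b = np.asarray(lw_b, dtype=float)
    if np.any(length_cm <= 0) or np.any(lw_a <= 0) or np.any(lw_b <= 0):
        raise InvalidArgumentError("length, lw_a and lw_b must all be positive")
    out = lw_a * length_cm**lw_b
    return float(out) if out.ndim == 0 else out


def parse_lengths(encoded: str) -> np.ndarray:
    """Decode a semicolon-separated lengths field into an array of cm values."""
    if not encoded or (isinstance(encoded, float) and np.isnan(encoded)):
        return np.empty(0)
    return np.fromiter((float(t) for t in str(encoded).split(";")), dtype=float)


def encode_lengths(lengths) -> str:
    return ";".join(f"{x:.12g}" for x in np.asarray(lengths, dtype=float))


def aggregate_replicate_biomass(
    observations: pd.DataFrame,
    species: pd.DataFrame,
    status_map: Mapping[str, str],
) -> pd.DataFrame:
    """Sum fish weights per replicate unit and target status.

    Every individual with a recorded length contributes a * L^b grams;
    counts without individual lengths fall back to the species' configured
    mean length (``mean_length_cm`` in the species table).  Replicates with
    no fish of a status get an explicit zero row, so downstream replicate
    means include true zeros.
    """
    obs = observations
    sp = species.set_index(species["species_id"].astype(str))
    unknown = set(obs["species_id"].astype(str)) - set(sp.index)
    missing_status = set(obs["species_id"].astype(str)) - set(status_map)
    offenders = sorted(unknown | missing_status)
    if offenders:
        raise MissingDataError(
            f"species without length-weight parameters or status: {offenders}"
        )

    sid = obs["species_id"].astype(str)
    a = sp["lw_a"].reindex(sid).to_numpy(dtype=float)
    b = sp["lw_b"].reindex(sid).to_numpy(dtype=float)
    mean_len = sp["mean_length_cm"].reindex(sid).to_numpy(dtype=float)
    counts = obs["count"].to_numpy()
    lengths_col = obs["lengths"].to_numpy() if "lengths" in obs.columns else None

    biomass = np.zeros(len(obs))
    for i in range(len(obs)):
        if counts[i] == 0:
            continue
        lens = parse_lengths(lengths_col[i]) if lengths_col is not None else np.empty(0)
        if lens.size:
            if lens.size != counts[i]:
                raise InvalidArgumentError(
                    f"row {obs.index[i]}: {lens.size} lengths for count {counts[i]}"
                )
            biomass[i] = float(np.sum(a[i] * lens ** b[i]))
        else:
            biomass[i] = counts[i] * a[i] * mean_len[i] ** b[i]

    work = obs[["mpa_id", "ecosystem", "year", "side", "replicate_id"]].copy()
    work["status"] = sid.map(status_map).to_numpy()
    work["biomass"] = biomass

    keys = ["mpa_id", "ecosystem", "year", "side", "replicate_id"]
    agg = work.groupby(keys + ["status"], sort=True)["biomass"].sum()
    replicates = work[keys].drop_duplicates()
    full = pd.MultiIndex.from_frame(
        replicates.merge(pd.DataFrame({"status": list(STATUSES)}), how="cross")
    )
    agg = agg.reindex(full, fill_value=0.0)
    return agg.rename("biomass").reset_index()


def summarize_pairs(
    replicate_biomass: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired inside/outside summaries per (MPA, ecosystem, year, status).

    Means, sample SDs (n - 1 denominator) and replicate counts per side.
    A single replicate leaves the SD undefined; it is recorded as 0 with
    ``sd_undefined`` flagged.  Groups missing a side entirely go to the
    exclusion table instead of being silently dropped.

    Returns ``(pairs, exclusions)``.
    """
    keys = ["mpa_id", "ecosystem", "year", "status"]
    g = replicate_biomass.groupby(keys + ["side"])["biomass"]
    summary = g.agg(mean="mean", sd="std", n="count").reset_index()
    summary["sd_undefined"] = summary["sd"].isna() & (summary["n"] == 1)
    summary["sd"] = summary["sd"].fillna(0.0)

    wide = summary.pivot(index=keys, columns="side")
    means = wide["mean"].reindex(columns=list(SIDES))
    sds = wide["sd"].reindex(columns=list(SIDES))
    ns = wide["n"].reindex(columns=list(SIDES))
    flags = wide["sd_undefined"].reindex(columns=list(SIDES))

    pairs = pd.DataFrame(
        {
            "mean_inside": means["inside"],
            "mean_outside": means["outside"],
            "sd_inside": sds["inside"],
            "sd_outside": sds["outside"],
            "n_inside": ns["inside"],
            "n_outside": ns["outside"],
            "sd_undefined": flags.eq(True).any(axis=1),
        },
        index=wide.index,
    ).reset_index()

    missing_side = means.isna().any(axis=1).to_numpy()
    exclusions = pairs.loc[missing_side, keys].copy()
    exclusions["reason"] = "missing_side"
    pairs = pairs.loc[~missing_side].copy()
    pairs[["n_inside", "n_outside"]] = pairs[["n_inside", "n_outside"]].astype(int)
    return pairs.reset_index(drop=True), exclusions.reset_index(drop=True)
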