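"""Synthetic paired MPA/reference survey generator with known ground truth.

Emulates the structure of a coastal MPA monitoring program: four regions,
four ecosystems (surf zone, kelp forest, shallow reef, deep reef), paired
inside/outside sites, replicate sampling units with per-species counts and
individual body lengths, targeted vs. nontargeted species, and no-take vs.
partial-take protection.  The protection effect on targeted abundance is

    effect(mpa, year) = beta0 + beta_age * age + beta_habdiv * habitat_diversity
                        + u_mpa,     u_mpa ~ Normal(0, sigma_between),

so the true effect grows with MPA age and habitat diversity.  Nontargeted
species respond with an attenuated multiple of the same effect (they feel
protection only indirectly).  Replicate counts are negative-binomial
(survey counts are overdispersed); inside means are the outside means
times exp(effect).  Body lengths are lognormal per species, identical
inside and outside by default (effects act on abundance), with an optional
inside length-shift knob.  Gear quirks are honoured: hook-and-line on the
shallow reef has zero catchability for nontargeted species, so they never
appear there.  Outside replicates are occasionally all-zero, as happens at
heavily fished reference sites.

All randomness flows from the single ``seed``: each stage draws from
``numpy.random.default_rng([seed, stage])`` with stage 0 = species pool,
1 = network, 2 = surveys, in that documented order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assembly import ECOSYSTEMS, encode_lengths
from .exceptions import InvalidArgumentError

__all__ = [
    "SpeciesSpec",
    "SimConfig",
    "generate_species_pool",
    "generate_network",
    "simulate_surveys",
    "species_to_frame",
    "write_tables",
    "LW_A_RANGE",
    "LW_B_RANGE",
    "MEDIAN_LENGTH_RANGE",
]

REGIONS = ("north", "north_central", "central", "south")

# Draw bounds for species parameters; recorded in the JSON sidecar.
LW_A_RANGE = (0.005, 0.05)  # log-uniform, weight in g for length in cm
LW_B_RANGE = (2.5, 3.5)  # uniform allometric exponent
MEDIAN_LENGTH_RANGE = (8.0, 40.0)  # uniform, cm
LENGTH_CV = 0.2
CATCHABILITY_RANGE = (0.3, 0.9)


@dataclass
class SpeciesSpec:
    """One simulated species: allometry, fishery status, and gear catchability."""

    species_id: str
    lw_a: float
    lw_b: float
    targeted_truth: bool
    annual_catch: float
    gear_catchability: dict[str, float]
    median_length_cm: float
    length_cv: float = LENGTH_CV
    #: mean count per replicate unit at a reference (outside) site, per ecosystem
    baseline_abundance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.lw_a <= 0 or self.lw_b <= 0:
            raise InvalidArgumentError("length-weight parameters must be positive")
        if not self.targeted_truth and self.gear_catchability.get("shallow_reef", 0):
            raise InvalidArgumentError(
                "hook-and-line sampling cannot catch nontargeted species"
            )


@dataclass
class SimConfig:
    """Study conditions for one simulated monitoring program."""

    n_mpas: int = 50
    n_species: int = 24
    years: tuple[int, ...] = (2017, 2018, 2019)
    regions: tuple[str, ...] = REGIONS
    ecosystems: tuple[str, ...] = ECOSYSTEMS
    beta0: float = 0.2  # baseline log effect for targeted species
    beta_age: float = 0.03  # per-year growth of the true effect
    beta_habdiv: float = 0.3  # per unit Shannon habitat-diversity index
    sigma_between: float = 0.2  # between-MPA SD of the true effect
    nontargeted_attenuation: float = 0.25
    replicate_count_range: tuple[int, int] = (4, 8)
    dispersion: float = 1.5  # negative-binomial shape; var = mu + mu^2/dispersion
    zero_inflation_outside: float = 0.05
    ecosystem_coverage: float = 0.7  # P(an MPA is sampled in an ecosystem)
    prop_no_take: float = 0.7
    implementation_year_range: tuple[int, int] = (2000, 2012)
    inside_length_shift: float = 0.0  # log-scale shift of inside body lengths
    seed: int = 0

    def validate(self) -> None:
        if self.n_mpas < 1 or self.n_species < 2:
            raise InvalidArgumentError("need n_mpas >= 1 and n_species >= 2")
        if len(self.regions) != 4 or len(self.ecosystems) != 4:
            raise InvalidArgumentError("exactly 4 regions and 4 ecosystems expected")
        for p in (
            self.zero_inflation_outside,
            self.ecosystem_coverage,
            self.prop_no_take,
        ):
            if not 0 <= p <= 1:
                raise InvalidArgumentError(f"probability {p} outside [0, 1]")
        if self.sigma_between < 0 or self.dispersion <= 0:
            raise InvalidArgumentError("sigma_between >= 0 and dispersion > 0 required")
        lo, hi = self.replicate_count_range
        if lo < 2 or hi < lo:
            raise InvalidArgumentError(
                "replicate_count_range minimum must be >= 2 (variance needs n >= 2)"
            )
        if not self.years:
            raise InvalidArgumentError("at least one survey year required")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stage])


def generate_species_pool(n_species: int, seed: int) -> list[SpeciesSpec]:
    """Draw a species pool with at least one targeted and one nontargeted species.

    lw_a is log-uniform on LW_A_RANGE, lw_b uniform on LW_B_RANGE; targeted
    species get positive simulated landings, nontargeted species none.
    Deterministic for a fixed seed.
    """
    if n_species < 2:
        raise InvalidArgumentError("n_species must be >= 2")
    rng = _rng(seed, 0)
    targeted = rng.random(n_species) < 0.5
    targeted[0], targeted[1] = True, False  # force both statuses to exist

    lw_a = np.exp(rng.uniform(np.log(LW_A_RANGE[0]), np.log(LW_A_RANGE[1]), n_species))
    lw_b = rng.uniform(*LW_B_RANGE, n_species)
    med_len = rng.uniform(*MEDIAN_LENGTH_RANGE, n_species)
    catch = np.where(targeted, np.exp(rng.normal(4.0, 1.0, n_species)), 0.0)

    pool = []
    for i in range(n_species):
        catchability = {
            eco: float(rng.uniform(*CATCHABILITY_RANGE)) for eco in ECOSYSTEMS
        }
        if not targeted[i]:
            catchability["shallow_reef"] = 0.0  # hook-and-line gear quirk
        abundance = {
            eco: float(np.exp(rng.normal(np.log(4.0), 0.6)) * catchability[eco])
            for eco in ECOSYSTEMS
        }
        pool.append(
            SpeciesSpec(
                species_id=f"sp{i:03d}",
                lw_a=float(lw_a[i]),
                lw_b=float(lw_b[i]),
                targeted_truth=bool(targeted[i]),
                annual_catch=float(catch[i]),
                gear_catchability=catchability,
                median_length_cm=float(med_len[i]),
                baseline_abundance=abundance,
            )
        )
    return pool


def true_effect(
    config: SimConfig, implementation_year, habitat_diversity, u_mpa, year
):
    """Ground-truth log effect on targeted abundance for an MPA in a year."""
    age = np.maximum(np.asarray(year) - np.asarray(implementation_year), 0)
    return (
        config.beta0
        + config.beta_age * age
        + config.beta_habdiv * np.asarray(habitat_diversity)
        + np.asarray(u_mpa)
    )


def generate_network(config: SimConfig) -> pd.DataFrame:
    """Draw the MPA network: regions, protection, and the eight features.

    The recorded ``true_effect_targeted`` is evaluated at the latest survey
    year; ``u_mpa`` is stored so per-year effects can be reconstructed.
    """
    config.validate()
    rng = _rng(config.seed, 1)
    n = config.n_mpas
    ref_year = max(config.years)

    region = np.asarray(config.regions)[rng.integers(0, 4, n)]
    protection = np.where(
        rng.random(n) < config.prop_no_take, "no_take", "partial_take"
    )
    impl = rng.integers(
        config.implementation_year_range[0],
        config.implementation_year_range[1] + 1,
        n,
    )
    habdiv = rng.uniform(0.3, 2.2, n)
    u = rng.normal(0.0, config.sigma_between, n)
    eff_t = true_effect(config, impl, habdiv, u, ref_year)

    return pd.DataFrame(
        {
            "mpa_id": [f"mpa{i:03d}" for i in range(n)],
            "region": region,
            "protection": protection,
            "implementation_year": impl,
            "size_km2": np.exp(rng.normal(np.log(10.0), 0.6, n)),
            "habitat_diversity": habdiv,
            "habitat_richness": rng.integers(1, 9, n),
            "prop_rock": rng.uniform(0.0, 1.0, n),
            "pre_landings": np.exp(rng.normal(np.log(50.0), 0.8, n)),
            "settlement_ecosystem": np.exp(rng.normal(0.0, 0.5, n)),
            "settlement_total": np.exp(rng.normal(1.0, 0.5, n)),
            "age": ref_year - impl,
            "u_mpa": u,
            "true_effect_targeted": eff_t,
            "true_effect_nontargeted": config.nontargeted_attenuation * eff_t,
        }
    )


def simulate_surveys(
    network: pd.DataFrame, species: list[SpeciesSpec], config: SimConfig
) -> pd.DataFrame:
    """Simulate replicate-level paired survey observations.

    For each sampled MPA x ecosystem x year x side a random number of
    replicate units is drawn; within each, per-species counts are
    negative-binomial with inside mean = outside mean x exp(true effect)
    (attenuated for nontargeted species; no effect in partial-take MPAs).
    All-zero replicates are registered with a single count-0 row so that
    downstream replicate means include true zeros.
    """
    if network.empty or not species:
        raise InvalidArgumentError("network and species pool must be non-empty")
    config.validate()
    rng = _rng(config.seed, 2)
    lo, hi = config.replicate_count_range
    disp = config.dispersion

    sp_abund = {
        eco: np.array([s.baseline_abundance.get(eco, 0.0) for s in species])
        for eco in config.ecosystems
    }
    sp_med = np.array([s.median_length_cm for s in species])
    sp_sigma = np.array([np.sqrt(np.log(1 + s.length_cv**2)) for s in species])
    sp_targeted = np.array([s.targeted_truth for s in species])
    sp_ids = np.array([s.species_id for s in species])

    rows: list[tuple] = []
    for mpa in network.itertuples():
        sampled = [
            eco for eco in config.ecosystems if rng.random() < config.ecosystem_coverage
        ]
        if not sampled:  # every MPA is monitored by at least one group
            sampled = [config.ecosystems[rng.integers(0, 4)]]
        protected = mpa.protection == "no_take"
        for eco in sampled:
            base = sp_abund[eco]
            present = base > 0
            for year in config.years:
                eff = true_effect(
                    config, mpa.implementation_year, mpa.habitat_diversity,
                    mpa.u_mpa, year,
                )
                mult = np.where(
                    sp_targeted, np.exp(eff), np.exp(config.nontargeted_attenuation * eff)
                ) if protected else np.ones(len(species))
                for side in ("inside", "outside"):
                    mu_all = base * (mult if side == "inside" else 1.0)
                    n_reps = int(rng.integers(lo, hi + 1))
                    for rep in range(n_reps):
                        rep_id = f"{mpa.mpa_id}_{eco}_{year}_{side}_r{rep}"
                        zeroed = (
                            side == "outside"
                            and rng.random() < config.zero_inflation_outside
                        )
                        if zeroed:
                            counts = np.zeros(len(species), dtype=int)
                        else:
                            mu = mu_all[present]
                            counts = np.zeros(len(species), dtype=int)
                            counts[present] = rng.negative_binomial(
                                disp, disp / (disp + mu)
                            )
                        nz = np.nonzero(counts)[0]
                        if nz.size == 0:
                            # register the empty replicate explicitly
                            rows.append(
                                (mpa.mpa_id, eco, year, side, rep_id, sp_ids[0], 0, "")
                            )
                            continue
                        shift = (
                            config.inside_length_shift if side == "inside" else 0.0
                        )
                        for j in nz:
                            lens = rng.lognormal(
                                np.log(sp_med[j]) + shift, sp_sigma[j], counts[j]
                            )
                            rows.append(
                                (
                                    mpa.mpa_id,
                                    eco,
                                    year,
                                    side,
                                    rep_id,
                                    sp_ids[j],
                                    int(counts[j]),
                                    encode_lengths(lens),
                                )
                            )
    return pd.DataFrame(
        rows,
        columns=[
            "mpa_id",
            "ecosystem",
            "year",
            "side",
            "replicate_id",
            "species_id",
            "count",
            "lengths",
        ],
    )


def species_to_frame(species: list[SpeciesSpec]) -> pd.DataFrame:
    """Flatten the species pool to the species.csv schema."""
    rows = []
    for s in species:
        row = {
            "species_id": s.species_id,
            "lw_a": s.lw_a,
            "lw_b": s.lw_b,
            "targeted_truth": s.targeted_truth,
            "annual_catch": s.annual_catch,
            "mean_length_cm": s.median_length_cm,
            "length_cv": s.length_cv,
        }
        for eco in ECOSYSTEMS:
            row[f"catchability_{eco}"] = s.gear_catchability.get(eco, 0.0)
            row[f"abundance_{eco}"] = s.baseline_abundance.get(eco, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def write_tables(
    outdir: str | Path,
    species: list[SpeciesSpec],
    network: pd.DataFrame,
    surveys: pd.DataFrame,
    config: SimConfig,
) -> dict[str, str]:
    """Write species.csv, mpas.csv, surveys.csv and a JSON ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "species": outdir / "species.csv",
        "mpas": outdir / "mpas.csv",
        "surveys": outdir / "surveys.csv",
        "truth": outdir / "truth.json",
    }
    species_to_frame(species).to_csv(paths["species"], index=False)
    network.to_csv(paths["mpas"], index=False)
    surveys.to_csv(paths["surveys"], index=False)
    sidecar = {
        "config": config.to_dict(),
        "draw_bounds": {
            "lw_a": LW_A_RANGE,
            "lw_b": LW_B_RANGE,
            "median_length_cm": MEDIAN_LENGTH_RANGE,
        },
        "true_effects": network.set_index("mpa_id")[
            ["true_effect_targeted", "true_effect_nontargeted"]
        ].to_dict(orient="index"),
    }
    paths["truth"].write_text(json.dumps(sidecar, indent=2, default=float))
    return {k: str(v) for k, v in paths.items()}
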