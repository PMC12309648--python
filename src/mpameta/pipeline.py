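"""End-to-end pipeline: simulate -> assemble -> effects -> pool -> diversity -> GAM.

One :class:`PipelineConfig` drives the whole analysis; a run writes every
stage's CSV output plus a JSON manifest (config hash, seed, per-stage row
counts) to the output directory.  Identical config and seed give
byte-identical outputs.

Replicate biomass is assembled in grams (lengths in cm with W = a * L^b)
and converted to kilograms before pairing: the within-study variance in
its printed form is not scale-invariant, and kilograms keep replicate
means of order one so the meta-analytic weights are on a sensible scale.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .assembly import (
    aggregate_replicate_biomass,
    classify_target_status,
    read_mpas,
    read_species,
    read_surveys,
    summarize_pairs,
)
from .biodiversity import all_ecosystem_ttests, diversity_response, mpa_level_metrics
from .effects import compute_effects, most_recent_filter, zero_adjust
from .exceptions import InvalidArgumentError
from .gam import build_model_frame, forward_select_gcv
from .pooling import SCALES, pool_at_scale
from .synthetic import (
    SimConfig,
    generate_network,
    generate_species_pool,
    simulate_surveys,
    write_tables,
)

logger = logging.getLogger("mpameta")

GRAMS_PER_KG = 1000.0


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run, serialisable to/from YAML."""

    outdir: str = "mpameta_out"
    seed: int = 0
    simulate: bool = True
    surveys_path: str | None = None
    species_path: str | None = None
    mpas_path: str | None = None
    zero_adjust_mode: str = "zero_pairs"
    variance_method: str = "as_printed"
    bycatch_threshold: float = 0.0
    status_overrides: dict = field(default_factory=dict)
    ttest_most_recent: bool = True
    gam_basis_dim: int = 5
    gam_rel_tol: float = 1e-2
    alpha: float = 0.05
    use_t: bool = False
    sim: SimConfig = field(default_factory=SimConfig)

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise InvalidArgumentError("alpha must be in (0, 1)")
        if not self.simulate:
            for name in ("surveys_path", "species_path", "mpas_path"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise InvalidArgumentError(
                        f"simulate is off and {name} is missing or does not "
                        f"exist: {path!r}"
                    )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            sim = {
                k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()
            }
            sim = SimConfig(**sim)
        return cls(sim=sim, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _config_hash(config: PipelineConfig) -> str:
    d = config.to_dict()
    d.pop("outdir")  # where outputs land is not part of the analysis identity
    payload = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, outdir: Path, name: str, manifest: dict) -> None:
    path = outdir / name
    df.to_csv(path, index=False)
    manifest["outputs"][name] = len(df)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "outputs": {},
    }

    # --- stage 1: inputs -------------------------------------------------
    if config.simulate:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        species_pool = generate_species_pool(sim.n_species, sim.seed)
        network = generate_network(sim)
        surveys = simulate_surveys(network, species_pool, sim)
        paths = write_tables(outdir, species_pool, network, surveys, sim)
        species = read_species(paths["species"])
        mpas = network
        for name in ("species.csv", "mpas.csv", "surveys.csv"):
            manifest["outputs"][name] = {
                "species.csv": len(species),
                "mpas.csv": len(mpas),
                "surveys.csv": len(surveys),
            }[name]
        logger.info("simulated %d survey rows for %d MPAs", len(surveys), len(mpas))
    else:
        surveys = read_surveys(config.surveys_path)
        species = read_species(config.species_path)
        mpas = read_mpas(config.mpas_path)

    # --- stage 2: assembly ------------------------------------------------
    status_map = classify_target_status(
        species[["species_id", "annual_catch"]],
        bycatch_threshold=config.bycatch_threshold,
        overrides=config.status_overrides,
    )
    replicate_biomass = aggregate_replicate_biomass(surveys, species, status_map)
    replicate_biomass["biomass"] = replicate_biomass["biomass"] / GRAMS_PER_KG
    pairs, pair_excl = summarize_pairs(replicate_biomass)
    protection = mpas[["mpa_id", "protection"]]
    pairs = pairs.merge(protection, on="mpa_id", how="left").merge(
        mpas[["mpa_id", "region"]], on="mpa_id", how="left"
    )
    _write(pairs, outdir, "paired_summaries.csv", manifest)
    logger.info("assembled %d paired summaries (%d excluded)", len(pairs), len(pair_excl))

    # --- stage 3: effect sizes ---------------------------------------------
    adjusted, constants, zero_excl = zero_adjust(pairs, mode=config.zero_adjust_mode)
    effects_annual, var_excl = compute_effects(adjusted, method=config.variance_method)
    exclusions = pd.concat(
        [pair_excl, zero_excl, var_excl], ignore_index=True, sort=False
    )
    effects = most_recent_filter(effects_annual)
    _write(constants, outdir, "constants.csv", manifest)
    _write(exclusions, outdir, "exclusions.csv", manifest)
    _write(effects_annual, outdir, "effects_annual.csv", manifest)
    _write(effects, outdir, "effects.csv", manifest)
    logger.info(
        "computed %d annual effects, %d most-recent (%d excluded)",
        len(effects_annual), len(effects), len(exclusions),
    )

    # --- stage 4: pooling ---------------------------------------------------
    pooled = pd.concat(
        [
            pool_at_scale(effects, scale, alpha=config.alpha, use_t=config.use_t)
            for scale in SCALES
        ],
        ignore_index=True,
        sort=False,
    )
    _write(pooled, outdir, "pooled.csv", manifest)

    # --- stage 5: biodiversity -----------------------------------------------
    records = mpa_level_metrics(surveys)
    records = records.merge(protection, on="mpa_id", how="left")
    responses, div_excl = diversity_response(
        records.drop(columns=["protection"]),
        protection,
        zero_adjust_mode=config.zero_adjust_mode,
    )
    tests = all_ecosystem_ttests(responses, most_recent_only=config.ttest_most_recent)
    _write(responses, outdir, "diversity.csv", manifest)
    _write(tests, outdir, "diversity_tests.csv", manifest)

    # --- stage 6: feature model -----------------------------------------------
    frame, dropped = build_model_frame(effects_annual, mpas)
    fit, trace = forward_select_gcv(
        frame, basis_dim=config.gam_basis_dim, rel_tol=config.gam_rel_tol
    )
    summary = pd.DataFrame(
        {
            "term": list(fit.edf),
            "edf": [fit.edf[t] for t in fit.edf],
            "p": [fit.term_p[t] for t in fit.edf],
        }
    )
    summary["gcv"] = fit.gcv
    summary["r2_adj"] = fit.r2_adj
    summary["n"] = fit.n
    partials = pd.concat(
        [df.assign(term=t) for t, df in fit.partials.items()], ignore_index=True
    )
    _write(summary, outdir, "gam_summary.csv", manifest)
    _write(partials, outdir, "partials.csv", manifest)
    _write(trace, outdir, "selection_trace.csv", manifest)
    logger.info(
        "GAM: %d rows, selected %s, r2_adj=%.3f",
        fit.n, fit.included_terms or "none", fit.r2_adj,
    )

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
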