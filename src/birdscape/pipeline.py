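"""End-to-end orchestration: synthesis → metrics → abundance → thresholds.

A pipeline run generates (or loads) a landscape series and survey data,
computes the landscape metrics per stop × buffer radius × raster date,
fits the hierarchical count model per taxon, and runs loess screening and
TITAN on the adjusted counts against every landscape variable at every
extent.  All outputs are plain CSV plus one JSON manifest; a second run
with the same configuration and seed is byte-identical apart from the
manifest's timestamps.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import (ConvergenceError, McmcConfig, adjusted_counts,
                        check_convergence, fit_abundance_model,
                        summarize_abundance)
from .landscape import (METRIC_COLUMNS, metrics_timeseries, summarize_metrics)
from .raster import read_ascii_grid, write_ascii_grid
from .synth import (SynthConfig, TaxonParams, default_taxa,
                    generate_counts, generate_landscape_series,
                    generate_survey_design)
from .titan import TitanConfig, classify_indicators, loess_screen, run_titan

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    output_dir: str = "out"
    seed: int = 0
    radii: tuple[float, ...] = (400.0, 1000.0)
    raster_match_rule: str = "nearest"  # or 'hold'
    titan_variables: tuple[str, ...] = tuple(METRIC_COLUMNS[:5] + METRIC_COLUMNS[6:])
    loess_span: float = 0.75
    loess_cutoff: float = 0.1
    synth: SynthConfig = field(default_factory=SynthConfig)
    taxa: dict[str, TaxonParams] = field(default_factory=default_taxa)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    titan: TitanConfig = field(default_factory=TitanConfig)
    # real-data inputs (synthetic mode when unset)
    counts_path: str | None = None
    stops_path: str | None = None
    raster_paths: dict[int, str] | None = None

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii):
            raise ValueError("radii must be positive")
        if self.raster_match_rule not in ("nearest", "hold"):
            raise ValueError("raster_match_rule must be 'nearest' or 'hold'")


def demo_config(seed: int = 0, output_dir: str = "out") -> PipelineConfig:
    """Reduced desk-scale scenario: 30 stops on 6 routes over 12 years,
    an 80×80-cell landscape with four raster dates, 200/400-m buffers,
    short MCMC and 100 permutations/bootstraps."""
    synth = SynthConfig(
        n_stops=30, n_routes=6, years=(1998, 2009),
        raster_dates=(1998, 2002, 2006, 2009), grid_size=80,
        initial_forest_fraction=0.55,
        exurban_growth_rates=(0.02, 0.03, 0.04, 0.05),
        forest_clearing_rates=(0.0, 0.02, 0.03, 0.03),
        observer_turnover_prob=0.25,
        min_spacing_m=250.0, route_margin_m=420.0, seed=seed,
    )
    taxa = {
        "FOR1": TaxonParams(beta0=-0.7, beta1=0.02, beta2=0.2,
                            response_var="forest_pct", response_radius=400.0,
                            response_cp=45.0, response_delta=1.5,
                            response_direction="+"),
        "FOR2": TaxonParams(beta0=-0.5, beta1=0.01, beta2=0.2,
                            response_var="forest_pct", response_radius=400.0,
                            response_cp=45.0, response_delta=1.5,
                            response_direction="+"),
        "EDG1": TaxonParams(beta0=-0.7, beta1=0.015, beta2=0.2,
                            response_var="forest_pct", response_radius=400.0,
                            response_cp=45.0, response_delta=1.5,
                            response_direction="-"),
        "EDG2": TaxonParams(beta0=-0.5, beta1=0.0, beta2=0.2,
                            response_var="forest_pct", response_radius=400.0,
                            response_cp=45.0, response_delta=1.5,
                            response_direction="-"),
        "NOIS": TaxonParams(beta0=-0.3, beta1=0.0, beta2=0.2),
    }
    return PipelineConfig(
        output_dir=output_dir, seed=seed, radii=(200.0, 400.0),
        synth=synth, taxa=taxa,
        mcmc=McmcConfig(n_chains=2, n_iterations=3000, n_burnin=1000,
                        thin=4, seed=seed),
        titan=TitanConfig(n_permutations=100, n_bootstrap=100, seed=seed),
    )


# ---------------------------------------------------------------------------
# configuration files


def config_to_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["taxa"] = {k: asdict(v) for k, v in config.taxa.items()}
    return d


def config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    if "synth" in d and isinstance(d["synth"], dict):
        for key in ("years", "raster_dates", "exurban_growth_rates",
                    "forest_clearing_rates"):
            if key in d["synth"]:
                d["synth"][key] = tuple(d["synth"][key])
        d["synth"] = SynthConfig(**d["synth"])
    if "taxa" in d:
        d["taxa"] = {k: TaxonParams(**v) if isinstance(v, dict) else v
                     for k, v in d["taxa"].items()}
    if "mcmc" in d and isinstance(d["mcmc"], dict):
        d["mcmc"] = McmcConfig(**d["mcmc"])
    if "titan" in d and isinstance(d["titan"], dict):
        if "cp_quantiles" in d["titan"]:
            d["titan"]["cp_quantiles"] = tuple(d["titan"]["cp_quantiles"])
        d["titan"] = TitanConfig(**d["titan"])
    for key in ("radii", "titan_variables"):
        if key in d:
            d[key] = tuple(d[key])
    return PipelineConfig(**d)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# year ↔ raster matching


def match_years_to_rasters(years, dates, rule: str = "nearest") -> dict[int, int]:
    """Map each survey year to a raster date.

    ``nearest`` takes the closest date, breaking ties toward the earlier
    date; ``hold`` keeps each classification until the next one (years
    before the first date map to the first).
    """
    dates = sorted(dates)
    if not dates:
        raise ValueError("need at least one raster date")
    out = {}
    for y in years:
        if rule == "hold":
            eligible = [d for d in dates if d <= y]
            out[int(y)] = int(eligible[-1] if eligible else dates[0])
        else:
            out[int(y)] = int(min(dates, key=lambda d: (abs(d - y), d)))
    return out


# ---------------------------------------------------------------------------
# stages


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all outputs under ``config.output_dir``.

    Returns the manifest dictionary.  Any stage error aborts with the
    stage name attached.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest = {
        "package": "birdscape", "version": __version__,
        "seed": config.seed, "config": config_to_dict(config),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {}, "warnings": [], "convergence": {},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    stage = "synth"
    try:
        # ------------------------------------------------ landscapes & design
        ts = time.time()
        if config.raster_paths:
            if not (config.counts_path and config.stops_path):
                raise ValueError(
                    "real-data mode needs counts_path and stops_path "
                    "alongside raster_paths")
            rasters = [read_ascii_grid(p, date=int(d))
                       for d, p in sorted(config.raster_paths.items())]
            stops = pd.read_csv(config.stops_path)
        else:
            synth_cfg = replace(config.synth, seed=config.synth.seed)
            rasters = generate_landscape_series(synth_cfg)
            stops, observers = generate_survey_design(synth_cfg)
            (out / "rasters").mkdir(exist_ok=True)
            for r in rasters:
                write_ascii_grid(r, out / "rasters" / f"landcover_{r.date}.asc")
            _write_csv(stops, out / "stops.csv")
            _write_csv(observers, out / "observers.csv")
        manifest["stages"]["synth"] = {
            "n_stops": len(stops), "n_rasters": len(rasters),
            "seconds": round(time.time() - ts, 2),
        }

        # ------------------------------------------------ landscape metrics
        stage = "metrics"
        ts = time.time()
        metrics = metrics_timeseries(rasters, stops, radii=config.radii)
        _write_csv(metrics, out / "metrics.csv")
        _write_csv(summarize_metrics(metrics), out / "metrics_summary.csv")
        manifest["stages"]["metrics"] = {
            "n_records": len(metrics), "seconds": round(time.time() - ts, 2),
        }

        # ------------------------------------------------ counts
        stage = "counts"
        ts = time.time()
        if config.counts_path:
            counts = pd.read_csv(config.counts_path)
            years = sorted(counts["year"].unique())
        else:
            years = config.synth.year_list
            year_to_date = match_years_to_rasters(
                years, [r.date for r in rasters], config.raster_match_rule)
            counts = generate_counts(stops, observers, metrics, config.taxa,
                                     seed=config.seed,
                                     year_to_date=year_to_date)
            _write_csv(counts, out / "counts.csv")
        year_to_date = match_years_to_rasters(
            years, [r.date for r in rasters], config.raster_match_rule)
        manifest["stages"]["counts"] = {
            "n_records": len(counts),
            "year_to_raster": {str(k): v for k, v in year_to_date.items()},
            "seconds": round(time.time() - ts, 2),
        }

        # ------------------------------------------------ abundance model
        stage = "abundance"
        ts = time.time()
        taxa = sorted(counts["taxon"].unique())
        mcmc_seeds = np.random.SeedSequence(config.seed).generate_state(
            len(taxa) + 1)[1:] % (2**31)
        adj_frames, summary_rows = [], []
        n_surveys = counts.groupby("taxon").size().max()
        for taxon, tseed in zip(taxa, mcmc_seeds):
            sub = counts[counts["taxon"] == taxon].reset_index(drop=True)
            # time to convergence varies by taxon: double the chain length
            # until the Gelman-Rubin gate passes (up to 3 extensions)
            mc = replace(config.mcmc, seed=int(tseed))
            for attempt in range(4):
                fit = fit_abundance_model(sub, mc)
                try:
                    report = check_convergence(fit)
                    break
                except ConvergenceError as err:
                    if attempt == 3:
                        raise
                    manifest["warnings"].append(
                        f"{taxon}: extending chains "
                        f"({mc.n_iterations} iterations): {err}")
                    mc = replace(mc,
                                 n_iterations=2 * mc.n_iterations,
                                 n_burnin=2 * mc.n_burnin,
                                 thin=2 * mc.thin)
            manifest["convergence"][taxon] = {
                "iterations": mc.n_iterations,
                **{k: round(v, 4) for k, v in report.items()}}
            adj = adjusted_counts(fit)
            adj.insert(0, "taxon", taxon)
            adj_frames.append(adj)
            detections = int((sub["count"] > 0).sum())
            row = summarize_abundance(fit, taxon)
            row["detections"] = detections
            row["pct_surveys"] = 100.0 * detections / n_surveys
            summary_rows.append(row)
        adj_all = pd.concat(adj_frames, ignore_index=True)
        _write_csv(adj_all, out / "adjusted_counts.csv")
        summary = pd.DataFrame(summary_rows)
        lead = ["taxon", "detections", "pct_surveys",
                "mean_adjusted_abundance", "sd_adjusted_abundance"]
        summary = summary[lead + [c for c in summary.columns if c not in lead]]
        _write_csv(summary, out / "abundance_summary.csv")
        manifest["stages"]["abundance"] = {
            "n_taxa": len(taxa), "seconds": round(time.time() - ts, 2),
        }

        # ------------------------------------------------ threshold analysis
        stage = "thresholds"
        ts = time.time()
        titan_frames, screen_rows, indicator_frames = [], [], []
        adj_mean = adj_all.pivot_table(index=["stop", "year"],
                                       columns="taxon", values="mean")
        titan_seeds = np.random.SeedSequence([config.seed, 7]).generate_state(
            len(config.radii) * len(config.titan_variables)) % (2**31)
        si = 0
        for radius in config.radii:
            m = metrics[np.isclose(metrics["radius_m"], radius)]
            m = m.set_index(["stop", "date"])
            for var in config.titan_variables:
                x = np.array([
                    m.loc[(s, year_to_date[y]), var]
                    for s, y in adj_mean.index
                ])
                samples = adj_mean.reset_index(drop=True).copy()
                samples[var] = x
                if np.ptp(x) == 0:
                    manifest["warnings"].append(
                        f"constant gradient {var}@{radius:g}; skipped")
                    si += 1
                    continue
                for taxon in taxa:
                    scr = loess_screen(x, samples[taxon].to_numpy(),
                                       span=config.loess_span,
                                       cutoff=config.loess_cutoff)
                    screen_rows.append({
                        "taxon": taxon, "variable": var, "extent": radius,
                        "score": scr["score"], "nonlinear": scr["nonlinear"],
                    })
                rng = np.random.default_rng(int(titan_seeds[si]))
                si += 1
                res = run_titan(samples, var, taxa, config.titan,
                                extent=radius, rng=rng)
                titan_frames.append(res)
                indicator_frames.append(classify_indicators(res, config.titan))
        titan_all = pd.concat(titan_frames, ignore_index=True)
        _write_csv(titan_all, out / "titan_results.csv")
        _write_csv(pd.DataFrame(screen_rows), out / "loess_screen.csv")
        _write_csv(pd.concat(indicator_frames, ignore_index=True),
                   out / "indicators.csv")
        manifest["stages"]["thresholds"] = {
            "n_results": len(titan_all), "seconds": round(time.time() - ts, 2),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest["total_seconds"] = round(time.time() - t0, 2)
    manifest["checksums"] = {
        p.name: _checksum(p) for p in sorted(out.glob("*.csv"))
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
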