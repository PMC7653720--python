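"""End-to-end orchestration: simulate -> segment -> metrics -> models ->
home ranges -> overlap, with a reproducible run manifest.

Every stage is a pure function of (inputs, config, seed); identical
resolved configs produce identical outputs. A failed stage aborts the
run with a stage-named error and removes the partial output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, geo, growth, lmm, overlap, repeatability, trips
from .homerange import akde, fit_ou, isopleths_geojson
from .simulate import (SimulationConfig, simulate_adult_masses,
                       simulate_growth, simulate_tracks)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 1
    min_trip_duration_min: float = 30.0
    min_trip_distance_km: float = 1.0
    local_utc_offset: float = 2.0
    n_boot_repeatability: int = 200
    n_boot_overlap: int = 0          # 0 disables overlap CIs
    cell_km: float = 1.0             # AKDE grid cell
    homerange_birds_per_group: int = 4
    sim: dict = field(default_factory=dict)   # SimulationConfig overrides

    def __post_init__(self):
        if self.min_trip_duration_min <= 0 or self.min_trip_distance_km <= 0:
            raise ValueError("trip filter thresholds must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def resolved(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {str(k): clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj

        d = clean(asdict(self))
        sim = SimulationConfig(seed=self.seed, **self.sim)
        d["sim_resolved"] = {k: (list(v) if isinstance(v, tuple) else v)
                             for k, v in asdict(sim).items()
                             if not isinstance(v, dict)}
        return d


def demo_config(seed: int = 1) -> RunConfig:
    """A small configuration that runs end-to-end in a few minutes."""
    return RunConfig(seed=seed, n_boot_repeatability=200,
                     homerange_birds_per_group=3,
                     sim={"n_birds_per_group": {"zb_zb": 6, "vl_vl": 5,
                                                "zb_vl": 5},
                          "n_days": 10,
                          "nests_per_group_brood": {("vl_vl", 1): 12,
                                                    ("vl_vl", 3): 14,
                                                    ("zb_vl", 1): 9,
                                                    ("zb_vl", 3): 8}})


def analyse_adult_mass(adults: pd.DataFrame) -> dict:
    """Linear model of male body mass on origin, with Tukey HSD."""
    fit = lmm.fit_lmm("mass_g ~ origin", adults.reset_index(drop=True))
    return {"fit": fit,
            "terms": lmm.term_table(fit),
            "means": lmm.group_means(fit, "origin"),
            "tukey": lmm.tukey_pairwise(fit, "origin")}


def run_all(config: RunConfig, outdir) -> dict:
    """Run every stage and write the report bundle into ``outdir``."""
    outdir = Path(outdir)
    fresh = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        sim_cfg = SimulationConfig(seed=config.seed, **config.sim)
        ds = simulate_tracks(sim_cfg)
        geo.write_fixes(ds.fixes, outdir / "fixes.csv")
        geo.write_colonies(ds.colonies, outdir / "colonies.geojson")
        ds.birds.to_csv(outdir / "birds.csv", index=False)
        ds.truth_trips.to_csv(outdir / "truth_trips.csv", index=False)

        stage = "segment"
        metrics, trips_by_bird = trips.metrics_for_dataset(
            ds.fixes, ds.colonies, ds.birds,
            local_utc_offset=config.local_utc_offset,
            min_duration_min=config.min_trip_duration_min,
            min_distance_km=config.min_trip_distance_km)
        all_trips = pd.concat(
            [trips.trips_table(t) for t in trips_by_bird.values() if t],
            ignore_index=True)
        all_trips.to_csv(outdir / "trips.csv", index=False)
        metrics.to_csv(outdir / "daily_metrics.csv", index=False)

        stage = "foraging-models"
        cmp = trips.compare_groups(metrics)
        pd.concat([d["terms"].assign(metric=m) for m, d in cmp.items()],
                  ignore_index=True).to_csv(
            outdir / "foraging_model_terms.csv", index=False)
        pd.concat([d["tukey"].assign(metric=m) for m, d in cmp.items()],
                  ignore_index=True).to_csv(
            outdir / "foraging_tukey.csv", index=False)
        pd.concat([d["means"].assign(metric=m) for m, d in cmp.items()],
                  ignore_index=True).to_csv(
            outdir / "foraging_group_means.csv", index=False)

        stage = "growth"
        records, _truth = simulate_growth(sim_cfg)
        records.to_csv(outdir / "growth_records.csv", index=False)
        params = growth.fit_all_chicks(records, seed=config.seed)
        params.to_csv(outdir / "growth_params.csv", index=False)
        gmodels = growth.analyse_growth(params)
        pd.concat([d["terms"].assign(parameter=p)
                   for p, d in gmodels.items()], ignore_index=True).to_csv(
            outdir / "growth_model_terms.csv", index=False)

        stage = "adult-mass"
        adults = simulate_adult_masses(sim_cfg)
        adults.to_csv(outdir / "adult_masses.csv", index=False)
        am = analyse_adult_mass(adults)
        am["tukey"].to_csv(outdir / "adult_mass_tukey.csv", index=False)

        stage = "repeatability"
        rpt = repeatability.repeatability_table(
            metrics, n_boot=config.n_boot_repeatability, seed=config.seed)
        rpt.to_csv(outdir / "repeatability.csv", index=False)

        stage = "homerange"
        fits, hrs = {}, {}
        for g, sub in ds.birds.groupby("group"):
            for bird in sub["bird_id"].iloc[:config.homerange_birds_per_group]:
                traj = ds.fixes[ds.fixes["bird_id"] == bird]
                f = fit_ou(traj)
                fits[bird] = f
                hrs[bird] = akde(f, cell_km=config.cell_km)
        hr_rows = [{"bird_id": b, "tau_pos_h": f.tau_pos,
                    "n_eff": f.n_eff, "loglik": f.loglik,
                    "area95_km2": hrs[b].isopleth_area(0.95)}
                   for b, f in fits.items()]
        pd.DataFrame(hr_rows).to_csv(outdir / "homerange_fits.csv",
                                     index=False)
        gj = {"type": "FeatureCollection", "features": []}
        for b, hr in hrs.items():
            gj["features"].extend(isopleths_geojson(hr)["features"])
        with open(outdir / "isopleths.geojson", "w") as fh:
            json.dump(gj, fh)

        stage = "overlap"
        ov = overlap.pairwise_overlap(hrs, fits,
                                      n_boot=config.n_boot_overlap,
                                      seed=config.seed)
        net = overlap.build_network(ov, ds.birds)
        overlap.write_network(net, outdir / "overlap_edges.csv",
                              outdir / "overlap_network.graphml")
        summ = overlap.clustering_summary(ov, ds.birds)
        summ.to_csv(outdir / "overlap_clustering.csv", index=False)

        stage = "manifest"
        resolved = config.resolved()
        blob = json.dumps(resolved, sort_keys=True, default=str)
        manifest = {"package": "colonyforage", "version": __version__,
                    "seed": config.seed,
                    "config_hash": hashlib.sha256(blob.encode()).hexdigest(),
                    "config": resolved,
                    "numpy": np.__version__, "pandas": pd.__version__}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
    except Exception as e:
        if fresh:
            shutil.rmtree(outdir, ignore_errors=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    return {"outdir": outdir, "metrics": metrics, "compare": cmp,
            "growth": gmodels, "repeatability": rpt,
            "overlap": ov, "clustering": summ, "manifest": manifest}
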