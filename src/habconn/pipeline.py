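"""End-to-end pipeline: synthesize -> covariates -> population RSF ->
suitability -> individual RSF -> connectivity -> disperser validation.

A single :class:`RunConfig` is the source of truth for every stage
parameter.  One master seed deterministically spawns per-stage seeds, so a
fixed (config, seed) pair reproduces every artifact byte for byte.  Each
run writes a manifest listing the artifacts with content hashes and a
serialized copy of the configuration.
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

from . import covariates as cov
from . import homerange as hr
from . import poprsf, synth, validation
from .connectivity import (
    NodeRegion,
    ResistanceTransform,
    cumulative_current,
    grid_to_graph,
    quantile_classify,
    suitability_to_resistance,
)
from .geodata import Grid, PointSet, write_grid, write_points

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("habconn")

STAGES = ("synth", "covars", "poprsf", "indrsf", "connect", "validate")

# stage -> stages it needs
_DEPS = {
    "synth": (),
    "covars": ("synth",),
    "poprsf": ("covars",),
    "indrsf": ("covars",),
    "connect": ("poprsf",),
    "validate": ("connect",),
}


@dataclass(frozen=True)
class RunConfig:
    """All stage parameters in one place.

    Defaults carry the analysis constants: 4:1 availability ratio, 5,600 m
    pseudo-absence exclusion buffer (radius of a circle with the 99.7 km^2
    mean home-range area), moving-window scales {7, 15, 30, 50} km^2,
    delta-AICc cutoff 2 for model averaging, 95% KDE isopleth, the three
    suitability-resistance transforms (linear, c = 2, c = 8), 3 available
    points per disperser within a 5,000 m buffer, and 10 quantile bins.
    Synthetic-landscape geometry is desk-scale (200 x 200 cells at 30 m)
    and the exclusion buffer must be overridden to match (a 5,600 m buffer
    on a 6 km extent leaves no free area).
    """

    # landscape
    nrows: int = 200
    ncols: int = 200
    cell_size: float = 30.0
    availability_ratio: float = 4.0
    mean_home_range_km2: float = 99.7
    pseudo_absence_buffer_m: float = 5600.0
    window_scales_km2: tuple = (7.0, 15.0, 30.0, 50.0)
    correlation_threshold: float = 0.7
    delta_cutoff: float = 2.0
    n_presences: int = 400
    # individual level
    isopleth: float = 0.95
    min_fixes: int = 30
    n_individuals: int = 6
    fixes_per_individual: int = 80
    hr_sigma_m: float = 350.0
    # connectivity
    transform_cs: tuple = (2.0, 8.0)
    n_regions: int = 5
    quantile_bins: int = 10
    # validation
    n_dispersers: int = 46
    n_avail_per_disperser: int = 3
    disperser_buffer_m: float = 5000.0
    disperser_preference: float = 2.0
    # truth for synthesis
    true_beta: tuple = (("forest_7km2", 1.2), ("pasture_7km2", 0.5))
    true_intercept: float = -2.0
    # control
    stages: tuple = STAGES
    seed: int = 0
    outdir: str = "habconn_run"

    def effective_buffer_m(self) -> float:
        """Exclusion buffer, shrunk when the extent cannot host the default."""
        extent = min(self.nrows, self.ncols) * self.cell_size
        if self.pseudo_absence_buffer_m * 2 >= extent:
            return max(4 * self.cell_size, 0.02 * extent)
        return self.pseudo_absence_buffer_m

    def to_yaml(self) -> str:
        d = asdict(self)
        d["true_beta"] = [list(t) for t in d["true_beta"]]
        return yaml.safe_dump(d, sort_keys=True)

    @staticmethod
    def from_yaml(text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        for key in ("window_scales_km2", "transform_cs", "stages"):
            if key in d:
                d[key] = tuple(d[key])
        if "true_beta" in d:
            d["true_beta"] = tuple((nm, float(b)) for nm, b in d["true_beta"])
        return RunConfig(**d)


def _spawn_seeds(master: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    children = ss.spawn(len(STAGES))
    return {
        st: int(c.generate_state(1, np.uint32)[0]) for st, c in zip(STAGES, children)
    }


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _default_regions(grid: Grid, n: int) -> list[NodeRegion]:
    """n square node regions spread over the valid extent (corners + center)."""
    nr, nc = grid.shape
    side = max(3, min(nr, nc) // 20)
    anchors = [
        (side, side),
        (nr - 2 * side, nc - 2 * side),
        (side, nc - 2 * side),
        (nr - 2 * side, side),
        ((nr - side) // 2, (nc - side) // 2),
    ][:n]
    regions = []
    for k, (i0, j0) in enumerate(anchors):
        m = np.zeros(grid.shape, bool)
        m[i0 : i0 + side, j0 : j0 + side] = True
        regions.append(NodeRegion(label=f"region{k + 1}", mask=m))
    return regions


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; return the manifest."""
    for st in config.stages:
        for dep in _DEPS[st]:
            if dep not in config.stages:
                raise ValueError(
                    f"stage {st!r} requires stage {dep!r}, which is toggled off"
                )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _spawn_seeds(config.seed)
    manifest: dict = {"config": yaml.safe_load(config.to_yaml()), "stages": {}, "artifacts": {}}
    (outdir / "config.yaml").write_text(config.to_yaml())

    state: dict = {}

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest["artifacts"][name] = _hash_file(path)

    def run_stage(name, fn):
        t0 = time.perf_counter()
        log.info("stage %s: start (seed %d)", name, seeds[name])
        fn()
        dt = time.perf_counter() - t0
        log.info("stage %s: done in %.2f s", name, dt)
        manifest["stages"][name] = {"seed": seeds[name], "seconds": round(dt, 3)}

    # --- synth ---------------------------------------------------------
    def stage_synth():
        lc_cfg = synth.LandscapeConfig(
            nrows=config.nrows,
            ncols=config.ncols,
            cell_size=config.cell_size,
            seed=seeds["synth"],
        )
        state["landcover"] = synth.generate_landcover(lc_cfg)
        state["lines"] = synth.generate_lines(lc_cfg)
        emit("landcover.asc", lambda p: write_grid(state["landcover"], p))

    # --- covariates ----------------------------------------------------
    def stage_covars():
        lc = state["landcover"]
        grids = {}
        smallest = min(config.window_scales_km2)
        usable = [
            s
            for s in config.window_scales_km2
            if cov.window_edge_cells(s, lc.cell_size) <= min(lc.shape)
        ] or [smallest]
        for cls_name in ("forest", "pasture", "herbaceous"):
            code = synth.CLASS_CODES[cls_name]
            for s in usable:
                grids[f"{cls_name}_{s:g}km2"] = cov.window_proportion(lc, code, s)
        grids["dist_main_roads"] = cov.distance_to(
            state["lines"], lc, classes=("high_traffic",)
        )
        raw = cov.CovariateStack(grids)
        state["stack_raw"] = raw
        state["stack"] = cov.scale_covariates(raw)
        state["corr"], state["flagged"] = cov.correlation_screen(
            state["stack"], config.correlation_threshold
        )
        emit(
            "covariate_manifest.json",
            lambda p: p.write_text(
                json.dumps(
                    {
                        "names": state["stack"].names,
                        "means": state["stack"].means,
                        "sds": state["stack"].sds,
                        "flagged_pairs": [
                            [a, b, round(r, 4)] for a, b, r in state["flagged"]
                        ],
                    },
                    indent=2,
                    sort_keys=True,
                )
            ),
        )

    # --- population RSF ------------------------------------------------
    def stage_poprsf():
        stack = state["stack"]
        truth = synth.TruthModel(
            beta=dict(config.true_beta),
            intercept=config.true_intercept,
            availability_ratio=config.availability_ratio,
            hr_sigma_m=config.hr_sigma_m,
        )
        state["truth"] = truth
        rng_seed = seeds["poprsf"]
        presences = synth.generate_presences(
            stack, truth, config.n_presences, seed=rng_seed
        )
        absences = poprsf.generate_pseudo_absences(
            presences,
            stack.geometry(),
            ratio=config.availability_ratio,
            buffer_m=config.effective_buffer_m(),
            seed=rng_seed + 1,
        )
        data = poprsf.build_design(presences, absences, stack)
        truth_terms = [nm for nm, _ in config.true_beta]
        candidates = [tuple(truth_terms), (truth_terms[0],), ()]
        models = [poprsf.fit_logistic(data, t) for t in candidates]
        ranked = poprsf.rank_models(models)
        state["models"] = ranked
        state["suitability"] = poprsf.model_average_predict(
            ranked, stack, config.delta_cutoff
        )
        top = ranked[0]
        scores = top.predict_eta(data[list(top.terms)].to_numpy(float))
        state["auc"] = poprsf.auc_roc(scores, data["response"])
        emit("presences.csv", lambda p: write_points(presences, p))
        emit("model_table.csv", lambda p: poprsf.model_table(ranked).to_csv(p, index=False))
        emit("suitability.asc", lambda p: write_grid(state["suitability"], p))

    # --- individual RSF ------------------------------------------------
    def stage_indrsf():
        stack = state["stack"]
        truth = state.get("truth") or synth.TruthModel(beta=dict(config.true_beta))
        telemetry = synth.generate_telemetry(
            stack,
            truth,
            n_individuals=config.n_individuals,
            fixes_per_individual=config.fixes_per_individual,
            seed=seeds["indrsf"],
        )
        kept, report = hr.filter_individuals(telemetry, min_fixes=config.min_fixes)
        ranges, avail_parts = [], []
        for k, ind in enumerate(kept.individuals()):
            fixes = kept.subset(kept.df["individual_id"] == ind)
            h = hr.kde_home_range(fixes, isopleth=config.isopleth, individual_id=str(ind))
            ranges.append(h)
            avail_parts.append(
                hr.sample_availability(
                    h, len(fixes), seed=seeds["indrsf"] + 7 * k + 1,
                    within=stack.geometry(),
                )
            )
        available = PointSet.concat(avail_parts)
        fit = hr.fit_weighted_rsf(kept, available, stack, form="exponential_RSF")
        state["homeranges"] = ranges
        state["rsf_fit"] = fit
        hr_table = pd.DataFrame(
            {
                "individual_id": [h.individual_id for h in ranges],
                "sex": [h.sex for h in ranges],
                "study_area": [h.study_area for h in ranges],
                "n_fixes": [h.n_fixes for h in ranges],
                "area_km2": [round(h.area_km2, 3) for h in ranges],
            }
        )
        coef_table = pd.DataFrame(
            {
                "term": list(fit.coef),
                "coef": [round(fit.coef[t], 6) for t in fit.coef],
                "se": [round(fit.se[t], 6) for t in fit.coef],
            }
        )
        emit("homeranges.csv", lambda p: hr_table.to_csv(p, index=False))
        emit("indrsf_coefficients.csv", lambda p: coef_table.to_csv(p, index=False))

    # --- connectivity ---------------------------------------------------
    def stage_connect():
        H = state["suitability"]
        transforms = [ResistanceTransform("linear")] + [
            ResistanceTransform("exponential", c) for c in config.transform_cs
        ]
        regions = _default_regions(H, config.n_regions)
        state["regions"] = regions
        state["current_maps"] = {}
        state["decile_maps"] = {}
        for tr in transforms:
            R = suitability_to_resistance(H, tr)
            graph = grid_to_graph(R)
            cm = cumulative_current(graph, regions)
            state["current_maps"][tr.label] = cm
            state["decile_maps"][tr.label] = quantile_classify(
                cm.grid, config.quantile_bins
            )
            emit(f"current_{tr.label}.asc", lambda p, g=cm.grid: write_grid(g, p))
            emit(
                f"deciles_{tr.label}.asc",
                lambda p, g=state["decile_maps"][tr.label]: write_grid(g, p),
            )
        reff_rows = [
            {"transform": lbl, "pair": f"{a}-{b}", "effective_resistance": r}
            for lbl, cm in state["current_maps"].items()
            for (a, b), r in cm.effective_resistance.items()
        ]
        emit(
            "effective_resistance.csv",
            lambda p: pd.DataFrame(reff_rows).to_csv(p, index=False),
        )

    # --- validation -----------------------------------------------------
    def stage_validate():
        ref_label = next(iter(state["current_maps"]))
        cur = state["current_maps"][ref_label].grid
        dispersers = synth.generate_dispersers(
            cur,
            config.n_dispersers,
            preference=config.disperser_preference,
            seed=seeds["validate"],
        )
        matched = validation.build_matched_sets(
            dispersers,
            state["decile_maps"],
            buffer_m=config.disperser_buffer_m,
            n_avail=config.n_avail_per_disperser,
            seed=seeds["validate"] + 1,
        )
        fits = [
            validation.fit_mixed_logistic(matched, nm) for nm in matched.map_names
        ]
        weights, avg = validation.rank_and_average_maps(
            fits, {nm: state["current_maps"][nm].grid for nm in matched.map_names}
        )
        state["map_weights"] = weights
        sel_table = pd.DataFrame(
            {
                "map": [f.map_name for f in fits],
                "loglik": [round(f.llf, 4) for f in fits],
                "slope": [round(f.slope, 4) for f in fits],
                "aicc": [round(f.aicc, 4) for f in fits],
                "weight": [round(weights[f.map_name], 4) for f in fits],
            }
        )
        emit("matched_sets.csv", lambda p: matched.table.to_csv(p, index=False))
        emit("map_selection.csv", lambda p: sel_table.to_csv(p, index=False))
        emit("connectivity_averaged.asc", lambda p: write_grid(avg, p))

    fns = {
        "synth": stage_synth,
        "covars": stage_covars,
        "poprsf": stage_poprsf,
        "indrsf": stage_indrsf,
        "connect": stage_connect,
        "validate": stage_validate,
    }
    for st in STAGES:
        if st in config.stages:
            try:
                run_stage(st, fns[st])
            except Exception as exc:
                log.error("stage %s failed: %s", st, exc)
                raise RuntimeError(f"stage {st!r} failed: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def with_stages(config: RunConfig, stages) -> RunConfig:
    return replace(config, stages=tuple(stages))
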