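"""Configuration, orchestration and reporting for end-to-end runs.

A run is described by a plain dictionary (usually loaded from YAML): a
global seed, an output directory and per-stage parameter blocks.  Each
requested stage receives a sub-seed derived from the global seed and its
stage name through ``numpy.random.SeedSequence``, so stages can be rerun
independently and every stochastic output is bitwise reproducible.

Stages: ``fcs`` (synthetic z-scan grids -> diffusion law -> confinement
call), ``acf`` (population-model selection on generated curves), ``mc``
(vesicle Monte Carlo -> mesh domains -> coverage histogram), ``image``
(synthetic GUV stack -> surface segmentation -> shape table), ``compare``
(coverage-histogram w selection against held-out data).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
import numpy as np

from . import io as mio
from . import synthetic as syn
from . import fcs as fcsmod
from . import vesicle_mc as mc
from . import domains as dom

__all__ = ["run_pipeline", "make_report", "load_config", "stage_seed",
           "ConfigError", "DEMO_FREE_DIFFUSION", "DEMO_C1P16_LIKE"]

KNOWN_STAGES = ("fcs", "acf", "mc", "image", "compare")


class ConfigError(ValueError):
    """Invalid run configuration; the message carries the offending field path."""


def load_config(path) -> dict:
    import yaml
    with open(path) as fh:
        return yaml.safe_load(fh)


def stage_seed(global_seed: int, stage: str) -> int:
    """Derived, recorded sub-seed for a stage (stable counter-based scheme)."""
    counter = KNOWN_STAGES.index(stage)
    return int(np.random.SeedSequence([int(global_seed), counter])
               .generate_state(1)[0] % (2**31 - 1))


def _require(cfg: dict, field: str, path: str):
    if field not in cfg:
        raise ConfigError(f"{path}.{field}: required field missing")
    return cfg[field]


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _stage_fcs(cfg: dict, seed: int, outdir: Path) -> dict:
    truth = syn.SyntheticTruth(d_eff=_require(cfg, "d_eff", "fcs"),
                               t0=cfg.get("t0", 0.0),
                               kind=cfg.get("kind", "free"))
    waists = cfg.get("waists", [0.20, 0.25, 0.30, 0.35, 0.40])
    z_offsets = cfg.get("z_offsets", [-1.0, -0.5, 0.0, 0.5, 1.0])
    optics = [syn.OpticsSpec(waist_w0=w, z_offsets=z_offsets) for w in waists]
    series = syn.gen_diffusion_time_grid(
        truth, optics, n_vesicles=cfg.get("n_vesicles", 5),
        noise_cv=cfg.get("noise_cv", 0.05), seed=seed)
    mio.write_zscan_csv(series, outdir / "zscan_grid.csv")
    law = fcsmod.diffusion_law_from_series(series)
    label = fcsmod.classify_confinement(law, alpha=cfg.get("alpha", 0.05))
    return {
        "truth": {"d_eff": truth.d_eff, "t0": truth.t0, "kind": truth.kind},
        "d_eff": law.d_eff, "se_d_eff": law.se_d_eff,
        "t0": law.t0, "se_t0": law.se_t0,
        "classification": label,
        "points": law.points,
        "files": ["zscan_grid.csv"],
    }


def _stage_acf(cfg: dict, seed: int, outdir: Path) -> dict:
    params = syn.ACFModelParams(
        n_particles=cfg.get("n_particles", 10.0),
        tau_d=cfg.get("tau_d_ms", [1.0]),
        fractions=cfg.get("fractions", None) or
        [1.0 / len(cfg.get("tau_d_ms", [1.0]))] * len(cfg.get("tau_d_ms", [1.0])))
    curve = syn.gen_acf_curve(params, noise_scale=cfg.get("noise_scale", 0.02),
                              seed=seed, vesicle_id="synthetic")
    mio.write_acf_csv([curve], outdir / "acf_curves.csv")
    n_pop = fcsmod.select_population_model(curve, alpha=cfg.get("alpha", 0.05))
    fit = fcsmod.fit_acf(curve, n_pop)
    return {
        "true_populations": len(params.tau_d),
        "selected_populations": n_pop,
        "n_particles": fit.n_particles,
        "tau_d_ms": list(fit.tau_d),
        "fractions": list(fit.fractions),
        "files": ["acf_curves.csv"],
    }


def _mc_params(cfg: dict, seed: int, **over) -> mc.MCParams:
    kw = dict(
        n_vertices=cfg.get("n_vertices", 642),
        rho=cfg.get("rho", 0.2),
        w=cfg.get("w", 1.4),
        kappa_matrix=cfg.get("kappa_matrix", 27.3),
        kappa_domain=cfg.get("kappa_domain", 32.6),
        sweeps_thermalize=cfg.get("sweeps_thermalize", 2000),
        n_samples=cfg.get("n_samples", 20),
        sample_interval=cfg.get("sample_interval", 100),
        seed=seed)
    kw.update(over)
    return mc.MCParams(**kw)


def _stage_mc(cfg: dict, seed: int, outdir: Path) -> dict:
    params = _mc_params(cfg, seed)
    result = mc.run_simulation(params)
    sets = [dom.find_mesh_domains(s) for s in result.snapshots]
    hist = dom.combined_coverage_histogram(sets)
    np.savetxt(outdir / "energy_trace.csv", result.energy_trace,
               header="total_energy_kBT", comments="")
    result.snapshots[-1].to_trimesh().export(outdir / "final_snapshot.ply")
    n_domains = [len(ds.domains) for ds in sets]
    largest = [max((d.size for d in ds.domains), default=0) for ds in sets]
    shapes = []
    for snap, ds in list(zip(result.snapshots, sets))[-5:]:
        for d in ds.domains:
            sh = dom.shape_descriptors(d, snap)
            if sh is not None:
                shapes.append(sh)
    return {
        "params": {"n_vertices": params.n_vertices, "rho": params.rho,
                   "w": params.w, "kappa_domain": params.kappa_domain},
        "mean_total_energy": float(np.mean([e.total for e in result.energies])),
        "mean_bending_energy": float(np.mean([e.bending for e in result.energies])),
        "mean_n_domains": float(np.mean(n_domains)),
        "mean_largest_domain": float(np.mean(largest)),
        "median_circularity": float(np.median([s.circularity for s in shapes]))
        if shapes else None,
        "coverage_histogram": {"bin_edges": list(hist.bin_edges),
                               "counts": list(hist.counts)},
        "files": ["energy_trace.csv", "final_snapshot.ply"],
    }


def _stage_image(cfg: dict, seed: int, outdir: Path) -> dict:
    plan = []
    for entry in cfg.get("domain_plan", []):
        plan.append((entry["shape"], np.deg2rad(entry["angular_size_deg"]),
                     tuple(entry["position"])))
    spec = syn.GUVImageSpec(
        radius=cfg.get("radius", 5.0),
        voxel_size=tuple(cfg.get("voxel_size", (0.2, 0.2, 0.2))),
        shell_sigma=cfg.get("shell_sigma", 0.25),
        domain_plan=plan,
        photon_scale=cfg.get("photon_scale", 150.0),
        seed=seed)
    stack, truth = syn.gen_guv_stack(spec)
    mio.write_stack_tiff(stack, outdir / "guv_stack.tif")
    geom = dom.detect_vesicle_geometry(stack)
    smap = dom.map_surface_signal(stack, geom,
                                  n_points=cfg.get("n_points", 8000))
    ds = dom.segment_surface_domains(smap)
    table = []
    for d in ds.domains:
        sh = dom.shape_descriptors(d, smap)
        row = {"area_um2": d.area, "max_extent_um": d.max_extent,
               "class": dom.classify_domain_scale(d)}
        if sh is not None:
            row.update(circularity=sh.circularity, roundness=sh.roundness)
        table.append(row)
    mio.write_json(table, outdir / "image_domains.json")
    return {
        "true_domains": [{"label": d.label, "area_um2": d.area}
                         for d in truth.domains],
        "detected_radius_um": geom.radius,
        "n_domains": len(ds.domains),
        "domains": table,
        "files": ["guv_stack.tif", "image_domains.json"],
    }


def _stage_compare(cfg: dict, seed: int, outdir: Path) -> dict:
    w_grid = cfg.get("w_grid", [1.2, 1.3, 1.4])
    replicates = cfg.get("replicates", 3)
    bin_edges = np.asarray(cfg.get("bin_edges", np.arange(0, 8.25, 0.25).tolist()))
    ss = np.random.SeedSequence([seed, 7])
    seeds = iter(ss.generate_state(replicates * (len(w_grid) + 1)) % (2**31 - 1))

    def pooled_hist(w):
        sets = []
        for _ in range(replicates):
            params = _mc_params(cfg, int(next(seeds)), w=w)
            res = mc.run_simulation(params)
            sets += [dom.find_mesh_domains(s) for s in res.snapshots]
        return dom.combined_coverage_histogram(sets, bin_edges)

    held_w = cfg.get("held_out_w", w_grid[0])
    experimental = pooled_hist(held_w)
    runs = {w: pooled_hist(w) for w in w_grid}
    overlaps = {w: dom.histogram_overlap(experimental, h)
                for w, h in runs.items()}
    pearson = {w: dom.histogram_pearson(experimental, h)
               for w, h in runs.items()}
    w_star = dom.select_w(experimental, runs)
    return {
        "held_out_w": held_w,
        "w_grid": list(w_grid),
        "overlap": {str(w): v for w, v in overlaps.items()},
        "pearson": {str(w): v for w, v in pearson.items()},
        "selected_w": w_star,
        "files": [],
    }


_STAGE_FN = {"fcs": _stage_fcs, "acf": _stage_acf, "mc": _stage_mc,
             "image": _stage_image, "compare": _stage_compare}


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

def run_pipeline(config: dict) -> dict:
    """Execute the requested stages and return the run manifest.

    The manifest records the config, the derived per-stage seeds, each
    stage's outputs and SHA-256 hashes of every file written.  Stage
    failures abort the run but already-written outputs are preserved.
    """
    if "seed" not in config:
        raise ConfigError("seed: required field missing")
    stages = config.get("stages", [])
    for s in stages:
        if s not in KNOWN_STAGES:
            raise ConfigError(f"stages: unknown stage {s!r}")
    outdir = Path(config.get("outdir", "pipeline_out"))
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = {"config": config, "stage_seeds": {}, "stages": {},
                "file_hashes": {}, "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}
    for stage in stages:
        seed = stage_seed(config["seed"], stage)
        manifest["stage_seeds"][stage] = seed
        stage_dir = outdir / stage
        stage_dir.mkdir(exist_ok=True)
        out = _STAGE_FN[stage](config.get(stage, {}), seed, stage_dir)
        manifest["stages"][stage] = out
        for fname in out.get("files", []):
            fpath = stage_dir / fname
            manifest["file_hashes"][f"{stage}/{fname}"] = hashlib.sha256(
                fpath.read_bytes()).hexdigest()
    mio.write_json(manifest, outdir / "manifest.json")
    return manifest


def make_report(manifest: dict) -> dict:
    """Condense a manifest into the final report (idempotent, timestamp-free).

    Missing stages are listed rather than fatal, so partial runs still
    produce a valid document.
    """
    report = {"summary": [], "missing": []}
    stages = manifest.get("stages", {})
    for name in KNOWN_STAGES:
        if name not in stages:
            report["missing"].append(name)
            continue
        out = {k: v for k, v in stages[name].items() if k != "files"}
        report[name] = out
    if "fcs" in stages:
        s = stages["fcs"]
        report["summary"].append(
            f"FCS diffusion law: D_eff = {s['d_eff']:.3f} +/- {s['se_d_eff']:.3f} "
            f"um^2/s, t0 = {s['t0']:.3f} +/- {s['se_t0']:.3f} ms "
            f"-> {s['classification']}")
    if "acf" in stages:
        s = stages["acf"]
        report["summary"].append(
            f"ACF model selection: {s['selected_populations']} population(s) "
            f"(truth: {s['true_populations']})")
    if "mc" in stages:
        s = stages["mc"]
        report["summary"].append(
            f"MC: mean largest domain {s['mean_largest_domain']:.1f} vertices "
            f"at w={s['params']['w']}, rho={s['params']['rho']}")
    if "image" in stages:
        s = stages["image"]
        report["summary"].append(
            f"Image: {s['n_domains']} segmented domain(s), "
            f"R = {s['detected_radius_um']:.2f} um")
    if "compare" in stages:
        s = stages["compare"]
        report["summary"].append(f"w selection: w* = {s['selected_w']}")
    return json.loads(json.dumps(report, sort_keys=True))


DEMO_FREE_DIFFUSION = {
    "seed": 1,
    "stages": ["fcs"],
    "fcs": {"d_eff": 6.46, "t0": 0.0, "kind": "free"},
}

DEMO_C1P16_LIKE = {
    "seed": 1,
    "stages": ["fcs", "acf", "mc", "image"],
    "fcs": {"d_eff": 4.10, "t0": -0.92, "kind": "meshwork"},
    "acf": {"tau_d_ms": [0.61, 94.0], "fractions": [0.5, 0.5]},
    "mc": {"kappa_domain": 96.3, "w": 1.2, "n_vertices": 362,
           "sweeps_thermalize": 800, "n_samples": 10, "sample_interval": 50},
    "image": {"radius": 5.0,
              "domain_plan": [
                  {"shape": "stripe", "angular_size_deg": 25,
                   "position": [0.0, 0.0, 1.0]}]},
}
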