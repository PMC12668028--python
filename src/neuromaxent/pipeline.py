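"""End-to-end orchestration: simulate -> bin -> classify -> fit -> thermo.

A plan names a dynamical state, a list of system sizes and a replicate
count; :func:`run_plan` executes every stage for every (N, replicate)
pair, writes each artifact as text next to a JSON manifest with content
digests, and skips stages whose outputs already exist with matching
digests.  One master seed expands into an independent stream per
(stage, N, replicate), recorded in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as nio
from .avalanches import classify_state, distributions
from .ifnet import (DynamicsParams, build_network, delta_u_rec_for_state,
                    pretrain, run_recording)
from .maxent import LearningSchedule, SamplerConfig, bm_fit
from .spike_stats import BinnedRaster, MomentSet, bin_events, compute_moments
from .thermo import finite_size_scaling, locate_maximum, response_curve

__all__ = ["ExperimentPlan", "run_plan", "ingest_recording"]

log = logging.getLogger("neuromaxent")


@dataclass
class ExperimentPlan:
    """Configuration of one simulation-to-thermodynamics experiment."""

    state: str = "crit"                    # sub | crit | super
    n_values: tuple = (20, 40, 80, 100)
    replicates: int = 5
    bin_width: int = 5                     # timesteps per bin
    n_bins: int = 100_000                  # recording length in bins
    delta_u_rec_crit: dict | None = None   # per-N override of the calibrated table
    schedule: LearningSchedule = field(default_factory=LearningSchedule)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    thermo_grid: np.ndarray | None = None
    master_seed: int = 0
    output_dir: str = "runs"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.state not in ("sub", "crit", "super"):
            raise ValueError("state must be one of sub/crit/super")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(master: int, stage: str, n: int, rep: int) -> np.random.SeedSequence:
    tag = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    return np.random.SeedSequence([int(master), tag, int(n), int(rep)])


def _fresh(path: Path, manifest: dict) -> bool:
    rel = path.name
    return path.exists() and manifest.get("artifacts", {}).get(rel) == _digest(path)


def run_plan(plan: ExperimentPlan) -> dict:
    """Execute every stage of the plan; returns the manifest.

    Stages per (N, replicate): event simulation, binning + moments,
    avalanche classification, BM fit, thermodynamic sweep.  After all
    replicates, the finite-size scaling of the response maxima is fitted
    across ``plan.n_values``.  Reruns with the same master seed reproduce
    identical artifacts; completed stages are skipped.
    """
    out = Path(plan.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    mpath = out / "manifest.json"
    manifest = json.loads(mpath.read_text()) if mpath.exists() else {}
    manifest.setdefault("artifacts", {})
    manifest.setdefault("seeds", {})
    manifest["plan"] = {
        "state": plan.state, "n_values": list(plan.n_values),
        "replicates": plan.replicates, "bin_width": plan.bin_width,
        "n_bins": plan.n_bins, "master_seed": plan.master_seed,
    }

    def record(path: Path) -> None:
        manifest["artifacts"][path.name] = _digest(path)
        mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))

    cv_max: dict[int, list[float]] = {}
    chi_max: dict[int, list[float]] = {}
    tmax: dict[int, list[float]] = {}
    for n in plan.n_values:
        crit_val = (plan.delta_u_rec_crit or {}).get(n)
        durec = delta_u_rec_for_state(n, plan.state, crit_val)
        params = DynamicsParams(delta_u_rec=durec)
        for rep in range(plan.replicates):
            tag = f"{plan.state}_N{n}_r{rep}"
            try:
                ev_path = out / f"events_{tag}.tsv"
                seed = _stage_seed(plan.master_seed, "simulate", n, rep)
                manifest["seeds"][f"simulate/{tag}"] = str(seed.entropy)
                if not _fresh(ev_path, manifest):
                    log.info("simulate %s", tag)
                    topo = build_network(n, params, int(seed.generate_state(1)[0] & 0x7FFFFFFF))
                    topo = pretrain(topo, params, seed.spawn(1)[0])
                    res = run_recording(topo, params,
                                        n_timesteps=plan.n_bins * plan.bin_width,
                                        seed=seed.spawn(1)[0],
                                        warmup_avalanches=1000)
                    nio.write_events(ev_path, res.events)
                    record(ev_path)
                    catalog = res.catalog
                else:
                    catalog = None

                mom_path = out / f"moments_{tag}.tsv"
                if not _fresh(mom_path, manifest):
                    log.info("moments %s", tag)
                    events = nio.read_events(ev_path)
                    raster = bin_events(events, plan.bin_width)
                    nio.write_moments(mom_path, compute_moments(raster))
                    record(mom_path)

                cls_path = out / f"classify_{tag}.json"
                if catalog is not None and not _fresh(cls_path, manifest):
                    label = classify_state(distributions(catalog), n)
                    cls_path.write_text(json.dumps(
                        {"label": label.label,
                         "evidence": {k: float(v) for k, v in label.evidence.items()
                                      if np.isscalar(v)}}, indent=1))
                    record(cls_path)

                model_path = out / f"model_{tag}.txt"
                if not _fresh(model_path, manifest):
                    log.info("bm_fit %s", tag)
                    moments = nio.read_moments(mom_path)
                    fseed = _stage_seed(plan.master_seed, "fit", n, rep)
                    model, _ = bm_fit(moments, plan.schedule, plan.sampler,
                                      seed=int(fseed.generate_state(1)[0] & 0x7FFFFFFF))
                    nio.write_model(model_path, model)
                    record(model_path)

                curve_path = out / f"thermo_{tag}.tsv"
                if not _fresh(curve_path, manifest):
                    log.info("thermo %s", tag)
                    model = nio.read_model(model_path)
                    tseed = _stage_seed(plan.master_seed, "thermo", n, rep)
                    cfg = SamplerConfig(
                        n_samples=plan.sampler.n_samples,
                        n_chains=plan.sampler.n_chains,
                        seed=int(tseed.generate_state(1)[0] & 0x7FFFFFFF))
                    curve = response_curve(model, plan.thermo_grid, cfg)
                    nio.write_curve(curve_path, curve)
                    record(curve_path)
                curve = nio.read_curve(curve_path)
                loc_cv = locate_maximum(curve.temperatures, curve.cv, t_min=0.75)
                loc_chi = locate_maximum(curve.temperatures, curve.chi, t_min=0.75)
                cv_max.setdefault(n, []).append(loc_cv.value)
                chi_max.setdefault(n, []).append(loc_chi.value)
                tmax.setdefault(n, []).append(loc_cv.t_max)
            except Exception:
                log.error("stage failed: %s (N=%d, replicate=%d)", tag, n, rep)
                raise

    if len(plan.n_values) >= 2:
        ns = list(plan.n_values)
        fit_cv = finite_size_scaling(ns, [cv_max[n] for n in ns],
                                     [float(np.mean(tmax[n])) for n in ns])
        fit_chi = finite_size_scaling(ns, [chi_max[n] for n in ns])
        scaling_path = out / f"scaling_{plan.state}.json"
        scaling_path.write_text(json.dumps({
            "n_values": ns,
            "cv_max": {str(n): cv_max[n] for n in ns},
            "chi_max": {str(n): chi_max[n] for n in ns},
            "a_cv": fit_cv.exponent, "a_cv_se": fit_cv.exponent_se,
            "b_chi": fit_chi.exponent, "b_chi_se": fit_chi.exponent_se,
            "tmax": {str(n): tmax[n] for n in ns},
        }, indent=1))
        record(scaling_path)
    return manifest


def ingest_recording(path, dt_ms: float | None = None, bin_ms: float = 25.0
                     ) -> tuple[BinnedRaster, MomentSet]:
    """Read an event-list file and bin it at ``bin_ms`` milliseconds.

    The channel count and clock resolution come from the file header
    (``dt_ms`` overrides the latter; model-time files use one bin per
    ``bin_ms`` clock ticks)."""
    events = nio.read_events(path)
    tick = dt_ms if dt_ms is not None else (events.dt_ms or 1.0)
    width = max(1, int(round(bin_ms / tick)))
    raster = bin_events(events, width)
    return raster, compute_moments(raster)
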