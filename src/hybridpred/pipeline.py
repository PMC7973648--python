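"""End-to-end orchestration: simulate -> cross -> preprocess -> kernels ->
fit -> cv -> heterosis -> report, driven by one config mapping.

Every random draw flows from the single manifest seed through named child
streams. Each stage logs one structured line (seed, dimensions in/out) and
lists its outputs in the run manifest; stages are cached by a hash of
their config section plus the hashes of their inputs, so a rerun with an
unchanged config reuses outputs and reproduces files byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .containers import CrossPlan, OmicsMatrix
from .cv import PredictorSet, compare_predictor_sets, run_cv
from .hybrids import heterosis_table, make_hybrid_profiles
from .kernels import (DEFAULT_BANDWIDTH_GRID, additive_kernel, dominance_kernel,
                      epistatic_kernel, estimate_bandwidth, euclidean_distances,
                      gaussian_kernel)
from .preprocess import scale_predictors
from .reml import fit_reml
from .simulate import SimulationConfig, evaluate_genetic_values, simulate_dataset
from .trial import TrialModelSpec, fit_trial_model

log = logging.getLogger("hybridpred")

VALID_SETS = {"G", "T", "M", "GT", "GM", "TM", "GTM", "A", "A+D", "A+E", "A+D+E"}
STAGES = ("simulate", "cross", "kernels", "fit", "cv", "heterosis", "report")


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seeds, hashes, timings, outputs."""

    config: dict
    seed: int
    outdir: str
    stages: dict[str, dict] = field(default_factory=dict)

    def add_stage(self, name: str, key: str, outputs: list[str],
                  seconds: float, cached: bool, **info) -> None:
        self.stages[name] = {"key": key, "outputs": outputs,
                             "seconds": round(seconds, 3), "cached": cached, **info}

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "seed": self.seed,
                       "outdir": self.outdir, "stages": self.stages},
                      fh, indent=1, sort_keys=True, default=str)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def load_config(path: str | Path) -> dict:
    """Read a YAML/JSON pipeline config file and validate it."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return validate_config(cfg)


def validate_config(config: dict) -> dict:
    """Schema check; raises before any compute on invalid entries."""
    cfg = dict(config)
    cv_cfg = cfg.get("cv", {})
    for s in cv_cfg.get("sets", ["G"]):
        if s not in VALID_SETS:
            raise ValueError(f"unknown predictor-set label {s!r}; "
                             f"valid: {sorted(VALID_SETS)}")
    model = cv_cfg.get("model", "gblup")
    if model not in ("gblup", "rkhs"):
        raise ValueError(f"unknown model class {model!r}")
    frac = cv_cfg.get("fraction", 0.25)
    if not 0 < frac < 1:
        raise ValueError("cv.fraction must lie in (0, 1)")
    sim_keys = set(SimulationConfig.__dataclass_fields__)
    unknown = set(cfg.get("simulate", {})) - sim_keys
    if unknown:
        raise ValueError(f"unknown simulate config keys: {sorted(unknown)}")
    return cfg


def _build_sets(labels, layer_kernels, genomic_scaled, model, dist_cache,
                y_for_bandwidth, grid):
    """Assemble PredictorSet objects for the requested labels."""
    sets = []
    for label in labels:
        if label in ("A", "A+D", "A+E", "A+D+E"):
            A = layer_kernels["G"]
            ks = [A]
            if "D" in label:
                ks.append(dominance_kernel(genomic_scaled))
            if "E" in label.replace("A+", "", 1):
                ks.append(epistatic_kernel(A))
            sets.append(PredictorSet(label, ks))
        else:
            ks = [layer_kernels[c] for c in label]
            sets.append(PredictorSet(label, ks))
    return sets


def run_pipeline(config: dict, outdir: str | Path) -> RunManifest:
    """Execute the requested stages in dependency order.

    ``config`` sections: ``simulate`` (generator parameters), ``cv``
    (model, sets, cycles, fraction), ``stages`` (subset to run; default
    all). Outputs and a ``manifest.json`` land in ``outdir``.
    """
    config = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", config.get("simulate", {}).get("seed", 0)))
    wanted = config.get("stages", list(STAGES))
    manifest = RunManifest(config, seed, str(outdir))
    prev_manifest = {}
    mpath = outdir / "manifest.json"
    if mpath.exists():
        try:
            prev_manifest = json.loads(mpath.read_text()).get("stages", {})
        except json.JSONDecodeError:
            prev_manifest = {}

    def cached(stage: str, key: str, outputs: list[Path]) -> bool:
        prev = prev_manifest.get(stage)
        return bool(prev and prev.get("key") == key
                    and all(o.exists() for o in outputs))

    state: dict = {}
    for stage in STAGES:
        if stage not in wanted:
            continue
        t0 = time.perf_counter()
        try:
            key, outputs, info = _run_stage(stage, config, seed, outdir, state,
                                            cached_check=cached)
        except Exception as exc:  # halt, name the failing stage, keep manifest
            manifest.save(mpath)
            raise StageError(stage, exc) from exc
        dt = time.perf_counter() - t0
        was_cached = info.pop("cached", False)
        manifest.add_stage(stage, key, [str(o) for o in outputs], dt,
                           was_cached, **info)
        log.info("stage=%s seed=%d cached=%s outputs=%d elapsed=%.2fs",
                 stage, seed, was_cached, len(outputs), dt)
    manifest.save(mpath)
    return manifest


def _run_stage(stage, config, seed, outdir, state, cached_check):
    sim_cfg = SimulationConfig(**{**config.get("simulate", {}), "seed": seed})
    cv_cfg = config.get("cv", {})

    if stage == "simulate":
        key = _hash_obj({"cfg": sim_cfg.__dict__})
        paths = {n: outdir / n for n in
                 ("parents_genotypes.tsv", "parents_transcripts.tsv",
                  "parents_metabolites.tsv", "phenotypes.tsv",
                  "cross_plan.tsv", "ground_truth.json")}
        ds = simulate_dataset(sim_cfg)   # regenerating is cheap and keeps state
        state["ds"] = ds
        if not cached_check(stage, key, list(paths.values())):
            hio.write_matrix(ds.parents.genotypes, paths["parents_genotypes.tsv"])
            hio.write_matrix(ds.parent_transcriptome, paths["parents_transcripts.tsv"])
            hio.write_matrix(ds.parent_metabolome, paths["parents_metabolites.tsv"])
            hio.write_phenotypes(ds.phenotypes, paths["phenotypes.tsv"])
            hio.write_cross_plan(ds.plan, paths["cross_plan.tsv"])
            hio.write_json({
                "sigma2_g": ds.truth.sigma2_g, "sigma2_e": ds.truth.sigma2_e,
                "trait_mean": ds.truth.trait_mean,
                "genetic_values": ds.truth.genetic_values,
                "seed": seed,
            }, paths["ground_truth.json"])
            return key, list(paths.values()), {"n_hybrids": len(ds.plan)}
        return key, list(paths.values()), {"cached": True, "n_hybrids": len(ds.plan)}

    ds = state["ds"]

    if stage == "cross":
        prof = make_hybrid_profiles(
            {"genomic": ds.parents.genotypes,
             "transcriptomic": ds.parent_transcriptome,
             "metabolic": ds.parent_metabolome}, ds.plan)
        state["hybrid_layers"] = {
            "G": scale_predictors(prof.profiles["genomic"]),
            "T": scale_predictors(prof.profiles["transcriptomic"]),
            "M": scale_predictors(prof.profiles["metabolic"]),
        }
        key = _hash_obj({"seed": seed, "n": len(ds.plan)})
        out = outdir / "hybrid_genotypes.tsv"
        if not cached_check(stage, key, [out]):
            hio.write_matrix(prof.profiles["genomic"], out)
            return key, [out], {}
        return key, [out], {"cached": True}

    if stage == "kernels":
        layers = state["hybrid_layers"]
        model = cv_cfg.get("model", "gblup")
        y = ds.hybrid_means
        grid = cv_cfg.get("bandwidth_grid")
        kernels = {}
        bandwidths = {}
        for tag, om in layers.items():
            if model == "rkhs":
                dist = euclidean_distances(om)
                prof = estimate_bandwidth(dist, y.to_numpy(),
                                          grid=grid or DEFAULT_BANDWIDTH_GRID)
                kernels[tag] = gaussian_kernel(dist, prof.best)
                bandwidths[tag] = prof.best
            else:
                kernels[tag] = additive_kernel(om)
        state["layer_kernels"] = kernels
        key = _hash_obj({"seed": seed, "model": model, "grid": grid})
        outs = []
        for tag, k in kernels.items():
            p = outdir / f"kernel_{tag}.tsv"
            pd.DataFrame(k.matrix, index=k.ids, columns=k.ids).to_csv(p, sep="\t")
            outs.append(p)
        return key, outs, {"bandwidths": bandwidths}

    if stage == "fit":
        kernels = state["layer_kernels"]
        sets = cv_cfg.get("sets", ["G"])
        model = cv_cfg.get("model", "gblup")
        predictor_sets = _build_sets(sets, kernels, state["hybrid_layers"]["G"],
                                     model, None, None, None)
        y = ds.hybrid_means.to_numpy()
        outs = []
        for ps in predictor_sets:
            fit = fit_reml(y, ps.kernels)
            p = outdir / f"fit_{ps.label.replace('+', '')}.json"
            hio.write_fit(fit, p)
            outs.append(p)
        key = _hash_obj({"seed": seed, "sets": sets, "model": model})
        return key, outs, {}

    if stage == "cv":
        kernels = state["layer_kernels"]
        model = cv_cfg.get("model", "gblup")
        sets = cv_cfg.get("sets", ["G"])
        predictor_sets = _build_sets(sets, kernels, state["hybrid_layers"]["G"],
                                     model, None, None, None)
        result = run_cv(ds.hybrid_means, predictor_sets, ds.plan, model=model,
                        cycles=int(cv_cfg.get("cycles", 50)),
                        fraction=float(cv_cfg.get("fraction", 0.25)),
                        seed=seed)
        state["cv_result"] = result
        long = result.accuracies.reset_index(names="cycle").melt(
            id_vars="cycle", var_name="set", value_name="accuracy")
        long.insert(2, "trait", result.trait)
        p_long = outdir / "cv_accuracies.tsv"
        long.to_csv(p_long, sep="\t", index=False, na_rep=".")
        summary = {"mean_accuracy": result.mean_accuracy().to_dict(),
                   "cycles": int(result.accuracies.shape[0]),
                   "failed_cycles": len(result.failed_cycles)}
        p_sum = outdir / "cv_summary.json"
        hio.write_json(summary, p_sum)
        outs = [p_long, p_sum]
        if len(sets) > 1:
            comp = compare_predictor_sets(result)
            p_cmp = outdir / "predictor_set_comparison.tsv"
            comp.to_csv(p_cmp, sep="\t", index=False)
            outs.append(p_cmp)
        key = _hash_obj({"seed": seed, "cv": cv_cfg})
        return key, outs, {"mean_accuracy": summary["mean_accuracy"]}

    if stage == "heterosis":
        f1 = ds.truth.trait_mean + ds.truth.genetic_values
        parents = ds.truth.trait_mean + evaluate_genetic_values(
            ds.truth, ds.parents.genotypes)
        table = heterosis_table(f1, parents, ds.plan, trait="trait")
        p = outdir / "heterosis.tsv"
        table.to_csv(p, sep="\t", index=False, na_rep=".")
        state["heterosis"] = table
        key = _hash_obj({"seed": seed})
        return key, [p], {"mph_mean": float(table["MPH"].mean())}

    if stage == "report":
        outs = []
        if "cv_result" in state:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            result = state["cv_result"]
            fig, ax = plt.subplots(figsize=(1 + len(result.sets), 4))
            result.accuracies.boxplot(ax=ax)
            ax.set_ylabel("Pearson prediction accuracy")
            ax.set_xlabel("predictor set")
            p = outdir / "accuracy_boxplot.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            outs.append(p)
        key = _hash_obj({"seed": seed})
        return key, outs, {}

    raise ValueError(f"unknown stage {stage!r}")


def blues_from_trials(pheno: pd.DataFrame, spec: TrialModelSpec | None = None) -> pd.Series:
    """Convenience: per-genotype BLUEs from a long trial table."""
    return fit_trial_model(pheno, spec or TrialModelSpec()).blues
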