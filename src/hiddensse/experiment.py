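"""Config-driven orchestration of the full simulation study.

A run crosses: generating modes x replicates x sampling-fraction levels x
(correctly specified + allowed mis-specified) likelihood sampling
fractions, under one tree-size class, extinction level and trimming
regime.  Results are written as CSV; every task derives its random seeds
from (seed, mode, replicate, ...) so runs are reproducible and resumable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, IneligibleTreeError, InfeasibleTargetError
from .fit import FitSettings, fit_model, get_model, select_best
from .likelihood import LikelihoodSettings
from .metrics import fp_fn_rates, sackin_index
from .simulate import sample_tree_set
from .states import DEFAULT_SPACE, GeneratingMode
from .trim import BiasConfig, biased_trim, random_trim

__all__ = [
    "SIZE_CLASSES",
    "EXTINCTION_LEVELS",
    "TABLE1_MISSPEC",
    "ExperimentConfig",
    "run_experiment",
]

log = logging.getLogger("hiddensse")

# study design constants: size classes (crown age MY, tip band) and
# extinction levels (events/lineage/MY)
SIZE_CLASSES = {
    "large": {"crown_age": 23.0, "band": (1000, 5000)},
    "medium": {"crown_age": 19.0, "band": (450, 650)},
    "small": {"crown_age": 13.4, "band": (100, 250)},
}
EXTINCTION_LEVELS = {"low": 0.001, "regular": 0.05}
ETD_CTD_LAMBDAS = (0.1, 0.3, 0.5)
CR_LAMBDA = 0.3
TRANSITION_RATE = 0.4

# which specified-SF values are admissible for each true SF level
TABLE1_MISSPEC: dict[float, tuple[float, ...]] = {
    1.0: (0.8,),
    0.8: (1.0, 0.6),
    0.6: (1.0, 0.8, 0.4),
    0.4: (1.0, 0.8),
    0.2: (),
}


@dataclass
class ExperimentConfig:
    """One arm of the study design.

    ``misspec_map`` maps a true SF level to the additional (incorrect)
    specified-SF values to fit under; it must be a subset of the design's
    admissible pairs.  The correctly specified fit is always run.
    """

    size_class: str = "small"
    extinction_level: str = "low"
    generating_modes: tuple[str, ...] = ("ETD", "CTD", "CR")
    n_replicates: int = 20
    sf_levels: tuple[float, ...] = (1.0, 0.8, 0.6, 0.4, 0.2)
    regime: str = "random"
    misspec_map: dict[float, tuple[float, ...]] = field(default_factory=dict)
    seed: int = 0
    models_to_fit: tuple[str, ...] = ("CR", "CTD", "ETD")
    crown_age: Optional[float] = None
    band: Optional[tuple[int, int]] = None
    condition_on_survival: bool = True
    root_weighting: str = "fitzjohn"
    ode_rel_tol: float = 1e-6
    ode_abs_tol: float = 1e-8
    max_cycles: int = 10
    optimizer_method: str = "hybrid"
    # kept above the ODE-solver noise so jittered restarts don't spuriously
    # count as improvements
    cycle_tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.size_class not in SIZE_CLASSES:
            raise ConfigError(f"unknown size class {self.size_class!r}")
        if self.extinction_level not in EXTINCTION_LEVELS:
            raise ConfigError(f"unknown extinction level {self.extinction_level!r}")
        if self.regime not in ("random", "biased"):
            raise ConfigError(f"unknown trimming regime {self.regime!r}")
        for m in self.generating_modes:
            if m.upper() not in ("ETD", "CTD", "CR"):
                raise ConfigError(f"unknown generating mode {m!r}")
        bad_models = set(m.upper() for m in self.models_to_fit) - {"CR", "CTD", "ETD", "ECTD"}
        if bad_models:
            raise ConfigError(f"unknown models to fit: {sorted(bad_models)}")
        cleaned: dict[float, tuple[float, ...]] = {}
        for true_sf, specs in self.misspec_map.items():
            true_sf = float(true_sf)
            allowed = TABLE1_MISSPEC.get(true_sf)
            if allowed is None:
                raise ConfigError(f"true SF {true_sf} is not a design level")
            specs = tuple(float(s) for s in np.atleast_1d(list(specs)))
            for s in specs:
                if s not in allowed:
                    raise ConfigError(
                        f"mis-specification {true_sf} -> {s} is not an admissible pair "
                        f"(allowed: {allowed or 'none'})"
                    )
            cleaned[true_sf] = specs
        self.misspec_map = cleaned

    @property
    def mu(self) -> float:
        return EXTINCTION_LEVELS[self.extinction_level]

    def size(self) -> tuple[float, tuple[int, int]]:
        sc = SIZE_CLASSES[self.size_class]
        return (
            self.crown_age if self.crown_age is not None else sc["crown_age"],
            tuple(self.band) if self.band is not None else sc["band"],
        )

    def generating_mode(self, name: str) -> GeneratingMode:
        name = name.upper()
        lams = (CR_LAMBDA,) if name == "CR" else ETD_CTD_LAMBDAS
        return GeneratingMode(name, np.array(lams), self.mu, TRANSITION_RATE)

    def likelihood_settings(self, rho_scalar: float) -> LikelihoodSettings:
        return LikelihoodSettings(
            rho=np.full(DEFAULT_SPACE.n_examined, rho_scalar),
            condition_on_survival=self.condition_on_survival,
            root_weighting=self.root_weighting,
            ode_rel_tol=self.ode_rel_tol,
            ode_abs_tol=self.ode_abs_tol,
        )

    def fit_settings(self) -> FitSettings:
        return FitSettings(
            max_cycles=self.max_cycles,
            method=self.optimizer_method,
            cycle_tol=self.cycle_tol,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("generating_modes", "sf_levels", "models_to_fit"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _jsonable(obj):
    """Recursively convert numpy scalars so task caches serialize cleanly."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def _task_seed(*parts) -> list[int]:
    """Stable integer seed stream from heterogeneous task coordinates."""
    out = []
    for p in parts:
        if isinstance(p, str):
            out.append(abs(hash_str(p)))
        elif isinstance(p, float):
            out.append(int(round(p * 1000)))
        else:
            out.append(int(p))
    return out


def hash_str(s: str) -> int:
    h = 2166136261
    for ch in s.encode():
        h = ((h ^ ch) * 16777619) % (2**31)
    return h


def _trim_tree(clade, sf, cfg: ExperimentConfig, seed_parts):
    if sf >= 1.0:
        return random_trim(clade, 1.0, np.random.default_rng(seed_parts))
    if cfg.regime == "random":
        return random_trim(clade, sf, np.random.default_rng(seed_parts))
    # biased: retry with fresh sub-clade/removal draws before giving up
    last_err: Exception | None = None
    for attempt in range(20):
        rng = np.random.default_rng(seed_parts + [attempt])
        n_sub = 1 if sf >= 0.8 else int(rng.integers(1, 3))
        try:
            return biased_trim(clade, sf, BiasConfig(n_subclades=n_sub), rng)
        except (IneligibleTreeError, InfeasibleTargetError) as err:
            last_err = err
    raise IneligibleTreeError(f"biased trimming failed after 20 attempts: {last_err}")


def run_experiment(config: ExperimentConfig, outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Execute one experiment arm; write fits/selection/metrics CSVs.

    Per-(mode, replicate) task results are cached as JSON under
    ``outdir/tasks`` so an interrupted run resumes where it stopped.
    """
    outdir = Path(outdir)
    taskdir = outdir / "tasks"
    taskdir.mkdir(parents=True, exist_ok=True)
    runlog = outdir / "runlog.jsonl"
    crown_age, band = config.size()

    fit_rows: list[dict] = []
    sel_rows: list[dict] = []
    for mode_name in config.generating_modes:
        mode = config.generating_mode(mode_name)
        for rep in range(config.n_replicates):
            task_id = f"{mode_name}_{rep:04d}"
            marker = taskdir / f"{task_id}.json"
            if marker.exists():
                cached = json.loads(marker.read_text())
                fit_rows.extend(cached["fits"])
                sel_rows.extend(cached["selections"])
                continue
            task_fits, task_sels = _run_task(
                config, mode, mode_name, rep, crown_age, band, runlog
            )
            # round-trip through the JSON form so resumed and fresh runs
            # produce byte-identical CSVs
            task_fits = _jsonable(task_fits)
            task_sels = _jsonable(task_sels)
            marker.write_text(json.dumps({"fits": task_fits, "selections": task_sels}))
            fit_rows.extend(task_fits)
            sel_rows.extend(task_sels)

    fits = pd.DataFrame(fit_rows).sort_values(
        ["generating", "replicate", "true_sf", "specified_sf", "model"], ignore_index=True
    )
    selections = pd.DataFrame(sel_rows).sort_values(
        ["generating", "replicate", "true_sf", "specified_sf"], ignore_index=True
    )
    metric_rows = []
    for (true_sf, spec_sf), grp in selections.groupby(["true_sf", "specified_sf"]):
        summ = fp_fn_rates(list(zip(grp.generating, grp.selected)))
        metric_rows.append(
            {
                "true_sf": true_sf,
                "specified_sf": spec_sf,
                "n_datasets": len(grp),
                "fp_rate": summ.fp_rate,
                "fn_rate": summ.fn_rate,
                "fp_from_ctd": summ.fp_from_ctd,
                "fp_from_cr": summ.fp_from_cr,
            }
        )
    metrics = pd.DataFrame(metric_rows).sort_values(
        ["true_sf", "specified_sf"], ignore_index=True
    )
    fits.to_csv(outdir / "fits.csv", index=False, float_format="%.10g")
    selections.to_csv(outdir / "selection.csv", index=False, float_format="%.10g")
    metrics.to_csv(outdir / "metrics.csv", index=False, float_format="%.10g")
    return {"fits": fits, "selection": selections, "metrics": metrics}


def _run_task(config, mode, mode_name, rep, crown_age, band, runlog_path):
    sim_seed = _task_seed(config.seed, "sim", mode_name, rep)
    clade = sample_tree_set(mode, crown_age, band, 1, seed=hash_seed(sim_seed))[0]
    opt = config.fit_settings()
    fit_rows: list[dict] = []
    sel_rows: list[dict] = []
    for sf in config.sf_levels:
        trimmed, spec = _trim_tree(clade, sf, config, _task_seed(config.seed, "trim", mode_name, rep, sf))
        specified_values = (sf,) + tuple(config.misspec_map.get(sf, ()))
        for spec_sf in specified_values:
            settings = config.likelihood_settings(spec_sf)
            fits = {}
            cr_start = None
            for model_name in sorted(config.models_to_fit, key=lambda m: get_model(m).k):
                model = get_model(model_name)
                extra = []
                if cr_start is not None and model_name != "CR":
                    extra.append(model.expand_free(*cr_start))
                if model_name == "ECTD" and "ETD" in fits and np.isfinite(fits["ETD"].lnl):
                    etd = fits["ETD"].mle
                    sp = model.space
                    lam9 = [etd[sp.examined_of(i)] for i in range(sp.n_states)]
                    extra.append(np.array(lam9 + [etd[-2], etd[-1]]))
                fr = fit_model(
                    trimmed,
                    model,
                    settings,
                    seed=hash_seed(_task_seed(config.seed, "fit", mode_name, rep, sf, spec_sf, model_name)),
                    extra_starts=extra,
                    opt=opt,
                )
                if model_name == "CR" and np.isfinite(fr.lnl):
                    cr_start = (fr.mle[0], fr.mle[1], fr.mle[2])
                fits[model_name] = fr
            core = {m: f for m, f in fits.items() if m != "ECTD"}
            pool = core if len(core) >= 2 else fits
            try:
                best, weights = select_best(pool)
            except ValueError:
                # too few fits report convergence (common on tiny demo
                # trees); compare every finite optimum instead
                best, weights = select_best(pool, require_converged=False)
            for model_name, fr in fits.items():
                row = {
                    "tree_id": f"{mode_name}_{rep:04d}",
                    "generating": mode_name,
                    "replicate": rep,
                    "n_tips_full": clade.n_tips,
                    "n_tips": trimmed.n_tips,
                    "true_sf": spec.true_sf,
                    "target_sf": sf,
                    "specified_sf": spec_sf,
                    "regime": spec.regime,
                    "model": model_name,
                    "lnl": fr.lnl,
                    "k": fr.k,
                    "aicc": fr.aicc,
                    "weight": weights.get(model_name, np.nan),
                    "converged": fr.converged,
                    "n_cycles": fr.n_cycles_used,
                }
                row.update({f"mle_{n}": v for n, v in fr.params_dict().items()})
                fit_rows.append(row)
            sel_rows.append(
                {
                    "tree_id": f"{mode_name}_{rep:04d}",
                    "generating": mode_name,
                    "replicate": rep,
                    "true_sf": spec.true_sf,
                    "target_sf": sf,
                    "specified_sf": spec_sf,
                    "regime": spec.regime,
                    "selected": best,
                    "sackin_mean": sackin_index(trimmed),
                    "n_tips": trimmed.n_tips,
                }
            )
    with open(runlog_path, "a") as fh:
        fh.write(
            json.dumps(
                {
                    "task": f"{mode_name}_{rep:04d}",
                    "n_tips": clade.n_tips,
                    "seed": sim_seed,
                }
            )
            + "\n"
        )
    return fit_rows, sel_rows


def hash_seed(parts: list[int]) -> int:
    """Collapse a seed-part list into one 63-bit integer seed."""
    h = 1469598103934665603
    for p in parts:
        h = ((h ^ (p & 0xFFFFFFFF)) * 1099511628211) % (2**63)
    return h
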