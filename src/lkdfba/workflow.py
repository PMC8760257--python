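"""End-to-end workflow: DFE -> fit all approaches -> simulate WT + perturbations
-> evaluate -> select, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .data import read_timecourse_csv, write_timecourse_csv
from .evaluation import PerturbationSpec, compare_approaches, select_best_approach
from .fitting import APPROACHES, fit_constraints, save_constraints
from .network import TimeGrid, load_network
from .synthetic import NoiseSpec, add_noise

logger = logging.getLogger("lkdfba")

__all__ = ["RunConfig", "run_workflow"]


@dataclass
class RunConfig:
    """Configuration for one workflow run (paths resolved at validation time)."""

    model_path: str
    wt_data_path: str
    out_dir: str
    perturbations: list[dict] = field(default_factory=list)  # {name, targets, factor, truth_path}
    approaches: list[str] = field(default_factory=lambda: list(APPROACHES))
    lam: float = 1e-4
    lag: int = 0
    kinetics_from_step: int = 0
    solver_tol: float = 1e-6
    objective_weights: dict | None = None
    noise: dict | None = None  # {nT, cov, n_replicates, seed} applied to WT data
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> list[str]:
        problems = []
        for p in [self.model_path, self.wt_data_path] + [
            e["truth_path"] for e in self.perturbations if "truth_path" in e
        ]:
            if not Path(p).exists():
                problems.append(f"missing path: {p}")
        bad = [a for a in self.approaches if a not in APPROACHES]
        if bad:
            problems.append(f"unknown approach(es): {bad}")
        return problems

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _stage(name):
    logger.info("stage %s: starting", name)
    return time.perf_counter()


def _done(name, t0, timings):
    dt = time.perf_counter() - t0
    timings[name] = round(dt, 3)
    logger.info("stage %s: done in %.2fs", name, dt)


def run_workflow(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a summary dict (also written to disk).

    Stages: load -> (noise) -> fit (per approach; DFE runs inside fitting when
    the data carry no fluxes) -> simulate+evaluate -> select.  Outputs under
    `config.out_dir`: fitted constraint sets, the NRMSE comparison matrix, and
    a manifest with seeds and the config hash.
    """
    problems = config.validate()
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = _stage("load")
    network = load_network(config.model_path)
    wt = read_timecourse_csv(config.wt_data_path)
    perts = [
        PerturbationSpec(
            e["name"], tuple(e["targets"]), float(e["factor"]),
            read_timecourse_csv(e["truth_path"]),
        )
        for e in config.perturbations
    ]
    _done("load", t0, timings)

    wt_sets = [wt]
    wt_truth = wt
    if config.noise:
        t0 = _stage("noise")
        spec = NoiseSpec(
            nT=int(config.noise["nT"]), cov=float(config.noise["cov"]),
            n_replicates=int(config.noise.get("n_replicates", 1)),
            seed=int(config.noise.get("seed", config.seed)),
        )
        wt_sets = add_noise(wt, spec)
        for r, ds in enumerate(wt_sets):
            write_timecourse_csv(ds, out / f"wt_noisy_rep{r}.csv")
        _done("noise", t0, timings)

    t0 = _stage("fit")
    from .estimator import LKDFBA  # local import avoids a cycle at module load

    for approach in config.approaches:
        est = LKDFBA(network=network, approach=approach, lag=config.lag, lam=config.lam)
        est.fit(wt_sets[0])
        save_constraints(est.constraints_, out / f"constraints_{approach}.json")
    _done("fit", t0, timings)

    t0 = _stage("evaluate")
    fit_sets = wt_sets
    if wt_sets[0].fluxes is None:
        from .dfe import estimate_fluxes_dfe

        fit_sets = []
        for ds in wt_sets:
            fluxes, pooling, _ = estimate_fluxes_dfe(network, ds.concentrations)
            ds2 = ds.copy()
            ds2.fluxes, ds2.pooling_fluxes = fluxes, pooling
            fit_sets.append(ds2)
    comparison = compare_approaches(
        network, fit_sets, perts, wt_truth=wt_truth,
        approaches=tuple(config.approaches),
        objective_weights=config.objective_weights,
        lam=config.lam, lag=config.lag,
        kinetics_from_step=config.kinetics_from_step,
        solver_tol=config.solver_tol,
    )
    comparison.to_csv(out / "comparison.csv")
    _done("evaluate", t0, timings)

    t0 = _stage("select")
    best = select_best_approach(comparison)
    _done("select", t0, timings)

    summary = {
        "version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "best_approach": best,
        "wt_nrmse": {a: float(comparison.nrmse_table.loc[a, "WT"]) for a in config.approaches},
        "timings_s": timings,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary
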