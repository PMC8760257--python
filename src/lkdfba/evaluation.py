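"""Model scoring and constraint-approach selection.

NRMSE is the per-metabolite root mean square error between predicted and
reference concentration trajectories, normalized by the reference range of
that metabolite, averaged across metabolites.  The four constraint approaches
are compared on the wild type and a panel of in-silico perturbations; the
approach with the lowest wild-type NRMSE is selected, and the *consistency
rate* measures how often that same approach is also the best predictor of
each perturbed phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import TimecourseDataset
from .fitting import APPROACHES, fit_constraints, scale_constraints
from .network import MetabolicNetwork, TimeGrid
from .program import TrajectorySolution, simulate_lkdfba

__all__ = [
    "nrmse",
    "PerturbationSpec",
    "ApproachComparison",
    "compare_approaches",
    "select_best_approach",
    "consistency_rate",
    "average_flux",
    "flux_correlation",
]

#: deterministic tie-break order (simplest constraint class first)
TIE_ORDER = {a: i for i, a in enumerate(APPROACHES)}

_RANGE_FLOOR = 1e-12


def nrmse(
    predicted: TimecourseDataset | pd.DataFrame,
    truth: TimecourseDataset | pd.DataFrame,
    species: list[str] | None = None,
) -> float:
    """Range-normalized RMSE between predicted and reference concentrations.

    Per metabolite: RMSE / (max - min) of the *truth* series (normalization by
    the reference makes the measure asymmetric under argument swap); constant
    truth series fall back to normalization by |mean| with a floor of 1.
    The per-metabolite values are averaged.
    """
    pred = predicted.concentrations if isinstance(predicted, TimecourseDataset) else predicted
    ref = truth.concentrations if isinstance(truth, TimecourseDataset) else truth
    if species is None:
        species = list(ref.columns)
    missing = [s for s in species if s not in pred.columns]
    if missing:
        raise ValueError(f"prediction missing species {missing}")
    p_times = pred.index.to_numpy(dtype=float)
    r_times = ref.index.to_numpy(dtype=float)
    if len(p_times) != len(r_times) or not np.allclose(p_times, r_times, rtol=0, atol=1e-9):
        raise ValueError("predicted and truth grids do not match")
    vals = []
    for s in species:
        err = pred[s].to_numpy(dtype=float) - ref[s].to_numpy(dtype=float)
        rmse = float(np.sqrt(np.mean(err**2)))
        span = float(np.ptp(ref[s].to_numpy(dtype=float)))
        if span < _RANGE_FLOOR:
            span = max(abs(float(ref[s].mean())), 1.0)  # documented fallback
        vals.append(rmse / span)
    return float(np.mean(vals))


@dataclass(frozen=True)
class PerturbationSpec:
    """One in-silico genetic perturbation: scale constraints on `targets` by
    `factor` and compare the simulation against `truth` (the perturbed system's
    reference data)."""

    name: str
    targets: tuple[str, ...]
    factor: float
    truth: TimecourseDataset


@dataclass
class ApproachComparison:
    """NRMSE matrix: rows = constraint approaches, columns = phenotypes (WT first).

    `statuses` carries the solver status per cell; infeasible cells hold NaN
    and are excluded from best-approach logic.
    """

    nrmse_table: pd.DataFrame
    statuses: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def phenotypes(self) -> list[str]:
        return list(self.nrmse_table.columns)

    def best_in_column(self, phenotype: str) -> str | None:
        col = self.nrmse_table[phenotype]
        finite = col[np.isfinite(col)]
        if finite.empty:
            return None
        lowest = finite.min()
        candidates = [a for a in finite.index if finite[a] == lowest]
        return min(candidates, key=lambda a: TIE_ORDER[a])

    def best_per_column(self) -> dict[str, str | None]:
        return {p: self.best_in_column(p) for p in self.phenotypes}

    def wt_best(self) -> str | None:
        return self.best_in_column("WT")

    def to_csv(self, path) -> None:
        self.nrmse_table.to_csv(path)

    def plot_heatmap(self, path=None, ax=None):
        """Render the NRMSE matrix, color-scaled per phenotype column (each
        column's best approach is the darkest green) with the wild-type best
        marked.  Requires matplotlib; returns the axes."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        vals = self.nrmse_table.to_numpy(dtype=float)
        scaled = np.full_like(vals, np.nan)
        for j in range(vals.shape[1]):
            col = vals[:, j]
            finite = np.isfinite(col)
            if finite.any() and np.ptp(col[finite]) > 0:
                scaled[finite, j] = (col[finite] - col[finite].min()) / np.ptp(col[finite])
            elif finite.any():
                scaled[finite, j] = 0.0
        if ax is None:
            _, ax = plt.subplots(figsize=(1 + vals.shape[1], 3))
        ax.imshow(scaled, cmap="RdYlGn_r", vmin=0, vmax=1, aspect="auto")
        ax.set_xticks(range(len(self.phenotypes)), self.phenotypes, rotation=45)
        ax.set_yticks(range(len(self.nrmse_table.index)), self.nrmse_table.index)
        wt = self.wt_best()
        if wt is not None:
            ax.text(0, list(self.nrmse_table.index).index(wt), "X",
                    ha="center", va="center", fontweight="bold")
        if path is not None:
            ax.figure.savefig(path, bbox_inches="tight", dpi=120)
            plt.close(ax.figure)
        return ax


def compare_approaches(
    network: MetabolicNetwork,
    wt_datasets: list[TimecourseDataset] | TimecourseDataset,
    perturbations: list[PerturbationSpec],
    wt_truth: TimecourseDataset | None = None,
    approaches: tuple[str, ...] = APPROACHES,
    x0=None,
    objective_weights: dict[str, float] | None = None,
    lam: float = 1e-4,
    lag: int = 0,
    kinetics_from_step: int = 0,
    solver_tol: float = 1e-6,
) -> ApproachComparison:
    """Fit every approach to wild-type data, simulate WT + perturbations, score NRMSE.

    `wt_datasets` may be a list of noisy replicates; each approach is then
    fitted to each replicate and cells hold the mean NRMSE across replicates
    (infeasible replicates are skipped; a cell is NaN only when every replicate
    fails).  `wt_truth` is the reference for the WT column (defaults to the
    first training dataset — appropriate for noiseless training data).
    """
    if isinstance(wt_datasets, TimecourseDataset):
        wt_datasets = [wt_datasets]
    if wt_truth is None:
        wt_truth = wt_datasets[0]
    phenos = ["WT"] + [p.name for p in perturbations]
    table = pd.DataFrame(np.nan, index=list(approaches), columns=phenos)
    statuses = pd.DataFrame("", index=list(approaches), columns=phenos)

    x0_vec = x0 if x0 is not None else wt_truth.concentrations.iloc[0].to_dict()

    for approach in approaches:
        cell_errors: dict[str, list[float]] = {p: [] for p in phenos}
        cell_statuses: dict[str, list[str]] = {p: [] for p in phenos}
        for ds in wt_datasets:
            constraints = fit_constraints(network, ds, approach, lag=lag)
            jobs = [("WT", constraints, wt_truth)]
            for p in perturbations:
                scaled = scale_constraints(
                    constraints, p.targets, p.factor, known_reactions=network.reaction_ids
                )
                jobs.append((p.name, scaled, p.truth))
            for name, cons, truth in jobs:
                grid = TimeGrid(truth.times[0], truth.times[-1], truth.n_points)
                sol = simulate_lkdfba(
                    network, cons, x0_vec, grid,
                    objective_weights=objective_weights, lam=lam,
                    kinetics_from_step=kinetics_from_step, tol=solver_tol,
                )
                cell_statuses[name].append(sol.status)
                if sol.is_optimal:
                    cell_errors[name].append(nrmse(sol.to_dataset(), truth))
        for name in phenos:
            errs = cell_errors[name]
            table.loc[approach, name] = float(np.mean(errs)) if errs else np.nan
            statuses.loc[approach, name] = ";".join(cell_statuses[name])

    return ApproachComparison(table, statuses, meta={"n_replicates": len(wt_datasets)})


def select_best_approach(comparison: ApproachComparison) -> str:
    """The approach with minimal wild-type NRMSE (ties: LR > NLR > DR > HP)."""
    best = comparison.wt_best()
    if best is None:
        raise ValueError("no approach produced a feasible wild-type simulation")
    return best


def consistency_rate(comparisons: list[ApproachComparison]) -> tuple[float, dict]:
    """Pooled fraction of perturbation columns whose best approach equals the
    wild-type-best approach of the same comparison.

    Columns with no feasible cell, and comparisons with no WT best, are
    excluded from numerator and denominator; the counts are reported.
    """
    matched = 0
    total = 0
    excluded = 0
    for comp in comparisons:
        wt = comp.wt_best()
        for pheno in comp.phenotypes:
            if pheno == "WT":
                continue
            best = comp.best_in_column(pheno) if wt is not None else None
            if wt is None or best is None:
                excluded += 1
                continue
            total += 1
            if best == wt:
                matched += 1
    rate = matched / total if total else float("nan")
    return rate, {"matched": matched, "evaluated": total, "excluded": excluded}


def average_flux(solution: TrajectorySolution, reaction_ids: list[str] | None = None) -> pd.Series:
    """Arithmetic mean of each predicted flux time course (summary for
    simulations that do not reach steady state)."""
    if not solution.is_optimal:
        raise ValueError(f"solution status is {solution.status!r}, not optimal")
    tab = solution.v if reaction_ids is None else solution.v[list(reaction_ids)]
    return tab.mean(axis=0)


def flux_correlation(predicted, reference) -> float:
    """Pearson correlation between two phenotype vectors of (average) fluxes.

    Returns NaN (with no exception) when either vector has zero variance.
    """
    a = np.asarray(predicted, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if a.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)
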