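"""Ground-truth synthetic data: a branched-pathway power-law ODE system.

The reference topology has five metabolites (x1..x4 plus a biomass species
xBM) and five irreversible fluxes with power-law (biochemical systems theory)
rate laws and two allosteric edges:

    v1:  -> x1        v1 = a1 * x3^g13          (x3 inhibits v1, g13 < 0)
    v2: x1 -> x2      v2 = a2 * x1^g21
    v3: x2 -> x3      v3 = a3 * x2^g32
    v4: x2 -> x4      v4 = a4 * x2^g42 * x3^g43 (x3 activates v4, g43 > 0)
    v5: x3 -> xBM     v5 = a5 * x3^g53

Feedback inhibition of the influx by the branch-point product x3 and
feed-forward activation of the x4 branch by x3 give the system non-trivial
transient dynamics.  Random
parameterizations with this fixed topology, ODE-level perturbations, Gaussian
noise with signal-proportional standard deviation, down-sampling, and impulse
smoothing emulate the full data-generation protocol used in the experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .data import TimecourseDataset
from .network import MetabolicNetwork, RegulatoryEdge, TimeGrid

__all__ = [
    "PowerLawModel",
    "NoiseSpec",
    "SimulationError",
    "branched_pathway_network",
    "reference_branched_model",
    "simulate_ode",
    "random_parameter_set",
    "resample_parameters_noisy",
    "perturb_ode_parameters",
    "downsample",
    "add_noise",
    "smooth_impulse",
    "DEFAULT_GRID",
]

#: default simulation horizon: 10 time units sampled at 50 points
DEFAULT_GRID = TimeGrid(0.0, 10.0, 50)

_X_FLOOR = 1e-9  # states are clipped here inside rate laws (fractional powers)


class SimulationError(RuntimeError):
    """ODE integration failed or produced a degenerate trajectory."""


@dataclass
class PowerLawModel:
    """Power-law kinetic model: v_j = a_j * prod_m x_m^g(j, m)."""

    network: MetabolicNetwork
    rate_constants: dict[str, float]
    kinetic_orders: dict[str, dict[str, float]]
    x0: dict[str, float]

    def __post_init__(self):
        rxns = set(self.network.reaction_ids)
        if set(self.rate_constants) != rxns:
            raise ValueError("rate_constants must cover every reaction exactly")
        for rxn, orders in self.kinetic_orders.items():
            if rxn not in rxns:
                raise ValueError(f"kinetic orders reference unknown reaction {rxn!r}")
            for met in orders:
                if met not in self.network.metabolite_ids:
                    raise ValueError(f"kinetic order for {rxn!r} references unknown metabolite {met!r}")
        for met in self.network.metabolite_ids:
            if met not in self.x0:
                raise ValueError(f"x0 missing metabolite {met!r}")
            if self.x0[met] < 0:
                raise ValueError(f"x0[{met!r}] must be >= 0")

    def x0_vector(self) -> np.ndarray:
        return np.asarray([self.x0[m] for m in self.network.metabolite_ids])

    def fluxes_at(self, x: np.ndarray) -> np.ndarray:
        """Instantaneous fluxes at state vector x (ordered as network.metabolite_ids)."""
        xs = np.maximum(x, _X_FLOOR)
        mets = self.network.metabolite_ids
        v = np.empty(self.network.n_reactions)
        for j, rxn in enumerate(self.network.reaction_ids):
            rate = self.rate_constants[rxn]
            for met, g in self.kinetic_orders.get(rxn, {}).items():
                rate *= xs[mets.index(met)] ** g
            v[j] = rate
        return v

    def copy(self) -> "PowerLawModel":
        return replace(
            self,
            rate_constants=dict(self.rate_constants),
            kinetic_orders={r: dict(o) for r, o in self.kinetic_orders.items()},
            x0=dict(self.x0),
        )

    def parameter_vector(self) -> np.ndarray:
        """Flat view (rate constants, kinetic orders, x0) in deterministic order."""
        vals = [self.rate_constants[r] for r in self.network.reaction_ids]
        for r in self.network.reaction_ids:
            for m in sorted(self.kinetic_orders.get(r, {})):
                vals.append(self.kinetic_orders[r][m])
        vals.extend(self.x0[m] for m in self.network.metabolite_ids)
        return np.asarray(vals)


def branched_pathway_network() -> MetabolicNetwork:
    """The fixed branched-pathway topology (5 metabolites incl. biomass, 5 fluxes)."""
    mets = ["x1", "x2", "x3", "x4", "xBM"]
    rxns = ["v1", "v2", "v3", "v4", "v5"]
    S = np.array(
        [
            #  v1   v2   v3   v4   v5
            [1.0, -1.0, 0.0, 0.0, 0.0],   # x1
            [0.0, 1.0, -1.0, -1.0, 0.0],  # x2
            [0.0, 0.0, 1.0, 0.0, -1.0],   # x3
            [0.0, 0.0, 0.0, 1.0, 0.0],    # x4
            [0.0, 0.0, 0.0, 0.0, 1.0],    # xBM
        ]
    )
    edges = [
        RegulatoryEdge("x3", "v1", "negative"),
        RegulatoryEdge("x3", "v4", "positive"),
    ]
    return MetabolicNetwork(mets, rxns, S, edges)


def reference_branched_model() -> PowerLawModel:
    """Synthetic reference parameterization of the branched pathway.

    This is a package-defined fixture, chosen once to give well-scaled,
    non-trivial transients over the default 10-unit horizon.
    """
    return PowerLawModel(
        network=branched_pathway_network(),
        rate_constants={"v1": 1.5, "v2": 2.0, "v3": 1.0, "v4": 1.2, "v5": 0.8},
        kinetic_orders={
            "v1": {"x3": -0.4},
            "v2": {"x1": 0.5},
            "v3": {"x2": 0.7},
            "v4": {"x2": 0.4, "x3": 0.3},
            "v5": {"x3": 0.6},
        },
        x0={"x1": 0.5, "x2": 0.5, "x3": 0.5, "x4": 0.5, "xBM": 0.05},
    )


def simulate_ode(
    model: PowerLawModel,
    grid: TimeGrid = DEFAULT_GRID,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    max_state: float = 1e6,
) -> TimecourseDataset:
    """Integrate the ODE system and sample concentrations, fluxes, and pooling fluxes.

    dx/dt = S v(x) holds along the trajectory by construction; the returned
    pooling fluxes are S v evaluated on the sampled states.
    """

    def rhs(_t, x):
        return model.network.S @ model.fluxes_at(x)

    def diverged(_t, x):  # terminal guard: stop instead of grinding into a blowup
        return max_state - float(np.max(np.abs(x)))

    diverged.terminal = True

    sol = solve_ivp(
        rhs, (grid.t0, grid.tf), model.x0_vector(),
        method="LSODA", t_eval=grid.times, rtol=rtol, atol=atol,
        events=diverged,
    )
    if sol.status == 1:  # divergence event fired
        raise SimulationError(
            f"trajectory diverged (|x| reached {max_state:g}); "
            f"rate constants {model.rate_constants}"
        )
    if not sol.success:
        raise SimulationError(
            f"ODE integration failed ({sol.message}); rate constants {model.rate_constants}"
        )
    X = sol.y.T
    if not np.all(np.isfinite(X)) or np.max(np.abs(X)) > max_state:
        raise SimulationError(
            f"trajectory diverged (max |x| > {max_state:g}); rate constants {model.rate_constants}"
        )
    V = np.vstack([model.fluxes_at(x) for x in X])
    VP = V @ model.network.S.T
    index = pd.Index(grid.times, name="time")
    return TimecourseDataset(
        grid.times,
        pd.DataFrame(X, index=index, columns=model.network.metabolite_ids),
        pd.DataFrame(V, index=index, columns=model.network.reaction_ids),
        pd.DataFrame(VP, index=index, columns=model.network.metabolite_ids),
        provenance={"source": "simulated", "horizon": (grid.t0, grid.tf)},
    )


#: default sampling intervals for random parameterizations:
#: rate constants log-uniform, kinetic-order magnitudes uniform (signs preserved
#: from the template), initial conditions log-uniform
DEFAULT_RANGES = {
    "rate_constant": (0.1, 10.0),
    "kinetic_order": (0.2, 1.0),
    "x0": (0.2, 2.0),
}


def _draw_log_uniform(rng, lo, hi):
    if hi <= lo:
        return lo
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi)))) if lo > 0 else float(rng.uniform(lo, hi))


def random_parameter_set(
    template: PowerLawModel,
    ranges: dict | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    grid: TimeGrid = DEFAULT_GRID,
    max_attempts: int = 50,
    flat_tol: float = 1e-4,
) -> PowerLawModel:
    """Draw a new random parameterization with the template's topology.

    Kinetic-order signs (activation vs inhibition) are preserved.  Candidates
    whose ODE solution fails, diverges, or is numerically flat over the grid
    are rejected and redrawn.
    """
    ranges = {**DEFAULT_RANGES, **(ranges or {})}
    if rng is None:
        rng = np.random.default_rng(seed)
    lo_a, hi_a = ranges["rate_constant"]
    lo_g, hi_g = ranges["kinetic_order"]
    lo_x, hi_x = ranges["x0"]

    for _ in range(max_attempts):
        model = template.copy()
        for rxn in model.rate_constants:
            model.rate_constants[rxn] = _draw_log_uniform(rng, lo_a, hi_a)
        for rxn, orders in model.kinetic_orders.items():
            for met, g in orders.items():
                magnitude = float(rng.uniform(lo_g, hi_g)) if hi_g > lo_g else lo_g
                orders[met] = float(np.sign(g)) * magnitude
        for met in model.x0:
            model.x0[met] = _draw_log_uniform(rng, lo_x, hi_x)
        try:
            data = simulate_ode(model, grid)
        except SimulationError:
            continue
        X = data.concentrations.to_numpy()
        spans = X.max(axis=0) - X.min(axis=0)
        scales = np.maximum(1.0, np.abs(X).max(axis=0))
        if np.max(spans / scales) < flat_tol:
            continue  # all-flat: dynamically degenerate
        return model
    raise SimulationError(
        f"no valid parameter set found in {max_attempts} attempts with ranges {ranges}"
    )


def resample_parameters_noisy(
    model: PowerLawModel,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    include_x0: bool = True,
) -> PowerLawModel:
    """Heavy whole-model perturbation: each parameter magnitude |p| is replaced by
    |N(|p|, |p|)| (signs of kinetic orders preserved; p = 0 stays 0)."""
    if rng is None:
        rng = np.random.default_rng(seed)

    def draw(p: float) -> float:
        mag = abs(p)
        return float(np.sign(p) * abs(rng.normal(mag, mag))) if mag > 0 else 0.0

    out = model.copy()
    for rxn in out.rate_constants:
        out.rate_constants[rxn] = draw(out.rate_constants[rxn])
    for orders in out.kinetic_orders.values():
        for met in orders:
            orders[met] = draw(orders[met])
    if include_x0:
        for met in out.x0:
            out.x0[met] = draw(out.x0[met])
    return out


def perturb_ode_parameters(model: PowerLawModel, targets, factor: float) -> PowerLawModel:
    """Scale the mass-action rate constants of `targets` by `factor` (regulatory
    and kinetic-order parameters untouched); emulates up/down-regulation in truth."""
    if factor <= 0:
        raise ValueError("perturbation factor must be positive")
    targets = list(targets) if not isinstance(targets, str) else [targets]
    unknown = [t for t in targets if t not in model.network.reaction_ids]
    if unknown:
        raise ValueError(f"unknown flux id(s): {unknown}")
    out = model.copy()
    for rxn in targets:
        out.rate_constants[rxn] *= factor
    return out


# ---- noise model -------------------------------------------------------------

@dataclass(frozen=True)
class NoiseSpec:
    """Sampling/noise condition: nT evenly spaced samples, CoV-proportional noise."""

    nT: int
    cov: float
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.nT < 2:
            raise ValueError("nT must be >= 2")
        if self.cov < 0:
            raise ValueError("CoV must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def downsample(dataset: TimecourseDataset, nT: int) -> TimecourseDataset:
    """Down-sample to nT evenly spaced time points (endpoints preserved exactly).

    When the source grid contains the target points as an exact subset they are
    selected directly; otherwise series are linearly interpolated onto the
    evenly spaced grid.
    """
    if nT > dataset.n_points:
        raise ValueError(f"cannot down-sample {dataset.n_points} points to {nT}")
    n = dataset.n_points
    if (n - 1) % (nT - 1) == 0:
        idx = np.arange(0, n, (n - 1) // (nT - 1))
        take = lambda tab: tab.iloc[idx].copy()  # noqa: E731
        new_times = dataset.times[idx]
    else:
        new_times = np.linspace(dataset.times[0], dataset.times[-1], nT)

        def take(tab):
            out = {c: np.interp(new_times, dataset.times, tab[c].to_numpy()) for c in tab.columns}
            return pd.DataFrame(out, index=pd.Index(new_times, name="time"))

    return TimecourseDataset(
        new_times,
        take(dataset.concentrations),
        None if dataset.fluxes is None else take(dataset.fluxes),
        None if dataset.pooling_fluxes is None else take(dataset.pooling_fluxes),
        {**dataset.provenance, "downsampled_to": nT},
    )


def add_noise(
    dataset: TimecourseDataset,
    spec: NoiseSpec,
    clip_nonnegative: bool = False,
) -> list[TimecourseDataset]:
    """Generate noisy replicates: down-sample to spec.nT, then replace every
    metabolite and flux value y with a draw from N(y, CoV*y).

    Draws are not clipped at zero unless `clip_nonnegative` (which applies to
    concentrations only).  Replicates use independent seeded substreams.
    """
    base = downsample(dataset, spec.nT)
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_replicates)
    out = []
    for r, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        rep = base.copy()
        conc = rep.concentrations.to_numpy()
        noisy_conc = rng.normal(conc, spec.cov * np.abs(conc))
        if clip_nonnegative:
            noisy_conc = np.maximum(noisy_conc, 0.0)
        rep.concentrations = pd.DataFrame(
            noisy_conc, index=rep.concentrations.index, columns=rep.concentrations.columns
        )
        if rep.fluxes is not None:
            flux = rep.fluxes.to_numpy()
            rep.fluxes = pd.DataFrame(
                rng.normal(flux, spec.cov * np.abs(flux)),
                index=rep.fluxes.index, columns=rep.fluxes.columns,
            )
        rep.provenance = {
            "source": "noisy", "cov": spec.cov, "nT": spec.nT,
            "replicate": r, "seed": spec.seed,
        }
        out.append(rep)
    return out


# ---- impulse smoothing -------------------------------------------------------

def _impulse(t, h0, h1, h2, beta, t1, t2):
    """Six-parameter double-sigmoid impulse curve (product of onset and offset)."""
    s1 = 1.0 / (1.0 + np.exp(-beta * (t - t1)))
    s2 = 1.0 / (1.0 + np.exp(beta * (t - t2)))
    return (1.0 / h1) * (h0 + (h1 - h0) * s1) * (h2 + (h1 - h2) * s2)


def _fit_impulse_series(t: np.ndarray, y: np.ndarray, rng: np.random.Generator,
                        n_starts: int = 5):
    """Bounded nonlinear least squares with seeded multi-start; returns
    (fitted values, rss) or None when no start converges."""
    span = float(np.ptp(y))
    scale = max(np.max(np.abs(y)), 1e-6)
    lo_h, hi_h = float(np.min(y)) - span - 1e-6, float(np.max(y)) + span + 1e-6
    t_lo, t_hi = float(t[0]), float(t[-1])
    t_span = t_hi - t_lo
    bounds = (
        [lo_h, 1e-6 * scale, lo_h, 1e-3 / t_span, t_lo - t_span, t_lo],
        [hi_h, 2 * scale + 1e-6, hi_h, 1e3 / t_span, t_hi, t_hi + t_span],
    )
    best = None
    for s in range(n_starts):
        beta0 = 10.0 ** rng.uniform(-0.5, 1.0) / t_span
        p0 = np.array([
            float(y[0]),
            float(np.clip(np.max(np.abs(y)), bounds[0][1], bounds[1][1])),
            float(y[-1]),
            beta0,
            t_lo + (0.2 + 0.3 * rng.random()) * t_span,
            t_lo + (0.5 + 0.4 * rng.random()) * t_span,
        ])
        p0 = np.clip(p0, bounds[0], bounds[1])
        try:
            res = least_squares(
                lambda p: _impulse(t, *p) - y, p0, bounds=bounds, max_nfev=2000
            )
        except Exception:
            continue
        rss = float(2 * res.cost)
        if best is None or rss < best[1]:
            best = (res.x, rss)
    if best is None:
        return None
    return _impulse(t, *best[0]), best[1]


def smooth_impulse(dataset: TimecourseDataset, seed: int = 0) -> TimecourseDataset:
    """Replace each metabolite and flux series by its best-fit impulse curve.

    Series whose impulse fit is worse than the constant-mean model (or whose
    fit fails) are returned unsmoothed and flagged in provenance — forcing a
    poorly matched impulse shape onto such data would increase error.
    """
    if dataset.n_points < 6:
        raise ValueError("impulse smoothing needs at least 6 points (6 parameters)")
    rng = np.random.default_rng(seed)
    out = dataset.copy()
    skipped: list[str] = []
    for attr in ("concentrations", "fluxes"):
        tab = getattr(out, attr)
        if tab is None:
            continue
        smoothed = tab.copy()
        for col in tab.columns:
            y = tab[col].to_numpy(dtype=float)
            baseline_rss = float(np.sum((y - np.mean(y)) ** 2))
            if baseline_rss == 0.0:
                continue  # constant series: impulse family contains it; leave as-is
            fit = _fit_impulse_series(dataset.times, y, rng)
            if fit is None or fit[1] > baseline_rss:
                skipped.append(col)
                continue
            smoothed[col] = fit[0]
        setattr(out, attr, smoothed)
    out.provenance = {**dataset.provenance, "smoothed": "impulse", "smoothing_skipped": skipped}
    return out
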