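"""Assembly and solution of the time-unrolled optimization program.

Time is discretized into K uniform steps of length dt.  The decision vector is

    omega = [w(t_1), ..., w(t_K), x(t_0), ..., x(t_K)],   w = [v; v_p]

with fluxes v, pooling fluxes v_p = dx/dt, and concentrations x.  Rows:

* mass balance        [S  -I] w(t_k) = 0                       (k = 1..K)
* Euler update        x(t_k) = x(t_{k-1}) + dt * v_p(t_k)      (k = 1..K)
* initial condition   x(t_0) = x0
* box bounds          w_LB <= w <= w_UB,  x_LB <= x <= x_UB
* kinetics            sum_i v_i(t_{k+1}) <= f_n(x(t_k))        per group n

and the objective maximizes c'omega - lam*omega'omega (a small ridge term
that removes solution degeneracy).  With LR/DR/HP constraints the program is
a convex QP solved directly with OSQP; active NLR rows are concave quadratic
inequalities handled by an outer tangent cutting-plane loop (each tangent of
a concave right-hand side is a valid outer approximation, so the loop
converges to the QCP optimum from above).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data import TimecourseDataset
from .fitting import KineticsConstraint
from .network import MetabolicNetwork, TimeGrid

__all__ = [
    "UnrolledProgram",
    "TrajectorySolution",
    "assemble_program",
    "solve_program",
    "simulate_lkdfba",
    "default_objective_weights",
    "DEFAULT_FLUX_UB",
    "DEFAULT_CONC_UB",
]

#: default (arbitrary, configurable) box bounds
DEFAULT_FLUX_UB = 1e4
DEFAULT_CONC_UB = 1e4

OPTIMAL_STATUSES = ("optimal", "near_optimal")


@dataclass
class QuadRow:
    """One concave quadratic kinetics row: sum(v_vars) <= a*x^2 + b*x + c."""

    v_vars: list[int]
    x_var: int
    a: float
    b: float
    c: float
    x_refs: tuple[float, ...]


@dataclass
class UnrolledProgram:
    network: MetabolicNetwork
    n_steps: int
    dt: float
    t0: float
    lam: float
    q: np.ndarray                 # linear objective coefficients (maximization)
    A_eq: sp.csr_matrix
    b_eq: np.ndarray
    lb: np.ndarray                # per-variable box bounds
    ub: np.ndarray
    A_kin: sp.csr_matrix          # linear kinetics rows, A_kin @ omega <= u_kin
    u_kin: np.ndarray
    quad_rows: list[QuadRow] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def n_variables(self) -> int:
        return len(self.q)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_steps + 1)

    # ---- variable indexing ---------------------------------------------------
    def idx_v(self, step: int, j: int) -> int:
        """Flux j at t_step, step = 1..K."""
        nw = self.network.n_reactions + self.network.n_metabolites
        return (step - 1) * nw + j

    def idx_vp(self, step: int, i: int) -> int:
        nw = self.network.n_reactions + self.network.n_metabolites
        return (step - 1) * nw + self.network.n_reactions + i

    def idx_x(self, step: int, i: int) -> int:
        """Concentration i at t_step, step = 0..K."""
        nw = self.network.n_reactions + self.network.n_metabolites
        return self.n_steps * nw + step * self.network.n_metabolites + i

    def objective_value(self, omega: np.ndarray) -> float:
        return float(self.q @ omega - self.lam * omega @ omega)

    def max_violation(self, omega: np.ndarray) -> float:
        """Worst residual over equality, bound, and kinetics rows (quadratics included)."""
        viol = 0.0
        if self.A_eq.shape[0]:
            viol = max(viol, float(np.max(np.abs(self.A_eq @ omega - self.b_eq))))
        viol = max(viol, float(np.max(self.lb - omega, initial=0.0)))
        viol = max(viol, float(np.max(omega - self.ub, initial=0.0)))
        if self.A_kin.shape[0]:
            viol = max(viol, float(np.max(self.A_kin @ omega - self.u_kin, initial=0.0)))
        for row in self.quad_rows:
            lhs = sum(omega[j] for j in row.v_vars)
            xval = omega[row.x_var]
            viol = max(viol, lhs - (row.a * xval**2 + row.b * xval + row.c))
        return viol


@dataclass
class TrajectorySolution:
    """Optimal trajectories plus solver diagnostics."""

    x: pd.DataFrame               # concentrations, t_0..t_K
    v: pd.DataFrame               # fluxes, t_1..t_K
    v_p: pd.DataFrame             # pooling fluxes, t_1..t_K
    objective: float
    status: str
    max_violation: float
    info: dict = field(default_factory=dict)

    @property
    def is_optimal(self) -> bool:
        return self.status in OPTIMAL_STATUSES

    def to_dataset(self) -> TimecourseDataset:
        """Concentration trajectories as a TimecourseDataset (fluxes attached,
        with the initial time point NaN since v(t_0) is not a decision variable)."""
        fluxes = self.v.reindex(self.x.index)
        return TimecourseDataset(
            self.x.index.to_numpy(dtype=float),
            self.x.copy(),
            fluxes,
            provenance={"source": "lkdfba", "status": self.status},
        )


def default_objective_weights(network: MetabolicNetwork) -> dict[str, float]:
    """Unit weight on the accumulation of every terminal product.

    Terminal products (biomass-like species that are produced but never
    consumed) get weight 1 on their *concentration* at every time point, i.e.
    the objective rewards cumulative production — producing early counts at
    every later time point, which drives flux through the pathway from the
    start instead of hoarding intermediates until the end of the horizon.
    Reactions with no products inside the system (pure effluxes) get weight 1
    on their flux.  Everything else is unweighted.  Used when no validated
    objective exists for the system; always overridable.
    """
    consumed = {
        m for j in range(network.n_reactions) for m in network.substrates(network.reaction_ids[j])
    }
    produced = {
        m for j in range(network.n_reactions) for m in network.products(network.reaction_ids[j])
    }
    weights: dict[str, float] = {}
    for met in network.metabolite_ids:
        if met in produced and met not in consumed:
            weights[met] = 1.0
    for rxn in network.reaction_ids:
        if not network.products(rxn):
            weights[rxn] = 1.0
    if not weights:  # fully cyclic network: fall back to total flux
        weights = {r: 1.0 for r in network.reaction_ids}
    return weights


def assemble_program(
    network: MetabolicNetwork,
    grid: TimeGrid,
    constraints: list[KineticsConstraint],
    x0,
    flux_bounds: dict[str, tuple[float, float]] | None = None,
    conc_bounds: dict[str, tuple[float, float]] | None = None,
    objective_weights: dict[str, float] | None = None,
    lam: float = 1e-4,
    kinetics_from_step: int = 0,
) -> UnrolledProgram:
    """Build the unrolled program for K = grid.n_points - 1 flux steps.

    Kinetics rows bound the target-flux sum at t_{k+1} by the fitted
    right-hand side evaluated at x(t_k), for k = kinetics_from_step..K-1.
    The default (0) constrains every flux step, including v(t_1) via the
    initial concentrations; 1 leaves v(t_1) bounded only by box bounds.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if kinetics_from_step not in (0, 1):
        raise ValueError("kinetics_from_step must be 0 or 1")
    n_m, n_r = network.n_metabolites, network.n_reactions
    K = grid.n_steps
    dt = grid.dt
    nw = n_r + n_m
    n_vars = K * nw + (K + 1) * n_m

    x0 = _as_vector(x0, network.metabolite_ids, "x0")
    met_index = {m: i for i, m in enumerate(network.metabolite_ids)}
    rxn_index = {r: j for j, r in enumerate(network.reaction_ids)}

    prog = UnrolledProgram(
        network=network, n_steps=K, dt=dt, t0=grid.t0, lam=lam,
        q=np.zeros(n_vars), A_eq=sp.csr_matrix((0, n_vars)), b_eq=np.zeros(0),
        lb=np.full(n_vars, -np.inf), ub=np.full(n_vars, np.inf),
        A_kin=sp.csr_matrix((0, n_vars)), u_kin=np.zeros(0),
    )

    # ---- equality rows -------------------------------------------------------
    rows, cols, vals, b_eq = [], [], [], []
    r = 0
    for k in range(1, K + 1):
        # mass balance: S v(t_k) - v_p(t_k) = 0
        for i in range(n_m):
            for j in range(n_r):
                if network.S[i, j] != 0:
                    rows.append(r); cols.append(prog.idx_v(k, j)); vals.append(network.S[i, j])
            rows.append(r); cols.append(prog.idx_vp(k, i)); vals.append(-1.0)
            b_eq.append(0.0)
            r += 1
    for k in range(1, K + 1):
        # Euler: x(t_k) - x(t_{k-1}) - dt * v_p(t_k) = 0
        for i in range(n_m):
            rows.append(r); cols.append(prog.idx_x(k, i)); vals.append(1.0)
            rows.append(r); cols.append(prog.idx_x(k - 1, i)); vals.append(-1.0)
            rows.append(r); cols.append(prog.idx_vp(k, i)); vals.append(-dt)
            b_eq.append(0.0)
            r += 1
    for i in range(n_m):
        rows.append(r); cols.append(prog.idx_x(0, i)); vals.append(1.0)
        b_eq.append(x0[i])
        r += 1
    prog.A_eq = sp.csr_matrix((vals, (rows, cols)), shape=(r, n_vars))
    prog.b_eq = np.asarray(b_eq)

    # ---- box bounds ----------------------------------------------------------
    flux_bounds = {**network.flux_bounds, **(flux_bounds or {})}
    for j, rxn in enumerate(network.reaction_ids):
        lo, hi = flux_bounds.get(
            rxn, (-DEFAULT_FLUX_UB if network.reversible[j] else 0.0, DEFAULT_FLUX_UB)
        )
        for k in range(1, K + 1):
            prog.lb[prog.idx_v(k, j)] = lo
            prog.ub[prog.idx_v(k, j)] = hi
    for i, met in enumerate(network.metabolite_ids):
        lo, hi = (conc_bounds or {}).get(met, (0.0, DEFAULT_CONC_UB))
        for k in range(K + 1):
            prog.lb[prog.idx_x(k, i)] = lo
            prog.ub[prog.idx_x(k, i)] = hi
        # pooling fluxes: bounded by the concentration change achievable in one step
        for k in range(1, K + 1):
            prog.lb[prog.idx_vp(k, i)] = -DEFAULT_FLUX_UB
            prog.ub[prog.idx_vp(k, i)] = DEFAULT_FLUX_UB

    # ---- kinetics rows -------------------------------------------------------
    krows, kcols, kvals, u_kin = [], [], [], []
    kr = 0
    for c in constraints:
        const, lin, quad = c.coefficients()
        v_js = [rxn_index[rxn] for rxn in c.group.target_fluxes]
        if quad:
            (ctrl, a_q), = quad.items()
            b_q = lin.get(ctrl, 0.0)
            if a_q >= 0:
                raise AssertionError(
                    "non-concave quadratic kinetics row reached assembly; "
                    "NLR fitting must fall back to the linear form"
                )
            x_refs = _tangent_refs(c)
            for k in range(kinetics_from_step, K):
                prog.quad_rows.append(QuadRow(
                    [prog.idx_v(k + 1, j) for j in v_js],
                    prog.idx_x(k, met_index[ctrl]),
                    a_q, b_q, const, x_refs,
                ))
            continue
        for k in range(kinetics_from_step, K):
            for j in v_js:
                krows.append(kr); kcols.append(prog.idx_v(k + 1, j)); kvals.append(1.0)
            for met, coef in lin.items():
                krows.append(kr); kcols.append(prog.idx_x(k, met_index[met])); kvals.append(-coef)
            u_kin.append(const)
            kr += 1
    prog.A_kin = sp.csr_matrix((kvals, (krows, kcols)), shape=(kr, n_vars))
    prog.u_kin = np.asarray(u_kin)

    # ---- objective -----------------------------------------------------------
    weights = objective_weights if objective_weights is not None else default_objective_weights(network)
    for sid, w in weights.items():
        if sid in rxn_index:
            j = rxn_index[sid]
            for k in range(1, K + 1):
                prog.q[prog.idx_v(k, j)] = w
        elif sid in met_index:
            i = met_index[sid]
            for k in range(K + 1):
                prog.q[prog.idx_x(k, i)] = w
        else:
            raise ValueError(f"objective weight references unknown species {sid!r}")

    prog.meta = {"approaches": sorted({c.approach for c in constraints})}
    return prog


def _as_vector(x0, ids: list[str], name: str) -> np.ndarray:
    if isinstance(x0, dict):
        missing = [m for m in ids if m not in x0]
        if missing:
            raise ValueError(f"{name} missing entries for {missing}")
        return np.asarray([float(x0[m]) for m in ids])
    arr = np.asarray(x0, dtype=float)
    if arr.shape != (len(ids),):
        raise ValueError(f"{name} has shape {arr.shape}, expected ({len(ids)},)")
    return arr


def _tangent_refs(constraint: KineticsConstraint, n_refs: int = 7) -> tuple[float, ...]:
    """Initial tangent points for a concave quadratic row.

    Spread over the fitted controller range extended by half a range on either
    side (clipped at zero): simulated concentrations often leave the training
    range, and a loose outer approximation there forces many cut rounds.
    """
    rng = constraint.diagnostics.get("x_range")
    if isinstance(rng, (tuple, list)) and len(rng) == 2:
        lo, hi = float(rng[0]), float(rng[1])
    else:
        lo, hi = 0.0, 10.0
    if hi <= lo:
        hi = lo + 1.0
    span = hi - lo
    lo_ext = max(0.0, lo - 0.5 * span)
    hi_ext = hi + 0.5 * span
    return tuple(np.linspace(lo_ext, hi_ext, n_refs))


# ---- solving -----------------------------------------------------------------

def _osqp_solve(P, q, A, l, u, tol, max_iter, warm=None):
    import osqp

    prob = osqp.OSQP()
    prob.setup(
        P=sp.csc_matrix(P), q=q, A=sp.csc_matrix(A), l=l, u=u,
        eps_abs=tol, eps_rel=tol, max_iter=max_iter,
        polishing=True, verbose=False,
    )
    if warm is not None:
        x0, y0 = warm
        y = np.zeros(A.shape[0])
        y[: len(y0)] = y0
        prob.warm_start(x=x0, y=y)
    return prob.solve()


_STATUS_MAP = {
    "solved": "optimal",
    "solved inaccurate": "near_optimal",
    "primal infeasible": "infeasible",
    "primal infeasible inaccurate": "infeasible",
    "dual infeasible": "unbounded",
    "dual infeasible inaccurate": "unbounded",
}


def solve_program(
    program: UnrolledProgram,
    tol: float = 1e-6,
    solver: str = "ipm",
    max_iter: int = 200_000,
    max_cut_rounds: int = 8,
    cut_tol: float = 1e-5,
) -> TrajectorySolution:
    """Solve the assembled convex QP/QCP.

    solver="ipm" (default) uses the package's primal-dual interior-point
    method, which handles the concave-quadratic NLR rows natively.
    solver="osqp" delegates to OSQP, with an outer tangent cutting-plane loop
    for the quadratic rows; it serves as an independent backend.

    Infeasibility is a first-class outcome (status "infeasible"), not an
    exception; solver failures surface as status "solver_error" with details
    in ``info``.
    """
    n = program.n_variables
    if np.any(program.lb > program.ub):
        return _empty_solution(program, "infeasible", {"reason": "lb > ub in box bounds"})
    if solver == "ipm":
        return _solve_ipm(program, tol)
    if solver != "osqp":
        raise ValueError(f"unknown solver {solver!r}; expected 'ipm' or 'osqp'")

    P = sp.diags(np.full(n, 2.0 * program.lam))
    q = -program.q

    eye = sp.identity(n, format="csr")
    base_A = [program.A_eq, eye, program.A_kin]
    base_l = [program.b_eq, program.lb, np.full(program.A_kin.shape[0], -np.inf)]
    base_u = [program.b_eq, program.ub, program.u_kin]

    # initial outer approximation of concave quadratic rows
    cuts: list[tuple[list[int], int, float, float]] = []  # (v_vars, x_var, slope, offset)
    for row in program.quad_rows:
        for xr in row.x_refs:
            cuts.append(_tangent(row, xr))

    res = None
    warm = None
    n_rounds = 0
    for n_rounds in range(1, max_cut_rounds + 1):
        A, l, u = _stack_with_cuts(base_A, base_l, base_u, cuts, n)
        res = _osqp_solve(P, q, A, l, u, tol, max_iter, warm=warm)
        status = _STATUS_MAP.get(res.info.status, "solver_error")
        if status not in OPTIMAL_STATUSES:
            return _empty_solution(
                program, status,
                {"osqp_status": res.info.status, "cut_rounds": n_rounds},
            )
        omega = np.asarray(res.x)
        warm = (omega, np.asarray(res.y))
        if not program.quad_rows:
            break
        new_cuts = []
        for row in program.quad_rows:
            lhs = sum(omega[j] for j in row.v_vars)
            xv = omega[row.x_var]
            if lhs - (row.a * xv**2 + row.b * xv + row.c) > cut_tol:
                new_cuts.append(_tangent(row, xv))
        if not new_cuts:
            break
        cuts.extend(new_cuts)
    else:
        # loop exhausted without closing the gap
        pass

    omega = np.asarray(res.x)
    status = _STATUS_MAP.get(res.info.status, "solver_error")
    return _unpack(program, omega, status, {
        "osqp_status": res.info.status,
        "osqp_iterations": int(res.info.iter),
        "cut_rounds": n_rounds,
        "n_cuts": len(cuts),
    })


def _solve_ipm(program: UnrolledProgram, tol: float) -> TrajectorySolution:
    from .qcp import QuadIneq, solve_qcp

    n = program.n_variables
    P_diag = np.full(n, 2.0 * program.lam)
    q = -program.q

    rows, cols, vals, h = [], [], [], []
    r = 0
    for i in range(n):
        if np.isfinite(program.ub[i]):
            rows.append(r); cols.append(i); vals.append(1.0); h.append(program.ub[i]); r += 1
        if np.isfinite(program.lb[i]):
            rows.append(r); cols.append(i); vals.append(-1.0); h.append(-program.lb[i]); r += 1
    G_box = sp.csr_matrix((vals, (rows, cols)), shape=(r, n))
    if program.A_kin.shape[0]:
        G = sp.vstack([G_box, program.A_kin], format="csr")
        h = np.concatenate([np.asarray(h), program.u_kin])
    else:
        G = G_box
        h = np.asarray(h)
    quads = [
        QuadIneq(tuple(row.v_vars), row.x_var, row.a, row.b, row.c)
        for row in program.quad_rows
    ]
    # interior-point iterations are cheap; solve tighter than the requested
    # tolerance so reported violations sit well inside it
    ipm_tol = min(tol, 1e-8)
    res = solve_qcp(P_diag, q, program.A_eq, program.b_eq, G, h, quads, tol=ipm_tol)
    info = {"solver": "ipm", "ipm_iterations": res.iterations, "mu": res.mu}
    if res.status != "optimal":
        return _empty_solution(program, res.status, info)
    return _unpack(program, res.x, "optimal", info)


def _tangent(row: QuadRow, x_ref: float) -> tuple[list[int], int, float, float]:
    """Tangent of the concave RHS at x_ref: v_sum <= (2a*x_ref + b)*x + (c - a*x_ref^2)."""
    slope = 2.0 * row.a * x_ref + row.b
    offset = row.c - row.a * x_ref**2
    return (row.v_vars, row.x_var, slope, offset)


def _stack_with_cuts(base_A, base_l, base_u, cuts, n):
    if cuts:
        rows, cols, vals, ub = [], [], [], []
        for r, (v_vars, x_var, slope, offset) in enumerate(cuts):
            for j in v_vars:
                rows.append(r); cols.append(j); vals.append(1.0)
            rows.append(r); cols.append(x_var); vals.append(-slope)
            ub.append(offset)
        A_cut = sp.csr_matrix((vals, (rows, cols)), shape=(len(cuts), n))
        A = sp.vstack(base_A + [A_cut], format="csc")
        l = np.concatenate(base_l + [np.full(len(cuts), -np.inf)])
        u = np.concatenate(base_u + [np.asarray(ub)])
    else:
        A = sp.vstack(base_A, format="csc")
        l = np.concatenate(base_l)
        u = np.concatenate(base_u)
    return A, l, u


def _unpack(program: UnrolledProgram, omega: np.ndarray, status: str, info: dict) -> TrajectorySolution:
    net = program.network
    K = program.n_steps
    times = program.times
    x = np.empty((K + 1, net.n_metabolites))
    v = np.empty((K, net.n_reactions))
    vp = np.empty((K, net.n_metabolites))
    for k in range(K + 1):
        for i in range(net.n_metabolites):
            x[k, i] = omega[program.idx_x(k, i)]
    for k in range(1, K + 1):
        for j in range(net.n_reactions):
            v[k - 1, j] = omega[program.idx_v(k, j)]
        for i in range(net.n_metabolites):
            vp[k - 1, i] = omega[program.idx_vp(k, i)]
    return TrajectorySolution(
        x=pd.DataFrame(x, index=pd.Index(times, name="time"), columns=net.metabolite_ids),
        v=pd.DataFrame(v, index=pd.Index(times[1:], name="time"), columns=net.reaction_ids),
        v_p=pd.DataFrame(vp, index=pd.Index(times[1:], name="time"), columns=net.metabolite_ids),
        objective=program.objective_value(omega),
        status=status,
        max_violation=program.max_violation(omega),
        info=info,
    )


def _empty_solution(program: UnrolledProgram, status: str, info: dict) -> TrajectorySolution:
    net = program.network
    times = program.times
    nan_x = pd.DataFrame(np.nan, index=pd.Index(times, name="time"), columns=net.metabolite_ids)
    nan_v = pd.DataFrame(np.nan, index=pd.Index(times[1:], name="time"), columns=net.reaction_ids)
    nan_vp = pd.DataFrame(np.nan, index=pd.Index(times[1:], name="time"), columns=net.metabolite_ids)
    return TrajectorySolution(nan_x, nan_v, nan_vp, float("nan"), status, float("nan"), info)


def simulate_lkdfba(
    network: MetabolicNetwork,
    constraints: list[KineticsConstraint],
    x0,
    grid: TimeGrid,
    objective_weights: dict[str, float] | None = None,
    lam: float = 1e-4,
    flux_bounds: dict[str, tuple[float, float]] | None = None,
    conc_bounds: dict[str, tuple[float, float]] | None = None,
    kinetics_from_step: int = 0,
    tol: float = 1e-6,
) -> TrajectorySolution:
    """Convenience composition: assemble the program and solve it."""
    prog = assemble_program(
        network, grid, constraints, x0,
        flux_bounds=flux_bounds, conc_bounds=conc_bounds,
        objective_weights=objective_weights, lam=lam,
        kinetics_from_step=kinetics_from_step,
    )
    return solve_program(prog, tol=tol)
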