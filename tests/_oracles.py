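"""Independent reference assemblies used by the solver-correctness tests.

These build the optimization problem directly from its mathematical statement
(dense matrices, scipy.optimize generic solvers), sharing no assembly code
with the package's sparse program builder or interior-point solver.
"""

import numpy as np
from scipy.optimize import linprog, minimize


def generic_solve(network, grid, constraints, x0, objective_weights, lam,
                  flux_bounds=None, conc_bounds=None, kinetics_from_step=0,
                  flux_ub=1e4, conc_ub=1e4):
    """Solve the unrolled program with SLSQP on a dense, independently built
    formulation.  Returns (objective, omega, layout) or (None, None, layout)
    when SLSQP reports failure.

    Variable layout (deliberately different from the package's interleaved
    layout): [v(1..K) | vp(1..K) | x(0..K)] grouped by kind.
    """
    mets, rxns = network.metabolite_ids, network.reaction_ids
    n_m, n_r = len(mets), len(rxns)
    K = grid.n_points - 1
    dt = grid.dt
    nv, nvp, nx = K * n_r, K * n_m, (K + 1) * n_m
    n = nv + nvp + nx

    def iv(k, j):
        return (k - 1) * n_r + j

    def ivp(k, i):
        return nv + (k - 1) * n_m + i

    def ix(k, i):
        return nv + nvp + k * n_m + i

    layout = (iv, ivp, ix, n)

    c = np.zeros(n)
    for sid, wgt in objective_weights.items():
        if sid in rxns:
            j = rxns.index(sid)
            for k in range(1, K + 1):
                c[iv(k, j)] = wgt
        else:
            i = mets.index(sid)
            for k in range(K + 1):
                c[ix(k, i)] = wgt

    A_eq, b_eq = [], []
    for k in range(1, K + 1):
        for i in range(n_m):
            row = np.zeros(n)
            for j in range(n_r):
                row[iv(k, j)] = network.S[i, j]
            row[ivp(k, i)] = -1.0
            A_eq.append(row)
            b_eq.append(0.0)
            row = np.zeros(n)
            row[ix(k, i)] = 1.0
            row[ix(k - 1, i)] = -1.0
            row[ivp(k, i)] = -dt
            A_eq.append(row)
            b_eq.append(0.0)
    for i in range(n_m):
        row = np.zeros(n)
        row[ix(0, i)] = 1.0
        A_eq.append(row)
        b_eq.append(float(x0[i]))
    A_eq = np.asarray(A_eq)
    b_eq = np.asarray(b_eq)

    bounds = [(None, None)] * n
    fb = dict(flux_bounds or {})
    for j, rxn in enumerate(rxns):
        lo, hi = fb.get(rxn, (-flux_ub if network.reversible[j] else 0.0, flux_ub))
        for k in range(1, K + 1):
            bounds[iv(k, j)] = (lo, hi)
    for i, met in enumerate(mets):
        lo, hi = (conc_bounds or {}).get(met, (0.0, conc_ub))
        for k in range(K + 1):
            bounds[ix(k, i)] = (lo, hi)
    for i in range(n_m):
        for k in range(1, K + 1):
            bounds[ivp(k, i)] = (-flux_ub, flux_ub)

    ineqs = []  # list of callables g(w) >= 0 (scipy convention)
    for con in constraints:
        v_js = [rxns.index(r) for r in con.group.target_fluxes]
        for k in range(kinetics_from_step, K):
            def g(w, con=con, v_js=v_js, k=k):
                xvec = {m: w[ix(k, mets.index(m))] for m in mets}
                lhs = sum(w[iv(k + 1, j)] for j in v_js)
                return con.evaluate(xvec) - lhs
            ineqs.append(g)

    def neg_obj(w):
        return -(c @ w - lam * w @ w)

    def neg_obj_grad(w):
        return -(c - 2 * lam * w)

    w0 = np.zeros(n)
    for i in range(n_m):
        for k in range(K + 1):
            w0[ix(k, i)] = x0[i]
    res = minimize(
        neg_obj, w0, jac=neg_obj_grad, method="SLSQP",
        bounds=bounds,
        constraints=(
            [{"type": "eq", "fun": lambda w: A_eq @ w - b_eq, "jac": lambda w: A_eq}]
            + [{"type": "ineq", "fun": g} for g in ineqs]
        ),
        options={"maxiter": 600, "ftol": 1e-12},
    )
    if not res.success:
        return None, None, layout
    return -res.fun, res.x, layout


def lp_oracle(network, grid, constraints, x0, objective_weights,
              flux_bounds=None, conc_bounds=None, kinetics_from_step=0,
              flux_ub=1e4, conc_ub=1e4):
    """HiGHS LP reference for programs with linear kinetics rows and lam = 0.

    Returns (status, objective): status 'optimal' or 'infeasible'.
    """
    mets, rxns = network.metabolite_ids, network.reaction_ids
    n_m, n_r = len(mets), len(rxns)
    K = grid.n_points - 1
    dt = grid.dt
    nv, nvp = K * n_r, K * n_m
    n = nv + nvp + (K + 1) * n_m

    def iv(k, j):
        return (k - 1) * n_r + j

    def ivp(k, i):
        return nv + (k - 1) * n_m + i

    def ix(k, i):
        return nv + nvp + k * n_m + i

    c = np.zeros(n)
    for sid, wgt in objective_weights.items():
        if sid in rxns:
            for k in range(1, K + 1):
                c[iv(k, rxns.index(sid))] = wgt
        else:
            for k in range(K + 1):
                c[ix(k, mets.index(sid))] = wgt

    A_eq, b_eq = [], []
    for k in range(1, K + 1):
        for i in range(n_m):
            row = np.zeros(n)
            row[[iv(k, j) for j in range(n_r)]] = network.S[i, :]
            row[ivp(k, i)] = -1.0
            A_eq.append(row); b_eq.append(0.0)
            row = np.zeros(n)
            row[ix(k, i)] = 1.0; row[ix(k - 1, i)] = -1.0; row[ivp(k, i)] = -dt
            A_eq.append(row); b_eq.append(0.0)
    for i in range(n_m):
        row = np.zeros(n)
        row[ix(0, i)] = 1.0
        A_eq.append(row); b_eq.append(float(x0[i]))

    A_ub, b_ub = [], []
    for con in constraints:
        const, lin, quad = con.coefficients()
        assert not quad, "lp_oracle handles linear kinetics rows only"
        v_js = [rxns.index(r) for r in con.group.target_fluxes]
        for k in range(kinetics_from_step, K):
            row = np.zeros(n)
            for j in v_js:
                row[iv(k + 1, j)] = 1.0
            for met, coef in lin.items():
                row[ix(k, mets.index(met))] = -coef
            A_ub.append(row); b_ub.append(const)

    bounds = [(None, None)] * n
    fb = dict(flux_bounds or {})
    for j, rxn in enumerate(rxns):
        lo, hi = fb.get(rxn, (-flux_ub if network.reversible[j] else 0.0, flux_ub))
        for k in range(1, K + 1):
            bounds[iv(k, j)] = (lo, hi)
    for i, met in enumerate(mets):
        lo, hi = (conc_bounds or {}).get(met, (0.0, conc_ub))
        for k in range(K + 1):
            bounds[ix(k, i)] = (lo, hi)
    for i in range(n_m):
        for k in range(1, K + 1):
            bounds[ivp(k, i)] = (-flux_ub, flux_ub)

    res = linprog(
        -c, A_ub=np.asarray(A_ub) if A_ub else None,
        b_ub=np.asarray(b_ub) if b_ub else None,
        A_eq=np.asarray(A_eq), b_eq=np.asarray(b_eq),
        bounds=bounds, method="highs",
    )
    if res.status == 2:
        return "infeasible", None
    return "optimal", -res.fun
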