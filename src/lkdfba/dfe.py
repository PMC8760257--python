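"""Dynamic flux estimation: infer fluxes from concentration time courses.

Each metabolite series is smoothed with a cubic smoothing spline (penalty
selected by generalized cross-validation); the spline derivative gives the
pooling flux v_p,i(t_k) = dx_i/dt.  Fluxes then solve S v(t_k) = v_p(t_k)
pointwise in the least-squares sense, subject to non-negativity for
irreversible reactions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import lsq_linear

from .network import MetabolicNetwork

__all__ = ["estimate_fluxes_dfe"]


def estimate_fluxes_dfe(
    network: MetabolicNetwork,
    concentrations: pd.DataFrame,
    times: np.ndarray | None = None,
    smoothing: str | float | None = "gcv",
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Infer fluxes and pooling fluxes from concentrations.

    Parameters
    ----------
    concentrations
        Table (time x metabolite); index used as time if `times` is None.
    smoothing
        "gcv" (default) selects the spline penalty by generalized
        cross-validation; a float fixes the penalty; None interpolates
        (no smoothing), appropriate for noiseless data.

    Returns
    -------
    (fluxes, pooling_fluxes, diagnostics)
        DataFrames on the same time index plus human-readable warnings.
    """
    if times is None:
        times = concentrations.index.to_numpy(dtype=float)
    times = np.asarray(times, dtype=float)
    diagnostics: list[str] = []

    cols = [m for m in network.metabolite_ids if m in concentrations.columns]
    missing = [m for m in network.metabolite_ids if m not in concentrations.columns]
    if missing:
        raise ValueError(f"concentration table missing metabolite(s): {missing}")

    lam = None if smoothing == "gcv" else smoothing
    vp = np.empty((len(times), len(cols)))
    for j, met in enumerate(cols):
        y = concentrations[met].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            vp[:, j] = 0.0
            continue
        if smoothing is None:
            spline = make_smoothing_spline(times, y, lam=0.0)
        else:
            spline = make_smoothing_spline(times, y, lam=lam)
        vp[:, j] = spline.derivative()(times)

    S = network.S[[network.metabolite_ids.index(m) for m in cols], :]
    rank = np.linalg.matrix_rank(S)
    if rank < network.n_reactions:
        diagnostics.append(
            f"stoichiometry rank {rank} < {network.n_reactions} reactions: fluxes are "
            "underdetermined; returning minimum-norm solutions. A substantial amount of "
            "concentration data is recommended before relying on DFE."
        )

    lb = np.where(network.reversible, -np.inf, 0.0)
    ub = np.full(network.n_reactions, np.inf)
    v = np.empty((len(times), network.n_reactions))
    for k in range(len(times)):
        target = vp[k]
        # unconstrained minimum-norm first; fall back to bounded solve only if needed
        sol, *_ = np.linalg.lstsq(S, target, rcond=None)
        if np.all(sol >= lb - 1e-12):
            v[k] = np.maximum(sol, lb)
        else:
            res = lsq_linear(S, target, bounds=(lb, ub))
            v[k] = res.x

    index = pd.Index(times, name="time")
    fluxes = pd.DataFrame(v, index=index, columns=network.reaction_ids)
    pooling = pd.DataFrame(vp, index=index, columns=cols)
    return fluxes, pooling, diagnostics
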