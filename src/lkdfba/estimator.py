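"""Scikit-learn-style estimator wrapping the fit-constraints / simulate loop.

``LKDFBA`` fits kinetics constraints to a time-course dataset (``fit``),
simulates the resulting time-unrolled program (``predict``), and scores
predictions as negative NRMSE (``score``), composing with sklearn's
``get_params``/``set_params``/``clone`` machinery.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .data import TimecourseDataset
from .dfe import estimate_fluxes_dfe
from .evaluation import nrmse
from .fitting import fit_constraints, scale_constraints
from .network import MetabolicNetwork, TimeGrid, derive_interaction_groups
from .program import TrajectorySolution, simulate_lkdfba

__all__ = ["LKDFBA"]


class LKDFBA(BaseEstimator):
    """Linear Kinetics-Dynamic FBA model with a selectable constraint class.

    Parameters
    ----------
    network
        The metabolic network (stoichiometry + regulatory edges).
    approach
        Constraint class: "LR", "NLR", "DR", or "HP".
    lag
        Regression pairing offset: v(t_{k+lag}) is paired with x(t_k); the
        default 0 pairs same-index samples.
    lam
        Ridge penalty on the decision vector (resolves solution degeneracy).
    objective_weights
        Per-species weights of the linear objective term; None selects unit
        weights on terminal-product fluxes.
    kinetics_from_step
        First discrete step whose flux is bounded by kinetics constraints
        (0 bounds every step, 1 leaves the first step box-bounded only).
    use_dfe
        "auto" runs dynamic flux estimation when the training data carry no
        fluxes; True forces it; False requires measured fluxes.

    Attributes
    ----------
    constraints_ : list of fitted KineticsConstraint
    groups_ : interaction groups the constraints were fitted to
    x0_ : initial concentrations from the training data
    training_grid_ : TimeGrid of the training data
    dfe_diagnostics_ : warnings from DFE (empty when DFE was not used)
    """

    def __init__(
        self,
        network: MetabolicNetwork | None = None,
        approach: str = "LR",
        lag: int = 0,
        lam: float = 1e-4,
        objective_weights: dict | None = None,
        flux_bounds: dict | None = None,
        conc_bounds: dict | None = None,
        kinetics_from_step: int = 0,
        solver_tol: float = 1e-6,
        use_dfe: str | bool = "auto",
    ):
        self.network = network
        self.approach = approach
        self.lag = lag
        self.lam = lam
        self.objective_weights = objective_weights
        self.flux_bounds = flux_bounds
        self.conc_bounds = conc_bounds
        self.kinetics_from_step = kinetics_from_step
        self.solver_tol = solver_tol
        self.use_dfe = use_dfe

    # ------------------------------------------------------------------
    def fit(self, X: TimecourseDataset, y=None) -> "LKDFBA":
        """Fit kinetics constraints to a TimecourseDataset."""
        if self.network is None:
            raise ValueError("LKDFBA requires a network before fitting")
        if not isinstance(X, TimecourseDataset):
            raise TypeError("X must be a TimecourseDataset")
        ds = X
        self.dfe_diagnostics_: list[str] = []
        need_dfe = self.use_dfe is True or (self.use_dfe == "auto" and ds.fluxes is None)
        if need_dfe:
            if ds.fluxes is not None and self.use_dfe == "auto":
                need_dfe = False
        if need_dfe:
            fluxes, pooling, diags = estimate_fluxes_dfe(self.network, ds.concentrations)
            ds = ds.copy()
            ds.fluxes = fluxes
            ds.pooling_fluxes = pooling
            self.dfe_diagnostics_ = diags
        elif ds.fluxes is None:
            raise ValueError("dataset has no fluxes and use_dfe=False")
        self.groups_ = derive_interaction_groups(
            self.network, "grouped" if self.approach in ("DR", "HP") else "paired"
        )
        self.constraints_ = fit_constraints(self.network, ds, self.approach, lag=self.lag)
        self.x0_ = ds.concentrations.iloc[0].to_dict()
        self.training_grid_ = TimeGrid(ds.times[0], ds.times[-1], ds.n_points)
        return self

    def perturbed(self, targets, factor: float) -> "LKDFBA":
        """A copy of the fitted model with constraints on `targets` scaled by
        `factor` (in-silico up/down-regulation)."""
        self._check_fitted()
        other = LKDFBA(**self.get_params())
        other.constraints_ = scale_constraints(
            self.constraints_, targets, factor, known_reactions=self.network.reaction_ids
        )
        other.groups_ = self.groups_
        other.x0_ = dict(self.x0_)
        other.training_grid_ = self.training_grid_
        other.dfe_diagnostics_ = list(self.dfe_diagnostics_)
        return other

    def predict(self, X=None, *, x0=None, grid: TimeGrid | None = None) -> TrajectorySolution:
        """Simulate the fitted program.

        `X` may be a TimecourseDataset supplying the grid (and default x0);
        otherwise the training grid and training initial conditions are used.
        """
        self._check_fitted()
        if isinstance(X, TimecourseDataset):
            grid = grid or TimeGrid(X.times[0], X.times[-1], X.n_points)
            if x0 is None:
                x0 = X.concentrations.iloc[0].to_dict()
        grid = grid or self.training_grid_
        x0 = x0 if x0 is not None else self.x0_
        return simulate_lkdfba(
            self.network, self.constraints_, x0, grid,
            objective_weights=self.objective_weights, lam=self.lam,
            flux_bounds=self.flux_bounds, conc_bounds=self.conc_bounds,
            kinetics_from_step=self.kinetics_from_step, tol=self.solver_tol,
        )

    def score(self, X: TimecourseDataset, y=None) -> float:
        """Negative NRMSE of the simulated trajectory against `X` (higher is better);
        -inf when the program is infeasible."""
        sol = self.predict(X)
        if not sol.is_optimal:
            return -np.inf
        return -nrmse(sol.to_dataset(), X)

    def _check_fitted(self):
        if not hasattr(self, "constraints_"):
            raise ValueError("this LKDFBA instance is not fitted yet; call fit first")
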