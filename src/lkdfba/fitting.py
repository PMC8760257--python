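"""Fitting the four kinetics-constraint classes (LR, NLR, DR, HP).

Each constraint is an inequality bounding a flux from above by a function of
its controller metabolite concentrations, parameterized by least squares on
time-course data:

* LR  — ``v <= a*x + b`` (one controller per constraint),
* NLR — ``v <= a*x**2 + b*x + c`` with ``a < 0`` (concave; falls back to the
  LR form whenever the fitted quadratic coefficient is not negative, so the
  feasible region stays convex),
* DR  — ``v <= a*PC1(x_1..x_n) + b`` where PC1 is the first principal
  component of the autoscaled controller matrix,
* HP  — ``v <= b + sum_i a_i*x_i`` (multivariate hyperplane).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .network import InteractionGroup, MetabolicNetwork, derive_interaction_groups

__all__ = [
    "KineticsConstraint",
    "fit_lr",
    "fit_nlr",
    "fit_dr",
    "fit_hp",
    "fit_constraints",
    "scale_constraints",
    "save_constraints",
    "load_constraints",
    "APPROACHES",
    "GROUPING_MODE",
]

APPROACHES = ("LR", "NLR", "DR", "HP")
#: grouping mode used when deriving interaction groups for each approach
GROUPING_MODE = {"LR": "paired", "NLR": "paired", "DR": "grouped", "HP": "grouped"}

#: fitted NLR quadratic coefficients must be strictly below -EPS_CONVEXITY to
#: keep the quadratic form; flat data falls back to the linear constraint
EPS_CONVEXITY = 1e-10


@dataclass
class KineticsConstraint:
    """One fitted inequality bounding the flux(es) of an interaction group.

    ``params`` is approach-specific:

    * LR:  {a, b}
    * NLR: {a, b, c, quadratic_active}; when inactive, a==0 and (b, c) hold
      the linear-fallback slope/intercept
    * DR:  {a, b, loading, center, scale, controllers}
    * HP:  {b, a: coefficient vector, controllers}
    """

    group: InteractionGroup
    approach: str
    params: dict
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.approach not in APPROACHES:
            raise ValueError(f"unknown approach {self.approach!r}")
        if self.approach == "NLR" and self.params.get("quadratic_active"):
            if not self.params["a"] < 0:
                raise ValueError("active NLR quadratic requires a < 0 (convexity)")
        if self.approach == "DR":
            loading = np.asarray(self.params["loading"], dtype=float)
            if loading.size and abs(np.linalg.norm(loading) - 1.0) > 1e-8:
                raise ValueError("DR loading vector must have unit norm")

    # ---- linear/quadratic view used by program assembly ----------------------
    def coefficients(self) -> tuple[float, dict[str, float], dict[str, float]]:
        """Return (constant, linear coefs per metabolite, quadratic coefs per metabolite)
        of the right-hand side f(x) with flux <= f(x)."""
        p = self.params
        if self.approach == "LR":
            (ctrl,) = self.group.controllers
            return p["b"], {ctrl: p["a"]}, {}
        if self.approach == "NLR":
            (ctrl,) = self.group.controllers
            if p.get("quadratic_active"):
                return p["c"], {ctrl: p["b"]}, {ctrl: p["a"]}
            return p["c"], {ctrl: p["b"]}, {}
        if self.approach == "HP":
            ctrls = list(p["controllers"])
            coefs = np.asarray(p["a"], dtype=float)
            return p["b"], dict(zip(ctrls, coefs)), {}
        # DR: a * loading.((x - center)/scale) + b, expanded to linear form in x
        ctrls = list(p["controllers"])
        loading = np.asarray(p["loading"], dtype=float)
        center = np.asarray(p["center"], dtype=float)
        scale = np.asarray(p["scale"], dtype=float)
        if loading.size == 0:  # all controllers degenerate
            return p["b"], {}, {}
        lin = p["a"] * loading / scale
        const = p["b"] - float(np.dot(lin, center))
        return const, dict(zip(ctrls, lin)), {}

    def evaluate(self, x: dict[str, float]) -> float:
        """Right-hand side of the constraint at concentration vector `x`."""
        const, lin, quad = self.coefficients()
        val = const
        for met, c in lin.items():
            val += c * x[met]
        for met, c in quad.items():
            val += c * x[met] ** 2
        return val

    def scaled(self, factor: float) -> "KineticsConstraint":
        """All right-hand-side parameters multiplied by `factor`."""
        p = dict(self.params)
        for key in ("a", "b", "c"):
            if key in p:
                v = p[key]
                p[key] = (np.asarray(v, dtype=float) * factor if isinstance(v, (list, tuple, np.ndarray)) else v * factor)
        return replace(self, params=p, diagnostics=dict(self.diagnostics))


# ---- elementary fitters ------------------------------------------------------

def _ols_line(x: np.ndarray, v: np.ndarray) -> tuple[float, float, float, dict]:
    """Ordinary least-squares line v ~ a*x + b; returns (a, b, rss, diagnostics)."""
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    if x.shape != v.shape:
        raise ValueError(f"series length mismatch: {x.shape} vs {v.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 points for a linear fit")
    diag: dict = {"n_points": int(x.size)}
    if np.ptp(x) == 0 or np.var(x) == 0:
        a, b = 0.0, float(np.mean(v))
        diag["degenerate"] = "zero-variance controller"
    else:
        a, b = np.polyfit(x, v, 1)
        a, b = float(a), float(b)
    rss = float(np.sum((v - (a * x + b)) ** 2))
    diag["rss"] = rss
    diag["x_range"] = (float(np.min(x)), float(np.max(x)))
    return a, b, rss, diag


def fit_lr(v: np.ndarray, x: np.ndarray, group: InteractionGroup | None = None) -> KineticsConstraint:
    """Linear constraint v <= a*x + b via OLS on paired (x(t_k), v(t_k)) samples."""
    a, b, _, diag = _ols_line(x, v)
    group = group or _anonymous_group(("v",), ("x",))
    return KineticsConstraint(group, "LR", {"a": a, "b": b}, diag)


def fit_nlr(v: np.ndarray, x: np.ndarray, group: InteractionGroup | None = None) -> KineticsConstraint:
    """Concave quadratic constraint v <= a*x^2 + b*x + c, LR fallback when a >= -eps."""
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    if x.shape != v.shape:
        raise ValueError(f"series length mismatch: {x.shape} vs {v.shape}")
    group = group or _anonymous_group(("v",), ("x",))
    diag: dict = {"n_points": int(x.size)}

    def _fallback(reason: str) -> KineticsConstraint:
        a_l, b_l, rss, d = _ols_line(x, v)
        d.update(diag)
        d["fallback"] = reason
        params = {"a": 0.0, "b": a_l, "c": b_l, "quadratic_active": False}
        return KineticsConstraint(group, "NLR", params, d)

    if x.size < 3:
        return _fallback("fewer than 3 points for quadratic fit")
    if np.var(x) == 0:
        return _fallback("zero-variance controller")
    design = np.column_stack([x**2, x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    a_q, b_q, c_q = (float(c) for c in coef)
    if a_q < -EPS_CONVEXITY:
        diag["rss"] = float(np.sum((v - design @ coef) ** 2))
        diag["x_range"] = (float(np.min(x)), float(np.max(x)))
        params = {"a": a_q, "b": b_q, "c": c_q, "quadratic_active": True}
        return KineticsConstraint(group, "NLR", params, diag)
    return _fallback(f"fitted quadratic coefficient {a_q:.3g} not negative")


def fit_dr(v: np.ndarray, X: np.ndarray, group: InteractionGroup | None = None,
           controllers: list[str] | None = None) -> KineticsConstraint:
    """Principal-component constraint v <= a*PC1(x) + b.

    Controller columns are autoscaled (mean-centered, unit variance) before
    PCA; constant columns are dropped with a diagnostic.  The PC1 sign is
    fixed so the fitted slope `a` is non-negative.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    v = np.asarray(v, dtype=float)
    if X.shape[0] != v.size:
        raise ValueError(f"controller matrix has {X.shape[0]} rows, flux series {v.size}")
    if X.shape[1] == 0:
        raise ValueError("DR constraint requires at least one controller")
    group = group or _anonymous_group(("v",), tuple(f"x{i}" for i in range(X.shape[1])))
    ctrls = list(controllers) if controllers is not None else list(group.controllers)
    diag: dict = {"n_points": int(v.size)}

    stds = X.std(axis=0, ddof=0)
    keep = stds > 0
    if not np.all(keep):
        diag["dropped_controllers"] = [c for c, k in zip(ctrls, keep) if not k]
    if not np.any(keep):
        params = {"a": 0.0, "b": float(np.mean(v)), "loading": np.zeros(0),
                  "center": np.zeros(0), "scale": np.ones(0), "controllers": []}
        diag["degenerate"] = "all controllers constant"
        return KineticsConstraint(group, "DR", params, diag)

    Xk = X[:, keep]
    kept = [c for c, k in zip(ctrls, keep) if k]
    center = Xk.mean(axis=0)
    scale = Xk.std(axis=0, ddof=0)
    Z = (Xk - center) / scale
    # PC1 via SVD of the autoscaled matrix
    _, svals, Vt = np.linalg.svd(Z, full_matrices=False)
    loading = Vt[0]
    scores = Z @ loading
    total_var = float(np.sum(svals**2))
    diag["explained_variance_ratio"] = float(svals[0] ** 2 / total_var) if total_var > 0 else 0.0
    a, b, rss, d = _ols_line(scores, v)
    if a < 0:  # resolve PCA sign ambiguity deterministically
        loading = -loading
        a = -a
    diag.update({"rss": rss})
    diag["x_range"] = {c: (float(col.min()), float(col.max())) for c, col in zip(kept, Xk.T)}
    params = {"a": float(a), "b": float(b), "loading": loading, "center": center,
              "scale": scale, "controllers": kept}
    return KineticsConstraint(group, "DR", params, diag)


def fit_hp(v: np.ndarray, X: np.ndarray, group: InteractionGroup | None = None,
           controllers: list[str] | None = None) -> KineticsConstraint:
    """Hyperplane constraint v <= b + sum_i a_i x_i via minimum-norm least squares."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    v = np.asarray(v, dtype=float)
    if X.shape[0] != v.size:
        raise ValueError(f"controller matrix has {X.shape[0]} rows, flux series {v.size}")
    if X.shape[1] == 0:
        raise ValueError("HP constraint requires at least one controller")
    group = group or _anonymous_group(("v",), tuple(f"x{i}" for i in range(X.shape[1])))
    ctrls = list(controllers) if controllers is not None else list(group.controllers)
    diag: dict = {"n_points": int(v.size)}

    stds = X.std(axis=0, ddof=0)
    keep = stds > 0
    if not np.all(keep):
        diag["dropped_controllers"] = [c for c, k in zip(ctrls, keep) if not k]
    if not np.any(keep):
        diag["degenerate"] = "all controllers constant"
        params = {"b": float(np.mean(v)), "a": np.zeros(0), "controllers": []}
        return KineticsConstraint(group, "HP", params, diag)
    Xk = X[:, keep]
    kept = [c for c, k in zip(ctrls, keep) if k]
    # center the design so the minimum-norm solution shrinks slopes, not the intercept
    xbar = Xk.mean(axis=0)
    vbar = float(np.mean(v))
    coef, _, rank, _ = np.linalg.lstsq(Xk - xbar, v - vbar, rcond=None)
    b = vbar - float(np.dot(coef, xbar))
    if rank < Xk.shape[1]:
        diag["rank_deficient"] = f"design rank {rank} < {Xk.shape[1]}; minimum-norm solution"
    pred = Xk @ coef + b
    diag["rss"] = float(np.sum((v - pred) ** 2))
    diag["x_range"] = {c: (float(col.min()), float(col.max())) for c, col in zip(kept, Xk.T)}
    params = {"b": b, "a": np.asarray(coef, dtype=float), "controllers": kept}
    return KineticsConstraint(group, "HP", params, diag)


def _anonymous_group(fluxes: tuple[str, ...], mets: tuple[str, ...]) -> InteractionGroup:
    return InteractionGroup(1, fluxes, mets, tuple("mass_action" for _ in mets))


# ---- dataset-level fitting ---------------------------------------------------

def fit_constraints(network: MetabolicNetwork, dataset, approach: str,
                    lag: int = 0) -> list[KineticsConstraint]:
    """Fit one constraint per interaction group from a TimecourseDataset.

    `lag` pairs v(t_{k+lag}) with x(t_k); default 0 pairs same-index samples.
    The dataset must carry flux values (measured or DFE-inferred).
    """
    if approach not in APPROACHES:
        raise ValueError(f"unknown approach {approach!r}")
    if dataset.fluxes is None:
        raise ValueError("dataset carries no flux values; run DFE first")
    if lag < 0:
        raise ValueError("lag must be >= 0")
    groups = derive_interaction_groups(network, GROUPING_MODE[approach])
    constraints = []
    for group in groups:
        v = sum(dataset.fluxes[rxn].to_numpy() for rxn in group.target_fluxes)
        X = dataset.concentrations[list(group.controllers)].to_numpy()
        if lag:
            v = v[lag:]
            X = X[:-lag]
        if approach == "LR":
            constraints.append(fit_lr(v, X[:, 0], group))
        elif approach == "NLR":
            constraints.append(fit_nlr(v, X[:, 0], group))
        elif approach == "DR":
            constraints.append(fit_dr(v, X, group))
        else:
            constraints.append(fit_hp(v, X, group))
    return constraints


def scale_constraints(constraints: list[KineticsConstraint], targets,
                      factor: float, known_reactions=None) -> list[KineticsConstraint]:
    """Emulate up/down-regulation of `targets` by multiplying every
    right-hand-side parameter of constraints on those fluxes by `factor`.

    The input list is not mutated.  Unknown reaction ids raise.
    """
    if factor <= 0:
        raise ValueError("perturbation factor must be positive")
    targets = set(targets)
    known = set(known_reactions) if known_reactions is not None else {
        r for c in constraints for r in c.group.target_fluxes
    }
    unknown = sorted(targets - known)
    if unknown:
        raise ValueError(f"unknown reaction id(s) in perturbation targets: {unknown}")
    return [
        c.scaled(factor) if targets & set(c.group.target_fluxes) else c.scaled(1.0)
        for c in constraints
    ]


# ---- serialization -----------------------------------------------------------

def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def save_constraints(constraints: list[KineticsConstraint], path) -> None:
    payload = []
    for c in constraints:
        payload.append({
            "approach": c.approach,
            "group": {
                "index": c.group.index,
                "target_fluxes": list(c.group.target_fluxes),
                "controllers": list(c.group.controllers),
                "origins": list(c.group.origins),
            },
            "params": _jsonify(c.params),
            "diagnostics": _jsonify(c.diagnostics),
        })
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_constraints(path) -> list[KineticsConstraint]:
    with open(path) as fh:
        payload = json.load(fh)
    out = []
    for entry in payload:
        g = entry["group"]
        group = InteractionGroup(g["index"], tuple(g["target_fluxes"]),
                                 tuple(g["controllers"]), tuple(g["origins"]))
        params = dict(entry["params"])
        for key in ("loading", "center", "scale"):
            if key in params:
                params[key] = np.asarray(params[key], dtype=float)
        if entry["approach"] == "HP" and isinstance(params.get("a"), list):
            params["a"] = np.asarray(params["a"], dtype=float)
        out.append(KineticsConstraint(group, entry["approach"], params, entry.get("diagnostics", {})))
    return out
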