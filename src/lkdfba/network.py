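"""Metabolic network representation and controller/flux interaction groups.

A :class:`MetabolicNetwork` couples a stoichiometric matrix ``S`` (metabolites
x reactions) with a list of signed regulatory edges (controller metabolite ->
target reaction).  From these two layers the *interaction groups* are derived:
the sets of controller metabolites whose concentrations bound each reaction
flux through fitted kinetics constraints.  A controller is either a substrate
of the flux (mass action: ``S[j, i] < 0``) or a declared allosteric regulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RegulatoryEdge",
    "MetabolicNetwork",
    "InteractionGroup",
    "TimeGrid",
    "derive_interaction_groups",
    "validate_network",
    "load_network",
    "save_network",
    "read_sbml",
]

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class RegulatoryEdge:
    """A signed allosteric interaction: `controller` metabolite acts on `target` reaction."""

    controller: str
    target: str
    sign: str = POSITIVE

    def __post_init__(self):
        if self.sign not in (POSITIVE, NEGATIVE):
            raise ValueError(f"regulatory edge sign must be positive/negative, got {self.sign!r}")


@dataclass
class MetabolicNetwork:
    """Stoichiometry plus regulatory topology.

    Parameters
    ----------
    metabolite_ids, reaction_ids
        Ordered unique identifiers.
    S
        Stoichiometric coefficient matrix, shape (n_metabolites, n_reactions).
        Negative entries are substrates, positive entries products.
    regulatory_edges
        Signed (controller metabolite, target reaction) pairs.
    reversible
        Per-reaction reversibility flags; irreversible reactions carry a
        non-negativity bound on their flux.
    exchange_flags
        Marks system-boundary reactions.  Defaults to reactions lacking either
        substrates or products inside the system.
    flux_bounds
        Optional per-reaction (lb, ub) overriding solver defaults.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    regulatory_edges: list[RegulatoryEdge] = field(default_factory=list)
    reversible: np.ndarray | None = None
    exchange_flags: np.ndarray | None = None
    flux_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        if self.S.shape != (len(self.metabolite_ids), len(self.reaction_ids)):
            raise ValueError(
                f"S shape {self.S.shape} inconsistent with "
                f"{len(self.metabolite_ids)} metabolites x {len(self.reaction_ids)} reactions"
            )
        if self.reversible is None:
            self.reversible = np.zeros(len(self.reaction_ids), dtype=bool)
        else:
            self.reversible = np.asarray(self.reversible, dtype=bool)
        if self.exchange_flags is None:
            has_substrate = (self.S < 0).any(axis=0)
            has_product = (self.S > 0).any(axis=0)
            self.exchange_flags = ~(has_substrate & has_product)
        else:
            self.exchange_flags = np.asarray(self.exchange_flags, dtype=bool)
        self.regulatory_edges = [
            e if isinstance(e, RegulatoryEdge) else RegulatoryEdge(*e)
            for e in self.regulatory_edges
        ]

    # ---- convenience accessors -------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def metabolite_index(self, met: str) -> int:
        return self.metabolite_ids.index(met)

    def reaction_index(self, rxn: str) -> int:
        return self.reaction_ids.index(rxn)

    def stoichiometry(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.metabolite_ids, columns=self.reaction_ids)

    def substrates(self, rxn: str) -> list[str]:
        j = self.reaction_index(rxn)
        return [m for i, m in enumerate(self.metabolite_ids) if self.S[i, j] < 0]

    def products(self, rxn: str) -> list[str]:
        j = self.reaction_index(rxn)
        return [m for i, m in enumerate(self.metabolite_ids) if self.S[i, j] > 0]

    def regulators(self, rxn: str) -> list[RegulatoryEdge]:
        return [e for e in self.regulatory_edges if e.target == rxn]

    def copy(self) -> "MetabolicNetwork":
        return replace(
            self,
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            regulatory_edges=list(self.regulatory_edges),
            reversible=self.reversible.copy(),
            exchange_flags=self.exchange_flags.copy(),
            flux_bounds=dict(self.flux_bounds),
        )


@dataclass(frozen=True)
class InteractionGroup:
    """One kinetics-constraint group: controllers bounding a set of target fluxes.

    ``origin`` records, per controller, whether the interaction stems from mass
    action (substrate) or declared regulation.
    """

    index: int
    target_fluxes: tuple[str, ...]
    controllers: tuple[str, ...]
    origins: tuple[str, ...]

    def __post_init__(self):
        if not self.controllers:
            raise ValueError("interaction group requires at least one controller")
        if not self.target_fluxes:
            raise ValueError("interaction group requires at least one target flux")
        if len(self.origins) != len(self.controllers):
            raise ValueError("origins must align with controllers")


@dataclass(frozen=True)
class TimeGrid:
    """Uniform sampling grid with `n_points` samples on [t0, tf]."""

    t0: float
    tf: float
    n_points: int

    def __post_init__(self):
        if self.n_points < 2:
            raise ValueError("grid needs at least 2 points")
        if not self.tf > self.t0:
            raise ValueError("tf must exceed t0")

    @property
    def dt(self) -> float:
        return (self.tf - self.t0) / (self.n_points - 1)

    @property
    def times(self) -> np.ndarray:
        return np.linspace(self.t0, self.tf, self.n_points)

    @property
    def n_steps(self) -> int:
        """Number of discrete flux steps K = n_points - 1."""
        return self.n_points - 1


def _controllers_of(network: MetabolicNetwork, rxn: str) -> list[tuple[str, str]]:
    """(controller, origin) pairs for one reaction, substrates first, deduplicated."""
    pairs: list[tuple[str, str]] = []
    seen: set[str] = set()
    for met in network.substrates(rxn):
        pairs.append((met, "mass_action"))
        seen.add(met)
    for edge in network.regulators(rxn):
        if edge.controller not in seen:
            pairs.append((edge.controller, "regulation"))
            seen.add(edge.controller)
    return pairs


def derive_interaction_groups(network: MetabolicNetwork, mode: str = "paired") -> list[InteractionGroup]:
    """Derive controller->flux interaction groups.

    mode="paired"
        One group per (controller, flux) pair — each controller gets its own
        independent constraint on the flux (LR / NLR approaches).
    mode="grouped"
        One group per flux, containing all of its controllers at once
        (DR / HP approaches).  Fluxes with no controller get no group and are
        bounded only by box bounds.

    Ordering is deterministic: sorted by reaction id, then controller id;
    groups are indexed 1..n_r.
    """
    if mode not in ("paired", "grouped"):
        raise ValueError(f"mode must be 'paired' or 'grouped', got {mode!r}")
    diagnostics = validate_network(network)
    if diagnostics:
        raise ValueError("invalid network: " + "; ".join(diagnostics))

    groups: list[InteractionGroup] = []
    idx = 1
    for rxn in sorted(network.reaction_ids):
        pairs = _controllers_of(network, rxn)
        if not pairs:
            continue
        pairs = sorted(pairs, key=lambda p: p[0])
        if mode == "paired":
            for met, origin in pairs:
                groups.append(InteractionGroup(idx, (rxn,), (met,), (origin,)))
                idx += 1
        else:
            mets = tuple(p[0] for p in pairs)
            origins = tuple(p[1] for p in pairs)
            groups.append(InteractionGroup(idx, (rxn,), mets, origins))
            idx += 1
    return groups


def validate_network(network: MetabolicNetwork) -> list[str]:
    """Return human-readable diagnostics; empty list iff the network is valid."""
    out: list[str] = []
    mets, rxns = network.metabolite_ids, network.reaction_ids
    if len(set(mets)) != len(mets):
        dupes = sorted({m for m in mets if mets.count(m) > 1})
        out.append(f"duplicate metabolite ids: {dupes}")
    if len(set(rxns)) != len(rxns):
        dupes = sorted({r for r in rxns if rxns.count(r) > 1})
        out.append(f"duplicate reaction ids: {dupes}")
    for j, rxn in enumerate(rxns):
        if not np.any(network.S[:, j]):
            out.append(f"reaction {rxn!r} has an all-zero stoichiometry column")
    met_set, rxn_set = set(mets), set(rxns)
    for edge in network.regulatory_edges:
        if edge.controller not in met_set:
            out.append(f"regulatory edge {edge.controller}->{edge.target}: unknown metabolite {edge.controller!r}")
        if edge.target not in rxn_set:
            out.append(f"regulatory edge {edge.controller}->{edge.target}: unknown reaction {edge.target!r}")
    if not np.all(np.isfinite(network.S)):
        out.append("stoichiometric matrix contains non-finite entries")
    return out


# ---- model file I/O ----------------------------------------------------------

def network_to_dict(network: MetabolicNetwork) -> dict:
    reactions = {}
    for j, rxn in enumerate(network.reaction_ids):
        entry: dict = {
            "stoichiometry": {
                m: float(network.S[i, j])
                for i, m in enumerate(network.metabolite_ids)
                if network.S[i, j] != 0
            },
            "reversible": bool(network.reversible[j]),
        }
        if rxn in network.flux_bounds:
            entry["bounds"] = list(network.flux_bounds[rxn])
        reactions[rxn] = entry
    return {
        "metabolites": list(network.metabolite_ids),
        "reactions": reactions,
        "regulation": [
            {"controller": e.controller, "target": e.target, "sign": e.sign}
            for e in network.regulatory_edges
        ],
    }


def network_from_dict(spec: dict) -> MetabolicNetwork:
    try:
        mets = list(spec["metabolites"])
        reactions = spec["reactions"]
    except KeyError as exc:
        raise ValueError(f"model file missing required block: {exc}") from exc
    rxn_ids = list(reactions)
    S = np.zeros((len(mets), len(rxn_ids)))
    reversible = np.zeros(len(rxn_ids), dtype=bool)
    flux_bounds = {}
    for j, rxn in enumerate(rxn_ids):
        entry = reactions[rxn]
        for met, coef in entry.get("stoichiometry", {}).items():
            if met not in mets:
                raise ValueError(f"reaction {rxn!r} references unknown metabolite {met!r}")
            S[mets.index(met), j] = float(coef)
        reversible[j] = bool(entry.get("reversible", False))
        if "bounds" in entry:
            lb, ub = entry["bounds"]
            flux_bounds[rxn] = (float(lb), float(ub))
    edges = [
        RegulatoryEdge(e["controller"], e["target"], e.get("sign", POSITIVE))
        for e in spec.get("regulation", [])
    ]
    return MetabolicNetwork(mets, rxn_ids, S, edges, reversible=reversible, flux_bounds=flux_bounds)


def save_network(network: MetabolicNetwork, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(network_to_dict(network), fh, sort_keys=False)


def load_network(path) -> MetabolicNetwork:
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    if not isinstance(spec, dict):
        raise ValueError(f"model file {path} does not contain a mapping")
    return network_from_dict(spec)


def read_sbml(path) -> MetabolicNetwork:
    """Read an SBML Level 3 file; reaction modifiers become positive regulatory edges."""
    import libsbml  # optional dependency, imported lazily

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise ValueError("SBML parse errors: " + "; ".join(msgs))
    model = doc.getModel()
    if model is None:
        raise ValueError(f"no model found in SBML file {path}")
    mets = [model.getSpecies(i).getId() for i in range(model.getNumSpecies())]
    rxn_ids = [model.getReaction(i).getId() for i in range(model.getNumReactions())]
    S = np.zeros((len(mets), len(rxn_ids)))
    reversible = np.zeros(len(rxn_ids), dtype=bool)
    edges: list[RegulatoryEdge] = []
    for j in range(model.getNumReactions()):
        rxn = model.getReaction(j)
        reversible[j] = rxn.getReversible()
        for k in range(rxn.getNumReactants()):
            ref = rxn.getReactant(k)
            S[mets.index(ref.getSpecies()), j] -= ref.getStoichiometry() or 1.0
        for k in range(rxn.getNumProducts()):
            ref = rxn.getProduct(k)
            S[mets.index(ref.getSpecies()), j] += ref.getStoichiometry() or 1.0
        for k in range(rxn.getNumModifiers()):
            edges.append(RegulatoryEdge(rxn.getModifier(k).getSpecies(), rxn.getId(), POSITIVE))
    return MetabolicNetwork(mets, rxn_ids, S, edges, reversible=reversible)
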