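"""Mass-action reaction networks and their polynomial vector fields.

A :class:`ReactionNetwork` holds species, named rate constants with strictly
positive nominal values, and mass-action reactions.  From it we derive the
rate equations ``dx/dt = f(x, p)`` (a polynomial vector field) and the exact
symbolic Jacobian ``J = df/dx``, which downstream modules use for stability
classification, sensitivity analysis and continuation.

Species listed in ``fixed`` (e.g. an external source held at constant
concentration) contribute to reaction rates but carry no differential
equation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import sympy as sp

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "ModelParseError",
    "ModelValidationError",
    "parse_model",
    "build_rates",
    "symbolic_jacobian",
    "bezout_number",
    "wilhelm_fixture",
    "wilhelm_document",
]


class ModelParseError(ValueError):
    """Raised when a model document is structurally malformed."""


class ModelValidationError(ValueError):
    """Raised when a model document violates a network invariant."""


@dataclass(frozen=True)
class Reaction:
    """A single mass-action reaction.

    ``reactants`` and ``products`` map species names to non-negative integer
    stoichiometries.  The rate is ``k * prod(conc[s] ** reactants[s])``; an
    empty reactant map gives a zeroth-order (constant-rate) reaction.
    """

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_constant: str

    @staticmethod
    def make(reactants: dict[str, int], products: dict[str, int],
             rate_constant: str) -> "Reaction":
        return Reaction(
            tuple(sorted(reactants.items())),
            tuple(sorted(products.items())),
            rate_constant,
        )

    def net_change(self, species: str) -> int:
        return (dict(self.products).get(species, 0)
                - dict(self.reactants).get(species, 0))


@dataclass
class ReactionNetwork:
    """Species, parameters and mass-action reactions of a chemical network.

    ``species`` are the dynamic state variables, in a fixed order that also
    fixes the ordering of state vectors everywhere downstream.  ``parameters``
    is an ordered name -> nominal-value map; all nominals must be strictly
    positive.  ``fixed`` species have constant concentration.
    """

    species: list[str]
    parameters: dict[str, float]
    reactions: list[Reaction]
    fixed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.species) + list(self.fixed)
        if len(set(names)) != len(names):
            raise ModelValidationError("species names must be unique "
                                       f"(got {names})")
        if len(set(self.parameters)) != len(self.parameters):
            raise ModelValidationError("parameter names must be unique")
        for name, value in self.parameters.items():
            if not (float(value) > 0):
                raise ModelValidationError(
                    f"parameter {name!r} must be strictly positive, "
                    f"got {value}")
        known = set(names)
        for rxn in self.reactions:
            if rxn.rate_constant not in self.parameters:
                raise ModelValidationError(
                    f"reaction references undeclared rate constant "
                    f"{rxn.rate_constant!r}")
            if not rxn.reactants and not rxn.products:
                raise ModelValidationError("reaction with empty reactants "
                                           "and products")
            for side in (rxn.reactants, rxn.products):
                for sname, stoich in side:
                    if sname not in known:
                        raise ModelValidationError(
                            f"reaction references unknown species {sname!r}")
                    if not (isinstance(stoich, int) and stoich >= 0):
                        raise ModelValidationError(
                            f"stoichiometry of {sname!r} must be a "
                            f"non-negative integer, got {stoich}")
        self._sym_cache: dict = {}

    # -- symbolic machinery -------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def parameter_names(self) -> list[str]:
        return list(self.parameters)

    def nominal(self) -> np.ndarray:
        """Nominal parameter vector, in declaration order."""
        return np.array([float(v) for v in self.parameters.values()])

    def state_symbols(self) -> list[sp.Symbol]:
        return [sp.Symbol(s, positive=True) for s in self.species]

    def parameter_symbols(self) -> list[sp.Symbol]:
        return [sp.Symbol(p, positive=True) for p in self.parameters]

    def rate_exprs(self) -> list[sp.Expr]:
        """Symbolic derivative of each dynamic species (mass action)."""
        if "rates" in self._sym_cache:
            return self._sym_cache["rates"]
        xsym = {s: sym for s, sym in zip(self.species, self.state_symbols())}
        psym = {p: sym for p, sym in
                zip(self.parameters, self.parameter_symbols())}
        exprs = [sp.Integer(0) for _ in self.species]
        for rxn in self.reactions:
            rate = psym[rxn.rate_constant]
            for sname, stoich in rxn.reactants:
                conc = xsym.get(sname, sp.Float(self.fixed.get(sname, 0.0)))
                rate = rate * conc ** stoich
            for i, sname in enumerate(self.species):
                change = rxn.net_change(sname)
                if change:
                    exprs[i] = exprs[i] + change * rate
        exprs = [sp.expand(e) for e in exprs]
        self._sym_cache["rates"] = exprs
        return exprs

    def jacobian_exprs(self) -> sp.Matrix:
        if "jac" not in self._sym_cache:
            f = sp.Matrix(self.rate_exprs())
            self._sym_cache["jac"] = f.jacobian(self.state_symbols())
        return self._sym_cache["jac"]

    def with_parameters(self, params) -> "ReactionNetwork":
        """Copy of the network with a new nominal parameter vector."""
        new = dict(zip(self.parameters, np.asarray(params, dtype=float)))
        return ReactionNetwork(list(self.species), new,
                               list(self.reactions), dict(self.fixed))


def build_rates(net: ReactionNetwork):
    """Return ``f(x, p) -> dx/dt`` for the network's rate equations.

    The returned callable accepts a state vector (length ``n_species``) and a
    parameter vector (in declaration order) and returns the derivative vector.
    """
    key = "rates_fn"
    if key not in net._sym_cache:
        fn = sp.lambdify(
            (net.state_symbols(), net.parameter_symbols()),
            net.rate_exprs(), modules="numpy")
        net._sym_cache[key] = fn
    fn = net._sym_cache[key]

    def rates(x, p):
        return np.asarray(fn(np.asarray(x, dtype=float),
                             np.asarray(p, dtype=float)), dtype=float)

    return rates


def symbolic_jacobian(net: ReactionNetwork):
    """Return ``J(x, p)`` evaluating the exact (symbolically derived) Jacobian.

    Entry ``(r, c)`` is the partial derivative of species ``r``'s rate with
    respect to species ``c``.  Differentiation is symbolic; no finite
    differences are involved.
    """
    key = "jac_fn"
    if key not in net._sym_cache:
        fn = sp.lambdify(
            (net.state_symbols(), net.parameter_symbols()),
            net.jacobian_exprs(), modules="numpy")
        net._sym_cache[key] = fn
    fn = net._sym_cache[key]

    def jac(x, p):
        return np.asarray(fn(np.asarray(x, dtype=float),
                             np.asarray(p, dtype=float)), dtype=float)

    return jac


def bezout_number(net: ReactionNetwork) -> int:
    """Product of the total degrees of the steady-state polynomials.

    This is the classical upper bound on the number of isolated complex
    solutions of the polynomial system ``f(x) = 0`` and a cost proxy for
    all-roots solvers.
    """
    xsyms = net.state_symbols()
    total = 1
    for expr in net.rate_exprs():
        if expr == 0:
            continue
        poly = sp.Poly(expr, *xsyms)
        total *= max(poly.total_degree(), 1)
    return total


# -- model document I/O -----------------------------------------------------

def parse_model(document: str | dict) -> ReactionNetwork:
    """Parse a JSON model document into a validated :class:`ReactionNetwork`.

    Schema: ``species`` (list of names), optional ``fixed`` (name -> constant
    concentration), ``parameters`` (name -> nominal value), ``reactions``
    (list of ``{"reactants": {...}, "products": {...}, "k": name}``).
    """
    if isinstance(document, str):
        try:
            doc = json.loads(document)
        except json.JSONDecodeError as exc:
            raise ModelParseError(f"invalid JSON: {exc}") from exc
    else:
        doc = document
    if not isinstance(doc, dict):
        raise ModelParseError("model document must be a JSON object")
    for req in ("species", "parameters", "reactions"):
        if req not in doc:
            raise ModelParseError(f"missing required key {req!r}")
    species = doc["species"]
    if (not isinstance(species, list)
            or not all(isinstance(s, str) for s in species)):
        raise ModelParseError("key 'species' must be a list of names")
    params = doc["parameters"]
    if not isinstance(params, dict):
        raise ModelParseError("key 'parameters' must be a name->value map")
    fixed = doc.get("fixed", {})
    if not isinstance(fixed, dict):
        raise ModelParseError("key 'fixed' must be a name->value map")
    reactions = []
    for i, entry in enumerate(doc["reactions"]):
        if not isinstance(entry, dict) or "k" not in entry:
            raise ModelParseError(
                f"reaction {i}: must be an object with key 'k'")
        try:
            reactants = {s: int(v)
                         for s, v in entry.get("reactants", {}).items()}
            products = {s: int(v)
                        for s, v in entry.get("products", {}).items()}
        except (TypeError, ValueError) as exc:
            raise ModelParseError(
                f"reaction {i}: stoichiometries must be integers") from exc
        reactions.append(Reaction.make(reactants, products, entry["k"]))
    return ReactionNetwork(
        species=list(species),
        parameters={str(k): float(v) for k, v in params.items()},
        reactions=reactions,
        fixed={str(k): float(v) for k, v in fixed.items()},
    )


# -- bundled fixture ---------------------------------------------------------

def wilhelm_document() -> dict:
    """JSON-ready document for the minimal two-species bistable network."""
    # Reactions: S+Y -> 2X (k1), 2X -> X+Y (k2), X+Y -> Y+P (k3), X -> P (k4)
    # with the source S held at concentration 1 and P inert (not modelled).
    # Nominal rate constants are pinned uniquely by the Jacobians of the
    # published worked example:
    #   J(0,0)      = [[-k4, 2*k1*S], [0, -k1*S]]   = [[-1.5, 16], [0, -8]]
    #     => k4 = 1.5, k1*S = 8
    #   J(2, 0.5)   off-diagonals 2*k1*S - 2*k3 = 14 and 4*k2 = 4
    #     => k3 = 1,  k2 = 1
    return {
        "species": ["X", "Y"],
        "fixed": {"S": 1.0},
        "parameters": {"k1": 8.0, "k2": 1.0, "k3": 1.0, "k4": 1.5},
        "reactions": [
            {"reactants": {"S": 1, "Y": 1}, "products": {"X": 2}, "k": "k1"},
            {"reactants": {"X": 2}, "products": {"X": 1, "Y": 1}, "k": "k2"},
            {"reactants": {"X": 1, "Y": 1}, "products": {"Y": 1}, "k": "k3"},
            {"reactants": {"X": 1}, "products": {}, "k": "k4"},
        ],
    }


def wilhelm_fixture() -> ReactionNetwork:
    """The smallest known bistable mass-action network (two species).

    Rate equations (with S fixed at 1, so k1 stands for k1*S):

        dx/dt = 2*k1*y - k2*x**2 - k3*x*y - k4*x
        dy/dt = k2*x**2 - k1*y

    At the nominal constants (8, 1, 1, 1.5) the system has stable states at
    (0, 0) and (6, 4.5) and a saddle at (2, 0.5).
    """
    return parse_model(wilhelm_document())
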