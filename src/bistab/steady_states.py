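"""Steady states of mass-action networks: all roots, stability, matching.

For two-species systems the polynomial steady-state system is solved exactly
in structure: the second species is eliminated by a symbolic resultant, the
resulting univariate polynomial is solved through its companion matrix
(``numpy.roots``), candidate pairs are back-substituted and Newton-polished
against the full system.  This reproduces the all-roots guarantee of
homotopy-continuation solvers for the network sizes this package targets.
Larger systems fall back to Groebner-basis solving in sympy.

Stability is classified from the eigenvalues of the exact symbolic Jacobian
evaluated at the polished root: all real parts negative is stable, mixed
signs a saddle, all non-negative (one positive) unstable.  An eigenvalue
with |Re| below ``MARGINAL_TOL`` makes the state "marginal" — a fold is near
and a stable/saddle label would be numerically meaningless.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import sympy as sp

from .reaction_model import ReactionNetwork, build_rates, symbolic_jacobian

__all__ = [
    "SteadyState",
    "BistableSolution",
    "SolverError",
    "NotASteadyStateError",
    "MonostableError",
    "MultistableError",
    "BistabilityChangeError",
    "solve_steady_states",
    "classify",
    "assert_bistable",
    "match_states",
]

RESIDUAL_TOL = 1e-9      # accepted max-norm residual of a polished root
POLISH_TOL = 1e-12       # Newton polish target
DEDUP_TOL = 1e-6         # relative dedup radius
CLIP_TOL = 1e-9          # negative coordinates above -CLIP_TOL clip to 0
MARGINAL_TOL = 1e-8      # |Re(lambda)| below this refuses a stability label

STABLE = "stable"
SADDLE = "saddle"
UNSTABLE = "unstable"
MARGINAL = "marginal"


class SolverError(RuntimeError):
    """A root candidate failed to converge under Newton polishing."""


class NotASteadyStateError(ValueError):
    """Coordinates passed to :func:`classify` are not a steady state."""


class MonostableError(ValueError):
    """Fewer than two stable states: the system is not bistable."""

    def __init__(self, msg, states=None):
        super().__init__(msg)
        self.states = states or []


class MultistableError(ValueError):
    """More than two stable states: beyond the bistable setting."""


class BistabilityChangeError(ValueError):
    """A perturbation changed the number of stable states."""


@dataclass
class SteadyState:
    """A steady state with its local linearization and stability class."""

    coordinates: np.ndarray
    jacobian: np.ndarray
    eigenvalues: np.ndarray
    stability: str
    spectral_abscissa: float

    def __repr__(self) -> str:  # keeps reports readable
        coords = ", ".join(f"{c:.6g}" for c in self.coordinates)
        return f"SteadyState(({coords}), {self.stability}, " \
               f"alpha={self.spectral_abscissa:.6g})"


@dataclass
class BistableSolution:
    """The two stable states (ascending first coordinate) and the saddle."""

    stable_states: list[SteadyState]
    saddle: SteadyState
    separation: float


# -- polynomial system construction -----------------------------------------

def _poly_system(net: ReactionNetwork):
    """(state symbols, parameter symbols, rate expressions)."""
    return net.state_symbols(), net.parameter_symbols(), net.rate_exprs()


def _eliminator(net: ReactionNetwork):
    """Cached symbolic elimination data for a two-species network.

    Returns ``(res_coeff_fn, y_polys)`` where ``res_coeff_fn(p)`` evaluates
    the coefficients (descending) of the resultant of the two rate
    polynomials with respect to the second species, and ``y_polys`` is a list
    of per-equation coefficient functions ``(x, p) -> descending y-coeffs``
    used for back-substitution.
    """
    key = "eliminator"
    if key in net._sym_cache:
        return net._sym_cache[key]
    xsyms, psyms, exprs = _poly_system(net)
    x, y = xsyms
    f1 = sp.Poly(exprs[0], y)
    f2 = sp.Poly(exprs[1], y)
    res = sp.resultant(exprs[0], exprs[1], y)
    res_poly = sp.Poly(sp.expand(res), x)
    res_fn = sp.lambdify((psyms,), res_poly.all_coeffs(), modules="numpy")
    y_polys = []
    for f in (f1, f2):
        coeffs = f.all_coeffs()
        y_polys.append((len(coeffs) - 1,
                        sp.lambdify((x, psyms), coeffs, modules="numpy")))
    net._sym_cache[key] = (res_fn, y_polys)
    return net._sym_cache[key]


def _real_roots(coeffs: np.ndarray, imag_tol: float = 1e-7) -> np.ndarray:
    coeffs = np.asarray(coeffs, dtype=float)
    scale = np.max(np.abs(coeffs)) if coeffs.size else 0.0
    if scale == 0.0:
        return np.array([])
    coeffs = np.trim_zeros(np.where(np.abs(coeffs) / scale < 1e-14, 0.0,
                                    coeffs), trim="f")
    if coeffs.size <= 1:
        return np.array([])
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < imag_tol * (1 + np.abs(roots))].real
    return real


def _newton_polish(rates, jac, x0, p, tol=POLISH_TOL, max_iter=60):
    x = np.array(x0, dtype=float)
    for _ in range(max_iter):
        f = rates(x, p)
        if np.max(np.abs(f)) < tol:
            return x, True
        J = jac(x, p)
        try:
            step = np.linalg.solve(J, f)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, f, rcond=None)[0]
        x = x - step
        if not np.all(np.isfinite(x)):
            return np.array(x0, dtype=float), False
    f = rates(x, p)
    return x, bool(np.max(np.abs(f)) < RESIDUAL_TOL)


def _candidates_2species(net, p):
    res_fn, y_polys = _eliminator(net)
    xs = _real_roots(np.atleast_1d(res_fn(p)))
    cands = []
    for xv in xs:
        ys = []
        for deg, coeff_fn in y_polys:
            if deg >= 1:
                ys.extend(_real_roots(np.atleast_1d(coeff_fn(xv, p))))
        if not ys:
            ys = [0.0]
        for yv in ys:
            cands.append(np.array([xv, yv]))
    return cands


def _candidates_general(net, p):
    xsyms, psyms, exprs = _poly_system(net)
    subs = dict(zip(psyms, [sp.Rational(format(v, ".17g")) for v in p]))
    polys = [sp.Poly(e.subs(subs), *xsyms) for e in exprs if e != 0]
    if not polys:
        return [np.zeros(len(xsyms))]
    sols = sp.solve_poly_system(polys, *xsyms)
    cands = []
    for sol in sols:
        vals = [complex(sp.N(v)) for v in sol]
        if all(abs(v.imag) < 1e-7 * (1 + abs(v)) for v in vals):
            cands.append(np.array([v.real for v in vals]))
    return cands


def solve_steady_states(net: ReactionNetwork, params=None) -> list[SteadyState]:
    """All non-negative real steady states of the network, classified.

    Roots are found by resultant elimination (two species) or Groebner-basis
    solving, Newton-polished to a residual below ``POLISH_TOL`` where the
    Jacobian permits, deduplicated, and classified from the exact Jacobian.
    Coordinates in ``(-CLIP_TOL, 0)`` are clipped to zero; more negative or
    complex roots are discarded.
    """
    p = net.nominal() if params is None else np.asarray(params, dtype=float)
    if not np.all(p > 0):
        raise ValueError("parameters must be strictly positive")
    rates = build_rates(net)
    jac = symbolic_jacobian(net)
    n = net.n_species
    if n == 2:
        cands = _candidates_2species(net, p)
    elif n == 1:
        xsyms, psyms, exprs = _poly_system(net)
        coeff_fn_key = "uni_fn"
        if coeff_fn_key not in net._sym_cache:
            poly = sp.Poly(exprs[0], xsyms[0])
            net._sym_cache[coeff_fn_key] = sp.lambdify(
                (psyms,), poly.all_coeffs(), modules="numpy")
        cands = [np.array([v]) for v in
                 _real_roots(np.atleast_1d(net._sym_cache[coeff_fn_key](p)))]
    else:
        cands = _candidates_general(net, p)

    states: list[np.ndarray] = []
    for x0 in cands:
        raw_res = np.max(np.abs(rates(x0, p))) if len(x0) else 0.0
        x, ok = _newton_polish(rates, jac, x0, p)
        if not ok:
            if raw_res < 1e-6:
                raise SolverError(
                    f"Newton polish failed from start point {x0.tolist()} "
                    f"at parameters {p.tolist()}")
            continue
        if np.any(x < -CLIP_TOL):
            continue
        x = np.where(np.abs(x) < CLIP_TOL, 0.0, x)
        if any(np.linalg.norm(x - s) < DEDUP_TOL * (1 + np.linalg.norm(s))
               for s in states):
            continue
        states.append(x)

    states.sort(key=lambda s: tuple(s))
    out = [classify(x, net, p) for x in states]
    return out


def classify(coordinates, net: ReactionNetwork, params=None) -> SteadyState:
    """Fill in Jacobian, eigenvalues, stability and spectral abscissa.

    Raises :class:`NotASteadyStateError` if the residual of the rate
    equations at ``coordinates`` exceeds 1e-6.
    """
    p = net.nominal() if params is None else np.asarray(params, dtype=float)
    x = np.asarray(coordinates, dtype=float)
    residual = np.max(np.abs(build_rates(net)(x, p)))
    if residual > 1e-6:
        raise NotASteadyStateError(
            f"residual {residual:.3g} at {x.tolist()} exceeds tolerance")
    J = symbolic_jacobian(net)(x, p)
    eig = np.linalg.eigvals(J)
    re = eig.real
    alpha = float(np.max(re))
    if np.any(np.abs(re) < MARGINAL_TOL):
        stability = MARGINAL
    elif np.all(re < 0):
        stability = STABLE
    elif np.all(re > 0):
        stability = UNSTABLE
    else:
        stability = SADDLE
    order = np.argsort(-re)
    return SteadyState(coordinates=x, jacobian=J, eigenvalues=eig[order],
                       stability=stability, spectral_abscissa=alpha)


def assert_bistable(states: list[SteadyState]) -> BistableSolution:
    """Check the two-stable-states-plus-saddle structure of a bistable system.

    Stable states are ordered by ascending first coordinate (SS1, SS2) and
    their Euclidean separation is recorded.
    """
    stable = [s for s in states if s.stability == STABLE]
    saddles = [s for s in states if s.stability == SADDLE]
    if len(stable) < 2:
        raise MonostableError(
            f"system is not bistable: {len(stable)} stable state(s) found",
            states=stable)
    if len(stable) > 2:
        raise MultistableError(
            f"system has {len(stable)} stable states, beyond bistable")
    if len(saddles) != 1:
        raise MonostableError(
            f"expected exactly one saddle, found {len(saddles)}",
            states=stable)
    ss = sorted(stable, key=lambda s: s.coordinates[0])
    sep = float(np.linalg.norm(ss[0].coordinates - ss[1].coordinates))
    return BistableSolution(stable_states=ss, saddle=saddles[0],
                            separation=sep)


def match_states(reference: list[SteadyState],
                 perturbed: list[SteadyState]) -> list[tuple[int, int]]:
    """Pair stable states across two models by minimal total distance.

    Returns index pairs ``(i_ref, i_pert)`` into the *stable* states of each
    list.  Unequal stable-state counts raise
    :class:`BistabilityChangeError` — the perturbation crossed a bifurcation.
    """
    ref = [s for s in reference if s.stability == STABLE]
    per = [s for s in perturbed if s.stability == STABLE]
    if len(ref) != len(per):
        raise BistabilityChangeError(
            f"stable-state count changed: {len(ref)} -> {len(per)}")
    k = len(ref)
    if k == 0:
        return []
    if k <= 3:  # exhaustive assignment
        best, best_cost = None, np.inf
        for perm in itertools.permutations(range(k)):
            cost = sum(np.linalg.norm(ref[i].coordinates
                                      - per[perm[i]].coordinates)
                       for i in range(k))
            if cost < best_cost - 1e-15:
                best, best_cost = perm, cost
        return [(i, best[i]) for i in range(k)]
    # greedy nearest neighbour, index tie-break
    pairs, used = [], set()
    for i, s in enumerate(ref):
        dists = [(np.linalg.norm(s.coordinates - t.coordinates), j)
                 for j, t in enumerate(per) if j not in used]
        d, j = min(dists)
        used.add(j)
        pairs.append((i, j))
    return pairs
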