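"""Spectral-abscissa and stable-state-separation sensitivity analysis.

Both measures are dimensionless logarithmic derivatives estimated by a
centered difference over a one-at-a-time fractional parameter perturbation
``p* (1 +/- eps)``:

* eigenvalue sensitivity ``m_ij``: log-derivative of the spectral abscissa
  ``alpha_i`` (largest real part of the Jacobian eigenvalues) of stable
  state ``i`` with respect to parameter ``j``.  For a stable state
  (``alpha < 0``), ``m > 0`` means increasing the parameter *stabilizes*
  the state and decreasing it destabilizes; ``m < 0`` the reverse.  Its
  magnitude reads as the local polynomial exponent of ``alpha(p)``.
* separation sensitivity ``s_j``: log-derivative of the Euclidean distance
  between the two stable states — a proxy for the switch's noise immunity;
  it belongs to the switch as a whole, not to one state.

Stable states are matched across the nominal and perturbed models by
Euclidean distance so that each difference compares like with like.  If a
perturbation exits the bistable region the fractional step is halved (up to
six times) before reporting bifurcation proximity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reaction_model import ReactionNetwork
from .steady_states import (
    MARGINAL_TOL,
    BistabilityChangeError,
    MonostableError,
    MultistableError,
    assert_bistable,
    match_states,
    solve_steady_states,
)

__all__ = [
    "SensitivityRecord",
    "SensitivityTable",
    "ParameterClusters",
    "BifurcationProximityError",
    "MarginalStabilityError",
    "centered_log_sensitivity",
    "eigenvalue_sensitivity",
    "separation_sensitivity",
    "sensitivity_table",
    "cluster_parameters",
    "global_sweep",
]

DEFAULT_EPSILON = 0.01
MAX_EPSILON_HALVINGS = 6
NEUTRAL_TOL = 1e-6


class BifurcationProximityError(RuntimeError):
    """Perturbations exit the bistable region even at the smallest eps."""


class MarginalStabilityError(ValueError):
    """The nominal spectral abscissa is (numerically) zero."""


@dataclass
class SensitivityRecord:
    """One-at-a-time sensitivities of a single parameter."""

    parameter: str
    epsilon: float
    eigen_sensitivity: dict[int, float] = field(default_factory=dict)
    separation_sensitivity: float | None = None
    error: str | None = None


@dataclass
class SensitivityTable:
    records: list[SensitivityRecord]
    most_sensitive: str | None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "parameter": r.parameter,
                "epsilon": r.epsilon,
                "m_SS1": r.eigen_sensitivity.get(0, np.nan),
                "m_SS2": r.eigen_sensitivity.get(1, np.nan),
                "s_sep": (np.nan if r.separation_sensitivity is None
                          else r.separation_sensitivity),
                "error": r.error or "",
            })
        return pd.DataFrame(rows)


def centered_log_sensitivity(fun, p_star: float, epsilon: float) -> float:
    """Centered-difference estimate of ``d ln|f| / d ln p`` at ``p_star``.

    Computed as ``(f(p(1+eps)) - f(p(1-eps))) / (2 eps f(p))``; for
    ``f(p) = C p^m`` this returns ``m + O(eps^2)``.
    """
    f_star = fun(p_star)
    if abs(f_star) < 1e-300:
        raise ZeroDivisionError("nominal value is zero")
    return (fun(p_star * (1 + epsilon))
            - fun(p_star * (1 - epsilon))) / (2 * epsilon * f_star)


# -- internal helpers --------------------------------------------------------

def _param_index(net: ReactionNetwork, parameter: str) -> int:
    try:
        return net.parameter_names.index(parameter)
    except ValueError:
        raise KeyError(f"unknown parameter {parameter!r}") from None


def _solve_bistable(net, p):
    states = solve_steady_states(net, p)
    return states, assert_bistable(states)


def _perturbed_pair(net, p, j_idx, epsilon):
    """Solve at ``p_j (1 +/- eps)``, halving eps while bistability is lost."""
    eps = epsilon
    for _ in range(MAX_EPSILON_HALVINGS + 1):
        try:
            results = []
            for sign in (+1, -1):
                q = np.array(p, dtype=float)
                q[j_idx] *= (1 + sign * eps)
                results.append(_solve_bistable(net, q))
            return results[0], results[1], eps
        except (MonostableError, MultistableError, BistabilityChangeError):
            eps /= 2
    raise BifurcationProximityError(
        f"bistability lost at +/-{epsilon:.3g} perturbation of parameter "
        f"index {j_idx} even after {MAX_EPSILON_HALVINGS} halvings")


def _matched_abscissa(nominal_states, nominal_sol, perturbed_states, i):
    """Spectral abscissa of the perturbed stable state matched to SS_{i+1}."""
    pairs = match_states(nominal_states, perturbed_states)
    stable_nom = [s for s in nominal_states if s.stability == "stable"]
    stable_per = [s for s in perturbed_states if s.stability == "stable"]
    target = nominal_sol.stable_states[i]
    for ri, pi in pairs:
        if stable_nom[ri] is target:
            return stable_per[pi].spectral_abscissa
    raise RuntimeError("matched state not found")  # pragma: no cover


# -- public operations -------------------------------------------------------

def eigenvalue_sensitivity(net: ReactionNetwork, params=None, *,
                           stable_state_index: int, parameter: str,
                           epsilon: float = DEFAULT_EPSILON) -> float:
    """Log-sensitivity of the spectral abscissa of one stable state.

    ``stable_state_index`` is 0 for SS1 and 1 for SS2 (stable states ordered
    by ascending first coordinate).
    """
    p = net.nominal() if params is None else np.asarray(params, dtype=float)
    j = _param_index(net, parameter)
    states, sol = _solve_bistable(net, p)
    alpha_star = sol.stable_states[stable_state_index].spectral_abscissa
    if abs(alpha_star) < MARGINAL_TOL:
        raise MarginalStabilityError(
            f"nominal spectral abscissa {alpha_star:.3g} is numerically "
            "zero; sensitivity undefined")
    (sp_states, _), (sm_states, _), _eps = _perturbed_pair(net, p, j, epsilon)
    a_plus = _matched_abscissa(states, sol, sp_states, stable_state_index)
    a_minus = _matched_abscissa(states, sol, sm_states, stable_state_index)
    return (a_plus - a_minus) / (2 * _eps * alpha_star)


def separation_sensitivity(net: ReactionNetwork, params=None, *,
                           parameter: str,
                           epsilon: float = DEFAULT_EPSILON) -> float:
    """Log-sensitivity of the Euclidean separation between SS1 and SS2."""
    p = net.nominal() if params is None else np.asarray(params, dtype=float)
    j = _param_index(net, parameter)
    _states, sol = _solve_bistable(net, p)
    (_, sol_p), (_, sol_m), _eps = _perturbed_pair(net, p, j, epsilon)
    return (sol_p.separation - sol_m.separation) / (2 * _eps * sol.separation)


def sensitivity_table(net: ReactionNetwork, params=None,
                      epsilon: float = DEFAULT_EPSILON) -> SensitivityTable:
    """One-at-a-time sensitivity loop over every parameter.

    Each record carries the eigenvalue sensitivity of both stable states and
    the separation sensitivity at the shared perturbed solves.  Per-parameter
    failures become flagged rows rather than aborting the table.  The most
    sensitive parameter is the one with the largest |m| across both stable
    states (ties broken by parameter order).
    """
    p = net.nominal() if params is None else np.asarray(params, dtype=float)
    states, sol = _solve_bistable(net, p)
    records = []
    for name in net.parameter_names:
        j = _param_index(net, name)
        rec = SensitivityRecord(parameter=name, epsilon=epsilon)
        try:
            (sp_states, sol_p), (sm_states, sol_m), eps = _perturbed_pair(
                net, p, j, epsilon)
            rec.epsilon = eps
            for i in (0, 1):
                alpha_star = sol.stable_states[i].spectral_abscissa
                if abs(alpha_star) < MARGINAL_TOL:
                    raise MarginalStabilityError(
                        f"SS{i + 1} spectral abscissa is numerically zero")
                a_plus = _matched_abscissa(states, sol, sp_states, i)
                a_minus = _matched_abscissa(states, sol, sm_states, i)
                rec.eigen_sensitivity[i] = (
                    (a_plus - a_minus) / (2 * eps * alpha_star))
            rec.separation_sensitivity = (
                (sol_p.separation - sol_m.separation)
                / (2 * eps * sol.separation))
        except (BifurcationProximityError, MarginalStabilityError) as exc:
            rec.error = str(exc)
        records.append(rec)
    best, best_mag = None, -np.inf
    for rec in records:
        if rec.error:
            continue
        mag = max(abs(v) for v in rec.eigen_sensitivity.values())
        if mag > best_mag + 1e-15:
            best, best_mag = rec.parameter, mag
    return SensitivityTable(records=records, most_sensitive=best)


@dataclass
class ParameterClusters:
    """Sign-based parameter clusters and the derived design rules."""

    stable_state_index: int
    eigen_positive: list[str]
    eigen_negative: list[str]
    eigen_neutral: list[str]
    separation_positive: list[str]
    separation_negative: list[str]
    separation_neutral: list[str]
    rules: dict[str, dict[str, str]]


def _sign_bucket(value: float | None, tol: float) -> str:
    if value is None or not np.isfinite(value) or abs(value) < tol:
        return "neutral"
    return "positive" if value > 0 else "negative"


def cluster_parameters(records: list[SensitivityRecord],
                       stable_state_index: int = 1,
                       tol: float = NEUTRAL_TOL) -> ParameterClusters:
    """Partition parameters by sensitivity sign and emit design rules.

    For the chosen stable state: ``m > 0`` parameters stabilize it when
    increased (and destabilize when decreased); ``m < 0`` the reverse.
    Separation: ``s > 0`` parameters widen the switch when increased.
    Near-zero values (|value| < ``tol``) fall in a neutral cluster.
    """
    buckets = {"positive": [], "negative": [], "neutral": []}
    sep_buckets = {"positive": [], "negative": [], "neutral": []}
    rules: dict[str, dict[str, str]] = {}
    for rec in records:
        m = rec.eigen_sensitivity.get(stable_state_index)
        s = rec.separation_sensitivity
        mb = _sign_bucket(None if rec.error else m, tol)
        sb = _sign_bucket(None if rec.error else s, tol)
        buckets[mb].append(rec.parameter)
        sep_buckets[sb].append(rec.parameter)
        k = rec.parameter
        rule_m = {
            "positive": f"increase {k} to stabilize; decrease to destabilize",
            "negative": f"decrease {k} to stabilize; increase to destabilize",
            "neutral": f"{k} has no local influence on this state's "
                       "stability",
        }[mb]
        rule_s = {
            "positive": f"increase {k} to widen the separation",
            "negative": f"decrease {k} to widen the separation",
            "neutral": f"{k} has no local influence on the separation",
        }[sb]
        rules[k] = {"stabilize": rule_m, "separation": rule_s}
    return ParameterClusters(
        stable_state_index=stable_state_index,
        eigen_positive=buckets["positive"],
        eigen_negative=buckets["negative"],
        eigen_neutral=buckets["neutral"],
        separation_positive=sep_buckets["positive"],
        separation_negative=sep_buckets["negative"],
        separation_neutral=sep_buckets["neutral"],
        rules=rules,
    )


def global_sweep(net: ReactionNetwork, parameter: str, params=None, *,
                 value_range: tuple[float, float] | None = None,
                 n_points: int = 21,
                 epsilon: float = DEFAULT_EPSILON) -> pd.DataFrame:
    """Sweep one parameter across the bistable region.

    At each grid value the model is re-solved and the local eigenvalue
    sensitivity of both stable states is evaluated with the same
    centered-difference estimator used at the nominal point.  If
    ``value_range`` is omitted the bistable interval is auto-detected from
    the folds in both directions (interior margin 2%, bounded by
    ``nominal / 10`` on an open side).  Grid points where the model is not
    bistable are flagged (``ok = False``) and skipped, not fatal.
    """
    from .bifurcation import find_fold  # deferred: avoids a module cycle

    p = net.nominal() if params is None else np.asarray(params, dtype=float)
    j = _param_index(net, parameter)
    nominal = p[j]
    if value_range is None:
        lo = find_fold(net, p, parameter, "decrease")
        hi = find_fold(net, p, parameter, "increase")
        lo = nominal / 10 if lo is None else lo
        hi = nominal * 10 if hi is None else hi
        width = hi - lo
        value_range = (lo + 0.02 * width, hi - 0.02 * width)
    grid = np.linspace(value_range[0], value_range[1], n_points)
    rows = []
    for v in grid:
        q = np.array(p, dtype=float)
        q[j] = v
        row = {"p": v, "ok": True,
               "alpha_SS1": np.nan, "alpha_SS2": np.nan,
               "m_SS1": np.nan, "m_SS2": np.nan}
        try:
            _, sol = _solve_bistable(net, q)
            row["alpha_SS1"] = sol.stable_states[0].spectral_abscissa
            row["alpha_SS2"] = sol.stable_states[1].spectral_abscissa
            for i in (0, 1):
                row[f"m_SS{i + 1}"] = eigenvalue_sensitivity(
                    net, q, stable_state_index=i, parameter=parameter,
                    epsilon=epsilon)
        except (MonostableError, MultistableError, BifurcationProximityError,
                MarginalStabilityError):
            row["ok"] = False
        rows.append(row)
    return pd.DataFrame(rows)
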