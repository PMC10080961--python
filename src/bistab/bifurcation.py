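"""One-parameter continuation to the fold and arc-length distance to it.

A bistable switch sits on a branch of stable states that terminates, as one
parameter is pushed, at a saddle-node (fold) bifurcation — the "cliff" where
the tracked stable state and the saddle coalesce and the switch collapses to
a monostable system.  This module locates folds by bisection on bistability,
tabulates the branch of a chosen stable state in joint parameter-state
space ``(p, x_1..x_n)``, and measures progress toward the cliff by arc
length along that curve:

    s_r = s / s_max        (fractional arc length travelled)
    s_c = 1 - s_r          (normalized distance to the cliff)

so ``(s_r, s_c) = (0, 1)`` at the nominal model and ``(1, 0)`` at the fold.

Near the fold the branch behaves like ``x - x_fold ~ sqrt(p_fold - p)``, so
samples are placed uniformly in ``sqrt(|p_fold - p|)``, which makes the
polyline chords roughly equal and the trapezoidal arc length accurate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reaction_model import ReactionNetwork
from .steady_states import (
    MonostableError,
    MultistableError,
    assert_bistable,
    solve_steady_states,
)

__all__ = [
    "BifurcationBranch",
    "OpenBranchError",
    "find_fold",
    "continue_branch",
    "arc_length",
    "distance_to_cliff",
    "beyond_fold",
    "switching_perturbation",
    "fold_summary",
    "s_curve",
]

FOLD_REL_TOL = 1e-8      # fold bisection tolerance, relative to nominal
SPAN_FACTOR = 100.0      # search span: nominal/SPAN .. nominal*SPAN
MIN_BRANCH_SAMPLES = 200


class OpenBranchError(RuntimeError):
    """No fold found within the search span; arc-length measures undefined."""


@dataclass
class BifurcationBranch:
    """Ordered samples of one stable state from the nominal point to a fold."""

    parameter: str
    nominal_value: float
    direction: int                      # +1 (increase) or -1 (decrease)
    fold_value: float | None
    samples_p: np.ndarray               # ascending |p - nominal|
    samples_x: np.ndarray               # matching state vectors, rows
    cumulative_arclength: np.ndarray
    species: list[str]

    @property
    def is_open(self) -> bool:
        return self.fold_value is None

    @property
    def s_max(self) -> float:
        if self.is_open:
            raise OpenBranchError(
                f"no fold found for {self.parameter}; s_max undefined")
        return float(self.cumulative_arclength[-1])

    @property
    def percent_from_nominal(self) -> float:
        return abs(self.fold_value - self.nominal_value) \
            / self.nominal_value * 100.0


def _param_index(net: ReactionNetwork, parameter: str) -> int:
    try:
        return net.parameter_names.index(parameter)
    except ValueError:
        raise KeyError(f"unknown parameter {parameter!r}") from None


def _is_bistable(net, p, j, value) -> bool:
    q = np.array(p, dtype=float)
    q[j] = value
    try:
        assert_bistable(solve_steady_states(net, q))
        return True
    except (MonostableError, MultistableError):
        return False


def find_fold(net: ReactionNetwork, params, parameter: str,
              direction: str, span_factor: float = SPAN_FACTOR,
              rel_tol: float = FOLD_REL_TOL) -> float | None:
    """Parameter value where bistability is lost in the given direction.

    Brackets the loss of bistability by geometric stepping away from the
    nominal value, then bisects to ``rel_tol`` (relative to the nominal).
    Returns ``None`` when the system stays bistable across the whole span
    (an open branch).
    """
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    p = np.asarray(params, dtype=float)
    j = _param_index(net, parameter)
    nominal = p[j]
    if not _is_bistable(net, p, j, nominal):
        raise MonostableError("nominal model is not bistable")
    sign = 1.0 if direction == "increase" else -1.0
    # geometric bracketing
    delta = 0.01 * nominal
    lo, hi = nominal, None
    while True:
        v = nominal + sign * delta
        if v <= 0 or not (nominal / span_factor <= v
                          <= nominal * span_factor):
            # final probe at the span edge
            edge = (nominal * span_factor if sign > 0
                    else nominal / span_factor)
            if _is_bistable(net, p, j, edge):
                return None
            hi = edge
            break
        if _is_bistable(net, p, j, v):
            lo = v
            delta *= 1.6
        else:
            hi = v
            break
    # bisection on bistability between lo (bistable) and hi (not)
    tol = rel_tol * nominal
    while abs(hi - lo) > tol:
        mid = 0.5 * (lo + hi)
        if _is_bistable(net, p, j, mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _auto_direction(net, p, j, parameter) -> str:
    """Destabilizing direction: the side whose fold is nearer (in percent).

    Falls back on the only side that has a fold; raises if neither does.
    """
    nominal = p[j]
    candidates = {}
    for direction, sign in (("increase", 1), ("decrease", -1)):
        fold = find_fold(net, p, parameter, direction)
        if fold is not None:
            candidates[direction] = abs(fold - nominal) / nominal
    if not candidates:
        raise OpenBranchError(
            f"no fold in either direction for {parameter!r} within the "
            f"search span")
    return min(candidates, key=lambda d: (candidates[d], d))


def continue_branch(net: ReactionNetwork, params=None,
                    stable_state_index: int = 1, parameter: str = "",
                    direction: str = "auto",
                    n_samples: int = MIN_BRANCH_SAMPLES + 56
                    ) -> BifurcationBranch:
    """Trace one stable state from the nominal parameters to the fold.

    The branch is sampled at parameter values uniform in
    ``sqrt(|p_fold - p|)`` (dense near the fold), each sample re-solved and
    matched to the previous one by nearest Euclidean distance, and the
    cumulative arc length accumulated over the polyline in ``(p, x)`` space.
    With ``direction='auto'`` the destabilizing side — the nearer fold — is
    chosen.
    """
    p = (net.nominal() if params is None
         else np.asarray(params, dtype=float))
    j = _param_index(net, parameter)
    nominal = p[j]
    sol = assert_bistable(solve_steady_states(net, p))
    tracked = sol.stable_states[stable_state_index].coordinates

    if direction == "auto":
        direction = _auto_direction(net, p, j, parameter)
    sign = 1 if direction == "increase" else -1
    fold = find_fold(net, p, parameter, direction)
    if fold is None:
        samples_p = np.array([nominal])
        samples_x = tracked[None, :]
        return BifurcationBranch(
            parameter=parameter, nominal_value=nominal, direction=sign,
            fold_value=None, samples_p=samples_p, samples_x=samples_x,
            cumulative_arclength=np.array([0.0]), species=list(net.species))

    span = abs(fold - nominal)
    # uniform in u = sqrt(|fold - p|); stop a hair inside the fold
    u_max = np.sqrt(span)
    u_min = np.sqrt(max(span * 1e-9, 1e-14))
    u = np.linspace(u_max, u_min, max(n_samples, MIN_BRANCH_SAMPLES))
    ps = fold - sign * u ** 2
    ps[0] = nominal

    xs = []
    prev = tracked
    for v in ps:
        q = np.array(p, dtype=float)
        q[j] = v
        states = solve_steady_states(net, q)
        if not states:
            raise OpenBranchError(
                f"lost all steady states at {parameter}={v:.6g}")
        coords = min((s.coordinates for s in states),
                     key=lambda c: np.linalg.norm(c - prev))
        xs.append(coords)
        prev = coords
    samples_x = np.asarray(xs)
    pts = np.column_stack([ps, samples_x])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return BifurcationBranch(
        parameter=parameter, nominal_value=nominal, direction=sign,
        fold_value=float(fold), samples_p=ps, samples_x=samples_x,
        cumulative_arclength=cum, species=list(net.species))


def arc_length(branch: BifurcationBranch, p: float) -> float:
    """Arc length travelled from the nominal model to parameter value ``p``.

    Linear interpolation between branch samples; ``p`` must lie between the
    nominal value and the fold (inclusive, with a small tolerance).
    """
    if branch.is_open:
        raise OpenBranchError(
            f"branch for {branch.parameter} has no fold; arc length to the "
            "cliff is undefined")
    lo = min(branch.nominal_value, branch.fold_value)
    hi = max(branch.nominal_value, branch.fold_value)
    tol = 1e-9 * (1 + abs(branch.nominal_value))
    if not (lo - tol <= p <= hi + tol):
        raise ValueError(
            f"{branch.parameter}={p:.6g} outside branch span "
            f"[{lo:.6g}, {hi:.6g}]")
    dist = np.abs(branch.samples_p - branch.nominal_value)
    return float(np.interp(abs(p - branch.nominal_value), dist,
                           branch.cumulative_arclength))


def distance_to_cliff(branch: BifurcationBranch,
                      p: float) -> tuple[float, float]:
    """``(s_r, s_c)`` at parameter value ``p`` along the branch."""
    s = arc_length(branch, p)
    s_r = float(np.clip(s / branch.s_max, 0.0, 1.0))
    return s_r, 1.0 - s_r


def beyond_fold(branch: BifurcationBranch, p, tol: float = 1e-6):
    """Whether parameter value(s) ``p`` lie at or past the fold.

    ``tol`` is relative to the nominal parameter value, absorbing the fold
    localization tolerance.
    """
    if branch.is_open:
        raise OpenBranchError(f"branch for {branch.parameter} has no fold")
    margin = tol * abs(branch.nominal_value)
    p = np.asarray(p, dtype=float)
    if branch.direction > 0:
        return p >= branch.fold_value - margin
    return p <= branch.fold_value + margin


def switching_perturbation(net: ReactionNetwork, params=None,
                           parameter: str = "") -> float:
    """Smallest percent change of one parameter that destroys bistability.

    Both directions are searched; the nearer fold (in percent of the
    nominal value) is reported.
    """
    p = (net.nominal() if params is None
         else np.asarray(params, dtype=float))
    j = _param_index(net, parameter)
    nominal = p[j]
    best = None
    for direction in ("increase", "decrease"):
        fold = find_fold(net, p, parameter, direction)
        if fold is not None:
            pct = abs(fold - nominal) / nominal * 100.0
            if best is None or pct < best:
                best = pct
    if best is None:
        raise OpenBranchError(
            f"no fold in either direction for {parameter!r}")
    return best


def fold_summary(net: ReactionNetwork, params=None) -> pd.DataFrame:
    """Fold location and percent distance for every parameter/direction."""
    p = (net.nominal() if params is None
         else np.asarray(params, dtype=float))
    rows = []
    for name in net.parameter_names:
        j = _param_index(net, name)
        for direction in ("increase", "decrease"):
            fold = find_fold(net, p, name, direction)
            rows.append({
                "parameter": name,
                "direction": direction,
                "nominal": p[j],
                "fold_value": np.nan if fold is None else fold,
                "percent_from_nominal": (
                    np.nan if fold is None
                    else abs(fold - p[j]) / p[j] * 100.0),
            })
    return pd.DataFrame(rows)


def s_curve(net: ReactionNetwork, params=None, parameter: str = "",
            span: tuple[float, float] = (0.0, 0.0),
            n_points: int = 101) -> pd.DataFrame:
    """One-parameter bifurcation diagram data (all branches, tabulated)."""
    p = (net.nominal() if params is None
         else np.asarray(params, dtype=float))
    j = _param_index(net, parameter)
    rows = []
    for v in np.linspace(span[0], span[1], n_points):
        if v <= 0:
            continue
        q = np.array(p, dtype=float)
        q[j] = v
        for k, state in enumerate(solve_steady_states(net, q)):
            row = {"p": v, "branch": k, "stability": state.stability,
                   "spectral_abscissa": state.spectral_abscissa}
            for sname, c in zip(net.species, state.coordinates):
                row[sname] = c
            rows.append(row)
    return pd.DataFrame(rows)
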