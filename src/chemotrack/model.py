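"""Chemostat model of a two-step nitrification cascade with interacting OTUs.

The community is split into two functional groups: ammonia-oxidizing
bacteria (AOB, group ``G1``) consume ammonium ``s1`` and produce nitrite
``s2``; nitrite-oxidizing bacteria (NOB, group ``G2``) consume ``s2`` and
produce nitrate ``s3``.  Each OTU grows at a Monod rate on its group's
substrate, multiplied by an affine generalized Lotka-Volterra interaction
term::

    mu_i(s, x) = f_i(s) * (1 + sum_j a_ij x_j)

where ``f_i(s) = mu_max_i * s_g / (K_i + s_g)`` with ``s_g`` the group
substrate.  The reactor is a chemostat with (possibly time-varying,
piecewise-constant) dilution rate ``D`` [1/day] and inlet ammonium
concentration ``s_in`` [g/L].  All concentrations are in g/L, all times in
days.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "Group",
    "FunctionalGrouping",
    "KineticParams",
    "StoichiometryMatrix",
    "InteractionMatrix",
    "OperatingConditions",
    "ChemostatState",
    "Trajectory",
    "CommunityModel",
    "monod_f",
    "growth_rates",
    "rhs",
    "simulate",
    "simulate_to_steady_state",
    "lemma_bounds",
    "interaction_norm_bound",
    "SteadyStateResult",
]

#: default ODE tolerances (stiff-capable solver)
RTOL = 1e-8
ATOL = 1e-10

#: steady-state detector: ||rhs||_inf below this, sustained over 10 output points
STEADY_STATE_TOL = 1e-9
STEADY_STATE_POINTS = 10


class Group(enum.IntEnum):
    """Functional group of an OTU: G1 = AOB, G2 = NOB."""

    G1 = 1
    G2 = 2


@dataclass(frozen=True)
class FunctionalGrouping:
    """Partition of the n OTUs into the two cascade functional groups.

    Parameters
    ----------
    groups : sequence of Group
        ``groups[i]`` is the functional group of OTU ``i`` (0-based).
        G1 and G2 partition the community; G1 must be non-empty because
        the cascade is fed only with the G1 substrate.
    """

    groups: tuple[Group, ...]

    def __init__(self, groups: Sequence[Group | int]) -> None:
        object.__setattr__(self, "groups", tuple(Group(g) for g in groups))
        if self.n1 < 1:
            raise ValueError("G1 (AOB) must contain at least one OTU")

    @property
    def n(self) -> int:
        return len(self.groups)

    @property
    def n1(self) -> int:
        return sum(1 for g in self.groups if g == Group.G1)

    @property
    def n2(self) -> int:
        return sum(1 for g in self.groups if g == Group.G2)

    @property
    def g1_indices(self) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.groups) if g == Group.G1], dtype=int)

    @property
    def g2_indices(self) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.groups) if g == Group.G2], dtype=int)

    @property
    def is_g1(self) -> np.ndarray:
        """Boolean mask, True where the OTU belongs to G1."""
        return np.array([g == Group.G1 for g in self.groups])


@dataclass(frozen=True)
class KineticParams:
    """Per-OTU Monod parameters.

    Attributes
    ----------
    mu_max : ndarray
        Maximal specific growth rates [1/day], strictly positive.
    K : ndarray
        Half-saturation constants [g/L], strictly positive.
    inv_yield : ndarray
        ``1/y_i`` [g substrate consumed per g biomass formed]; parameter
        tables print this quantity, so it is stored as given.
    """

    mu_max: np.ndarray
    K: np.ndarray
    inv_yield: np.ndarray

    def __post_init__(self) -> None:
        for name in ("mu_max", "K", "inv_yield"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.ndim != 1 or np.any(arr <= 0) or not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be a 1-D strictly positive array")
        if not (self.mu_max.shape == self.K.shape == self.inv_yield.shape):
            raise ValueError("kinetic parameter arrays must share one length")

    @property
    def n(self) -> int:
        return self.mu_max.size

    @property
    def yields(self) -> np.ndarray:
        """y_i [g biomass per g substrate]."""
        return 1.0 / self.inv_yield


@dataclass(frozen=True)
class StoichiometryMatrix:
    """Signed 3 x n matrix Y of substrate yields per biomass formed.

    Column j reads (-1/y_j, +1/y_j, 0) for an AOB and (0, -1/y_j, +1/y_j)
    for a NOB: each gram of substrate consumed in one cascade step
    reappears in the next pool, so every column sums to zero.
    """

    Y: np.ndarray

    @classmethod
    def from_kinetics(cls, grouping: FunctionalGrouping, kinetics: KineticParams) -> "StoichiometryMatrix":
        n = grouping.n
        Y = np.zeros((3, n))
        inv_y = kinetics.inv_yield
        for j, g in enumerate(grouping.groups):
            if g == Group.G1:
                Y[0, j] = -inv_y[j]
                Y[1, j] = +inv_y[j]
            else:
                Y[1, j] = -inv_y[j]
                Y[2, j] = +inv_y[j]
        return cls(Y=Y)

    def __post_init__(self) -> None:
        Y = np.asarray(self.Y, dtype=float)
        object.__setattr__(self, "Y", Y)
        if Y.ndim != 2 or Y.shape[0] != 3:
            raise ValueError("stoichiometry matrix must be 3 x n")
        if not np.allclose(Y.sum(axis=0), 0.0, atol=1e-12):
            raise ValueError("cascade stoichiometry columns must sum to zero")


@dataclass(frozen=True)
class InteractionMatrix:
    """Pairwise gLV interaction matrix A; ``a_ij`` is the effect of OTU j
    on the growth of OTU i (per g/L of x_j)."""

    A: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "A", A)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("interaction matrix must be square")

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def infinity_norm(self) -> float:
        """Max row sum of |a_ij|, the quantity the well-posedness
        sufficient condition bounds."""
        if self.n == 0:
            return 0.0
        return float(np.abs(self.A).sum(axis=1).max())

    @property
    def is_zero(self) -> bool:
        return bool(np.all(self.A == 0.0))


@dataclass(frozen=True)
class OperatingConditions:
    """Piecewise-constant operating schedule of the chemostat.

    ``segments`` is an ordered list of ``(t_start, D, s_in)`` with
    ``t_start`` in days, ``D`` in 1/day and ``s_in`` in g/L; segment k
    applies on ``[t_start_k, t_start_{k+1})`` and the last one up to
    ``horizon``.
    """

    segments: tuple[tuple[float, float, float], ...]
    horizon: float

    def __init__(self, segments: Sequence[tuple[float, float, float]], horizon: float) -> None:
        segs = tuple((float(t), float(d), float(s)) for t, d, s in segments)
        if not segs:
            raise ValueError("at least one operating segment is required")
        starts = [t for t, _, _ in segs]
        if starts != sorted(starts) or len(set(starts)) != len(starts):
            raise ValueError("segment start times must be strictly increasing")
        if any(d < 0 or s < 0 for _, d, s in segs):
            raise ValueError("D and s_in must be non-negative")
        if horizon <= starts[0]:
            raise ValueError("horizon must exceed the first segment start")
        object.__setattr__(self, "segments", segs)
        object.__setattr__(self, "horizon", float(horizon))

    @classmethod
    def constant(cls, D: float, s_in: float, horizon: float, t_start: float = 0.0) -> "OperatingConditions":
        return cls([(t_start, D, s_in)], horizon)

    @property
    def t0(self) -> float:
        return self.segments[0][0]

    def at(self, t: float) -> tuple[float, float]:
        """Return (D, s_in) applying at time t."""
        if t < self.t0 - 1e-12 or t > self.horizon + 1e-12:
            raise ValueError(f"t={t} outside operating schedule [{self.t0}, {self.horizon}]")
        D, s_in = self.segments[0][1], self.segments[0][2]
        for t_start, d, s in self.segments:
            if t >= t_start - 1e-12:
                D, s_in = d, s
            else:
                break
        return D, s_in

    def breakpoints(self) -> list[float]:
        """Segment boundaries within [t0, horizon], including both ends."""
        pts = [t for t, _, _ in self.segments if self.t0 < t < self.horizon]
        return [self.t0, *pts, self.horizon]

    @property
    def max_s_in(self) -> float:
        return max(s for _, _, s in self.segments)


@dataclass(frozen=True)
class ChemostatState:
    """State of the reactor: OTU concentrations ``x`` (n-vector) and
    substrate concentrations ``s = (s1, s2, s3)``, all in g/L."""

    x: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        x = np.atleast_1d(np.asarray(self.x, dtype=float))
        s = np.asarray(self.s, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "s", s)
        if s.shape != (3,):
            raise ValueError("s must be a 3-vector (ammonium, nitrite, nitrate)")
        if np.any(x < 0) or np.any(s < 0):
            raise ValueError("concentrations must be non-negative")

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.x, self.s])

    @classmethod
    def from_vector(cls, v: np.ndarray, clip_tol: float = 1e-8) -> "ChemostatState":
        """Build a state from a raw (n+3)-vector, clamping solver-level
        negative round-off (components above ``-clip_tol``) to zero."""
        v = np.asarray(v, dtype=float)
        if np.any(v < -clip_tol):
            raise ValueError(f"state has negative components beyond tolerance: min={v.min()}")
        v = np.clip(v, 0.0, None)
        return cls(x=v[:-3], s=v[-3:])


@dataclass(frozen=True)
class Trajectory:
    """Time-gridded solution of the model.

    ``states`` has shape (len(times), n+3) with columns x_1..x_n, s1, s2, s3.
    ``controls`` optionally stores the per-OTU growth controls u(t) applied
    (shape (len(times), n)); ``None`` for uncontrolled runs.
    """

    times: np.ndarray
    states: np.ndarray
    controls: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.states, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", y)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if y.shape[0] != t.size:
            raise ValueError("states must have one row per time point")

    @property
    def n(self) -> int:
        return self.states.shape[1] - 3

    @property
    def x(self) -> np.ndarray:
        return self.states[:, : self.n]

    @property
    def s(self) -> np.ndarray:
        return self.states[:, self.n :]

    def final_state(self, clip_tol: float = 1e-6) -> ChemostatState:
        return ChemostatState.from_vector(self.states[-1], clip_tol=clip_tol)


@dataclass(frozen=True)
class CommunityModel:
    """Complete parameterization of the cascade chemostat community."""

    grouping: FunctionalGrouping
    kinetics: KineticParams
    stoich: StoichiometryMatrix
    interactions: InteractionMatrix

    def __post_init__(self) -> None:
        n = self.grouping.n
        if self.kinetics.n != n or self.interactions.n != n or self.stoich.Y.shape[1] != n:
            raise ValueError("model component dimensions are inconsistent")

    @classmethod
    def build(
        cls,
        groups: Sequence[Group | int],
        mu_max: Sequence[float],
        K: Sequence[float],
        inv_yield: Sequence[float],
        A: np.ndarray | None = None,
    ) -> "CommunityModel":
        grouping = FunctionalGrouping(groups)
        kinetics = KineticParams(
            mu_max=np.asarray(mu_max, float),
            K=np.asarray(K, float),
            inv_yield=np.asarray(inv_yield, float),
        )
        if A is None:
            A = np.zeros((grouping.n, grouping.n))
        return cls(
            grouping=grouping,
            kinetics=kinetics,
            stoich=StoichiometryMatrix.from_kinetics(grouping, kinetics),
            interactions=InteractionMatrix(np.asarray(A, float)),
        )

    @property
    def n(self) -> int:
        return self.grouping.n

    def with_interactions(self, A: np.ndarray) -> "CommunityModel":
        return replace(self, interactions=InteractionMatrix(np.asarray(A, float)))

    # -- convenience wrappers -------------------------------------------------
    def monod_f(self, s: np.ndarray) -> np.ndarray:
        return monod_f(s, self)

    def growth_rates(self, s: np.ndarray, x: np.ndarray) -> np.ndarray:
        return growth_rates(s, x, self)


def monod_f(s: np.ndarray, model: CommunityModel) -> np.ndarray:
    """Substrate-limited (Monod) part of the growth rates.

    ``f_i(s) = mu_max_i * s1 / (K_i + s1)`` for AOB and the same with
    ``s2`` for NOB.  Always in ``[0, mu_max_i)``.
    """
    s = np.asarray(s, dtype=float)
    if s.shape != (3,):
        raise ValueError("s must be a 3-vector")
    if np.any(s < 0):
        raise ValueError("substrate concentrations must be non-negative")
    kin = model.kinetics
    sg = np.where(model.grouping.is_g1, s[0], s[1])
    return kin.mu_max * sg / (kin.K + sg)


def growth_rates(s: np.ndarray, x: np.ndarray, model: CommunityModel) -> np.ndarray:
    """Full growth rates ``mu_i = f_i(s) * (1 + (A x)_i)``.

    Strong negative interactions can make this negative; the value is
    returned as computed (biomass non-negativity is preserved by the
    ``x_i = 0`` boundary of the ODE, not by clipping here).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.shape != (model.n,):
        raise ValueError(f"x must have length n={model.n}")
    f = monod_f(s, model)
    return f * (1.0 + model.interactions.A @ x)


def _rhs_vec(t: float, v: np.ndarray, model: CommunityModel, D: float, s_in: float) -> np.ndarray:
    """Right-hand side on the raw (n+3)-vector; substrates may be slightly
    negative during solver steps, so f is evaluated on the clipped s."""
    n = model.n
    x = v[:n]
    s = np.clip(v[n:], 0.0, None)
    f = monod_f(s, model)
    mu = f * (1.0 + model.interactions.A @ x)
    dx = (mu - D) * x
    ds = np.array([s_in, 0.0, 0.0]) * D - v[n:] * D + model.stoich.Y @ (mu * x)
    return np.concatenate([dx, ds])


def rhs(
    t: float,
    state: ChemostatState | np.ndarray,
    model: CommunityModel,
    operating: OperatingConditions,
) -> np.ndarray:
    """Time derivative of the full state under the operating schedule.

    The three substrate derivatives sum to ``D * (s_in - s1 - s2 - s3)``
    identically: the biomass uptake terms cancel along the cascade.
    """
    D, s_in = operating.at(t)
    v = state.as_vector() if isinstance(state, ChemostatState) else np.asarray(state, float)
    return _rhs_vec(t, v, model, D, s_in)


def simulate(
    model: CommunityModel,
    operating: OperatingConditions,
    init: ChemostatState,
    times: np.ndarray,
    controls: Callable[[float], np.ndarray] | None = None,
    rtol: float = RTOL,
    atol: float = ATOL,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model on a time grid.

    The schedule is solved segment by segment so that discontinuities in
    ``D`` and ``s_in`` fall on solver restarts rather than inside a step.

    Parameters
    ----------
    controls : callable, optional
        ``controls(t) -> n-vector u(t)`` replacing the gLV interaction
        factor: growth becomes ``f_i(s) u_i(t)`` (the observed-community
        tracking dynamics).  ``None`` runs the mechanistic gLV model.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing grid with >= 2 points")
    if times[0] < operating.t0 - 1e-9 or times[-1] > operating.horizon + 1e-9:
        raise ValueError("time grid must lie within the operating schedule")

    n = model.n
    Y = model.stoich.Y

    def seg_rhs(t: float, v: np.ndarray, D: float, s_in: float) -> np.ndarray:
        if controls is None:
            return _rhs_vec(t, v, model, D, s_in)
        x = v[:n]
        s = np.clip(v[n:], 0.0, None)
        mu = monod_f(s, model) * controls(t)
        dx = (mu - D) * x
        ds = np.array([s_in, 0.0, 0.0]) * D - v[n:] * D + Y @ (mu * x)
        return np.concatenate([dx, ds])

    breaks = operating.breakpoints()
    # restrict to the simulated window
    t_lo, t_hi = times[0], times[-1]
    cuts = [t_lo] + [b for b in breaks if t_lo < b < t_hi] + [t_hi]

    v = init.as_vector()
    out = np.empty((times.size, n + 3))
    out[0] = v
    filled = 1
    for a, b in zip(cuts[:-1], cuts[1:]):
        D, s_in = operating.at(0.5 * (a + b))
        mask = (times > a + 1e-12) & (times <= b + 1e-12)
        t_eval = times[mask]
        sol = solve_ivp(
            seg_rhs,
            (a, b),
            v,
            t_eval=np.union1d(t_eval, [b]),
            args=(D, s_in),
            method=method,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE solver failed on segment [{a}, {b}] (D={D}, s_in={s_in}): {sol.message}"
            )
        # map evaluated points back onto the requested grid
        for ti, yi in zip(sol.t, sol.y.T):
            idx = np.searchsorted(times, ti)
            if idx < times.size and abs(times[idx] - ti) < 1e-9:
                out[idx] = yi
                filled = max(filled, idx + 1)
        v = sol.y[:, -1]
    if filled != times.size:
        raise RuntimeError("internal error: simulation grid not fully covered")
    return Trajectory(times=times, states=out)


@dataclass(frozen=True)
class SteadyStateResult:
    """Outcome of running the model until the steady-state detector fires."""

    state: ChemostatState
    trajectory: Trajectory
    converged: bool
    residual: float


def simulate_to_steady_state(
    model: CommunityModel,
    D: float,
    s_in: float,
    init: ChemostatState,
    t_block: float = 100.0,
    max_time: float = 5000.0,
    dt: float = 1.0,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> SteadyStateResult:
    """Integrate at constant (D, s_in) until ``||rhs||_inf`` stays below the
    steady-state tolerance over consecutive output points, extending the
    horizon block by block up to ``max_time``."""
    operating = OperatingConditions.constant(D, s_in, horizon=max_time)
    t0 = 0.0
    state = init
    all_t: list[np.ndarray] = []
    all_y: list[np.ndarray] = []
    converged = False
    resid = np.inf
    while t0 < max_time and not converged:
        t1 = min(t0 + t_block, max_time)
        times = np.arange(t0, t1 + dt / 2, dt)
        traj = simulate(model, operating, state, times, rtol=rtol, atol=atol)
        res = np.array(
            [np.abs(_rhs_vec(t, y, model, D, s_in)).max() for t, y in zip(traj.times, traj.states)]
        )
        tail = res[-STEADY_STATE_POINTS:]
        resid = float(tail.max())
        converged = tail.size >= STEADY_STATE_POINTS and resid < STEADY_STATE_TOL
        all_t.append(traj.times if not all_t else traj.times[1:])
        all_y.append(traj.states if not all_y else traj.states[1:])
        state = traj.final_state()
        t0 = t1
    full = Trajectory(times=np.concatenate(all_t), states=np.vstack(all_y))
    return SteadyStateResult(state=state, trajectory=full, converged=converged, residual=resid)


def lemma_bounds(init: ChemostatState, model: CommunityModel, operating: OperatingConditions) -> tuple[float, float, float]:
    """A-priori trajectory bounds from the dilution structure.

    Each of the three weighted sums

    * ``V1 = sum_{i in G1} x_i / y_i + s1``
    * ``V2 = sum_{i in G2} x_i / y_i + s1 + s2``
    * ``V3 = s1 + s2 + s3``

    obeys ``dV/dt = D (s_in - V)`` exactly (the growth terms cancel), so
    each stays below ``max(V(0), max_t s_in(t))``.  Returned with a small
    multiplicative safety margin to absorb solver round-off.
    """
    safety = 1.0 + 1e-9
    inv_y = model.kinetics.inv_yield
    g1 = model.grouping.is_g1
    x, s = init.x, init.s
    s_in_max = operating.max_s_in
    v1 = float(np.sum(x[g1] * inv_y[g1]) + s[0])
    v2 = float(np.sum(x[~g1] * inv_y[~g1]) + s[0] + s[1])
    v3 = float(s.sum())
    return (
        max(v1, s_in_max) * safety,
        max(v2, s_in_max) * safety,
        max(v3, s_in_max) * safety,
    )


def interaction_norm_bound(
    init: ChemostatState, model: CommunityModel, operating: OperatingConditions
) -> float:
    """Sufficient bound M on ||A||_inf for well-posedness (diagnostic).

    Inside the invariant box implied by :func:`lemma_bounds`, each biomass
    satisfies ``x_j <= y_j * M1`` (AOB) or ``x_j <= y_j * M2`` (NOB).  If
    ``||A||_inf`` times the largest such biomass bound stays below 1, every
    growth rate stays non-negative, which keeps the substrate pools (and
    hence the whole state) non-negative.  This is sufficient, not
    necessary: larger interaction matrices are often still well behaved.
    """
    m1, m2, _ = lemma_bounds(init, model, operating)
    y = model.kinetics.yields
    g1 = model.grouping.is_g1
    x_max = 0.0
    if g1.any():
        x_max = max(x_max, float((y[g1] * m1).max()))
    if (~g1).any():
        x_max = max(x_max, float((y[~g1] * m2).max()))
    if x_max == 0.0:
        return np.inf
    return 1.0 / x_max
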