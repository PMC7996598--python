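"""Equilibrium enumeration and stability analysis of the cascade chemostat.

At a steady state every *active* OTU (positive concentration) grows exactly
at the dilution rate, ``mu_i(s, x) = D``.  For an invertible active
interaction block ``A_act`` this pins the active biomasses to

    x_act = A_act^{-1} ( D / f_act(s) - 1 )                        (componentwise)

and substituting into the substrate balances eliminates the state down to a
single polynomial in the ammonium concentration ``s1``:

* both groups active: a rational map gives nitrite ``s2`` as a function of
  ``s1`` and the elimination closes with a polynomial of degree <= 4;
* all NOB washed out: nitrate ``s3 = 0``, ``s2 = s_in - s1``, and the
  elimination closes with a quadratic;
* total washout: the closed-form point ``x = 0, s = (s_in, 0, 0)``.

The module enumerates every candidate active set, solves the corresponding
polynomial, filters non-negative candidates, and classifies local stability
through the eigenvalues of the analytic Jacobian.  The elimination itself
is performed symbolically (exact rational arithmetic, dilution rate and
inlet concentration kept symbolic) once per active set and then evaluated
numerically over operating conditions.

With a zero interaction matrix the active-biomass formula is unavailable
(``A`` is singular); the classical break-even analysis applies instead and
is special-cased: each surviving species sits at its break-even substrate
concentration and within-group coexistence is non-generic.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import sympy as sp

from .model import (
    ChemostatState,
    CommunityModel,
    FunctionalGrouping,
    OperatingConditions,
    rhs,
)

__all__ = [
    "ActiveSet",
    "EquilibriumPolynomial",
    "EquilibriumPoint",
    "EquilibriumAnalyzer",
    "enumerate_active_sets",
    "candidate_bound",
    "active_biomass",
    "interior_candidates",
    "g2_washout_candidates",
    "washout_point",
    "jacobian",
    "find_all_equilibria",
    "SingularActiveInteraction",
]

#: eigenvalue real parts within +-STABILITY_TOL of zero are 'marginal'
STABILITY_TOL = 1e-7
#: residual gate for accepting a candidate as an equilibrium
RESIDUAL_TOL = 1e-8
#: max-norm tolerance for deduplicating equilibria
DEDUP_TOL = 1e-6
#: tiny negative components clamped to zero when filtering candidates
CLAMP_TOL = 1e-10
#: imaginary parts below 1e-9 * (1 + |Re|) are treated as real roots
IMAG_TOL = 1e-9
#: default cap on community size for the exponential enumeration
ENUMERATION_CAP = 12


class SingularActiveInteraction(ValueError):
    """The interaction submatrix of an active set is singular, so the
    active-biomass elimination (which assumes invertibility) does not apply."""


@dataclass(frozen=True)
class ActiveSet:
    """A candidate equilibrium support.

    ``inactive`` is the set J of washed-out OTU indices (0-based); the
    complement is the active set.
    """

    inactive: frozenset[int]
    n: int
    case: str  # 'interior' | 'g2_washout' | 'washout'

    @property
    def active(self) -> tuple[int, ...]:
        return tuple(i for i in range(self.n) if i not in self.inactive)

    @property
    def n_act(self) -> int:
        return self.n - len(self.inactive)

    def counts(self, grouping: FunctionalGrouping) -> tuple[int, int]:
        """(n1_act, n2_act) — active members per functional group."""
        g1 = set(grouping.g1_indices.tolist())
        act = set(self.active)
        n1_act = len(act & g1)
        return n1_act, len(act) - n1_act

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return "{" + ",".join(f"x{i+1}" for i in self.active) + "}" if self.active else "{}"


@dataclass(frozen=True)
class EquilibriumPolynomial:
    """Numeric coefficients of the eliminated polynomial at one (D, s_in).

    For the interior case ``coeffs`` holds the degree-<=4 polynomial in s1
    (highest degree first) and ``rational_map_denominator`` the quadratic
    denominator (b1, b2, b3) of the nitrite map ``s2 = s1 / (b1 s1^2 +
    b2 s1 + b3)`` when that map exists (dense interaction coupling); for
    the NOB-washout case ``coeffs`` is the quadratic.
    """

    case: str
    coeffs: tuple[float, ...]
    rational_map_denominator: tuple[float, float, float] | None = None

    @property
    def degree(self) -> int:
        return len(self.coeffs) - 1


@dataclass(frozen=True)
class EquilibriumPoint:
    """An equilibrium with its support, spectrum and stability label."""

    x: np.ndarray
    s: np.ndarray
    active_set: ActiveSet
    eigenvalues: np.ndarray
    stability: str  # 'stable' | 'unstable' | 'marginal'
    residual: float

    @property
    def survivors(self) -> tuple[int, ...]:
        return self.active_set.active

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.x, self.s])


def candidate_bound(n1: int, n2: int) -> int:
    """Upper bound on the number of candidate equilibria: every non-empty
    AOB subset combined with up to 4 interior roots per non-empty NOB
    subset plus 2 NOB-washout roots, plus the washout point."""
    return (2**n1 - 1) * (4 * (2**n2 - 1) + 2) + 1


def enumerate_active_sets(grouping: FunctionalGrouping, cap: int = ENUMERATION_CAP) -> list[ActiveSet]:
    """All candidate supports: interior (both groups partially present),
    NOB washout (some AOB active), and total washout.

    The count is ``(2^n1 - 1)(2^n2 - 1) + (2^n1 - 1) + 1``; supports with
    all AOB washed out but NOB present are impossible (the cascade feeds
    NOB only through AOB activity) and are not generated.
    """
    n, n1 = grouping.n, grouping.n1
    if n1 < 1:
        raise ValueError("the cascade requires at least one AOB (G1) member")
    if n > cap:
        raise ValueError(
            f"enumeration over {n} OTUs exceeds the cap of {cap} "
            f"(2^n supports); raise `cap` explicitly to proceed"
        )
    g1 = list(grouping.g1_indices)
    g2 = list(grouping.g2_indices)
    out: list[ActiveSet] = []

    def subsets(idx: list[int]) -> Iterable[tuple[int, ...]]:
        for r in range(1, len(idx) + 1):
            yield from itertools.combinations(idx, r)

    for a1 in subsets(g1):
        for a2 in subsets(g2):
            inact = frozenset(range(n)) - set(a1) - set(a2)
            out.append(ActiveSet(inactive=inact, n=n, case="interior"))
        inact = frozenset(range(n)) - set(a1)
        out.append(ActiveSet(inactive=inact, n=n, case="g2_washout"))
    out.append(ActiveSet(inactive=frozenset(range(n)), n=n, case="washout"))
    return out


def active_biomass(
    s: np.ndarray, active_set: ActiveSet, model: CommunityModel, D: float
) -> np.ndarray:
    """Solve ``mu_act(x, s) = D`` for the active biomasses at fixed s.

    Returns ``A_act^{-1} (D / f_act(s) - 1)``; entries may be negative, in
    which case the support cannot carry an admissible equilibrium and the
    candidate is rejected by the caller.
    """
    act = list(active_set.active)
    if not act:
        return np.zeros(0)
    f = model.monod_f(np.asarray(s, float))[act]
    if np.any(f <= 0):
        raise ValueError("active OTUs need positive substrate-limited growth at s")
    A_act = model.interactions.A[np.ix_(act, act)]
    w = D / f - 1.0
    try:
        cond = np.linalg.cond(A_act)
    except np.linalg.LinAlgError:  # pragma: no cover
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        raise SingularActiveInteraction(
            f"interaction block for active set {act} is singular or nearly so"
        )
    return np.linalg.solve(A_act, w)


# ---------------------------------------------------------------------------
# symbolic elimination machinery
# ---------------------------------------------------------------------------

_S1, _S2, _D, _SIN = sp.symbols("s1 s2 D s_in", positive=True)


def _rationalize(x: float) -> sp.Rational:
    # exact binary representation; keeps the elimination in exact arithmetic
    return sp.Rational(x)


@dataclass
class _Elimination:
    """Lambdified elimination products for one active set of one model."""

    case: str  # 'interior_map' | 'interior_decoupled' | 'g2_washout'
    # coefficients (highest first) of the s1 polynomial, callable (D, s_in)
    s1_coeffs: callable
    s1_degree: int
    # interior_map: jointly-normalized [num (deg 1) | den (deg 2)]
    # coefficients of the rational nitrite map s2(s1), callable (D, s_in)
    s2_map_coeffs: callable | None = None
    # interior_decoupled: coefficients of the quadratic in s2, callable (s1, D, s_in)
    s2_coeffs: callable | None = None


class EquilibriumAnalyzer:
    """Caches the per-active-set symbolic eliminations for one model and
    evaluates the full equilibrium analysis at arbitrary (D, s_in)."""

    def __init__(self, model: CommunityModel, cap: int = ENUMERATION_CAP):
        self.model = model
        self.cap = cap
        self._elim_cache: dict[tuple[tuple[int, ...], str], _Elimination | None] = {}

    # -- symbolic pieces ----------------------------------------------------
    def _symbolic_x_act(self, act: Sequence[int]):
        """x_act as exact rational expressions in (s1, s2, D)."""
        model = self.model
        kin = model.kinetics
        g1 = set(model.grouping.g1_indices.tolist())
        A_act = sp.Matrix(
            [[_rationalize(model.interactions.A[i, j]) for j in act] for i in act]
        )
        if A_act.det() == 0:
            raise SingularActiveInteraction(f"singular interaction block for active set {list(act)}")
        w = sp.Matrix(
            [
                _D * (_rationalize(kin.K[i]) + (_S1 if i in g1 else _S2))
                / (_rationalize(kin.mu_max[i]) * (_S1 if i in g1 else _S2))
                - 1
                for i in act
            ]
        )
        return A_act.inv() * w

    def _substrate_residuals(self, act: Sequence[int], x_act):
        """The two substrate balances at mu_act = D, divided by D:

        e1 = (s_in - s1) - sum_{G1 act} x_i / y_i
        e2 = -s2 + sum_{G1 act} x_i / y_i - sum_{G2 act} x_i / y_i
        """
        g1 = set(self.model.grouping.g1_indices.tolist())
        inv_y = self.model.kinetics.inv_yield
        e1 = _SIN - _S1
        e2 = -_S2
        for pos, i in enumerate(act):
            term = _rationalize(inv_y[i]) * x_act[pos]
            if i in g1:
                e1 -= term
                e2 += term
            else:
                e2 -= term
        return e1, e2

    def _eliminate_interior(self, act: tuple[int, ...]) -> _Elimination:
        x_act = self._symbolic_x_act(act)
        e1, e2 = self._substrate_residuals(act, x_act)
        p1 = sp.expand(sp.numer(sp.together(e1)))
        p2 = sp.expand(sp.numer(sp.together(e2)))

        p1_s2 = sp.Poly(p1, _S2)
        if p1_s2.degree() >= 1:
            # generic coupling: the first balance is linear in s2 and gives
            # the rational nitrite map s2 = s1 / (b1 s1^2 + b2 s1 + b3)
            if p1_s2.degree() != 1:
                raise RuntimeError("unexpected s2 degree in first substrate balance")
            lin, const = p1_s2.all_coeffs()
            s2_sol = sp.cancel(-const / lin)
            num, den = sp.fraction(sp.together(s2_sol))
            num_p = sp.Poly(num, _S1)
            den_p = sp.Poly(den, _S1)
            if den_p.degree() > 2 or num_p.degree() > 1:
                raise RuntimeError("nitrite map degrees exceed the expected s1/quadratic form")
            # one joint rescale keeps the num/den ratio (the map's value) intact
            nm = _to_floats(num_p.all_coeffs() + den_p.all_coeffs())
            n_num = num_p.degree() + 1
            map_coeffs = (
                [sp.Float(0)] * (2 - n_num) + nm[:n_num]
                + [sp.Float(0)] * (3 - (len(nm) - n_num)) + nm[n_num:]
            )
            final = sp.expand(sp.numer(sp.together(p2.subs(_S2, s2_sol))))
            # clearing denominators leaves a spurious root at s1 = 0;
            # cancelling it recovers the degree-<=4 polynomial
            poly = _strip_zero_root(sp.Poly(final, _S1))
            if poly.degree() > 4:
                raise RuntimeError(
                    f"interior elimination degree {poly.degree()} exceeds the expected 4"
                )
            coeffs = _padded_coeffs(poly, poly.degree())
            return _Elimination(
                case="interior_map",
                s1_coeffs=sp.lambdify((_D, _SIN), coeffs, "numpy"),
                s1_degree=poly.degree(),
                s2_map_coeffs=sp.lambdify((_D, _SIN), map_coeffs, "numpy"),
            )
        # decoupled support (e.g. triangular interaction blocks): the first
        # balance involves s1 only; solve it, then the second balance is a
        # quadratic for s2 at each s1 root
        poly1 = _strip_zero_root(sp.Poly(p1, _S1))
        if poly1.degree() > 4:
            raise RuntimeError(
                f"decoupled elimination degree {poly1.degree()} exceeds the expected 4"
            )
        p2_s2 = sp.Poly(p2, _S2)
        if p2_s2.degree() > 2:
            raise RuntimeError("nitrite balance degree in s2 exceeds 2")
        c2 = _padded_coeffs(p2_s2, 2)
        return _Elimination(
            case="interior_decoupled",
            s1_coeffs=sp.lambdify((_D, _SIN), _padded_coeffs(poly1, poly1.degree()), "numpy"),
            s1_degree=poly1.degree(),
            s2_coeffs=sp.lambdify((_S1, _D, _SIN), c2, "numpy"),
        )

    def _eliminate_g2_washout(self, act: tuple[int, ...]) -> _Elimination:
        x_act = self._symbolic_x_act(act)
        e1, _ = self._substrate_residuals(act, x_act)
        p1 = sp.expand(sp.numer(sp.together(e1)))
        poly = _strip_zero_root(sp.Poly(p1, _S1))
        if poly.degree() > 2:
            raise RuntimeError(
                f"NOB-washout elimination degree {poly.degree()} exceeds the expected 2"
            )
        return _Elimination(
            case="g2_washout",
            s1_coeffs=sp.lambdify((_D, _SIN), _padded_coeffs(poly, poly.degree()), "numpy"),
            s1_degree=poly.degree(),
        )

    def _elimination(self, active_set: ActiveSet) -> _Elimination | None:
        key = (active_set.active, active_set.case)
        if key not in self._elim_cache:
            try:
                if active_set.case == "interior":
                    self._elim_cache[key] = self._eliminate_interior(active_set.active)
                else:
                    self._elim_cache[key] = self._eliminate_g2_washout(active_set.active)
            except SingularActiveInteraction:
                self._elim_cache[key] = None
                warnings.warn(
                    f"active set {list(active_set.active)} skipped: singular interaction block",
                    stacklevel=2,
                )
        return self._elim_cache[key]

    # -- numeric evaluation --------------------------------------------------
    def polynomial(self, active_set: ActiveSet, D: float, s_in: float) -> EquilibriumPolynomial:
        """The eliminated s1 polynomial of a support at one operating point."""
        elim = self._elimination(active_set)
        if elim is None:
            raise SingularActiveInteraction(
                f"no elimination for active set {list(active_set.active)}"
            )
        coeffs = tuple(float(c) for c in np.atleast_1d(elim.s1_coeffs(D, s_in)))
        den = None
        if elim.s2_map_coeffs is not None:
            nm = np.atleast_1d(np.asarray(elim.s2_map_coeffs(D, s_in), float))
            num_c, den_c = nm[:2], nm[2:]
            # report the denominator normalized to a monic-in-s1 numerator
            if num_c[0] != 0:
                den = tuple(float(c) for c in den_c / num_c[0])
        case = "interior" if elim.case.startswith("interior") else "G2_washout"
        return EquilibriumPolynomial(case=case, coeffs=coeffs, rational_map_denominator=den)

    def _candidate_states(
        self, active_set: ActiveSet, D: float, s_in: float
    ) -> list[tuple[np.ndarray, np.ndarray]]:
        elim = self._elimination(active_set)
        if elim is None:
            raise SingularActiveInteraction(
                f"no elimination for active set {list(active_set.active)}"
            )
        pairs: list[tuple[float, float]] = []  # (s1, s2)
        c = np.atleast_1d(np.asarray(elim.s1_coeffs(D, s_in), float))
        for s1 in _real_nonneg_roots(c):
            if s1 <= 0 or s1 > s_in + 1e-9:
                continue
            if elim.case == "interior_map":
                nm = np.atleast_1d(np.asarray(elim.s2_map_coeffs(D, s_in), float))
                den_v = float(np.polyval(nm[2:], s1))
                if den_v == 0:
                    continue
                pairs.append((s1, float(np.polyval(nm[:2], s1)) / den_v))
            elif elim.case == "interior_decoupled":
                c2 = np.atleast_1d(np.asarray(elim.s2_coeffs(s1, D, s_in), float))
                for s2 in _real_nonneg_roots(c2):
                    pairs.append((s1, s2))
            else:  # g2_washout
                pairs.append((s1, s_in - s1))
        out: list[tuple[np.ndarray, np.ndarray]] = []
        for s1, s2 in pairs:
            s2 = _clamp(s2)
            if s2 is None:
                continue
            if active_set.case == "g2_washout":
                s3 = 0.0
            else:
                s3 = _clamp(s_in - s1 - s2)
                if s3 is None:
                    continue
            s = np.array([s1, s2, s3])
            try:
                x_act = active_biomass(s, active_set, self.model, D)
            except (ValueError, SingularActiveInteraction):
                continue
            x_act_c = np.array([_clamp(v, allow_none=False) for v in x_act])
            if np.any(x_act < -CLAMP_TOL) or np.any(x_act_c <= 0):
                continue  # support not admissible at this root
            x = np.zeros(self.model.n)
            x[list(active_set.active)] = x_act_c
            out.append((x, s))
        return out

    def _classify(
        self, x: np.ndarray, s: np.ndarray, active_set: ActiveSet, D: float, s_in: float
    ) -> EquilibriumPoint | None:
        operating = OperatingConditions.constant(D, s_in, horizon=1.0)
        resid = float(np.abs(rhs(0.0, np.concatenate([x, s]), self.model, operating)).max())
        if resid > RESIDUAL_TOL:
            return None
        J = jacobian(np.concatenate([x, s]), self.model, D, s_in)
        eig = np.linalg.eigvals(J)
        max_re = float(eig.real.max())
        if max_re < -STABILITY_TOL:
            label = "stable"
        elif max_re <= STABILITY_TOL:
            label = "marginal"
        else:
            label = "unstable"
        return EquilibriumPoint(
            x=x, s=s, active_set=active_set, eigenvalues=eig, stability=label, residual=resid
        )

    def interior_candidates(self, active_set: ActiveSet, D: float, s_in: float) -> list[EquilibriumPoint]:
        if active_set.case != "interior":
            raise ValueError("active set is not an interior support")
        pts = [
            self._classify(x, s, active_set, D, s_in)
            for x, s in self._candidate_states(active_set, D, s_in)
        ]
        return [p for p in pts if p is not None]

    def g2_washout_candidates(self, active_set: ActiveSet, D: float, s_in: float) -> list[EquilibriumPoint]:
        if active_set.case != "g2_washout":
            raise ValueError("active set is not a NOB-washout support")
        pts = [
            self._classify(x, s, active_set, D, s_in)
            for x, s in self._candidate_states(active_set, D, s_in)
        ]
        return [p for p in pts if p is not None]

    def washout_point(self, D: float, s_in: float) -> EquilibriumPoint:
        n = self.model.n
        active_set = ActiveSet(inactive=frozenset(range(n)), n=n, case="washout")
        x = np.zeros(n)
        s = np.array([s_in, 0.0, 0.0])
        pt = self._classify(x, s, active_set, D, s_in)
        assert pt is not None  # closed form: residual is exactly zero
        return pt

    def _no_interaction_candidates(self, D: float, s_in: float) -> list[EquilibriumPoint]:
        """Break-even analysis for A = 0: each survivor sits at
        f_i(s*) = D; at most one species per group survives generically."""
        model = self.model
        kin = model.kinetics
        n = model.n
        out: list[EquilibriumPoint] = []

        def break_even(i: int) -> float | None:
            if kin.mu_max[i] <= D:
                return None
            se = D * kin.K[i] / (kin.mu_max[i] - D)
            return se if se > 0 else None

        for j in model.grouping.g1_indices:
            s1 = break_even(j)
            if s1 is None or s1 >= s_in:
                continue
            xj = kin.yields[j] * (s_in - s1)
            # NOB washout branch: s2 = s_in - s1, s3 = 0
            x = np.zeros(n)
            x[j] = xj
            s = np.array([s1, s_in - s1, 0.0])
            aset = ActiveSet(inactive=frozenset(range(n)) - {int(j)}, n=n, case="g2_washout")
            pt = self._classify(x, s, aset, D, s_in)
            if pt is not None:
                out.append(pt)
            for k in model.grouping.g2_indices:
                s2 = break_even(k)
                if s2 is None or s2 >= s_in - s1:
                    continue
                xk = kin.yields[k] * (s_in - s1 - s2)
                x2 = np.zeros(n)
                x2[j], x2[k] = xj, xk
                s_vec = np.array([s1, s2, s_in - s1 - s2])
                aset2 = ActiveSet(
                    inactive=frozenset(range(n)) - {int(j), int(k)}, n=n, case="interior"
                )
                pt2 = self._classify(x2, s_vec, aset2, D, s_in)
                if pt2 is not None:
                    out.append(pt2)
        return out

    def find_all(self, D: float, s_in: float) -> list[EquilibriumPoint]:
        """Union over all supports of admissible equilibria, classified and
        deduplicated.  Per-support elimination failures (singular
        interaction blocks) degrade to warnings."""
        model = self.model
        points: list[EquilibriumPoint] = [self.washout_point(D, s_in)]
        if model.interactions.is_zero:
            points.extend(self._no_interaction_candidates(D, s_in))
        else:
            for aset in enumerate_active_sets(model.grouping, cap=self.cap):
                if aset.case == "washout":
                    continue
                try:
                    if aset.case == "interior":
                        points.extend(self.interior_candidates(aset, D, s_in))
                    else:
                        points.extend(self.g2_washout_candidates(aset, D, s_in))
                except SingularActiveInteraction as exc:
                    warnings.warn(str(exc), stacklevel=2)
        return _dedupe(points)


def _to_floats(exprs: list) -> list:
    """Jointly rescale a coefficient list by its largest rational constant
    and lower all numbers to floats.  The elimination runs in exact
    rational arithmetic (so cancellations are exact), but the resulting
    integers can exceed the double range even though coefficient *ratios*
    — all that matters for a polynomial equation — are moderate."""
    rats: set = set()
    for e in exprs:
        rats |= {abs(r) for r in sp.sympify(e).atoms(sp.Rational)}
    rats.discard(sp.Integer(0))
    scale = max(rats) if rats else sp.Integer(1)
    return [sp.nfloat(sp.expand(e / scale)) for e in exprs]


def _padded_coeffs(poly: sp.Poly, degree: int) -> list:
    """all_coeffs padded on the left to the requested degree (highest
    first), rescaled and lowered to floats."""
    c = _to_floats(poly.all_coeffs())
    return [sp.Float(0)] * (degree + 1 - len(c)) + c


def _strip_zero_root(poly: sp.Poly) -> sp.Poly:
    """Cancel factors of s1 (roots at zero) introduced by clearing the
    rational-map denominators; s1 = 0 is never an admissible equilibrium
    concentration for an active AOB."""
    coeffs = poly.all_coeffs()
    while len(coeffs) > 1 and coeffs[-1] == 0:
        coeffs = coeffs[:-1]
    return sp.Poly(coeffs, poly.gens[0])


def _real_nonneg_roots(coeffs: np.ndarray) -> list[float]:
    c = np.trim_zeros(np.atleast_1d(coeffs), "f")
    if c.size <= 1:
        return []
    roots = np.roots(c)
    out = []
    for r in roots:
        if abs(r.imag) < IMAG_TOL * (1.0 + abs(r.real)) and r.real > -CLAMP_TOL:
            out.append(max(float(r.real), 0.0))
    return out


def _clamp(v: float, allow_none: bool = True):
    if v >= 0:
        return v
    if v > -CLAMP_TOL:
        return 0.0
    return None if allow_none else v


def _dedupe(points: list[EquilibriumPoint]) -> list[EquilibriumPoint]:
    kept: list[EquilibriumPoint] = []
    for p in points:
        dup = False
        for q in kept:
            if np.abs(p.as_vector() - q.as_vector()).max() < DEDUP_TOL:
                dup = True
                break
        if not dup:
            kept.append(p)
    return kept


# ---------------------------------------------------------------------------
# module-level operations (thin wrappers over the analyzer)
# ---------------------------------------------------------------------------


def interior_candidates(
    active_set: ActiveSet, model: CommunityModel, D: float, s_in: float
) -> list[EquilibriumPoint]:
    return EquilibriumAnalyzer(model).interior_candidates(active_set, D, s_in)


def g2_washout_candidates(
    active_set: ActiveSet, model: CommunityModel, D: float, s_in: float
) -> list[EquilibriumPoint]:
    return EquilibriumAnalyzer(model).g2_washout_candidates(active_set, D, s_in)


def washout_point(model: CommunityModel, D: float, s_in: float) -> EquilibriumPoint:
    return EquilibriumAnalyzer(model).washout_point(D, s_in)


def find_all_equilibria(
    model: CommunityModel, D: float, s_in: float, cap: int = ENUMERATION_CAP
) -> list[EquilibriumPoint]:
    return EquilibriumAnalyzer(model, cap=cap).find_all(D, s_in)


def jacobian(
    point: np.ndarray | ChemostatState, model: CommunityModel, D: float, s_in: float
) -> np.ndarray:
    """Analytic Jacobian of the model right-hand side at a state.

    Block structure: the biomass block is ``diag(mu - D) + diag(x f) A``;
    biomass-substrate coupling runs through the Monod derivative of the
    group substrate; the substrate block combines dilution with the
    stoichiometry-weighted growth sensitivities.
    """
    v = point.as_vector() if isinstance(point, ChemostatState) else np.asarray(point, float)
    n = model.n
    x, s = v[:n], np.clip(v[n:], 0.0, None)
    kin = model.kinetics
    A = model.interactions.A
    Y = model.stoich.Y
    g1 = model.grouping.is_g1

    sg = np.where(g1, s[0], s[1])
    f = kin.mu_max * sg / (kin.K + sg)
    dfds = kin.mu_max * kin.K / (kin.K + sg) ** 2  # d f_i / d s_{g(i)}
    inter = 1.0 + A @ x
    mu = f * inter

    J = np.zeros((n + 3, n + 3))
    # d xdot / dx
    J[:n, :n] = np.diag(mu - D) + (x * f)[:, None] * A
    # d xdot / ds  (only the group substrate column)
    dmu_ds = dfds * inter  # d mu_i / d s_{g(i)}
    sub_col = np.where(g1, n, n + 1)
    for i in range(n):
        J[i, sub_col[i]] += x[i] * dmu_ds[i]
    # d sdot / dx
    J[n:, :n] = Y @ (np.diag(mu) + (x * f)[:, None] * A)
    # d sdot / ds
    J[n:, n:] -= D * np.eye(3)
    for i in range(n):
        J[n:, sub_col[i]] += Y[:, i] * x[i] * dmu_ds[i]
    return J
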