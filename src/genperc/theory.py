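"""Mean-field theory of generational percolation on two-layer multiplexes.

The central object is the giant-cluster function F(x): the relative size of
the giant component of a layer ensemble when only a random fraction x of
nodes may be used, measured with respect to the used nodes.  Writing S^n
for the usable fraction after generation n (S^0 = 1 without initial
removal), the process obeys the alternating recursion

    S^n   = S^0 * F_A(S^{n-1})   (odd n),
    S^n   = S^0 * F_B(S^{n-1})   (even n),
    psi^n = S^{n-1} * F(S^{n-1}),

with psi^n the order parameter (giant-cluster fraction of the whole
network) at generation n.  For ER layers of mean degree z, F(x) is the
largest root u of u = 1 - exp(-z x u); under bond dilution at occupation p
the same ensemble has F_p(x) = F(p x).

Finite generations inherit a continuous transition from the classical
ensemble; the infinite-generation limit satisfies the fixed point
S = S^0 F(S), whose tangent bifurcation produces a *discontinuous*
transition.  For identical ER layers the fixed point is S = 1 - exp(-zS^2),
critical at z_c ≈ 2.455 with S_c ≈ 0.715 and order-parameter jump
psi_c = S_c^2 ≈ 0.512.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .generators import DegreeDistribution

__all__ = [
    "TheoryState",
    "FixedPointResult",
    "er_F",
    "occupation_F",
    "configmodel_F",
    "recursion_trace",
    "finite_generation_threshold",
    "infinite_fixed_point",
    "discontinuous_critical_point",
    "er_tangency_point",
]

_ROOT_TOL = 1e-10
_CONTROL_TOL = 1e-4
_PSI_POSITIVE = 1e-8


@dataclass
class TheoryState:
    """Recorded mean-field recursion: S^0, the S sequence and psi sequence."""

    S0: float
    S_seq: list[float] = field(default_factory=list)
    psi_seq: list[float] = field(default_factory=list)
    converged: bool = False

    def psi_at(self, n: int) -> float:
        if n < 1:
            raise ValueError("generations are 1-based")
        return self.psi_seq[min(n, len(self.psi_seq)) - 1]


@dataclass(frozen=True)
class FixedPointResult:
    """Discontinuous critical point: control value, S_c, and the jump psi_c."""

    control_c: float
    S_c: float
    psi_c: float


def er_F(z: float, x: float) -> float:
    """Giant-cluster fraction (relative to used nodes) of an ER layer of mean
    degree z restricted to a random node fraction x.

    Solves u = 1 - exp(-z x u); returns 0 in the subcritical regime zx <= 1.
    """
    if z < 0 or not 0.0 <= x <= 1.0:
        raise ValueError("need z >= 0 and x in [0, 1]")
    zx = z * x
    if zx <= 1.0:
        return 0.0
    return brentq(lambda u: u - 1.0 + np.exp(-zx * u), 1e-12, 1.0, xtol=_ROOT_TOL)


def occupation_F(F_base: Callable[[float], float], p: float) -> Callable[[float], float]:
    """Giant-cluster function of the bond-diluted ensemble: x -> F_base(p*x)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("occupation probability p must lie in [0, 1]")
    return lambda x: F_base(p * x)


def configmodel_F(dist: DegreeDistribution, x: float, max_iter: int = 10_000) -> float:
    """Giant-cluster fraction of a configuration-model ensemble restricted to
    a random usable node fraction x, via probability generating functions.

    With G0, G1 the degree and excess-degree generating functions, solves
    u = (1 - x) + x G1(u) for the smallest root in [0, 1) and returns
    1 - G0(u) (relative to used nodes).  Reduces to ``er_F`` for Poisson
    degrees.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError("x must lie in [0, 1]")
    if x == 0.0:
        return 0.0
    k = dist.k.astype(float)
    pk = dist.p_k
    kbar = float(k @ pk)
    nz = k >= 1  # zero-degree nodes carry no stubs and drop out of G1
    kq, qk = k[nz], (k * pk)[nz] / kbar  # size-biased; G1(u) = sum q_k u^{k-1}

    def G0(u: float) -> float:
        return float(pk @ u**k)

    def G1(u: float) -> float:
        return float(qk @ u ** (kq - 1.0))

    def g(u: float) -> float:
        return u - (1.0 - x) - x * G1(u)

    # subcritical iff the map has no root below 1: slope at 1 is x*G1'(1)
    G1p1 = float(qk @ (kq - 1.0))
    if x * G1p1 <= 1.0:
        return 0.0
    hi = 1.0 - 1e-9
    if g(hi) <= 0.0:
        # root numerically indistinguishable from 1 (vanishing giant cluster)
        return 0.0
    u = brentq(g, 0.0, hi, xtol=_ROOT_TOL, maxiter=max_iter)
    return 1.0 - G0(u)


def recursion_trace(
    F_A: Callable[[float], float],
    F_B: Callable[[float], float] | None = None,
    S0: float = 1.0,
    n_max: int = 10_000,
    tol: float = 1e-12,
) -> TheoryState:
    """Iterate the alternating mean-field recursion from S^0.

    Records S^n and psi^n for n = 1..; stops when |S^n - S^{n-1}| < tol or
    at n_max.  With identical layers pass F_B=None.
    """
    if not 0.0 <= S0 <= 1.0:
        raise ValueError("S0 must lie in [0, 1]")
    if F_B is None:
        F_B = F_A
    state = TheoryState(S0=S0)
    S_prev = S0
    for n in range(1, n_max + 1):
        F = F_A if n % 2 == 1 else F_B
        val = F(S_prev)
        state.psi_seq.append(S_prev * val)
        S_new = S0 * val
        state.S_seq.append(S_new)
        if abs(S_new - S_prev) < tol:
            state.converged = True
            break
        S_prev = S_new
    return state


def _make_controlled_F(
    control: str,
    value: float,
    dist: DegreeDistribution | None = None,
    z: float | None = None,
) -> Callable[[float], float]:
    """Build F(x) for a control setting.

    ``control='z'``: ER ensemble at mean degree = value.
    ``control='p'``: bond occupation at probability = value over a fixed
    ensemble (ER at mean degree z, or a configuration model ``dist``).
    """
    if control == "z":
        return lambda x: er_F(value, x)
    if control == "p":
        if dist is not None:
            return occupation_F(lambda x: configmodel_F(dist, x), value)
        if z is None:
            raise ValueError("occupation control needs a fixed ensemble (z or dist)")
        return occupation_F(lambda x: er_F(z, x), value)
    raise ValueError("control must be 'z' or 'p'")


def finite_generation_threshold(
    n: int,
    control: str = "z",
    dist: DegreeDistribution | None = None,
    z: float | None = None,
    bracket: tuple[float, float] | None = None,
    tol: float = _CONTROL_TOL,
) -> float:
    """Critical control value of generation n: the smallest control value
    with psi^n > 0, found by bisection (continuous transitions are
    approached from above)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if bracket is None:
        bracket = (0.0, 10.0) if control == "z" else (0.0, 1.0)

    def psi_n(c: float) -> float:
        F = _make_controlled_F(control, c, dist=dist, z=z)
        return recursion_trace(F, n_max=n).psi_at(n)

    lo, hi = bracket
    if psi_n(hi) <= _PSI_POSITIVE:
        raise ValueError("no transition inside the bracket (psi^n = 0 at the top)")
    if psi_n(lo) > _PSI_POSITIVE:
        raise ValueError("bracket lower end is already supercritical")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if psi_n(mid) > _PSI_POSITIVE:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def infinite_fixed_point(
    F: Callable[[float], float], S0: float = 1.0, grid: int = 64
) -> tuple[float, float]:
    """Largest stable solution of S = S0 * F(S) and the corresponding
    psi = S * F(S); returns (0, 0) below threshold.

    The nonzero fixed point is bracketed via g(S) = S - S0*F(S): a coarse
    grid locates the interior minimum of g, bounded minimization refines it
    (the dip below zero shrinks to a point at the tangent bifurcation, so
    plain sign-scanning would miss it), and the largest root is then
    bisected on [argmin, 1].
    """

    def g(S: float) -> float:
        return S - S0 * F(S)

    xs = np.linspace(1e-6, 1.0, grid)
    Fs = np.array([F(x) for x in xs])
    pos = np.nonzero(Fs > 0.0)[0]
    if len(pos) == 0:
        return 0.0, 0.0
    # the dip of g can only lie where F is nonzero (below that g(S) = S > 0)
    lo_i = int(pos[0])
    gs = xs[lo_i:] - S0 * Fs[lo_i:]
    j = lo_i + int(np.argmin(gs))
    a, b = xs[max(j - 1, 0)], xs[min(j + 1, grid - 1)]
    if b > a:
        res = minimize_scalar(g, bounds=(a, b), method="bounded",
                              options={"xatol": 1e-12})
        x_min, g_min = float(res.x), float(res.fun)
    else:
        x_min, g_min = float(xs[j]), float(g(xs[j]))
    if g_min >= 0.0:
        return 0.0, 0.0
    if g(1.0) <= 0.0:
        return 1.0, F(1.0)
    S = brentq(g, x_min, 1.0, xtol=_ROOT_TOL)
    return S, S * F(S)


def discontinuous_critical_point(
    F_of_control: Callable[[float], Callable[[float], float]],
    bracket: tuple[float, float],
    S0: float = 1.0,
    tol: float = 1e-9,
) -> FixedPointResult:
    """Critical control value of the infinite-generation (steady-state)
    transition: the smallest control value whose fixed-point map S = S0*F(S)
    admits a nonzero solution.  At that value the nonzero fixed point
    appears tangentially, so the order parameter jumps from 0 to
    psi_c = S_c * F(S_c).

    Near the tangency S(c) grows like sqrt(c - c_crit), so the control
    bisection runs to a tight tolerance to pin the reported S_c and psi_c.
    """
    lo, hi = bracket

    def S_of(c: float) -> float:
        return infinite_fixed_point(F_of_control(c), S0=S0)[0]

    if S_of(hi) <= 0.0:
        raise ValueError("no nonzero fixed point at the top of the bracket")
    if S_of(lo) > 0.0:
        raise ValueError("bracket lower end already has a nonzero fixed point")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if S_of(mid) > 0.0:
            hi = mid
        else:
            lo = mid
    c_crit = hi  # smallest bracketed control value with a surviving cluster
    S_c, psi_c = infinite_fixed_point(F_of_control(c_crit), S0=S0)
    return FixedPointResult(control_c=c_crit, S_c=S_c, psi_c=psi_c)


def er_tangency_point() -> FixedPointResult:
    """Closed-form cross-check for identical ER layers.

    Solves the tangency system {S = 1 - exp(-z S^2),
    d/dS [1 - exp(-z S^2)] = 1} which reduces to -2 (1-S) ln(1-S) / S = 1;
    then z_c = -ln(1-S_c)/S_c^2 and S_c = (1 + sqrt(1 - 2/z_c))/2.
    """
    S_c = brentq(lambda S: -2.0 * (1.0 - S) * np.log1p(-S) / S - 1.0, 0.05, 0.95, xtol=_ROOT_TOL)
    z_c = -np.log1p(-S_c) / S_c**2
    return FixedPointResult(control_c=float(z_c), S_c=float(S_c), psi_c=float(S_c**2))
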