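"""Mean-field maps for population activity in neuronal cultures.

Two discrete-time models of the fraction ``q_t`` of simultaneously active
neurons in a network with mean coordination number ``z``:

1-D excitation map
    ``q_{t+1} = 1 - (1 - p)**(z * q_t)`` — each neuron fires with
    probability ``p`` in response to any one of its ``z * q_t`` active
    neighbours, all inputs independent.  All orbits are monotone and
    converge to a fixed point; a nonzero attractor exists exactly when
    ``-z * log(1 - p) > 1``.

Activity–energy map
    The 2-D extension couples activity to a phenomenological energy
    resource ``E_t``::

        q_{t+1} = 1 - (1 - p * sigma(E_t))**(z * q_t)
        E_{t+1} = (1 - eps) * E_t + eps * E_bar - r * q_t * [E_t >= r * q_t]

    with the energy-modulated synaptic efficacy
    ``sigma(E) = (tanh(w*E - E_low) + 1) / 2``.  Activation costs energy
    ``r`` per unit activity (paid only when affordable, Heaviside gate
    with H(0) = 1) and energy relaxes toward the recovery level ``E_bar``
    at rate ``eps``.  Depending on ``z`` the map has up to three fixed
    points — silent (0, E_bar), an interior balance point on
    ``E = E_bar - r q / eps``, and a saturated point at ``E = E_bar`` —
    and exhibits periodic and chaotic-like orbits past a Neimark–Sacker
    bifurcation of the interior point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "MeanFieldParams",
    "MeanFieldOrbit",
    "FixedPoint",
    "sigma",
    "step_1d",
    "step_2d",
    "simulate",
    "simulate_batch",
    "critical_z1",
    "critical_z2",
    "critical_z3",
    "equilibrium_energy_curve",
    "find_fixed_points",
    "classify_fixed_point",
    "classify_orbit_tail",
    "classify_asymptotic_regime",
]

_TANH_CLAMP = 40.0  # tanh saturates far below double rounding beyond this
_RESIDUAL_TOL = 1e-10
_UNIT_CIRCLE_TOL = 1e-8


@dataclass(frozen=True)
class MeanFieldParams:
    """The seven scalars of the activity–energy map.

    Attributes
    ----------
    p : maximal activation probability, in (0, 1)
    z : mean coordination number (connectivity), > 0
    w : sigmoid steepness of the energy gate, > 0
    E_low : energy activation threshold (the sigmoid midpoint sits at
        ``E = E_low / w``), > 0 in the nominal model but any real value
        is accepted for limit studies
    E_bar : energy recovery value, > E_low required only when E_low > 0
    eps : energy relaxation rate, in (0, 1)
    r : energy cost of unit activation, > 0
    """

    p: float
    z: float
    w: float
    E_low: float
    E_bar: float
    eps: float
    r: float

    def __post_init__(self):
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"p must be in (0, 1), got {self.p}")
        if self.z <= 0:
            raise ValueError(f"z must be > 0, got {self.z}")
        if self.w <= 0:
            raise ValueError(f"w must be > 0, got {self.w}")
        if not 0.0 < self.eps < 1.0:
            raise ValueError(f"eps must be in (0, 1), got {self.eps}")
        if self.r <= 0:
            raise ValueError(f"r must be > 0, got {self.r}")
        if self.E_bar <= 0:
            raise ValueError(f"E_bar must be > 0, got {self.E_bar}")
        if self.E_low > 0 and self.E_bar <= self.E_low:
            raise ValueError(
                f"E_bar must exceed E_low, got E_bar={self.E_bar}, E_low={self.E_low}"
            )


@dataclass(frozen=True)
class MeanFieldOrbit:
    """A simulated trajectory of the activity–energy map."""

    q: np.ndarray
    E: np.ndarray
    params: MeanFieldParams
    q0: float
    E0: float

    def __len__(self) -> int:
        return len(self.q)

    def tail(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        return self.q[-n:], self.E[-n:]


@dataclass
class FixedPoint:
    """An equilibrium of the activity–energy map.

    ``branch`` is one of ``silent`` (0, E_bar), ``interior``
    (E* = E_bar - r q*/eps on the affordable side E* >= r q*) or
    ``saturated`` (E* = E_bar with r q* > E_bar).  ``stability`` is
    filled by :func:`classify_fixed_point`.
    """

    q_star: float
    E_star: float
    branch: str
    eigenvalues: tuple = None
    stability: str = None


def sigma(E, E_low: float, w: float):
    """Energy-modulated synaptic efficacy ``(tanh(w*E - E_low) + 1) / 2``.

    Strictly increasing in ``E`` with range (0, 1); the midpoint value 1/2
    is attained at ``E = E_low / w``.  Accepts scalars or arrays.
    """
    arg = np.clip(w * np.asarray(E, dtype=float) - E_low, -_TANH_CLAMP, _TANH_CLAMP)
    out = 0.5 * (np.tanh(arg) + 1.0)
    return float(out) if np.isscalar(E) or np.ndim(E) == 0 else out


def step_1d(q, p: float, z: float):
    """One step of the 1-D excitation map ``q -> 1 - (1 - p)**(z*q)``."""
    q_arr = np.asarray(q, dtype=float)
    if np.any(q_arr < 0) or np.any(q_arr > 1):
        raise ValueError("q must lie in [0, 1]")
    out = -np.expm1(z * q_arr * np.log1p(-p))
    return float(out) if np.ndim(q) == 0 else out


def _step_2d_raw(q, E, p, z, w, E_low, E_bar, eps, r):
    """Unvalidated vectorized step of the activity–energy map.

    All arguments broadcast; used by the batch/scenario drivers where the
    parameters vary per orbit or per time step.
    """
    s = 0.5 * (np.tanh(np.clip(w * E - E_low, -_TANH_CLAMP, _TANH_CLAMP)) + 1.0)
    q_next = -np.expm1(z * q * np.log1p(-p * s))
    pay = E >= r * q  # Heaviside gate, H(0) = 1
    E_next = (1.0 - eps) * E + eps * E_bar - np.where(pay, r * q, 0.0)
    return q_next, E_next


def _step_scalar(qt, Et, p, z, w, E_low, E_bar, eps, r):
    """Scalar-arithmetic step shared by :func:`simulate` and the
    time-varying scenario drivers (bit-identical between the two)."""
    arg = w * Et - E_low
    if arg > _TANH_CLAMP:
        arg = _TANH_CLAMP
    elif arg < -_TANH_CLAMP:
        arg = -_TANH_CLAMP
    s = 0.5 * (math.tanh(arg) + 1.0)
    q_next = -math.expm1(z * qt * math.log1p(-p * s))
    E_next = (1.0 - eps) * Et + eps * E_bar - (r * qt if Et >= r * qt else 0.0)
    return q_next, E_next


def step_2d(q, E, params: MeanFieldParams):
    """One step of the activity–energy map from a state in the invariant
    domain [0, 1] x [0, E_bar].

    The energy cost ``r*q`` is paid only on the affordable branch
    ``E >= r*q`` (Heaviside convention H(0) = 1); the image stays in the
    domain for any valid parameters.
    """
    q_arr = np.asarray(q, dtype=float)
    E_arr = np.asarray(E, dtype=float)
    if np.any(q_arr < 0) or np.any(q_arr > 1):
        raise ValueError("q must lie in [0, 1]")
    if np.any(E_arr < 0) or np.any(E_arr > params.E_bar):
        raise ValueError(f"E must lie in [0, {params.E_bar}]")
    q_next, E_next = _step_2d_raw(
        q_arr, E_arr, params.p, params.z, params.w,
        params.E_low, params.E_bar, params.eps, params.r,
    )
    if np.ndim(q) == 0 and np.ndim(E) == 0:
        return float(q_next), float(E_next)
    return q_next, E_next


def simulate(params: MeanFieldParams, q0: float, E0: float, T: int) -> MeanFieldOrbit:
    """Deterministic orbit of length ``T + 1`` starting at ``(q0, E0)``."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if not 0.0 <= q0 <= 1.0 or not 0.0 <= E0 <= params.E_bar:
        raise ValueError("initial condition outside the invariant domain")
    q = np.empty(T + 1)
    E = np.empty(T + 1)
    q[0], E[0] = q0, E0
    qt, Et = float(q0), float(E0)
    p, z, w = params.p, params.z, params.w
    E_low, E_bar, eps, r = params.E_low, params.E_bar, params.eps, params.r
    for t in range(1, T + 1):
        qt, Et = _step_scalar(qt, Et, p, z, w, E_low, E_bar, eps, r)
        q[t], E[t] = qt, Et
    return MeanFieldOrbit(q=q, E=E, params=params, q0=q0, E0=E0)


def simulate_batch(
    p, z, w, E_low, E_bar, eps, r, q0, E0, T: int, keep_last: int
) -> tuple[np.ndarray, np.ndarray]:
    """Iterate many orbits in lock-step (parameters broadcast per orbit).

    Returns the final ``keep_last`` points of each orbit as two arrays of
    shape ``(keep_last, n_orbits)``.  This is the workhorse behind the
    parametric portraits and the metrics ensemble, where thousands of
    orbits with different (z, E_low, p, r) run simultaneously.
    """
    shape = np.broadcast_shapes(
        *(np.shape(a) for a in (p, z, w, E_low, E_bar, eps, r, q0, E0))
    )
    q = np.broadcast_to(np.asarray(q0, float), shape).copy()
    E = np.broadcast_to(np.asarray(E0, float), shape).copy()
    if keep_last > T + 1:
        raise ValueError("keep_last cannot exceed orbit length T + 1")
    n = shape
    q_tail = np.empty((keep_last,) + n)
    E_tail = np.empty((keep_last,) + n)
    first_kept = T + 1 - keep_last
    if first_kept == 0:
        q_tail[0], E_tail[0] = q, E
    for t in range(1, T + 1):
        q, E = _step_2d_raw(q, E, p, z, w, E_low, E_bar, eps, r)
        if t >= first_kept:
            q_tail[t - first_kept] = q
            E_tail[t - first_kept] = E
    return q_tail, E_tail


# ---------------------------------------------------------------------------
# critical connectivities


def critical_z1(p: float) -> float:
    """Critical coordination number of the 1-D map: ``-1 / log(1 - p)``.

    Below it the silent state is the unique (attracting) fixed point; for
    small ``p`` the threshold is approximately ``1 / p``.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    return -1.0 / math.log1p(-p)


def critical_z2(params: MeanFieldParams) -> float:
    """Connectivity at which the silent state of the 2-D map loses
    stability: ``-1 / log(1 - p * sigma(E_bar))``."""
    s = sigma(params.E_bar, params.E_low, params.w)
    return -1.0 / math.log1p(-params.p * s)


def critical_z3(params: MeanFieldParams) -> float:
    """Lower critical connectivity for the saturated branch,
    ``log(1 - E_bar/r) / ((E_bar/r) * log(1 - p * sigma(E_bar)))``;
    requires ``E_bar / r < 1``."""
    ratio = params.E_bar / params.r
    if ratio >= 1.0:
        raise ValueError(
            f"saturated branch requires E_bar/r < 1, got {ratio}; "
            "branch not applicable"
        )
    s = sigma(params.E_bar, params.E_low, params.w)
    return math.log1p(-ratio) / (ratio * math.log1p(-params.p * s))


# ---------------------------------------------------------------------------
# equilibria


def _sigma_needed(q_star: float, z: float, p: float) -> float:
    """Efficacy sigma required for ``q*`` to be a nonzero fixed point of
    the activity equation: ``(1/p) * (1 - (1-q*)**(1/(q* z)))``."""
    if q_star <= 0.0:
        # limit q -> 0+ of (1-q)^(1/(qz)) is exp(-1/z)
        return -math.expm1(-1.0 / z) / p
    if q_star >= 1.0:
        return 1.0 / p
    return -math.expm1(math.log1p(-q_star) / (q_star * z)) / p


def equilibrium_energy_curve(q_star: float, params: MeanFieldParams) -> float:
    """Energy at which ``q*`` balances the activity equation.

    Inverts the efficacy sigmoid:
    ``E*(q*) = (atanh(2*s_req - 1) + E_low) / w`` with
    ``s_req = (1/p)(1 - (1-q*)**(1/(q* z)))``.  Every nonzero equilibrium
    of the 2-D map lies on this strictly increasing curve.

    Raises
    ------
    ValueError
        If ``s_req`` falls outside (0, 1): no energy level can make
        ``q*`` an equilibrium (activation demand exceeds the maximal
        probability ``p``).
    """
    if not 0.0 < q_star < 1.0:
        raise ValueError(f"q_star must be in (0, 1), got {q_star}")
    s_req = _sigma_needed(q_star, params.z, params.p)
    if not 0.0 < s_req < 1.0:
        raise ValueError(
            f"required efficacy {s_req:.6g} outside (0, 1): "
            f"no equilibrium at q* = {q_star}"
        )
    return (math.atanh(2.0 * s_req - 1.0) + params.E_low) / params.w


def _interior_gap(q: float, params: MeanFieldParams) -> float:
    """Signed gap h(q) - (E_bar - r q / eps); +inf where the equilibrium
    curve is undefined (demand >= p).  Strictly increasing in q."""
    s_req = _sigma_needed(q, params.z, params.p)
    if s_req >= 1.0:
        return math.inf
    if s_req <= 0.0:  # unreachable for q in (0,1) but keep the bisection safe
        return -math.inf
    h = (math.atanh(2.0 * s_req - 1.0) + params.E_low) / params.w
    return h - (params.E_bar - params.r * q / params.eps)


def _find_interior(params: MeanFieldParams) -> FixedPoint | None:
    """Bisect the monotone crossing of the equilibrium-energy curve with
    the relaxation line ``E = E_bar - r q / eps`` on the affordable side
    ``E >= r q``."""
    # affordability E* >= r q*  <=>  q* <= eps*E_bar / (r*(1+eps))
    q_hi = min(1.0 - 1e-12, params.eps * params.E_bar / (params.r * (1.0 + params.eps)))
    if q_hi <= 0.0:
        return None
    q_lo = 1e-15
    g_lo = _interior_gap(q_lo, params)
    g_hi = _interior_gap(q_hi, params)
    if not (g_lo < 0.0 <= g_hi):
        return None
    for _ in range(200):
        q_mid = 0.5 * (q_lo + q_hi)
        if _interior_gap(q_mid, params) < 0.0:
            q_lo = q_mid
        else:
            q_hi = q_mid
        if q_hi - q_lo < 1e-16:
            break
    q_star = 0.5 * (q_lo + q_hi)
    E_star = params.E_bar - params.r * q_star / params.eps
    return FixedPoint(q_star=q_star, E_star=E_star, branch="interior")


def _find_saturated(params: MeanFieldParams) -> FixedPoint | None:
    """Nonzero root of ``q = 1 - (1 - p*sigma(E_bar))**(q z)`` with
    ``q > E_bar / r`` (cost unaffordable, energy pinned at E_bar)."""
    if params.E_bar / params.r >= 1.0:
        return None
    s = sigma(params.E_bar, params.E_low, params.w)
    a = math.log1p(-params.p * s)  # < 0
    if -params.z * a <= 1.0:
        return None  # slope at 0 too small: no nonzero root
    def g(q):
        return -math.expm1(params.z * q * a) - q
    lo, hi = 1e-12, 1.0
    if g(lo) <= 0.0:
        return None
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-16:
            break
    q_star = 0.5 * (lo + hi)
    if q_star <= params.E_bar / params.r:
        return None  # root lies on the affordable side: belongs to interior
    return FixedPoint(q_star=q_star, E_star=params.E_bar, branch="saturated")


def _residual(fp: FixedPoint, params: MeanFieldParams) -> float:
    q1, E1 = _step_2d_raw(
        fp.q_star, fp.E_star, params.p, params.z, params.w,
        params.E_low, params.E_bar, params.eps, params.r,
    )
    return max(abs(float(q1) - fp.q_star), abs(float(E1) - fp.E_star))


def find_fixed_points(params: MeanFieldParams) -> list[FixedPoint]:
    """All fixed points of the activity–energy map, stability classified.

    The silent point (0, E_bar) always exists.  The interior point is the
    unique crossing (if any) of the strictly increasing equilibrium-energy
    curve with the decreasing line ``E = E_bar - r q / eps``; the
    saturated point solves ``q = 1 - (1 - p sigma(E_bar))**(q z)`` with
    ``r q > E_bar`` and can exist only when ``E_bar / r < 1``.  At most
    three points are returned; residuals are below 1e-10.
    """
    points = [FixedPoint(q_star=0.0, E_star=params.E_bar, branch="silent")]
    interior = _find_interior(params)
    if interior is not None and _residual(interior, params) <= _RESIDUAL_TOL:
        points.append(interior)
    saturated = _find_saturated(params)
    if saturated is not None and _residual(saturated, params) <= _RESIDUAL_TOL:
        points.append(saturated)
    return [classify_fixed_point(fp, params) for fp in points]


def _branch_map(branch: str, params: MeanFieldParams):
    """The smooth map coinciding with the full dynamics on one side of the
    Heaviside gate (cost paid on silent/interior, withheld on saturated)."""
    pay = branch in ("silent", "interior")

    def f(q, E):
        s = 0.5 * (math.tanh(
            max(-_TANH_CLAMP, min(_TANH_CLAMP, params.w * E - params.E_low))
        ) + 1.0)
        q_next = -math.expm1(params.z * q * math.log1p(-params.p * s))
        E_next = (1.0 - params.eps) * E + params.eps * params.E_bar
        if pay:
            E_next -= params.r * q
        return q_next, E_next

    return f


def classify_fixed_point(fp: FixedPoint, params: MeanFieldParams) -> FixedPoint:
    """Fill eigenvalues and stability of a fixed point.

    The silent point uses the closed-form eigenvalues
    ``lambda_1 = -z log(1 - p sigma(E_bar))`` and ``lambda_2 = 1 - eps``.
    Other branches differentiate the branch-restricted smooth map by
    central differences (step 1e-7).  A point is an attractor when both
    ``|lambda| < 1``, a repeller when some ``|lambda| > 1``, and
    nonhyperbolic when an eigenvalue sits on the unit circle to 1e-8.
    """
    if fp.branch == "silent":
        s = sigma(params.E_bar, params.E_low, params.w)
        lam1 = -params.z * math.log1p(-params.p * s)
        lam2 = 1.0 - params.eps
        eigs = (complex(lam1), complex(lam2))
    else:
        f = _branch_map(fp.branch, params)
        h = 1e-7
        J = np.empty((2, 2))
        fq_p = f(fp.q_star + h, fp.E_star)
        fq_m = f(fp.q_star - h, fp.E_star)
        fE_p = f(fp.q_star, fp.E_star + h)
        fE_m = f(fp.q_star, fp.E_star - h)
        J[0, 0] = (fq_p[0] - fq_m[0]) / (2 * h)
        J[1, 0] = (fq_p[1] - fq_m[1]) / (2 * h)
        J[0, 1] = (fE_p[0] - fE_m[0]) / (2 * h)
        J[1, 1] = (fE_p[1] - fE_m[1]) / (2 * h)
        eigs = tuple(np.linalg.eigvals(J))
    mags = [abs(l) for l in eigs]
    if any(abs(m - 1.0) <= _UNIT_CIRCLE_TOL for m in mags):
        stability = "nonhyperbolic"
    elif all(m < 1.0 for m in mags):
        stability = "attractor"
    else:
        stability = "repeller"
    fp.eigenvalues = eigs
    fp.stability = stability
    return fp


# ---------------------------------------------------------------------------
# asymptotic-regime classification


def classify_orbit_tail(
    q_tail: np.ndarray,
    E_tail: np.ndarray,
    tol: float = 1e-6,
    max_period: int = 1000,
    curve_tol: float = 0.05,
    n_candidates: int = 10,
) -> tuple[str, int | None]:
    """Label a post-transient orbit segment.

    ``("fixed-point", None)`` when the tail's diameter is below ``tol``.
    ``("periodic", P)`` when the tail recurs with some lag
    ``P <= max_period``: either exactly (shift by ``P`` matches the whole
    tail to within ``tol``) or in the relative sense that the shift
    mismatch stays below ``curve_tol`` times the attractor diameter.  The
    relative criterion recognises the attracting invariant closed curve
    born at a Neimark–Sacker bifurcation, whose rotation number is
    generally irrational: successive near-returns shadow the whole curve
    with a small uniform offset, whereas on a chaotic set a near-return
    at one point diverges elsewhere (mismatch comparable to the
    diameter).  Everything else is ``("complex", None)``.
    """
    n = len(q_tail)
    if n < 2 * max_period or n != len(E_tail):
        raise ValueError(
            f"orbit tail too short for classification: {n} points, "
            f"need >= {2 * max_period}"
        )
    diameter = max(np.ptp(q_tail), np.ptp(E_tail))
    if diameter < tol:
        return "fixed-point", None
    # candidate lags: best near-returns to the final state
    ret = np.maximum(
        np.abs(q_tail[:-1] - q_tail[-1]), np.abs(E_tail[:-1] - E_tail[-1])
    )[::-1][:max_period]  # ret[P-1] = return distance at lag P
    order = np.argsort(ret, kind="stable")
    best_ratio = np.inf
    best_lag = None
    for idx in order[:n_candidates]:
        P = int(idx) + 1
        mismatch = max(
            np.max(np.abs(q_tail[P:] - q_tail[:-P])),
            np.max(np.abs(E_tail[P:] - E_tail[:-P])),
        )
        if mismatch < tol:
            return "periodic", P
        ratio = mismatch / diameter
        if ratio < best_ratio:
            best_ratio, best_lag = ratio, P
    if best_ratio < curve_tol:
        return "periodic", best_lag
    return "complex", None


def _limit_summary(q_tail, E_tail):
    return (
        float(np.min(q_tail)), float(np.max(q_tail)),
        float(np.min(E_tail)), float(np.max(E_tail)),
    )


def classify_orbit_outcomes(
    orbits: Sequence[MeanFieldOrbit],
    tail: int = 20000,
    tol: float = 1e-6,
    max_period: int = 1000,
) -> list[str]:
    """Per-orbit asymptotic outcome.

    Fixed points are split by branch: ``silent`` (q below 1e-4),
    ``saturated`` (cost unaffordable at the limit, ``E < r*q``) or
    ``interior``; otherwise ``periodic`` / ``complex`` as in
    :func:`classify_orbit_tail`.
    """
    outcomes = []
    for orb in orbits:
        if len(orb) < tail:
            raise ValueError(f"orbit length {len(orb)} shorter than tail {tail}")
        q_t, E_t = orb.tail(tail)
        lab, _ = classify_orbit_tail(q_t, E_t, tol=tol, max_period=max_period)
        if lab == "fixed-point":
            q_lim, E_lim = float(q_t[-1]), float(E_t[-1])
            if q_lim < 1e-4:
                lab = "silent"
            elif E_lim < orb.params.r * q_lim:
                lab = "saturated"
            else:
                lab = "interior"
        outcomes.append(lab)
    return outcomes


_FIXED_OUTCOMES = {"silent": "silent-eq", "interior": "interior-eq",
                   "saturated": "saturated-eq"}


def classify_asymptotic_regime(
    orbits: Sequence[MeanFieldOrbit],
    tail: int = 20000,
    tol: float = 1e-6,
    max_period: int = 1000,
    set_tol: float = 0.05,
) -> str:
    """Classify the long-run dynamics seen across several orbits.

    Each orbit (from a distinct initial condition) keeps its last ``tail``
    points and receives an outcome via :func:`classify_orbit_outcomes`.
    The joint label is ``silent-eq``, ``interior-eq``, ``saturated-eq``,
    ``periodic`` or ``complex`` when the orbits agree, and
    ``multistable`` when they disagree — different outcomes, distinct
    fixed points, or periodic/complex limit sets separated by more than
    ``set_tol`` in either variable.
    """
    if len(orbits) < 2:
        raise ValueError("need at least two orbits from distinct initial conditions")
    outcomes = classify_orbit_outcomes(orbits, tail=tail, tol=tol,
                                       max_period=max_period)
    if len(set(outcomes)) > 1:
        return "multistable"
    summaries = np.asarray([_limit_summary(*orb.tail(tail)) for orb in orbits])
    spread = np.max(summaries, axis=0) - np.min(summaries, axis=0)
    if outcomes[0] in _FIXED_OUTCOMES:
        if np.max(spread) > max(tol * 10, 1e-5):
            return "multistable"
        return _FIXED_OUTCOMES[outcomes[0]]
    if np.max(spread) > set_tol:
        return "multistable"
    return outcomes[0]
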