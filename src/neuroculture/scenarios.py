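"""Experiment drivers: parametric portraits and the hypoxia protocol.

``run_portrait`` maps the asymptotic regime of the activity–energy map
over an (E_low, z) grid — the numerical analogue of scanning a culture's
excitation threshold against its maturing connectivity — replacing
visual inspection of orbit plots with the algorithmic classifier from
:mod:`neuroculture.meanfield`.

``run_hypoxia`` drives the same map with piecewise-scheduled parameters
emulating acute oxygen deprivation and its aftermath: the energy
recovery level ``E_bar`` collapses and is restored (hypoxia /
reoxygenation), while the activation probability ``p`` transiently
rises (glutamate release), is suppressed, and finally decays linearly
(excitotoxic degeneration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import child_seed, config_hash
from .meanfield import (
    MeanFieldOrbit,
    MeanFieldParams,
    _step_scalar,
    classify_asymptotic_regime,
    classify_orbit_outcomes,
    simulate_batch,
)

__all__ = [
    "PortraitSpec",
    "RegimeMap",
    "run_portrait",
    "HypoxiaProtocol",
    "HypoxiaResult",
    "run_hypoxia",
]


def _default_z_grid() -> tuple:
    # fine steps (0.1) on (0, 50] and (200, 300], coarse (5) on (50, 200]
    return tuple(
        np.round(
            np.concatenate(
                [
                    np.arange(0.1, 50.0 + 1e-9, 0.1),
                    np.arange(55.0, 200.0 + 1e-9, 5.0),
                    np.arange(200.1, 300.0 + 1e-9, 0.1),
                ]
            ),
            1,
        )
    )


@dataclass(frozen=True)
class PortraitSpec:
    """Grid specification for a parametric portrait at fixed ``r``.

    Full scale uses the dense grids (21 E_low points in [1, 3],
    piecewise z grid up to 300, 3e5-step orbits from 5 random initial
    conditions); :meth:`reduced` gives a 10 x 10 preset that runs in
    minutes while preserving the band ordering along ``z``.
    """

    r: float = 10.0
    e_low_grid: tuple = tuple(np.linspace(1.0, 3.0, 21))
    z_grid: tuple = field(default_factory=_default_z_grid)
    w: float = 1.5
    p: float = 0.1
    E_bar: float = 4.0
    eps: float = 0.05
    n_initial_conditions: int = 5
    steps: int = 300_000
    tail: int = 20_000
    seed: int = 0

    def __post_init__(self):
        for name, grid in (("e_low_grid", self.e_low_grid), ("z_grid", self.z_grid)):
            if len(grid) == 0 or np.any(np.diff(grid) <= 0):
                raise ValueError(f"{name} must be non-empty and increasing")
        if self.tail > self.steps:
            raise ValueError("tail cannot exceed steps")

    @classmethod
    def reduced(cls, r: float = 10.0, seed: int = 0) -> "PortraitSpec":
        """10 x 10 grid, 3e4-step orbits — the presentable desk-scale run.

        The z grid straddles the silent/active boundary z2 ~ 9.5 so the
        first transition can be located to within one grid step.
        """
        return cls(
            r=r,
            e_low_grid=tuple(np.linspace(1.0, 3.0, 10)),
            z_grid=(5.0, 8.0, 10.0, 11.0, 11.5, 12.0, 13.0, 15.0, 18.0, 20.0),
            steps=30_000,
            tail=10_000,
            seed=seed,
        )


@dataclass
class RegimeMap:
    """Regime label per (E_low, z) grid point, with provenance.

    ``labels[i, j]`` is the joint label at (e_low_grid[i], z_grid[j]);
    ``orbit_outcomes[i, j]`` keeps the tuple of per-initial-condition
    outcomes behind it, so coexisting behaviours remain visible where the
    joint label is ``multistable``.
    """

    e_low_grid: np.ndarray
    z_grid: np.ndarray
    labels: np.ndarray  # shape (n_e_low, n_z), dtype=object strings
    orbit_outcomes: np.ndarray  # same shape, tuples of per-orbit outcomes
    spec: PortraitSpec
    seed: int

    def label(self, e_low: float, z: float) -> str:
        i = int(np.argmin(np.abs(self.e_low_grid - e_low)))
        j = int(np.argmin(np.abs(self.z_grid - z)))
        return self.labels[i, j]

    def first_z_with(self, i: int, outcome: str) -> float | None:
        """Smallest z in row ``i`` where any orbit shows ``outcome``."""
        for j in range(len(self.z_grid)):
            if outcome in self.orbit_outcomes[i, j]:
                return float(self.z_grid[j])
        return None

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "e_low": el,
                "z": z,
                "label": self.labels[i, j],
                "orbit_outcomes": "|".join(self.orbit_outcomes[i, j]),
            }
            for i, el in enumerate(self.e_low_grid)
            for j, z in enumerate(self.z_grid)
        ]
        return pd.DataFrame(rows)

    def provenance(self) -> dict:
        return {"config_hash": config_hash(self.spec), "seed": self.seed}


def run_portrait(spec: PortraitSpec, done: RegimeMap | None = None) -> RegimeMap:
    """Classify the asymptotic regime at every (E_low, z) grid point.

    For each point, ``n_initial_conditions`` orbits start from uniform
    random states in (0, 1] x [0, E_bar] (q = 0 is excluded — it is
    absorbing) and are classified jointly.  Columns run one at a time so
    memory stays bounded; passing a partially filled ``done`` map (same
    spec) resumes where it stopped.
    """
    e_lows = np.asarray(spec.e_low_grid, dtype=float)
    zs = np.asarray(spec.z_grid, dtype=float)
    n_ic = spec.n_initial_conditions
    labels = np.full((len(e_lows), len(zs)), None, dtype=object)
    outcomes = np.full((len(e_lows), len(zs)), None, dtype=object)
    if done is not None:
        labels[:] = done.labels
        outcomes[:] = done.orbit_outcomes
    base = MeanFieldParams(
        p=spec.p, z=float(zs[0]), w=spec.w, E_low=float(e_lows[0]),
        E_bar=spec.E_bar, eps=spec.eps, r=spec.r,
    )
    for i, e_low in enumerate(e_lows):
        if all(lab is not None for lab in labels[i]):
            continue
        rng = np.random.default_rng(child_seed(spec.seed, "portrait", f"{i}"))
        # shape (n_z, n_ic): every z shares the column's initial conditions
        q0 = np.broadcast_to(rng.uniform(0.0, 1.0, n_ic), (len(zs), n_ic)).copy()
        q0 = np.nextafter(q0, 1.0)  # keep q0 strictly positive
        E0 = np.broadcast_to(rng.uniform(0.0, spec.E_bar, n_ic), (len(zs), n_ic)).copy()
        q_tail, E_tail = simulate_batch(
            p=spec.p, z=zs[:, None], w=spec.w, E_low=e_low, E_bar=spec.E_bar,
            eps=spec.eps, r=spec.r, q0=q0, E0=E0,
            T=spec.steps, keep_last=spec.tail,
        )
        for j in range(len(zs)):
            if labels[i, j] is not None:
                continue
            orbits = [
                MeanFieldOrbit(
                    q=q_tail[:, j, m], E=E_tail[:, j, m], params=base,
                    q0=float(q0[j, m]), E0=float(E0[j, m]),
                )
                for m in range(n_ic)
            ]
            labels[i, j] = classify_asymptotic_regime(orbits, tail=spec.tail)
            outcomes[i, j] = tuple(
                classify_orbit_outcomes(orbits, tail=spec.tail)
            )
    return RegimeMap(e_low_grid=e_lows, z_grid=zs, labels=labels,
                     orbit_outcomes=outcomes, spec=spec, seed=spec.seed)


# ---------------------------------------------------------------------------
# hypoxia / reoxygenation


@dataclass(frozen=True)
class HypoxiaProtocol:
    """Scheduled parameter changes emulating acute oxygen deprivation.

    Zones of the run:

    a. [0, t_hypoxia_on): normal operation (E_bar nominal, p nominal)
    b. [t_hypoxia_on, t_hypoxia_off): hypoxia — E_bar drops to
       ``E_bar_hypoxic``
    c. [t_hypoxia_off, t_suppression): reoxygenation — E_bar restored,
       p raised to ``p_glutamate`` (glutamate release)
    d. [t_suppression, t_ramp): glutamate-induced suppression,
       p = ``p_suppressed``
    e. [t_ramp, t_end): degeneration — p decays linearly to ``p_final``
    """

    r: float = 1.5
    z: float = 170.0
    eps: float = 0.05
    w: float = 1.5
    E_low: float = 2.0
    E_bar_nominal: float = 4.0
    E_bar_hypoxic: float = 0.4
    p_nominal: float = 0.1
    p_glutamate: float = 0.15
    p_suppressed: float = 0.07
    p_final: float = 0.01
    t_hypoxia_on: int = 1500
    t_hypoxia_off: int = 2500
    t_suppression: int = 2700
    t_ramp: int = 5000
    t_end: int = 8000
    q0: float = 0.5
    E0: float = 4.0

    def __post_init__(self):
        ts = (0, self.t_hypoxia_on, self.t_hypoxia_off, self.t_suppression,
              self.t_ramp, self.t_end)
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError(f"zone breakpoints must be strictly increasing: {ts}")
        for name, v in (("E_bar_nominal", self.E_bar_nominal),
                        ("E_bar_hypoxic", self.E_bar_hypoxic)):
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        for name, v in (("p_nominal", self.p_nominal),
                        ("p_glutamate", self.p_glutamate),
                        ("p_suppressed", self.p_suppressed),
                        ("p_final", self.p_final)):
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")

    def zones(self) -> list[tuple[str, int, int]]:
        return [
            ("a", 0, self.t_hypoxia_on),
            ("b", self.t_hypoxia_on, self.t_hypoxia_off),
            ("c", self.t_hypoxia_off, self.t_suppression),
            ("d", self.t_suppression, self.t_ramp),
            ("e", self.t_ramp, self.t_end),
        ]

    def schedules(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-step arrays (E_bar_t, p_t) of length ``t_end`` — the value
        in force when stepping from t to t + 1."""
        T = self.t_end
        E_bar_t = np.full(T, self.E_bar_nominal)
        E_bar_t[self.t_hypoxia_on : self.t_hypoxia_off] = self.E_bar_hypoxic
        p_t = np.full(T, self.p_nominal)
        p_t[self.t_hypoxia_off : self.t_suppression] = self.p_glutamate
        p_t[self.t_suppression : self.t_ramp] = self.p_suppressed
        ramp_len = T - self.t_ramp
        p_t[self.t_ramp :] = np.linspace(
            self.p_suppressed, self.p_final, ramp_len, endpoint=False
        )
        return E_bar_t, p_t


@dataclass
class HypoxiaResult:
    """Orbit aligned with the schedule that generated it."""

    t: np.ndarray
    q: np.ndarray
    E: np.ndarray
    E_bar_schedule: np.ndarray
    p_schedule: np.ndarray
    zones: list
    protocol: HypoxiaProtocol

    def zone_slice(self, name: str) -> slice:
        for label, t0, t1 in self.zones:
            if label == name:
                return slice(t0, t1)
        raise KeyError(f"no zone named {name!r}")

    def to_dataframe(self) -> pd.DataFrame:
        sched_E = np.append(self.E_bar_schedule, self.E_bar_schedule[-1])
        sched_p = np.append(self.p_schedule, self.p_schedule[-1])
        return pd.DataFrame(
            {"t": self.t, "q": self.q, "E": self.E,
             "E_bar": sched_E, "p": sched_p}
        )


def run_hypoxia(protocol: HypoxiaProtocol) -> HypoxiaResult:
    """Iterate the activity–energy map under the time-varying schedule.

    Deterministic; uses the same scalar arithmetic as
    :func:`neuroculture.meanfield.simulate`, so a constant schedule
    reproduces the plain simulation exactly.  Note the state may sit
    above the *current* ``E_bar`` right after the recovery level drops;
    it then relaxes toward the new level geometrically.
    """
    E_bar_t, p_t = protocol.schedules()
    T = protocol.t_end
    q = np.empty(T + 1)
    E = np.empty(T + 1)
    q[0], E[0] = protocol.q0, protocol.E0
    qt, Et = float(protocol.q0), float(protocol.E0)
    for t in range(T):
        qt, Et = _step_scalar(
            qt, Et, p_t[t], protocol.z, protocol.w, protocol.E_low,
            E_bar_t[t], protocol.eps, protocol.r,
        )
        q[t + 1], E[t + 1] = qt, Et
    return HypoxiaResult(
        t=np.arange(T + 1), q=q, E=E,
        E_bar_schedule=E_bar_t, p_schedule=p_t,
        zones=protocol.zones(), protocol=protocol,
    )
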