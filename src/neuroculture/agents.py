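"""Energy-gated stochastic spiking network and avalanche statistics.

Each of ``N`` nodes carries a binary activity ``q_i`` and an energy
``E_i`` in ``[0, E_bar]``.  At every synchronous step a node may fire
only if its energy strictly exceeds the cost of doing so,

    cost_i = r1 * outdeg_i / <N_out> + r2 * (active in-neighbours) / <N_in>,

which charges generation of the node's own spike (``r1`` term) and
transmission of the spikes arriving on its inputs (``r2`` term).  An
eligible node fires with a probability set by the energy-modulated
efficacy ``s_i = p * sigma(E_i)`` and the number ``k_i`` of currently
active in-neighbours.  Two firing rules are provided:

``corrected`` (default)
    ``P(fire) = 1 - (1 - s_i)**(1 + k_i)`` — independent chances from
    each active input plus one spontaneous chance, the per-node analogue
    of the mean-field activation ``1 - (1 - p*sigma)**(z q)``.
``as_printed``
    ``P(fire) = (1 - s_i)**(1 + k_i)`` — the literal complement.  This
    variant *decreases* with input drive and rises as energy falls, at
    odds with the mean-field form; it is kept runnable so the two
    conventions can be compared directly.

Firing nodes pay their cost and all energies relax toward the recovery
level ``E_bar`` at rate ``eps``.  Population activity forms avalanches —
maximal runs of nonzero total firing bounded by silent steps — whose
size and duration histograms follow power laws near criticality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .meanfield import sigma

__all__ = [
    "AgentNetworkParams",
    "AgentState",
    "AgentTrace",
    "Avalanche",
    "PowerLawFit",
    "AvalancheStatistics",
    "fire_cost",
    "fire_probability",
    "step_network",
    "simulate_network",
    "detect_avalanches",
    "avalanche_statistics",
    "fit_power_law",
    "sample_power_law",
    "load_adjacency",
]

FIRING_RULES = ("corrected", "as_printed")


@dataclass
class AgentNetworkParams:
    """Parameters of the spiking network.

    ``adjacency=None`` selects the fully connected topology
    ``c_ij = 1 - delta_ij``; otherwise a 0/1 matrix with empty diagonal.
    Defaults are the critical-regime operating point: slow energy
    recovery (``eps = 0.0025``) against transmission costs (``r2``) large
    enough that system-wide firing is unaffordable.
    """

    N: int = 625
    p: float = 0.01
    E_low: float = 2.0
    E_bar: float = 4.0
    w: float = 1.5
    eps: float = 0.0025
    r1: float = 1.1
    r2: float = 5.5
    firing_rule: str = "corrected"
    adjacency: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.firing_rule not in FIRING_RULES:
            raise ValueError(
                f"firing_rule must be one of {FIRING_RULES}, got {self.firing_rule!r}"
            )
        if self.adjacency is not None:
            C = np.asarray(self.adjacency)
            if C.shape != (self.N, self.N):
                raise ValueError(
                    f"adjacency shape {C.shape} does not match N={self.N}"
                )
            if np.any(np.diag(C) != 0):
                raise ValueError("adjacency must have an empty diagonal (c_ii = 0)")
            if not np.isin(C, (0, 1)).all():
                raise ValueError("adjacency entries must be 0 or 1")
            if C.sum() == 0:
                raise ValueError("adjacency must contain at least one link")
            self.adjacency = C.astype(np.int8)

    @property
    def mean_degree(self) -> float:
        """<N_in> = <N_out> = (sum of c_ij) / N."""
        if self.adjacency is None:
            return float(self.N - 1)
        return float(self.adjacency.sum()) / self.N

    def out_degrees(self) -> np.ndarray:
        if self.adjacency is None:
            return np.full(self.N, self.N - 1)
        return self.adjacency.sum(axis=1)

    def active_inputs(self, q: np.ndarray) -> np.ndarray:
        """Number of currently active in-neighbours of every node."""
        if self.adjacency is None:
            return q.sum() - q
        return self.adjacency.T @ q


@dataclass
class AgentState:
    """Per-node activities (0/1) and energies at one time step."""

    q: np.ndarray
    E: np.ndarray
    t: int = 0


@dataclass
class AgentTrace:
    """Output of a network simulation.

    ``activity[t]`` is the population firing count ``sum_i q_{i,t}`` for
    ``t = 0 .. T``; full per-node histories are stored only on request.
    """

    activity: np.ndarray
    params: AgentNetworkParams
    seed: int
    final_state: AgentState
    q_history: np.ndarray | None = None
    E_history: np.ndarray | None = None


@dataclass(frozen=True)
class Avalanche:
    """A zero-bounded interval of nonzero network firing."""

    t_start: int
    t_end: int
    size: int

    @property
    def duration(self) -> int:
        return self.t_end - self.t_start + 1


def _costs(q: np.ndarray, params: AgentNetworkParams) -> np.ndarray:
    k = params.active_inputs(q)
    return (
        params.r1 * params.out_degrees() / params.mean_degree
        + params.r2 * k / params.mean_degree
    )


def fire_cost(i: int, state: AgentState, params: AgentNetworkParams) -> float:
    """Energy a node must spend to fire now: generation cost weighted by
    its out-degree plus transmission cost per active input."""
    return float(_costs(state.q, params)[i])


def _fire_probs(q, E, params: AgentNetworkParams) -> np.ndarray:
    k = params.active_inputs(q)
    s = params.p * sigma(E, params.E_low, params.w)
    printed = (1.0 - s) ** (1.0 + k)
    if params.firing_rule == "as_printed":
        return printed
    return 1.0 - printed


def fire_probability(i: int, state: AgentState, params: AgentNetworkParams) -> float:
    """Probability that node ``i`` fires this step, given it can afford to."""
    return float(_fire_probs(state.q, state.E, params)[i])


def step_network(
    state: AgentState, params: AgentNetworkParams, rng: np.random.Generator
) -> AgentState:
    """One synchronous update of the whole network.

    Costs and firing probabilities are evaluated on the time-``t``
    activities; a node fires only if ``E_i > cost_i`` (strict), then
    ``q_i <- a_i`` and ``E_i <- (1-eps) E_i + eps E_bar - a_i cost_i``.
    """
    q, E = state.q, state.E
    costs = _costs(q, params)
    probs = _fire_probs(q, E, params)
    can_afford = E > costs
    fired = can_afford & (rng.random(params.N) < probs)
    a = fired.astype(np.int8)
    E_next = (1.0 - params.eps) * E + params.eps * params.E_bar
    E_next[fired] -= costs[fired]
    return AgentState(q=a, E=E_next, t=state.t + 1)


def simulate_network(
    params: AgentNetworkParams,
    T: int,
    E0_rule: str = "uniform",
    seed: int | None = None,
    record_states: bool = False,
) -> AgentTrace:
    """Simulate ``T`` steps from the standard initial condition.

    All nodes start silent; energies are drawn uniformly from
    ``[0.5 * E_low, E_bar]`` (``E0_rule="uniform"``) or start at
    ``E_bar`` (``E0_rule="full"``).  Only the population activity series
    is kept unless ``record_states`` is set.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    q = np.zeros(params.N, dtype=np.int8)
    if E0_rule == "uniform":
        E = rng.uniform(0.5 * params.E_low, params.E_bar, params.N)
    elif E0_rule == "full":
        E = np.full(params.N, float(params.E_bar))
    else:
        raise ValueError(f"unknown E0_rule {E0_rule!r}")
    state = AgentState(q=q, E=E, t=0)
    activity = np.empty(T + 1, dtype=np.int64)
    activity[0] = 0
    if record_states:
        q_hist = np.empty((T + 1, params.N), dtype=np.int8)
        E_hist = np.empty((T + 1, params.N))
        q_hist[0], E_hist[0] = state.q, state.E
    for t in range(1, T + 1):
        state = step_network(state, params, rng)
        activity[t] = int(state.q.sum())
        if record_states:
            q_hist[t], E_hist[t] = state.q, state.E
    return AgentTrace(
        activity=activity,
        params=params,
        seed=params.seed if seed is None else seed,
        final_state=state,
        q_history=q_hist if record_states else None,
        E_history=E_hist if record_states else None,
    )


def detect_avalanches(activity_series) -> list[Avalanche]:
    """Maximal zero-bounded runs of positive population activity.

    A run must be preceded and followed by a genuinely silent step, so
    runs touching either end of the series are discarded.
    """
    a = np.asarray(activity_series)
    if np.any(a < 0):
        raise ValueError("activity series must be non-negative")
    pos = a > 0
    if not pos.any():
        return []
    padded = np.concatenate([[False], pos, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    keep = (starts > 0) & (ends < len(a) - 1)  # need bounding zeros both sides
    csum = np.concatenate([[0], np.cumsum(a)])
    return [
        Avalanche(t_start=int(s), t_end=int(e), size=int(csum[e + 1] - csum[s]))
        for s, e in zip(starts[keep], ends[keep])
    ]


# ---------------------------------------------------------------------------
# power-law statistics


@dataclass
class PowerLawFit:
    """Log-binned histogram of a positive integer sample with a power-law
    exponent estimated two ways: least squares on (log centre, log
    density) and discrete maximum likelihood."""

    bin_edges: np.ndarray
    counts: np.ndarray
    density: np.ndarray
    exponent: float | None
    stderr: float | None
    r_squared: float | None
    mle_exponent: float | None
    fit_range: tuple


@dataclass
class AvalancheStatistics:
    size_fit: PowerLawFit
    duration_fit: PowerLawFit
    n_avalanches: int


def _log_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Geometric bin edges; for integer samples the edges snap to
    half-integers so every bin covers whole integers (raw geometric edges
    narrower than 1 produce sawtooth densities on discrete data)."""
    lo, hi = values.min(), values.max()
    if lo == hi:
        return np.array([lo * 0.999, hi * 1.001])
    if np.all(values == np.round(values)) and lo >= 1:
        ints = np.unique(np.floor(np.geomspace(lo, hi, n_bins + 1)).astype(int))
        return np.concatenate([[lo - 0.5], ints + 0.5])
    return np.geomspace(lo * 0.999, hi * 1.001, n_bins + 1)


def fit_power_law(values, n_bins: int = 30, fit_range=None, min_count: int = 50
                  ) -> PowerLawFit:
    """Fit ``P(x) ~ x**(-alpha)`` to a sample of positive integers.

    The histogram uses geometric bin edges spanning the sample; the
    least-squares exponent is the negative slope of the line through
    (log10 bin-centre, log10 probability-density) over non-empty bins in
    ``fit_range``; the MLE cross-check uses the continuous approximation
    ``alpha = 1 + n / sum(log(x / (xmin - 0.5)))``.  With fewer than
    ``min_count`` observations (or a degenerate sample) fitting is
    skipped with a warning and only the histogram is returned.
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0 or np.any(values <= 0):
        raise ValueError("need a non-empty sample of positive values")
    edges = _log_bins(values, n_bins)
    counts, _ = np.histogram(values, bins=edges)
    widths = np.diff(edges)
    density = counts / (widths * len(values))
    if fit_range is None:
        fit_range = (float(values.min()), float(values.max()))
    if len(values) < min_count or values.min() == values.max():
        warnings.warn(
            f"only {len(values)} value(s) spanning "
            f"[{values.min():g}, {values.max():g}]: exponent fit skipped",
            stacklevel=2,
        )
        return PowerLawFit(edges, counts, density, None, None, None, None,
                           tuple(fit_range))
    centers = np.sqrt(edges[:-1] * edges[1:])
    keep = (counts > 0) & (centers >= fit_range[0]) & (centers <= fit_range[1])
    if keep.sum() < 3:
        warnings.warn("fewer than 3 usable bins in fit range: fit skipped",
                      stacklevel=2)
        return PowerLawFit(edges, counts, density, None, None, None, None,
                           tuple(fit_range))
    res = stats.linregress(np.log10(centers[keep]), np.log10(density[keep]))
    in_range = values[(values >= fit_range[0]) & (values <= fit_range[1])]
    xmin = max(in_range.min(), 1.0)
    mle = 1.0 + len(in_range) / np.sum(np.log(in_range / (xmin - 0.5)))
    return PowerLawFit(
        bin_edges=edges,
        counts=counts,
        density=density,
        exponent=float(-res.slope),
        stderr=float(res.stderr),
        r_squared=float(res.rvalue**2),
        mle_exponent=float(mle),
        fit_range=tuple(fit_range),
    )


def avalanche_statistics(
    avalanches: list[Avalanche],
    n_bins: int = 30,
    fit_range_size=None,
    fit_range_duration=None,
) -> AvalancheStatistics:
    """Size and duration histograms with power-law exponent estimates."""
    if len(avalanches) == 0:
        raise ValueError("no avalanches to summarize")
    sizes = np.array([av.size for av in avalanches])
    durations = np.array([av.duration for av in avalanches])
    return AvalancheStatistics(
        size_fit=fit_power_law(sizes, n_bins, fit_range_size),
        duration_fit=fit_power_law(durations, n_bins, fit_range_duration),
        n_avalanches=len(avalanches),
    )


def sample_power_law(
    n: int, alpha: float, x_min: int, x_max: int, seed: int
) -> np.ndarray:
    """Draw ``n`` integers from ``P(s) ~ s**(-alpha)`` on [x_min, x_max]
    by inverting the discrete CDF — an oracle for exponent recovery."""
    support = np.arange(x_min, x_max + 1, dtype=float)
    pmf = support**-alpha
    pmf /= pmf.sum()
    rng = np.random.default_rng(seed)
    return rng.choice(support.astype(np.int64), size=n, p=pmf)


def load_adjacency(path) -> np.ndarray:
    """Read an adjacency matrix from a plain-text file.

    Accepts either a whitespace/comma-delimited square 0/1 matrix or an
    edge list (two 0-based integers per line, ``i j`` meaning i -> j; the
    node count is one past the largest index).
    """
    text = Path(path).read_text()
    rows = [
        [float(tok) for tok in line.replace(",", " ").split()]
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if not rows:
        raise ValueError(f"no data in adjacency file {path}")
    arr = np.asarray(rows)
    if arr.shape[0] == arr.shape[1] and arr.shape[0] > 2:
        return arr.astype(np.int8)
    if arr.shape[1] == 2:
        n = int(arr.max()) + 1
        C = np.zeros((n, n), dtype=np.int8)
        C[arr[:, 0].astype(int), arr[:, 1].astype(int)] = 1
        np.fill_diagonal(C, 0)
        return C
    raise ValueError(
        f"cannot interpret adjacency file {path}: neither square matrix nor edge list"
    )
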