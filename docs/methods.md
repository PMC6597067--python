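# Methods

This note records the models implemented in `neuroculture`, the
parameter conventions, the numerical choices, and what the simulations
do and do not say about real cultures.

## Geometric tier: continuum percolation of cell connectivity

Cells are points placed i.i.d. uniformly in the unit square; each cell
carries a dendrite circle of radius `R` around its soma ("tail") and an
axon of fixed length `H` in an isotropic random direction, ending in a
"head". All lengths are in unit-square units. Three coupling rules are
implemented: `circle` (tail–tail overlap within `2R`, axons ignored),
`dipole` (any head/tail pair of two cells within `2R`, undirected) and
`vector` (directed link i→j when the head of i lies within `2R` of the
tail of j). Overlap uses the closed inequality `dist <= 2R`; the
boundary set has measure zero.

The occupancy parameter is `B = pi * R**2 * n` with `n` the number of
cells per unit area — the expected number of cell centres inside one
dendrite circle. A configuration *spans* when one connected cluster
contains a cell whose tail- or head-circle touches the left edge
(`x <= R`) and one touching the right edge (`x >= 1 - R`). Choices made
here:

- **Open boundaries, left–right spanning.** No periodic wrap; wrapping
  would shift the estimated threshold.
- **Undirected reachability for the vector case.** Spanning clusters are
  defined geometrically for all three cases; the directed edge list is
  preserved so a strongly-connected variant can be added without
  re-simulating.
- **Fixed `N`, radius derived per density.** A sweep holds the cell
  count fixed and sets `R = sqrt(B / (pi * N))` (and `H = (H/R) * R`)
  at each grid density. This keeps one sample size — and hence one
  Monte-Carlo error scale — across the whole spanning curve, and it is
  the parametrization under which the package's threshold estimates are
  quoted (N = 3000 for the scalar case, N = 2000 for the axon-bearing
  cases).
- **Cells partially outside the square are kept** (no clipping),
  consistent with uniform sampling of centres.
- **Threshold estimator.** Spanning probability per grid density over
  seeded independent realizations (union-find connected components on
  the overlap graph); `B_c` is the linear interpolation of the first
  crossing of probability 1/2. With >= 15 realizations per point a
  logistic fit adds nothing at this precision. If the curve never
  brackets 1/2 the estimator raises instead of extrapolating.

Desk-scale results: the scalar threshold reproduces the classical
disk-percolation value `B_c ≈ 1.1` to within ±0.05 at N = 3000; all
dipole/vector thresholds at H/R in {1, 2, 4} fall well below 1.4 and
decrease with H/R (longer axons connect farther at equal occupancy).
Finite-size drift between N = 1000 and N = 3000 is below 0.15. No
thermodynamic-limit extrapolation is attempted.

## Mean-field tier: the activity–energy map

The 1-D excitation map `q -> 1 - (1-p)**(z*q)` assumes each neuron fires
with probability `p` per active neighbour, independently, with `z*q`
active neighbours on average. Its orbits are monotone; activity
persists exactly when `-z*log(1-p) > 1`, i.e. above the critical
connectivity `z1 = -1/log(1-p) ≈ 1/p`.

The 2-D extension modulates efficacy by an energy resource through
`sigma(E) = (tanh(w*E - E_) + 1)/2` and charges a cost `r*q` to the
energy balance when affordable. Parameter conventions (defaults used
throughout the equilibrium analysis in parentheses):

| parameter | meaning | default |
|---|---|---|
| `p` | maximal activation probability | 0.1 |
| `z` | mean coordination number | varied |
| `w` | sigmoid steepness, 1/energy | 1.5 |
| `E_low` (`E_`) | activation threshold; the sigmoid midpoint sits at `E = E_/w`, since the threshold enters the tanh argument unscaled | 2 |
| `E_bar` (`Ē`) | energy recovery level | 4 |
| `eps` (`ε`) | energy relaxation rate per step | 0.05 |
| `r` | energy cost of unit activation | 1, 1.5 or 10 |

- **Heaviside convention `H(0) = 1`:** the cost is paid on the branch
  `E >= r*q`. This is what makes the invariant-domain argument close
  (the energy update then satisfies `E' >= eps*(E_bar - E) >= 0`).
- **`tanh` overflow** is avoided by clamping the argument to ±40, far
  beyond where the sigmoid saturates at double precision.
- **Fixed points.** The silent point `(0, E_bar)` always exists with
  closed-form eigenvalues `(-z*log(1 - p*sigma(E_bar)), 1 - eps)`. Every
  nonzero equilibrium lies on the strictly increasing energy curve
  `E*(q*) = (atanh(2*s_req - 1) + E_)/w`,
  `s_req = (1/p)*(1 - (1-q*)**(1/(q* z)))`. The interior point is the
  unique crossing of this curve with the decreasing relaxation line
  `E = E_bar - r*q/eps` restricted to the affordable side `E >= r*q`;
  the saturated point solves `q = 1 - (1 - p*sigma(E_bar))**(q z)` with
  `r*q > E_bar` (possible only when `E_bar/r < 1`). Both are located by
  bisection on monotone scalar functions (no multistart root finding);
  residuals of the full fixed-point equations are verified to 1e-10.
  The critical connectivities `z2 = -1/log(1 - p*sigma(E_bar))` and
  `z3 = log(1 - E_bar/r) / ((E_bar/r)*log(1 - p*sigma(E_bar)))` mark
  where the nonzero branches appear.
- **Stability** of non-silent points uses a central-difference Jacobian
  (step 1e-7) of the smooth map restricted to the branch the point lies
  on (cost paid for interior, withheld for saturated); eigenvalues
  within 1e-8 of the unit circle are reported as nonhyperbolic. The
  interior branch's stability is asserted numerically, not analytically.

### Asymptotic-regime classification

Post-transient orbit tails (default: last 2e4 of 3e5 steps at full
scale; last 1e4 of 3e4 in the reduced preset) are labelled:

- **fixed-point** when the tail diameter is below 1e-6, split into
  silent / interior / saturated by the limit state;
- **periodic** when a lag `P <= 1000` recurs. Two criteria are applied
  in order: exact recurrence (shifting the tail by `P` matches to 1e-6),
  and a relative *shadowing* criterion — the shift mismatch stays below
  5% of the attractor diameter. The second criterion is what recognises
  the attracting invariant closed curve born at the Neimark–Sacker
  bifurcation: its rotation number is generally irrational, so exact
  recurrence never occurs, but near-returns shadow the whole curve with
  a small uniform offset. On chaotic sets a near-return at one point
  diverges elsewhere; measured mismatch ratios separate the two cases by
  roughly two orders of magnitude (< 0.5% on closed curves vs > 90% on
  chaotic tails), so the 5% threshold is not delicate;
- **complex** otherwise. The package deliberately labels these orbits
  "complex" rather than "chaotic": no Lyapunov-exponent certification is
  attempted.

Across several initial conditions (default 5, drawn uniformly from
(0, 1] × [0, E_bar]; q = 0 is excluded because the silent state is
absorbing), a grid point is `multistable` when outcomes disagree or
agree-but-with-separated limit sets (bounding boxes differing by more
than 0.05). The regime map stores the per-orbit outcomes alongside the
joint label, since coexistence of a chaotic-like set with the saturated
equilibrium is common at large `r` and would otherwise be invisible.

The reduced portrait preset (10 × 10 grid, 3e4-step orbits) places z
grid points at {5, 8, 10, 11, 11.5, 12, 13, 15, 18, 20} so that the
silent→active boundary near z2 ≈ 9.5 and the narrow periodic band above
it (which starts near z ≈ 11.5 at E_ = 1 and near 12.5 at E_ = 3 for
r = 10) are both resolved. At full scale the dense default grid (E_ on 21
points in [1, 3]; z steps of 0.1 on (0, 50] and (200, 300], 5 on
(50, 200]) is the default.

## Multi-agent tier: energy-gated spiking network

Each of `N` nodes carries binary activity and an energy in
`[0, E_bar]`. Per synchronous step, node i may fire only if
`E_i > cost_i` (strict inequality, unlike the mean-field gate which
pays at equality — the asymmetry is intentional and documented), with

```
cost_i = r1 * outdeg_i / <N_out> + r2 * k_i / <N_in>
```

where `k_i` counts currently active in-neighbours and
`<N_in> = <N_out>` is the mean degree. Defaults are the critical
operating point: `N = 625`, fully connected, `p = 0.01`, `E_ = 2`,
`E_bar = 4`, `w = 1.5`, `eps = 0.0025`, `r1 = 1.1`, `r2 = 5.5`; runs
start from all-silent activity with energies uniform on
`[0.5*E_, E_bar]`.

**Firing rules.** The default (`corrected`) firing probability is
`1 - (1 - p*sigma(E_i))**(1 + k_i)`: one independent activation chance
per active input plus one spontaneous chance, the per-node analogue of
the mean-field activation term. The complementary form
`(1 - p*sigma)**(1 + k_i)` is also runnable (`as_printed`); it decreases
with input drive and rises as energy falls, which contradicts the
mean-field construction, but it is kept selectable so the two
conventions can be compared rather than silently reconciled.

Costs and probabilities are evaluated on time-`t` activities and all
nodes update synchronously. At the default operating point a 1e5-step
run yields several thousand avalanches whose sizes span about three
decades; raising `eps` to 0.01 floods the network with system-size
events (energy recovers faster than the transmission cost can gate it),
the supercritical signature.

**Avalanches** are maximal runs of positive population activity bounded
by silent steps on both sides; runs touching either end of the series
are discarded because their bounding zero is unconfirmed.

**Exponent estimation.** Histograms use geometric bins; for
integer-valued samples the bin edges snap to half-integers so every bin
covers whole integers (raw geometric edges narrower than one unit
produce sawtooth densities on discrete data). The reported exponent is
the negative slope of the least-squares line through (log bin centre,
log density) over non-empty bins in the fit range, with a discrete
maximum-likelihood estimate `1 + n / sum(log(x/(xmin - 0.5)))` as a
cross-check. The estimator recovers a known exponent of 1.5 to within
±0.05 on 1e5 synthetic draws. On network output the scale-free range
ends in a hump of near-system-size events, so fits are quoted over an
explicit fit range (sizes 1–50 at the default operating point); no
reference numeric exponent is targeted.

## ASDR, burstiness and the development ensemble

`ASDR_t = (q_t - theta) * [q_t > theta]` with
`theta = median(q)/0.6745`, the robust noise-scale rule used by
multi-electrode spike detectors. The burstiness index partitions the
ASDR series into adjacent bins of `k = 30` steps, ranks bins by summed
activity (ties favour earlier bins, a deterministic and numerically
irrelevant choice), takes the fraction `f_m` of total activity in the
top `m = 50`% of bins, and reports `BI = (f_m - m/100)/(1 - m/100)`.
`m = 50` matches the typical ~10-step width of the model's activity
spikes. The median ASDR of an orbit segment is the median of
per-interval sums over non-overlapping 30-step intervals (a raw-sample
median is exposed as an option; the interval form is the default
because the tail length is an exact multiple of the interval, 1000 × 30
at full scale).

The ensemble draws `n_triples = 60` random (p, r, E_) triples — p
uniform on [0.10, 0.11], r on [1.5, 2], E_ on [2, 2.5] — each swept
over 86 equally spaced `z` in [10, 180], with 2e5-step orbits and
3e4-step analysis tails. The p interval deserves a note: it is a narrow
band around the baseline p = 0.1 used everywhere else, emulating
culture-to-culture variability in excitability without changing the
regime structure. The reduced preset (6 triples, 9 z values, 2e4-step
orbits, 3e3 tails) preserves the qualitative result: the z-averaged
median ASDR rises and then falls with connectivity, as culture-wide
firing does over days in vitro.

## Hypoxia / reoxygenation protocol

The mean-field map (r = 1.5, z = 170, eps = 0.05, w = 1.5, E_ = 2) is
driven by piecewise schedules: normal operation (E_bar = 4, p = 0.1)
for 1500 steps; hypoxia (E_bar = 0.4) for 1000 steps; reoxygenation at
t = 2500 with E_bar restored and p raised to 0.15 (glutamate release),
held until t = 2700 — the brief window between restoration and
suppression is not separately specified by the phenomenology, and the
surge is taken to precede suppression; suppression (p = 0.07) on
[2700, 5000); then p decreasing linearly (degeneration), by default to
0.01 at t = 8000 — the decline's endpoint and slope are free choices,
only its direction is constrained. The run is deterministic, uses the
same scalar arithmetic as the plain simulator (a constant schedule
reproduces it bit-for-bit), and returns the orbit with zone annotations
a–e aligned exactly with the schedule breakpoints. During hypoxia the
energy state relaxes from above toward the reduced E_bar; the domain
invariant `E <= E_bar` applies to the autonomous map, not mid-schedule.

## Problem sizes and determinism

All randomness flows from per-purpose seeds derived by hashing a root
seed with string keys (`child_seed`), keeping every derived seed below
2^31 and making every component independently reproducible. The package
quotes its results at desk scale: percolation at N = 2000–3000 with
15–20 realizations per density, portraits on 10 × 10 grids with
3e4-step orbits, network runs of 1e5 steps, and the 1/10-scale
ensemble. These sizes give Monte-Carlo errors comfortably inside the
stated tolerances (e.g. ±0.03 spread of B_c across seeds at N = 3000).

## What the simulations do not show

All inputs are model-generated; no multi-electrode recordings are read
or fitted. Agreement of ASDR/BI trends with cultured-network
development is therefore qualitative: the model has no spatial
electrode geometry, no inhibition (excluded by scope — adding a
fraction of inhibitory links is reported not to change the dynamics
qualitatively), no synaptic weights or plasticity, and a single global
energy pool per node rather than metabolic detail. The mean-field tier
ignores spatial structure entirely; the multi-agent default topology is
fully connected, so its criticality is maintained by energy balance,
not by connectivity sparseness. Regime maps are classified
algorithmically; individual boundary cells can differ from a visual
classification of the same orbits, and conclusions should rest on the
band structure, not per-cell labels.
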