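# neuroculture

Models of how spontaneous activity develops in dissociated neuronal
cultures, for computational neuroscientists studying network bursts,
neuronal avalanches and self-organized criticality.

Cultured neurons grow connections over days in vitro and, once
connectivity passes a critical level, begin to produce population
bursts whose sizes follow power laws. `neuroculture` implements a
three-tier model hierarchy of this development:

1. **Geometric tier** (`neuroculture.percolation`) — neurons as randomly
   placed cells in the unit square, each with a circular dendrite region
   of radius *R* and an axon of length *H*. Connectivity arises from
   circle overlaps (no axons), head/tail dipole overlaps (bidirectional
   axons) or directed head-to-dendrite contacts. The control parameter is
   the mean occupancy *B* = π*R*²*n*; Monte-Carlo sweeps locate the
   threshold *B*_c at which a cluster first spans the square.

2. **Mean-field tier** (`neuroculture.meanfield`) — the population
   fraction of active neurons *q*_t coupled to a phenomenological energy
   resource *E*_t:

   ```
   q_{t+1} = 1 − (1 − p·σ(E_t))^{z·q_t}
   E_{t+1} = (1 − ε)·E_t + ε·Ē − r·q_t·H(E_t − r·q_t)
   σ(E)    = (tanh(w·E − E_) + 1) / 2
   ```

   Here *z* is the mean coordination number (connectivity), *p* the
   maximal activation probability, *r* the energy cost of activity, Ē
   the recovery level and ε the relaxation rate. The module provides the
   map itself, closed-form critical connectivities (z̄₁, z̄₂, z̄₃), fixed
   points on all three equilibrium branches with stability from the
   Jacobian eigenvalues, and an asymptotic-regime classifier
   (silent / interior equilibrium / saturated / periodic / complex /
   multistable). Increasing *z* drives the map from silence through a
   stable active equilibrium and a Neimark–Sacker bifurcation into
   periodic and then chaotic-like bursting — the model's account of
   culture maturation.

3. **Multi-agent tier** (`neuroculture.agents`) — *N* spiking nodes with
   per-node binary activity and energy. A node fires only if its energy
   strictly exceeds the cost of generating and receiving spikes;
   avalanches are zero-bounded runs of population firing, summarized by
   log-binned size/duration histograms with least-squares and
   maximum-likelihood power-law exponents.

Around these sit `neuroculture.metrics` (array-wide spike detection
rate, burstiness index, and the simulated-culture ensemble that tracks
both against *z*) and `neuroculture.scenarios` (parametric regime
portraits over (E_, *z*) and a scheduled hypoxia/reoxygenation
protocol).

## Worked example

Equilibria of the activity–energy map at *p* = 0.1, *w* = 1.5, *E*_ = 2,
Ē = 4, ε = 0.05, *r* = 10 and connectivity *z* = 25:

```
$ neuroculture meanfield fixed-points --z 25
[
  {"q_star": 0.0,      "E_star": 4.0,   "branch": "silent",    ... "stability": "repeller"},
  {"q_star": 0.014045, "E_star": 1.191, "branch": "interior",  ... "stability": "repeller"},
  {"q_star": 0.908589, "E_star": 4.0,   "branch": "saturated", ... "stability": "attractor"}
]
```

At this connectivity the silent state (0, Ē) is unstable (its leading
eigenvalue −z·log(1 − p·σ(Ē)) ≈ 2.63 exceeds 1), the interior balance
point has lost stability through a Neimark–Sacker bifurcation (complex
eigenvalues 0.971 ± 0.508i, modulus ≈ 1.10), and the network is drawn to
the saturated state where ~91% of neurons fire while the energy cost of
full activity (r·q* ≈ 9.1) exceeds what recovery can supply.

A desk-scale percolation sweep and a spiking-network run:

```
$ neuroculture percolation --case circle --n-cells 1000 --realizations 10 --seed 1 --out curve.csv
B_c_hat = 1.1250 (circle, H/R=0.0)

$ neuroculture agents run --n 625 --steps 20000 --seed 11
725 avalanches in 20000 steps
```

The estimated spanning threshold sits near the classical disk-percolation
value *B*_c ≈ 1.1, and the spiking network at its default operating point
(p = 0.01, ε = 0.0025, r₁ = 1.1, r₂ = 5.5) produces intermittent
avalanches separated by silent steps rather than saturating.

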