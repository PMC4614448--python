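# mhvg — multiplex horizontal visibility graphs

`mhvg` analyses multivariate time series by mapping them to multilayer
networks.  Each channel `x[α](t)` of an M-dimensional signal becomes a
**horizontal visibility graph** (HVG): nodes are the N time points and
`(i, j)` is an edge iff every intermediate datum satisfies
`x(k) < min(x(i), x(j))`.  The M HVGs, sharing the time-point node
set, form a **multiplex visibility graph**, and the structure shared
across layers quantifies the coherence of the underlying dynamics with
no phase-space partitioning, symbolization or stationarity assumptions:

* **average edge overlap** `ω ∈ [1/M, 1]` — the mean fraction of
  layers an edge of the union edge set appears in
  (`ω = Σ_{i<j} Σ_α a_ij^[α] / (M Σ_{i<j} 1{Σ_α a_ij^[α] > 0})`);
  `M·ω` is the expected number of layers per edge;
* **interlayer degree mutual information**
  `I_αβ = Σ P(k^[α],k^[β]) log [P(k^[α],k^[β]) / (P(k^[α]) P(k^[β]))]`
  between the degree sequences of two layers, and its pair average `I`;
* the **graph of layers** — the weighted complete graph on the M
  layers with weights `I_αβ`, a visibility analogue of a functional
  network — with backbone and maximum-spanning-tree summaries;
* **windowed (temporal) profiles** of all of the above for long
  nonstationary records, the structure used to scan multichannel data
  (e.g. asset prices, physiological recordings) for epochs of elevated
  synchronisation.

A coupled-map-lattice (CML) simulator — a ring of diffusively coupled
fully chaotic logistic maps `f(x) = 4x(1−x)`, plus a globally coupled
mean-field variant — provides ground-truthed multivariate test
signals whose dynamical phases (turbulence, pattern selection,
intermittency, synchronisation) the metrics are known to resolve.  A
fixed-partition symbolic mutual-information baseline (`I^SYMB`) is
included for comparison.

Intended users: researchers in nonlinear time-series analysis, network
physiology, econophysics and systems biology who want functional-
network-style summaries of multichannel signals without symbolization.

## Worked example

```python
from mhvg import (CMLParams, simulate_cml, build_multiplex,
                  average_edge_overlap, mean_interlayer_mutual_information,
                  graph_of_layers, maximum_spanning_tree, hub_fraction)

for eps in (0.05, 0.17):
    params = CMLParams(n_sites=5, epsilon=eps, n_steps=2**14, seed=42)
    mux = build_multiplex(simulate_cml(params))
    omega = average_edge_overlap(mux)
    mi = mean_interlayer_mutual_information(mux)
    mst = maximum_spanning_tree(graph_of_layers(mux))
    print(f"eps={eps:.2f}  omega={omega:.3f}  I={mi:.3f}  "
          f"MST edges={sorted(mst.edges())}  hub={hub_fraction(mst):.2f}")
```

prints

```
eps=0.05  omega=0.451  I=0.022  MST edges=[(0, 1), (0, 4), (1, 2), (3, 4)]  hub=0.50
eps=0.17  omega=0.500  I=0.798  MST edges=[(0, 2), (0, 4), (1, 4), (2, 3)]  hub=0.50
```

At weak coupling (ε = 0.05, fully developed turbulence) the five maps
evolve almost independently: the layers share little degree structure
(I ≈ 0.02 nats) and the overlap sits near its incoherent baseline.  At
ε = 0.17 the lattice selects a periodic pattern and the shared
structure jumps by more than an order of magnitude in I, with ω rising
as well — the multiplex metrics act as an order parameter for the
dynamical phase.  (Exact MST edges vary with the realization; the I
contrast does not.)

The same pipeline is available from the shell:

```sh
mhvg simulate-cml --m 5 --eps 0.17 --n 16384 --seed 42 --out cml.csv
mhvg multiplex --in cml.csv            # omega, I, full I_ab matrix
mhvg layers --in cml.csv               # graph of layers, backbone, MST
mhvg windows --in cml.csv --window 1024
mhvg symbolic-mi --in cml.csv --p 2 --range 0,1
```

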