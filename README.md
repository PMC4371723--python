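# grnrestore

Restoration of gene regulatory networks (GRNs) from time-course
expression data by nonlinear data assimilation.

Biologists and network-inference tool builders often start from an
*original* network — assembled from the literature or inferred by a
method such as a graphical Gaussian model or a dynamic Bayesian
network — that is only approximately right for the data at hand.
`grnrestore` treats that network as the starting point of a model
search: it fits a nonlinear state-space model of transcription to the
time-course data and greedily adds, deletes and replaces regulatory
elements until the Bayesian information criterion (BIC) stops
improving, returning a restored network, fitted kinetic parameters and
a full decision log.

## Model

Gene abundances x_t ∈ R^p evolve by a combinatorial transcription
model — a first-order difference equation with linear effects and
pairwise (synergistic) product effects between regulators:

    x_{i,t+1} = (1 + a_ii) x_{i,t} + Σ_{j∈A_i} a_ij x_{j,t}
                + Σ_{(j,k)∈B_i} b_{i,(j,k)} x_{j,t} x_{k,t}
                + Σ_{m∈G_i} g_im d_{m,t} + u_i + v_{i,t}

    y_t = x_t + w_t,   v_t ~ N(0, Q),  w_t ~ N(0, R)  (Q, R diagonal)

where A_i, B_i, G_i are the active regulator / pair / exogenous-input
sets of gene i (d_t can carry e.g. a drug concentration), and the edge
set {j → i : j ∈ A_i} is the network being restored.

The quadratic terms make the state conditionals non-Gaussian, so the
likelihood and the EM-algorithm's smoothed expectations are computed
with a **higher-moment ensemble particle filter (HMEnPF)**: at every
observed time a particle-filter step, an ensemble-Kalman-filter step
and a moment-matching merge produce an ensemble that carries the
particle filter's first four elementwise moments while preserving the
EnKF ensemble's particle pairing — the particle count is never reduced,
and the retained third/fourth moments feed directly into the EM
statistics. A deterministic unscented Kalman filter (UKF) over the same
model serves as the cheap screening evaluator: candidate edits are
pre-screened by residual heuristics, the top r1 per row are scored by
UKF-based EM, the top r2 overall by HMEnPF-based EM, and a move is
accepted only if it strictly lowers the BIC

    BIC = −2 log L + k log(n),

with k the number of free coefficients of the structure.

## Worked example

Fitting the model to five simulated 30-point series from a known
5-gene network (`python examples/fit_parameters.py`):

```
EM iterations: 200, converged: False
final log-likelihood: -666.00, BIC: 1543.84
    edge    true  fitted
   2->1    -0.095  -0.100
   3->2    -0.538  -0.593
   4->2    -0.565  -0.515
   1->3     0.617   0.614
   5->4    -0.650  -0.539
   1->5     0.278   0.254
   3->5     0.178   0.174
RMSE of active linear coefficients: 0.051
```

Each row compares a generating coefficient a_ij with its EM estimate;
at system-noise variance 0.01 and observation-noise variance 0.3 the
active coefficients come back with errors around 0.05–0.1. The other
examples cover benchmark simulation (`simulate_benchmark.py`), the
ensemble filter and its moment summaries (`filter_and_smooth.py`), and
end-to-end restoration of a corrupted network (`restore_network.py`).

A thin command line mirrors the library:

```
grnrestore simulate --network truth.tsv --out sim/ --seed 1
grnrestore fit --expr sim/expr_series1.tsv --network truth.tsv --out fit.json
grnrestore restore --expr expr.tsv --network original.tsv --out outdir --seed 1
grnrestore evaluate --inferred restored.tsv --truth truth.tsv --genes 10
grnrestore benchmark --network wnt5a --noise 0.01 --out bench/ --seed 1
```

Networks are edge-list TSVs (`regulator  target  kind  partner  locked`),
expression matrices are genes-by-timepoints TSVs with `t<k>[_rep<j>]`
columns, and fitted models are serialized as JSON.

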