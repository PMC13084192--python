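# Methods

## Network construction

Each subject's input is a regions × time matrix of preprocessed BOLD
signals (band-pass filtering, nuisance regression etc. are assumed already
applied; this package starts at the time-series stage). Functional
connectivity is the Pearson correlation over all time points — no
windowing. Negative correlations have no agreed biological interpretation
in this framework and are zeroed, as is the diagonal; the remaining
weights are Fisher-transformed (`z = artanh r`, entries clipped at
`1 − 1e−7` so duplicated signals cannot produce infinities).

Binarisation retains the `K = ⌊s·N(N−1)/2⌋` strongest connections at
sparsity `s`. Flooring guarantees the retained fraction never exceeds `s`;
ties at the `K`-th weight are broken by (descending weight, ascending row,
ascending column), so results are bit-reproducible. Because thresholding
depends only on the weight ranking, binarising raw `r` or Fisher-`z`
weights yields identical networks — asserted by test rather than assumed.
The pipeline evaluates `s ∈ {0.2, 0.3, 0.4}` with 0.3 primary.

## Graph metrics and their conventions

Distances are unweighted hop counts (breadth-first search). Where the
defining formulas leave degenerate cases open, the conventions are:

* **Characteristic path length** averages over *connected* ordered pairs
  only (`l = ∞` for disconnected pairs would otherwise dominate); the
  connected-pair fraction is reported next to `L` so the choice is
  visible. At the sparsities used, networks are almost always connected.
* **Global efficiency** averages `1/l` over all ordered pairs with
  `1/∞ = 0`; an empty network scores 0.
* **Betweenness** sums `σ_YZ(X)/σ_YZ` over unordered pairs, endpoints
  excluded, unnormalised. An ordered-pair convention is exactly double
  and cancels in the hub-disruption slope (tested).
* **Clustering** `C_X` and **local efficiency** `E_loc(X)` are 0 for nodes
  of degree < 2, where their denominators vanish. The network mean `C`
  includes zero-degree nodes.
* **Local efficiency** measures distances inside the subgraph induced on
  `X`'s neighbours with `X` removed, averaged over ordered neighbour
  pairs.

Geodesic counting uses breadth-first predecessor accumulation (Brandes'
algorithm via networkx); the test suite re-derives every metric with an
independent Floyd–Warshall / dynamic-programming / exhaustive-enumeration
evaluator and requires agreement to 1e−12 relative error on hundreds of
random graphs.

## Hub disruption index

For one nodal metric, subject `i`'s index `k` is the OLS slope of
`y = m_i − m̄_NC` on `x = m̄_NC` across all regions (no outlier trimming),
where `m̄_NC` is the control group's per-region mean profile. `k ≈ 0`
means the subject's profile parallels the control profile; `k < 0` means
high-profile regions (hubs) lost value while low-profile regions gained —
reorganisation without necessarily any global shift, which the intercept
absorbs.

Two deliberate choices:

* **Intercept included** (default). A through-origin fit would conflate a
  uniform metric offset with hub reorganisation. `include_intercept=False`
  (CLI `--no-intercept`) exposes the alternative.
* **Control subjects are scored against the full-group mean including
  themselves** (default). This gives the exact identity mean(k over
  controls) = 0, because the slope is linear in `y` and the per-region
  differences sum to zero across the group — a useful built-in
  calibration. `leave_one_out=True` (CLI `--loo`) scores each control
  against the other controls' mean; the identity then no longer holds.

`k` is computed per sparsity; no averaging across sparsities.

## Statistics

Each quantity (global metric or `k`) is compared between groups after a
Shapiro–Wilk normality screen at α = 0.05 on both samples: both normal →
independent-samples t-test (Welch by default; `pooled_t=True` for
Student's), otherwise two-sided Mann–Whitney U (exact for small untied
samples, normal approximation with tie correction otherwise). The report
records the route and the normality p-values that drove it. Significance
is flagged at p < 0.05 and p < 0.01. No multiple-testing correction is
applied by default across the 21 comparisons; `fdr=True` appends
Benjamini–Hochberg q-values.

Abnormal regions are ranked by the signed difference of group-level mean
nodal metrics (patient − control); no significance threshold is imposed —
the output is a ranking with the top-`top_k` (default 4) elevated and
reduced regions flagged, ties broken by region order.

## Synthetic cohort generator

The generator emulates the *output* of fMRI preprocessing: per-subject
multivariate normal time series drawn from group-level target correlation
matrices. Defaults mirror a typical resting-state study: 90 atlas
regions, 187 retained time points, 45 subjects per group.

The control target has baseline correlation `base_strength` everywhere
and `hub_strength` on every pair incident to a designated hub set. The
patient target multiplies the hub excess by `(1 − δ)` and redistributes
the removed mass uniformly over non-hub pairs, so mean connectivity
matches between groups *before* the positive-semidefinite repair: the
hub-disruption signal is reorganisation, not global strength.

Parameter defaults where no external anchor exists, chosen once as
plausible for resting-state functional connectivity:

| parameter | default | rationale |
|---|---|---|
| `n_hubs` | 12 (of 90) | ≈13% hub fraction, typical of cortical hub sets |
| `hub_strength` | 0.55 | strong but sub-unity hub coupling |
| `base_strength` | 0.15 | weak background coupling |
| `subject_noise_sd` | 0.04 | between-subject SD on r entries; no empirical anchor exists, free simulation parameter |

Tests and the acceptance script run a reduced scale (20 regions, 4 hubs,
20 + 20 subjects, 200 time points, 20 replicates), which keeps the full
replicated pipeline under a minute while preserving the qualitative
regime.

### Numerical notes

* **PSD repair.** The entry-wise hub/baseline construction is *not*
  positive semidefinite for any meaningful hub excess (two peripheral
  regions cannot each correlate 0.55 with every hub yet only 0.15 with
  each other). Negative eigenvalues are clipped to 1e−8, the matrix
  reconstructed and renormalised to unit diagonal; the maximum entry
  distortion is logged. Post-repair, group mean connectivity matches only
  approximately (difference ≈ 0.03 at the test scale).
* **Subject heterogeneity** is additive symmetric Gaussian jitter on the
  correlation entries followed by PSD repair — a direct handle on the
  between-subject SD, in contrast to a Wishart draw whose spread is tied
  to its degrees of freedom.
* **Sampling** uses an eigendecomposition square root of the repaired
  correlation matrix and a per-subject `SeedSequence`-spawned generator:
  cohorts are bit-for-bit reproducible from the master seed.

### What the generator does and does not show

Time points are i.i.d.: there is no hemodynamic response, no temporal
autocorrelation, no scanner drift, no motion artifact, and no negative
functional coupling. Passing recovery tests therefore demonstrates that
the pipeline detects covariance-level hub flattening under Gaussian
assumptions — not that it is robust to fMRI noise processes, which are
removed upstream by preprocessing in real studies.

### Known limitations

* **Monotonicity in δ holds for degree and betweenness, not local
  efficiency.** In dense binary networks, local efficiency
  *anti*-correlates with degree (hub neighbourhoods are larger and hence
  sparser; measured r ≈ −0.86 at sparsity 0.3), so hubs sit at the *low*
  end of the local-efficiency profile. Flattening hubs then raises the
  low-abscissa end and the patient mean `k_loc` is not a monotone
  function of δ under this generator. Recovery guarantees are therefore
  stated for the degree and betweenness indices.
* **Attenuation bias at δ = 0.** The regression abscissa is the
  finite-sample control mean, which carries sampling noise that also
  enters `−y`; for metrics with a narrow between-region spread (local
  efficiency, clustering) this biases the null mean `k` slightly
  negative. It shrinks as the control group grows and does not affect
  the degree/betweenness null behaviour at the tested scale.
* **Mild anticonservatism of the null k comparison.** Under the default
  convention, control subjects' k values are fitted against a profile
  that includes themselves, which shrinks them toward zero relative to
  the independently scored patient k values; the resulting variance
  mismatch inflates the two-group test's null rejection rate to roughly
  0.12 at α = 0.05 (measured over 100 null replicates at the test
  scale). The leave-one-out option restores the nominal level (measured
  ≈ 0.02–0.05) at the cost of the exact zero-mean identity. The default
  mirrors the plain group-mean reference; switch to `leave_one_out=True`
  when calibrated type-I control matters more than the identity.
* With fewer time points than regions, per-subject sample correlation
  matrices are rank-deficient (logged, not an error); the default 187
  time points for 90 regions is above that line but estimation noise in
  the correlations remains substantial, as in real data.
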