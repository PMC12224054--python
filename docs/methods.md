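# Methods

`gradspike` implements an unsupervised spike-sorting pipeline built around a
simple idea: the temporal derivatives of a spike waveform carry shape
information that raw amplitudes hide, especially when units are strongly
correlated. The pipeline differentiates each snippet, embeds the result in a
low-dimensional space nonlinearly, clusters agglomeratively, and lets the
silhouette score choose every free parameter. The spectral-embedding variant
is called GSA; the UMAP variant GUA.

## Gradient preprocessing

The n-th temporal gradient of a waveform is n repeated applications of the
first-order central difference

    f'(x_i) = (f(x_{i+1}) - f(x_{i-1})) / (2h) + O(h^2),

applied row-wise to the `n_spikes x n_samples` matrix. The step `h` is fixed
at one sample: rescaling `h` multiplies every feature by a constant, which
distance-based embeddings absorb only if their own scales move too, so a
fixed `h` keeps runs comparable. Boundaries default to first-order one-sided
differences (length-preserving); `replicate` and `trim` policies exist.
The operator is linear, shift-equivariant and exact for polynomials of
degree <= 2 on interior points; n applications equal one convolution with
the n-fold self-convolution of `[-1/2h, 0, 1/2h]`, which the tests use as an
oracle. Differentiation reweights the spectrum toward high frequencies:
beyond roughly the fourth order the slow shape differences that distinguish
smooth units are destroyed, which is why the default search stops at order
10 and the selection procedure (below) has to be robust against
over-differentiated orders.

## Spectral embedding (GSA)

An affinity graph is built over spikes — by default a binary exact-kNN graph
symmetrized by union, with `k_nn = max(n/10, 2)` doubled until the graph is
connected (an explicitly requested `k_nn` that leaves the graph disconnected
raises instead of silently bridging). A Gaussian kernel
`s_ij = exp(-||x_i - x_j||^2 / 2 sigma^2)` is available as an alternative,
with `sigma` defaulting to the median pairwise distance. The unnormalized
Laplacian `L = D - S` (D = diagonal of row sums) is decomposed densely; the
embedding consists of the eigenvectors of the smallest nonzero eigenvalues,
ordered by eigenvalue and sign-fixed (largest-|entry| positive) for
reproducibility. A symmetric-normalized Laplacian is offered as an option.
Degenerate (repeated) eigenvalues keep solver order; no re-orthogonalization
heuristics are applied.

Inside the sorter, the spectral subspace grows with the candidate cluster
count: a k-cluster cut is scored on the first `max(2, k-1)` nontrivial
eigenvectors, the classic spectral-clustering prescription — two
eigenvectors cannot separate more than about three groups. The floor of two
dimensions keeps silhouettes comparable across candidates (1-D silhouettes
are systematically inflated); its price is that the spectral arm cannot
prefer k=2 over splitting one of two clean blobs, so it tends to overcount
very small unit counts. The UMAP arm does not share this bias and is the
one used for cluster-count prediction checks.

## UMAP embedding (GUA)

The fuzzy graph is built from exact Euclidean kNN (no approximate index;
ties break toward lower index). For each point, `rho_i` is its
nearest-neighbor distance and `sigma_i` solves

    sum_j exp(-max(0, d_ij - rho_i) / sigma_i) = log2(k)

by bisection on [1e-6, 1e3] to 1e-5 or 100 iterations; points where the
target is unattainable (e.g. all neighbors exactly at `rho_i`) are flagged
and fall back to the nearest achievable end. Membership strengths
`w_ij = exp(-max(0, d_ij - rho_i)/sigma_i)` are symmetrized by the fuzzy
union `p_ij = w_ij + w_ji - w_ij w_ji`. An optional row normalization of
`w` before symmetrization is off by default: it shrinks every `p_ij` to
about `1/k`, starving the attraction term of the optimizer and blurring
cluster structure (measured as a collapse of silhouette-driven selection).

The layout minimizes the fuzzy cross-entropy

    C = sum_{i != j} [ p log(p/q) + (1-p) log((1-p)/(1-q)) ],
    q_ij = (1 + ||y_i - y_j||^2)^{-1}

with the low-dimensional kernel fixed at `a = b = 1` (`min_dist` is
accepted for interface compatibility but inert). Two optimizers exist:

* **Full-pairs gradient** (`negative_samples=0`): the deterministic update
  `y_i <- y_i - eta * 4 sum_j (p_ij - q_ij)(y_i - y_j) q_ij`. It is exactly
  permutation-equivariant and descends the loss at small learning rates,
  but its repulsive term vanishes for coincident points (the force is
  `-q^2 r -> 0` as `r -> 0`), so clusters that the 2-D initialization
  overlaps can never untangle. It is the right tool for small or
  well-spread problems and for the stationary-point and descent property
  tests.
* **Stochastic per-edge optimizer** (default, `negative_samples=5`): per
  epoch every positive edge fires with probability `p_ij / max(p)`; a fired
  edge pulls both endpoints with the exact attractive term (coefficient
  `2q`) and pushes `negative_samples` uniformly drawn points away from its
  head with the exact regularized repulsive term `2q/(eps + r^2)`,
  `eps = 1e-3`, updates clipped at 4 for stability. The `1/r^2` growth of
  the exact repulsion at small distances is what separates overlapping
  clusters; this is the standard UMAP optimization scheme and it matches
  the reference implementation's behavior on our benchmarks (within a few
  accuracy points on identical features).

Initialization is PCA by default (deterministic SVD with a sign
convention), rescaled to a layout standard deviation of 10; random
Gaussian init at the same scale is available. Starting much smaller puts
every `q` near 1 and the first repulsion step explodes the layout. The
learning rate decays linearly from 1.0 to 0 over `n_epochs` (default 500).
`n_neighbors` defaults to 150, the middle of the 100-200 range effective
for spike data, clamped to `n//2` with a warning on small inputs. Given a
seed the whole embedding is bit-reproducible on one platform.

## Clustering and model selection

Clustering is bottom-up agglomerative (scipy's linkage machinery) with
Ward/Euclidean by default; single, complete and average linkage are
options. The silhouette `s(i) = (b - a)/max(a, b)` is computed brute-force
on the embedded points, with singleton clusters contributing 0; it agrees
with scikit-learn to 1e-10.

The sorter scans gradient orders (default 0-10, up to 90 behind a flag),
cluster counts (default 2-20) and a small neighbor-count sweep
({15, 50, 150} for UMAP; {15, 50, auto} for spectral), and selects in three
marginalized stages:

1. **Order**: highest silhouette averaged over every (hyperparameter, k)
   cell, with failed or degenerate cells counting 0. Averaging over the k
   scan identifies an informative order: an over-differentiated order
   collapses smooth units into one tight blob that scores spectacularly at
   one (wrong) k and poorly or not at all elsewhere, whereas an informative
   order scores well across the scan.
2. **Cluster count**: highest silhouette averaged across the
   hyperparameter sweep at the chosen order (averaging across the sweep
   smooths out razor-thin single-cell ties).
3. **Hyperparameter**: argmax at the chosen (order, k).

Ties always break toward lower order, lower k, lower hyperparameter.
Candidate cuts containing a cluster smaller than `min_cluster_size`
(default 2) are excluded: a singleton cluster is no neuron, yet one outlier
split off into its own cluster drives everyone else's silhouette toward 1
and would hijack the argmax. Grid cells that fail (disconnected graphs,
degenerate cuts) are recorded and skipped rather than aborting the search.
The final labels come from re-embedding and re-clustering at the selected
cell, so a `SortResult` is reproducible from its seed and selection alone.

Silhouette-guided selection is genuinely imperfect: when two units are more
similar to each other than to a third, merging them can out-score the
correct partition in any embedding, and an over-differentiated order can
still slip through the averaging. These failure modes are intrinsic to the
criterion, not to its implementation; the limitations section below
quantifies them.

## Detection and waveform extraction

Per-channel thresholds are `multiplier x sigma` with `sigma` the plain
standard deviation (a MAD-based robust option exists, off by default).
Detection is negative-polarity by default: somatic extracellular spikes are
negative-dominant, and absolute-value thresholding re-triggers on the
positive after-wave of large spikes about 1 ms after the trough, inflating
false positives; `both` and `pos` are flags. One event is emitted per
supra-threshold excursion at its extreme sample. Events closer in time than
the refractory window (default 1 ms) are merged keeping the larger
amplitude; when channel positions are known the merge is restricted to
channels within 100 µm — simultaneous spikes on distant channels are
different neurons, not duplicates — and spans all channels otherwise.

Snippets are cut from each event's peak channel (default window 0.8 ms
before to 1.9 ms after the extreme, ~64 samples at 24 kHz). By default the
extremum is refined to sub-sample precision with a least-squares parabola
over the 7 surrounding samples and the snippet is resampled there with a
cubic spline: without this, flat-troughed spikes split into distinct
one-sample-phase clusters downstream (a 3-point parabola is too
noise-sensitive to fix this). `align="sample"` keeps the raw grid. Events
whose window clips a recording edge are dropped and counted.

## Synthetic data

The simulator exists so every stage is testable offline; it emulates three
regimes rather than reproducing any particular dataset.

**Templates** are parametric tri-phasic shapes — a negative Gaussian trough
(width 0.06-0.45 ms, position 22-42% of the window), a positive after-wave
(relative height 0.1-0.55, delay 0.2-1.2 ms) and an optional positive
pre-deflection (<= 0.3) — peak-normalized to 1, with secondary lobes well
below the trough as in averaged extracellular shapes. Banks are redrawn
until every pairwise max-lag normalized cross-correlation is below a
threshold (0.999 by default; test fixtures that claim "well-separated
units" use 0.9 as the quantitative reading of that phrase).

**Labeled snippet sets** pool per-unit Poisson trains (rates drawn from
5-15 Hz unless given; optional 2 ms refractory, off by default) and build
one snippet per spike: the unit's template, plus background noise made of
many faint randomly shifted templates scaled so the background std matches
`noise_level` (0.05-0.4 of the unit peak covers the intended range), plus —
crucially — every *physically colliding* spike superposed at its true lag.
Overlap flags mark exactly these collisions; an extra forced-collision
fraction exists for targeted fixtures but defaults to 0. A pooled
"multiunit" mode adds a 5 Hz background process of 20 faint extra shapes
(0.25 Hz each, amplitude 0.5 of a unit peak).

**Multichannel recordings** place units within ~10 µm of a two-column,
20 µm-pitch, 24-channel probe, at least 20 µm apart (rejection sampling).
Each unit's peak amplitude is drawn from 100-500 µV and realized exactly on
its nearest channel; other channels decay as `exp(-d/30 µm)`, a localized
footprint in the spirit of biophysically simulated high-density data (a
flatter decay produces duplicate detections on distant channels that real
recordings do not show). Spikes are inserted at Poisson times at 32 kHz
and 1 µV Gaussian noise is added. Ground truth records each spike's time
(at the template extremum) and unit.

What the generator does **not** emulate: electrode drift, bursting,
amplitude adaptation, realistic 1/f noise spectra, biophysical template
families, or probe geometries beyond the two-column layout. Passing tests
therefore demonstrate the pipeline's mechanics and its behavior under
controlled collision/noise/amplitude structure, not performance on real
tissue.

## Problem sizes and numerical choices

The acceptance script runs 10 seeds of the multichannel regime
(~800 true spikes each) with sort scans over orders 0-4 (the optimum
consistently sits in 0-4; higher orders only add degenerate cells),
k = 2-12, and 300 UMAP epochs; the test suite uses 3-5 seeds and 150-300
epochs at the same conditions. Cross-entropy computations clamp q to
[1e-12, 1 - 1e-12]. The eigensolver path is dense (`scipy.linalg.eigh`) —
deterministic and exact at these sizes. All randomness flows from
`numpy.random.default_rng(seed)`; every simulation, embedding and sort is a
pure function of its config and seed.

## Known limitations

* Silhouette-driven cluster-count selection undercounts when two units are
  mutually similar (the merged partition scores higher in any space) and
  the spectral arm overcounts two-unit data (the 2-D eigenvector floor).
  Measured count-prediction rates for the UMAP arm on well-separated
  synthetic units: 20/20 (2 units), 19/20 (3), ~17/20 (4), ~14/20 (5).
* On the multichannel regime the UMAP arm typically selects one extra
  cluster (collision-contaminated snippets form their own blob), costing a
  few points of per-unit accuracy; the spectral arm can collapse to coarse
  super-clusters on seeds where the affinity graph is strongly fragmented,
  with large accuracy loss. At a forced correct cluster count both arms
  reach 93-97% per-unit accuracy on the same data.
* Collisions bound all-spike accuracy on snippet sets: near-zero-lag
  superpositions are intrinsically ambiguous, so all-spike accuracy sits
  0.2-1.2 points below the 100% routinely reached on non-overlapping
  spikes.
* The full-pairs optimizer is kept exactly as specified (bounded
  repulsion); use the stochastic optimizer for anything but small,
  well-spread problems.
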