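# gradspike

Unsupervised spike sorting for extracellular recordings, built around
gradient-based waveform preprocessing and nonlinear dimensionality
reduction.

Spike sorting assigns each detected extracellular action potential to the
neuron that produced it, using only waveform shape. When units are strongly
correlated, raw amplitudes separate them poorly; the temporal derivatives
of the waveform often do better. `gradspike` implements that idea as a
fully automatic pipeline:

1. **Gradient preprocessing** — the n-th temporal gradient of each snippet
   via repeated first-order central differences,
   `f'(x_i) = (f(x_{i+1}) - f(x_{i-1})) / 2h + O(h^2)`.
2. **Nonlinear embedding** — either a graph-Laplacian spectral embedding
   (affinity `s_ij = exp(-||x_i - x_j||² / 2σ²)` or an exact-kNN graph,
   Laplacian `L = D - S`, eigenvectors of the smallest nonzero
   eigenvalues), or a from-first-principles UMAP (fuzzy kNN graph with
   per-point scales `ρ_i, σ_i` solving `Σ_j exp(-max(0, d_ij - ρ_i)/σ_i) =
   log₂ k`, fuzzy-union symmetrization, and cross-entropy layout
   optimization with kernel `q_ij = (1 + ||y_i - y_j||²)⁻¹`).
3. **Agglomerative clustering** (Ward by default) cut at a candidate
   cluster count.
4. **Silhouette-guided selection** of the gradient order, the cluster
   count and the embedding neighbor count, jointly over a grid.

The spectral variant is called **GSA**, the UMAP variant **GUA**. The
package also provides 5σ threshold detection with sub-sample-aligned
waveform extraction, evaluation metrics (optimal-assignment accuracy,
detection precision/recall/F1, unit detection rate), readers/writers for
CSV/HDF5/MAT spike data, and a ground-truth simulator so the entire
pipeline is testable offline. See `docs/methods.md` for the full model
description and design choices.

## Worked example

```python
import numpy as np
from gradspike import (SimConfig, simulate_recording, estimate_thresholds,
                       detect_spikes, extract_waveforms, sort_spikes,
                       match_spike_trains, match_labels)

# 24-channel probe, 8 units, 10 s at 32 kHz, 1 µV noise
cfg = SimConfig(n_units=8, duration=10.0, fs=32000.0, noise_level=1.0, seed=0)
rec, truth = simulate_recording(cfg)

det = detect_spikes(rec, estimate_thresholds(rec, 5.0), refractory=1e-3)
ws = extract_waveforms(rec, det)
res = sort_spikes(ws, method="umap", orders=range(5), ks=range(2, 13), seed=0)

di, ti = match_spike_trains(ws.spike_times, truth.spike_times, 1e-3)
rep = match_labels(res.labels.labels[di], truth.unit_ids[ti])
print(f"{res.method_name}: order={res.selection.best_order} "
      f"k={res.selection.best_k} silhouette={res.selection.best_score:.3f}")
print(f"matched-spike accuracy: {rep.accuracy:.1f}%")
```

Output:

```
GUA-Spike: order=2 k=9 silhouette=0.911
matched-spike accuracy: 94.8%
```

The sorter scanned gradient orders 0–4 and cluster counts 2–12, settled on
the second-order gradient features with nine clusters (the eight true units
plus one cluster of collision-contaminated snippets), and classified 94.8%
of the detected, ground-truth-matched spikes into the right unit. On
cleaner single-channel snippet sets (three well-separated units, noise
0.05–0.4 of the spike peak) both pipelines reach 99–100% accuracy and
recover the true cluster count.

The same pipeline is available from the shell:

```bash
gradspike simulate --mode recording --units 8 --noise 1.0 --duration 10 --seed 0 --out rec.h5
gradspike detect --in rec.h5 --multiplier 5 --out waves.h5
gradspike sort --in waves.h5 --method gua --orders 0:4 --k 2:12 --seed 0 --out sort.h5
gradspike evaluate --sort sort.h5 --truth rec_truth.h5 --report report.json
```

or as one chained run from a YAML config: `gradspike run --config run.yaml`.

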