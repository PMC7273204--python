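# eventdtw

Dynamic time warping (DTW) aligns two temporal sequences by minimizing
cumulative point-to-point distances. When the two sequences sample the same
phenomenon at *different* rates — a chest ECG heart-rate stream at ~1.26 Hz
against a wrist PPG stream at ~0.2 Hz, say — plain DTW suffers from the
**singularity problem**: one observation in one signal gets linked to long
runs of consecutive observations in the other, and the alignment degenerates
exactly where it matters.

`eventdtw` implements **EventDTW**, a DTW variant for this setting, together
with the evaluation machinery needed to measure alignment quality at all:

* **Four alignment engines** sharing one dynamic program (symmetric steps,
  diagonal-first tie-break): classic DTW on amplitudes, derivative DTW
  (Keogh first-derivative estimator), shape DTW (local-subsequence
  descriptors), and EventDTW. EventDTW detects monotone slopes, keeps the
  top 20% by *elevation* (observation count × amplitude range) as key
  events, matches companion slopes to them by timestamp proximity, and
  propagates *event information* exponentially along each matched slope —
  I = 1 at the slope's peak decaying to I = 0.1 at its other end, 0
  elsewhere — then aligns the 3-vectors `(v, I_up, I_down)` under the
  Euclidean distance. With no events it reduces exactly to DTW.

* **Two alignment-quality metrics.** For a companion signal Q built from a
  reference R with down-sampling ratio d (so Q_j is optimally aligned with
  a known group G_j of d consecutive reference observations):

  - the **error rate** `ER = Σ_links |k − j| / (½·L_Q·(L_Q−1)·(1+d) − (L_Q−1))`,
    0 at the optimal alignment and 1 at the worst-case path (every Q linked
    to the first R, every R linked to the last Q);
  - the **singularity score** `SS = Σ_j (m_j − d)² / L_Q`, where m_j is the
    number of reference observations linked to Q_j, with m_j replaced by
    1/M when M > 1 companion observations collapse onto a single reference
    observation (the directional penalty).

* **A synthetic companion generator**: warps a uniform reference with a
  sigmoid-derivative time shift and a Gaussian amplitude bump around an
  anchor, down-samples by d with linear interpolation, and recovers the
  ground-truth alignment by an exact dynamic program — giving signal pairs
  whose optimal alignment is known, so ER can be computed.

## Worked example

```python
import numpy as np
from eventdtw import (preprocess, generate_companion_pair, WarpSpec,
                      dtw_align, event_dtw_align, score_alignment)
from eventdtw.cli_io import sine_mixture

rng = np.random.default_rng(0)
R = preprocess(sine_mixture(rng, 200))           # smooth + z-score
_, Q, opt = generate_companion_pair(R, 5, WarpSpec(shift_scale=8.0))
for algo, fn in [("dtw", dtw_align), ("edtw", event_dtw_align)]:
    rep = score_alignment(fn(R, Q), opt, algo)
    print(f"{algo}: ER={rep.error_rate:.4f} SS={rep.singularity_score:.3f} "
          f"W={rep.path_length}")
```

prints

```
dtw: ER=0.0243 SS=3.900 W=200
edtw: ER=0.0248 SS=3.950 W=200
```

— both algorithms recover the warp almost perfectly on this easy pair (ER a
few percent of worst case; SS small relative to the worst-case path's ≈975).
Across a 20-dataset benchmark the difference shows up in how often each
algorithm is *best*:

```sh
eventdtw bench --seed 1 --n-datasets 20 -o bench.txt
```

```
algorithm  pct_best_er  pct_best_ss
      dtw         47.5         37.5
     ddtw          0.0          0.0
     sdtw          0.0          0.0
     edtw         52.5         62.5
```

EventDTW is the most frequent winner on both metrics, and the derivative-
and shape-based baselines never win on these down-sampled pairs. The CLI
also exposes `synth` (write an R/Q pair plus ground-truth groups), `align`
(any engine on two CSV signals), and `score` (ER/SS/W report for a path).

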