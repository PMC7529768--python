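# scapd — agent-based stem-cell patterning on micropatterns

When mouse embryonic stem cells are confined on small adhesive islands
(micropatterns), the colony self-organises: cells primed for
differentiation (brachyury-positive, **T+**) end up at the edge of a
disc-shaped island or at the tips of an elliptical one, while naive
(**T−**) cells stay near the centre.  This package is for computational
biologists who want to ask *which minimal motility rules are sufficient
to produce that pattern* — and to score candidate rule sets
quantitatively against reference data.

It provides:

* **An agent-based simulator** of 6-cell colonies on a 97.5 µm-radius
  disc or a 195.5 × 49 µm ellipse, advanced in 15-minute steps for 48 h.
  Four motility rules can be toggled independently, giving 16 models:
  (i) differential speed (T+ 100 µm/h vs T− 40 µm/h), (ii) differential
  directional persistence (105 vs 15 min), (iii) neighbour-directed
  movement — inverse-square forces `F ∝ 1/D²` within a sensing radius
  *R*, pushing T+ away from neighbours and pulling T− toward them, with
  Gaussian heading noise σ — and (iv) a border-turning rule (turn by a
  fixed angle α instead of leaving the island).  An improved variant
  scales speed by the **velocity ratio** `|ΣF| / Σ|F|`, so cells in
  balanced-force configurations slow down.
* **SCAPD**, the *stem cell aggregate pattern distance*: per cell type,
  pooled positions are turned into a 256 × 256 Gaussian kernel density
  map (diffusion/Botev bandwidth), thresholded at
  `T = (max gᵢ + min gᵢ)/2`, the high-density-area borders are fitted
  with least-squares circles/ellipses and symmetrised, and the metric is

  `SCAPD = |T_e(T+) − T_m(T+)| + |T_e(T−) − T_m(T−)|`

  where `T_e`/`T_m` are reference/model total densities inside the
  reference borders.  0 means a perfect pattern match; the maximum is 2.
* **Baseline metrics** (earth mover's distance via an exact transportation
  LP, KL divergence, ensemble CRPS) for methodological comparison.
* **Grid-search calibration** of (R, σ) — shared or per cell type — and a
  border-angle sensitivity sweep.
* **A synthetic reference generator** emulating the qualitative
  organisation of patterned cultures (centre-clustered T−, rim/tip T+),
  so the whole pipeline runs without any external data.

## Worked example

Rank all 16 models against a synthetic disc reference:

```sh
scapd synth --pattern disc --seed 3 --out ref.csv
scapd ground-truth --pattern disc --reference ref.csv --out gt.json
scapd rank --pattern disc --reference ref.csv --seed 1 --n-runs 50 --out rank.csv
```

The `ground-truth` step prints the reference total densities; with these
seeds it reports

```
T_e: T+ 0.4156, T- 0.6752
```

meaning 42 % of the pooled T+ density lies in the rim annulus outside the
fitted inner circle, and 68 % of the T− density inside the fitted central
circle.  The ranking (one SCAPD per model, common random numbers) puts
the neighbour-force models in front; with these seeds the best rows of
`rank.csv` are models 12 (0.139), 14 (0.219) and 4 (0.245), with model 7
at 0.315 and the rule-free random model 1 at 0.346 — smaller is closer
to the reference pattern.

The same works in Python:

```python
import numpy as np
from scapd import (disc, PatternSpec, generate_reference, build_ground_truth,
                   ModelSpec, SimParams, run_model, scapd)
from scapd.io import colonies_to_table

pattern = disc()
ref = generate_reference(pattern, PatternSpec(), np.random.default_rng(3))
gt = build_ground_truth(ref, pattern)
finals = run_model(ModelSpec.from_number(7), SimParams(), pattern,
                   n_colonies=50, rng=np.random.default_rng(1))
print(scapd(gt, colonies_to_table(finals)).scapd)
```

Evaluating a reference against itself returns exactly `0.0` — the
metric's self-distance identity.

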