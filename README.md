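# mbviop

**Multiblock variable influence on orthogonal projections (MB-VIOP)** — a
variable-importance and variable-selection method for multiblock
latent-variable models of the OnPLS/O2PLS family.

## The problem

Multi-omics and multi-instrument studies measure the same samples on several
data matrices ("blocks"): a transcript block, a protein block, a metabolite
block; or six spectrometers looking at the same specimens.  Symmetric
multiblock decompositions such as OnPLS split each block's variance into
components typed by how widely they are shared — **global** (all blocks),
**local** (some blocks), **unique** (one block).  What those decompositions
do not tell you is *which input variables matter* for each kind of shared
variation.  MB-VIOP answers that: it scores every variable of every block
for its importance to the unique, local, global and total variation of the
model, on a calibrated scale where 1 is the equal-contribution reference.

## The method

Given a decomposed model with scores `t_a` and unit-norm loadings `p_{a,d}`
(component `a`, block `d`), let `SSD_{a,d} = ||D_d^T t_a||² / ||t_a||²` be
the sum of squares of block `d` explained by component `a`, and `SSD_cum,d`
its cumulative counterpart.  Each profile of block `d_i` (with `K` variables)
has the same shape,

```
MB-VIOP(d_i) = √K · v / ||v||₂ ,   v_k = sqrt( Σ  p²_{a,d_i,k} · SSD_{a,d} / SSD_cum,d )
```

where the sum ranges over:

* **unique** — `d_i`'s own unique components, with its own SS ratios;
* **local** — `d_i`'s local components, with the SS ratios of each
  component's *partner* blocks (the block's connection to itself is
  excluded), averaged by the connectivity degree β = number of
  (local component, partner block) connections of `d_i`;
* **global** — all global components, with the SS ratios of *all* blocks;
* **total** — the quadratic combination
  `√(unique² + local² + global²)`, renormalized.

The normalization makes every profile's squared values sum to `K`, so the
mean square is 1: variables scoring ≥ 1 are important for that kind of
variation, and selections at a lower threshold (e.g. 0.5) are conservative
supersets.  Selecting on a profile, rebuilding the blocks from the kept
columns, and refitting gives a smaller model that typically explains *more*
of its (reduced) data — dimensionality reduction with a gain in
interpretability.

The package also ships:

* a simplified OnPLS-style fitter (`OnPLS`, sklearn-compatible): sequential
  SVD extraction of global, local and unique scores with deflation, followed
  by a monotone coordinate/Jacobi refinement of the explained sum of squares;
* a fully specified synthetic four-block generator (`sd16_235glu`):
  50 samples, blocks of 61/79/96/96 variables, 2 global + 3 local + 5 unique
  components with Gaussian/pulse pure profiles and 0.1 % noise, returned
  together with its ground-truth decomposition — everything is testable with
  no external data;
* the reduce-and-refit workflow, CSV/JSON serialization, profile grid plots
  and a `mbviop` command-line interface
  (`simulate | fit | viop | select | reduce | plot | report`).

## Worked example

```python
import numpy as np
from mbviop import (sd16_235glu, generate, explained_variation_table,
                    compute_profiles, select_variables)

design = sd16_235glu(seed=1)
dataset, truth = generate(design)
print(explained_variation_table(truth, dataset).round(1).to_string())

profiles = compute_profiles(truth, dataset)
print("beta per block:", dict(zip(dataset.block_names, profiles.beta)))
sel = np.sort(select_variables(profiles, "D1", "unique")) + 1
print("D1 unique variables (MB-VIOP >= 1):", sel.tolist())
v = profiles.get("D1", "unique")
print("peak: variable", int(np.argmax(v)) + 1, "with MB-VIOP = %.2f" % v.max())
```

prints

```
      g1    g2    l1    l2    l3    u1    u2    u3    u4    u5  TOTAL
D1  14.3  14.3  14.3  14.2   NaN  14.3  14.2  14.3   NaN   NaN   99.9
D2  25.0  25.0   NaN  25.0  24.9   NaN   NaN   NaN   NaN   NaN   99.9
D3  25.0  25.0   NaN   NaN  24.9   NaN   NaN   NaN  25.0   NaN   99.9
D4  20.0  20.0  20.0   NaN  20.0   NaN   NaN   NaN   NaN  20.0   99.9
beta per block: {'D1': 2, 'D2': 3, 'D3': 2, 'D4': 3}
D1 unique variables (MB-VIOP >= 1): [7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 24, 25, 26, 27, 28, 29, 30, 31, 32]
peak: variable 13 with MB-VIOP = 2.41
```

Each block's variance splits equally over its components (1/7 ≈ 14.3 % in
D1, 25 % in D2/D3, 20 % in D4), and the unique profile of D1 flags exactly
the designed pulse supports.  Variable 13 — the one variable sitting in
*two* unique components — stands out with more than twice the reference
importance: the method credits a variable in proportion to how much model
variation it helps explain, which the loading vectors alone cannot do.

The same pipeline from a shell:

```sh
mbviop --seed 1 --out-dir sim simulate
mbviop --out-dir out viop --model sim/truth_model \
       --blocks sim/D1.csv --blocks sim/D2.csv --blocks sim/D3.csv --blocks sim/D4.csv
mbviop --out-dir out select --profiles out --profile total --threshold 1.0
```

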