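# snfold

Analysis toolkit for **single-nucleus Hi-C** (snHi-C): from chimeric
sequencing reads to per-cell contact maps, TAD segmentations, null-model
statistics, and 3D chromosome reconstructions.

Single-nucleus Hi-C recovers thousands to ~10⁵ proximity-ligation
contacts from one nucleus after Phi29 whole-genome amplification. Two
problems dominate the analysis. First, Phi29 template switching creates
chimeric DNA that mimics ligation products; `snfold` implements the
one-read-based junction filter that accepts a chimeric read only when
both ligated ends fall within 10 bp of a restriction site, followed by
fragment-pair deduplication and a valency filter (a restriction
fragment has two ends per genome copy, so a diploid fragment supports
at most four unique contacts, the haploid male X at most two). Second,
the resulting maps are sparse, so every structural claim needs a
calibrated control; `snfold` provides random-graph null models,
conservative shuffles, and two independent TAD callers.

The core quantitative pieces, in the field's standard notation:

* **Modularity TAD segmentation.** A chromosome of N bins is
  partitioned to maximize Σ segments of
  `score(a,b; γ) = W/T − γ (M/2T)²` (W within-segment sum, M segment
  marginal, T total), solved exactly by an O(N²) dynamic program with
  unassigned "null" bins; γ is swept (0–375) and the TAD scale is
  γ_max/2, where γ_max maximizes the number of called domains.
* **Non-backtracking (NBT) spectral calling.** The operator
  `B_{i→j,k→l} = δ_il(1 − δ_jk)` on directed edges resolves communities
  in sparse graphs; bins are embedded via the isolated real
  eigenvectors and clustered by spherical k-means.
* **MS/MSS null models.** Link probabilities
  `p_ij = P_c(|i−j|)/Σ_s (N−s)P_c(s) · N_c` (marginal scaling) and
  `p_ij ∝ k_i k_j P_c(|i−j|)` with per-bin stickiness `k_i` fitted by
  the fixed point `k̃_i = k_i α_i`; observed maps are compared with
  nulls through Poisson goodness-of-fit of contact counts in triangular
  diagonal windows.
* **DPD polymer reconstruction.** A bead chain (one bead per 10-kb bin)
  in explicit solvent at the theta point (χ ≈ 0.5), with single-cell
  contacts imposed as harmonic bonds, overstretched bonds pruned, and
  structures compared by the coefficient of difference
  `K = ‖D−D′‖/‖D+D′‖` and the scaling `R(s)`.

A synthetic-data module generates ground-truth architectures (planted
TADs, compartments, stickiness, power-law decay `P_c(s) ∝ s^−1.5`),
sparse cells, and labeled chimeric read sets, so the full stack runs
and is tested without any external data.

## Worked example

```python
import numpy as np
from snfold import synthetic, tad_modularity
from snfold.segmentation import match_boundaries

# plant 55 TADs (median 9 bins = 90 kb) on a 500-bin chromosome
arch = synthetic.make_architecture(500, seed=11)
cell = synthetic.sample_cell_contacts(arch, 30_000, seed=12)

sweep = tad_modularity.gamma_sweep(cell, np.arange(0, 375.001, 0.5))
tads = sweep.segmentation_half          # the gamma_max/2 (TAD-scale) call
rec = match_boundaries(arch.tad_edges, tads.boundary_edges(), offset=1).mean()

print(f"gamma_max = {sweep.gamma_max:.1f}")
print(f"{tads.n_tads} TADs, median {tads.median_tad_size():.0f} bins")
print(f"boundary recovery: {100 * rec:.1f}%")
```

prints

```
gamma_max = 33.0
66 TADs, median 7 bins
boundary recovery: 100.0%
```

i.e. the γ-sweep peaks at γ_max = 33 on this dense synthetic cell, the
TAD-scale call at γ_max/2 finds 66 domains with a median size of 7 bins
(70 kb, two bins under the planted 9-bin median: the call includes
sub-domain splits of the largest planted TADs), and every
planted boundary has a called boundary within one 10-kb bin.

The same stack runs end to end from the command line:

```bash
snfold pipeline --seed 3 --out artifacts/        # simulate -> orbita -> maps
                                                 # -> TADs (both callers)
                                                 # -> nulls -> aggregates
snfold simulate --n-bins 300 --n-contacts 10000 --seed 1 --out cell.tsv
snfold tads --map cell.tsv --gamma-step 0.5 --out tads.bed
snfold tads-nbt --map cell.tsv --seed 1 --out tads_nbt.bed
```

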