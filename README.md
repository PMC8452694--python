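# hsifuse

Multiplatform hyperspectral image (HSI) fusion and linear unmixing by
constrained MCR-ALS.

Hyperspectral microscopes record a full spectrum at every pixel, but no
single platform sees every constituent of a biological sample:
fluorescence imaging locates natural fluorophores (chlorophylls, lignins)
at high spatial resolution, Raman microscopy fingerprints pigments like
carotenoids, and (synchrotron) FTIR reveals proteins, lipids and
carbohydrates. `hsifuse` fuses cubes from several such platforms — with
different pixel sizes, orientations and scanned areas — into one joint
data structure and unmixes it into pure component spectra and spatial
distribution maps.

The package is aimed at chemometricians and bio-imaging groups who have
co-acquired cubes of the same specimens on different instruments and want
a single, constraint-aware decomposition instead of three separate ones.

## The model

Unfolding a cube into a matrix **D** (pixels × channels), the measurement
follows the bilinear Beer–Lambert-like model

```
D = C·Sᵀ + E
```

where the K rows of **Sᵀ** are invariant pure component spectra, the
columns of **C** their per-pixel abundances, and **E** the residuals.
Multivariate Curve Resolution–Alternating Least Squares (MCR-ALS) refines
**C** and **Sᵀ** alternately by least squares under constraints —
non-negativity, and selectivity/local rank (entries forced to exactly
zero) — applicable per component, per mode (**C** or **Sᵀ**) and per
block. Fit quality is the lack of fit and explained variance

```
LOF(%) = 100·√(Σe²ᵢⱼ / Σd²ᵢⱼ),     r² = 1 − Σe²ᵢⱼ / Σd²ᵢⱼ
```

For several samples and platforms, blocks are appended row-wise (same
spectral axis) and column-wise (same pixels) into an augmented multiset;
three samples × three platforms give nine blocks sharing one **C** (per
sample) and one **Sᵀ** (per platform). Joining blocks meaningfully
requires two preparations that `hsifuse` automates:

1. **Pixel congruency** — each cube is cleaned per platform (saturation
   masking, spectral cropping, Savitzky–Golay second derivative for IR,
   AsLS baseline subtraction and cosmic-spike repair for Raman), binned or
   area-resampled to the coarsest pixel grid, and rigidly registered
   (shift + rotation, Nelder–Mead simplex on binarized global-intensity
   maps) against the reference platform; only the jointly scanned area
   enters the multiset.
2. **Block balancing** — each block is divided by its Frobenius 2-norm so
   platforms with brighter signals or more channels do not dominate the
   factorization.

No public data accompany this problem domain's typical studies, so the
package ships a first-class phantom generator producing co-registered
fluorescence/Raman/FTIR cubes of leaf-section-like scenes with full
ground truth (maps, spectra, misalignments, baselines, spikes,
saturation) for testing and benchmarking.

## Worked example

Generate a congruent three-sample phantom, fuse it, and unmix:

```python
import numpy as np
import hsifuse as hf
from hsifuse.io import unfold
from hsifuse.multiset import assemble, balance
from hsifuse.phantom import (PhantomSpec, generate_phantom,
                             balanced_truth_spectra, match_components)

phantom = generate_phantom(PhantomSpec.clean(n_px=20, seed=1, snr=50.0))
blocks = {key: unfold(cube) for key, cube in phantom["cubes"].items()}
mset = assemble(dict(zip(blocks, balance(list(blocks.values())))))
print(f"multiset: {mset.M.shape[0]} pixels x {mset.M.shape[1]} channels, "
      f"{mset.n_blocks} blocks")

constraints = hf.ConstraintSet(4).set_nonneg("C").set_nonneg("S")
result = hf.run_mcr_als(mset, n_components=4, constraints=constraints)
print(f"LOF = {result.lof_final:.2f}%   r2 = {result.r2:.4f}   "
      f"iterations = {result.n_iter}")

S_true = balanced_truth_spectra(phantom["truth"], mset)
perm, corr = match_components(result.St, S_true)
print("matched spectrum correlations:", np.round(corr, 4))

maps = hf.component_maps(result, mset, "s1")
print("distribution maps per sample:", maps.shape)
```

Output:

```
multiset: 1200 pixels x 324 channels, 9 blocks
LOF = 1.99%   r2 = 0.9996   iterations = 2
matched spectrum correlations: [1. 1. 1. 1.]
distribution maps per sample: (4, 20, 20)
```

The multiset stacks 400 congruent pixels per sample against the 67
fluorescence + 176 Raman + 81 IR channels. At a signal-to-noise ratio of
50 the model explains 99.96% of the variance (LOF is then dominated by
the noise floor), and each of the four resolved spectra is essentially
identical (|r| = 1.0 to four decimals) to the ground-truth signature it
was matched with by the Hungarian assignment. Refolding a column of **C**
gives that component's 20×20 distribution map in each sample.

The core solver is also exposed as a scikit-learn estimator:

```python
est = hf.MCRALS(n_components=4, constraints=constraints).fit(mset)
est.C_, est.St_, est.lof_, est.r2_   # fitted attributes
```

## Command line

```sh
hsifuse simulate --preset realistic --seed 1 --out data/   # phantom + truth
hsifuse align --ref data/s1_ftir.h5 --moving data/s1_raman.h5 --out t.json
hsifuse run --config run.yaml                              # full workflow
```

`run.yaml` lists the input cubes, per-platform preprocessing recipes, the
reference platform, the number of components and the constraint grid; see
`tests/test_pipeline_cli.py` for a complete example. Every stage writes
its artifacts under the output directory and `--resume-from <stage>`
restarts midway.

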