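# barriermap

Mapping and quantifying blood–brain-barrier opening (BBBo) from
delayed-contrast MRI (DCM).

Subtle, transient opening of the blood–brain barrier — for example after
low pulsed electric field treatment — is invisible on a single
post-contrast T1 scan: the tracer leaks in too slowly. Scanning repeatedly
for ~30 min after injection and following each voxel's intensity over time
reveals the slow accumulation. `barriermap` implements this analysis for
researchers working on BBB-opening technologies and drug delivery: it
turns a 4D post-contrast series into voxelwise permeability summary maps,
a filtered binary BBBo mask with cluster inventory, and distributional
summaries — plus the surrounding quantitative toolkit (dose-response IC50
fits, tissue-concentration arithmetic, tumor growth rates) and synthetic
phantom generators so every stage is testable without animal data.

## The model

Each voxel's curve, normalized to the first post-contrast frame, is fit by
a five-parameter two-exponential function rooted in the two-compartment
exchange picture:

    f(t) = x1 · t · e^(−t/x2) + x3 · e^(−t/x4) + x5

Three summaries are read off the fitted curve over the scan window
[t_first, t_last]:

- **Dyn** = 100 · (max_t f(t) − f(t_first)) — maximal signal increase (%);
- **TT** = measure{ t : f(t) ≥ 1.05 } — time over the 5 % threshold (min);
- **AOT** = ∫ max(f(t) − 1.05, 0) dt — area over the threshold, a
  composite of opening intensity and duration.

A voxel counts as BBBo iff r² > 0.6, Dyn > 5 %, and it belongs to a
3D-connected cluster of ≥ 30 such voxels. BBBo volume is voxel count ×
voxel volume (0.39 × 0.39 × 0.4 mm³ by default). Over the BBBo voxels the
AOT histogram decays approximately exponentially, and is summarized by a
least-squares fit of A·e^(−x/τ).

## Worked example

```python
import numpy as np
from barriermap import PhantomSpec, generate_phantom, run_arrays

spec = PhantomSpec(shape=(64, 64, 64), n_clusters=3, noise_sigma=0.02, seed=2)
series, truth = generate_phantom(spec)           # 8 frames, 1–30 min
maps, result, summary = run_arrays(series, truth.brain_mask)

print("detected BBBo voxels:", result.n_voxels)
print("volume (mm^3):", round(result.volume_mm3, 3))
print("clusters:", result.clusters)
print("true voxels:", int(truth.bbbo_mask.sum()))
```

prints

```
detected BBBo voxels: 232
volume (mm^3): 14.115
clusters: ((1, 96), (2, 76), (3, 60))
true voxels: 213
```

i.e. the three implanted cortical clusters are recovered (recall 1.0 on
this phantom) with a thin halo of noise voxels attached to them (precision
0.92); the 6 isolated sub-cluster enhancing spots and all pure-noise
voxels are removed by the Dyn/r²/cluster filters. The same pipeline is
available from the shell:

```bash
barriermap simulate --out phantom --seed 2
barriermap run phantom/series.nii.gz phantom/times.csv phantom/brain_mask.nii.gz --out out
```

The numbered drivers under `analysis/` run the full study-shaped analysis
(phantom cohort → BBBo mapping → AOT distributions → pharmacology →
efficacy) and write their tables under `results/`.

## Layout

- `src/barriermap/` — the library: `kinetics` (voxel model and fit),
  `bbbo` (registration, brain-wide fitting, classification),
  `distributions`, `pharmacology`, `efficacy`, `synthetic` (generators),
  `config`/`pipeline`/`io`/`cli` (orchestration).
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — pytest suite with independent brute-force oracles.
- `docs/methods.md` — models, assumptions, parameter choices, limitations.
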