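# sxtmorph

Quantitative 3D mitochondrial morphometry for soft X-ray cryo-tomography
(cryo-SXT).

Cryo-SXT images whole vitrified cells at nanometer resolution in the
water window, where the reconstructed voxel signal is a physical quantity:
the linear absorption coefficient (LAC, µm⁻¹), proportional to local mass
density. That makes it possible to ask quantitative questions about
organelles — are mitochondria in one cell population more elongated, denser
in the matrix, or larger than in another? — provided every step from raw
tilt series to group statistics is reproducible. `sxtmorph` implements that
chain for anyone who works with (or teaches, or benchmarks against)
cryo-SXT organelle data:

- **phantoms** — digital cells with prescribed mitochondrial shape
  anisotropy and matrix LAC, nucleus, and 200 nm gold fiducials, with full
  ground truth;
- **optics** — Beer–Lambert forward projection (`T = exp(−∫µ dt)`) over a
  single-axis tilt scheme (default 140° range, 1° steps → 141 frames),
  flat-field normalization, Poisson photon noise, absorbance conversion
  `A = −ln T`;
- **recon** — ART (block-Kaczmarz) reconstruction, default 15 sweeps at
  relaxation 0.01, with nonnegativity and convergence diagnostics;
- **segment** — bead detection and half-maximum organelle segmentation
  (contrast-unbiased boundaries), plus ground-truth label pass-through;
- **morphometry** — per-organelle volume (voxel count × voxel volume),
  mean ± SD LAC with gold-bead normalization, second-moment shape
  eigenvalues and fractional anisotropy

  FA = 100 · √(3/2) · √Σᵢ(λᵢ − λ̄)² / √Σᵢλᵢ² ∈ [0, 100],

  which is 0 for a sphere and 100 for a line;
- **stats** — Welch/Student two-group comparisons with significance stars,
  and oxygraph respirometry arithmetic (ROX correction, coupling
  efficiency, spare respiratory capacity).

## Worked example

Run the bundled two-arm study: 7 "S-like" cells (elongated 4:1:1,
dense-matrix µ = 0.45 µm⁻¹ mitochondria) vs 7 "R-like" cells
(near-spherical 1.2:1:1, lucent µ = 0.35), 15–20 organelles per cell,
imaged, reconstructed and quantified end to end:

```python
from sxtmorph import StudyConfig, run_study

records, report = run_study(StudyConfig(seed=1))
print(report["n_mitochondria_pooled"])   # {'S': 102, 'R': 112}
print(report["fa_median"])               # {'S': 92.0, 'R': 30.5}
print(report["lac_normalized_mean"])     # {'S': 0.0567, 'R': 0.0474}
for name, cmp in report["comparisons"].items():
    print(name, cmp["significance"], f"p={cmp['p_value']:.2g}")
```

```
fa_percent *** p=1.4e-58
lac_normalized *** p=8.3e-08
total_volume_nm3 ns p=0.75
```

Reading the output: the elongated arm's pooled FA median (92%) sits far
above the round arm's (30%) — the round arm is not at zero because the 140°
tilt range leaves a missing wedge that elongates every reconstructed object
along the beam axis. Bead-normalized LAC (organelle LAC divided by the
measured gold-bead LAC, dimensionless) recovers the injected matrix-density
contrast per cell. Total mitochondrial volume shows no significant
difference — the two generators are volume-matched, and the half-maximum
segmentation keeps boundary placement independent of object contrast, so no
spurious volume effect appears. `records` is the pooled per-organelle
table (one row per mitochondrion: voxel count, volume in nm³, LAC mean/SD,
normalized LAC, shape eigenvalues, FA, cell and group).

The same pipeline is scriptable stage by stage from a shell, with MRC
volumes, TIFF tilt stacks (+ JSON angle sidecars) and CSV tables on disk:

```sh
sxtmorph generate --seed 1 --out cell/
sxtmorph project --phantom cell/ --out tilt.tiff
sxtmorph reconstruct --tilt tilt.tiff --out recon.mrc
sxtmorph segment --recon recon.mrc --threshold 0.29 --out labels.mrc
sxtmorph quantify --recon recon.mrc --labels labels.mrc --out records.csv
sxtmorph run-all --seed 1 --out study/
```

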