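# rlbpseg

Multi-atlas segmentation of 3D structures with **random local binary
pattern (RLBP)** texture features and closed-form **ridge-regression label
fusion**, plus the baselines, metrics and volumetric group analysis needed
to evaluate it.  The motivating application is hippocampus segmentation
from T1 MR brain images for Alzheimer's disease studies, but the code
operates on any target volume with a set of atlases (image + expert label
map) already warped into its space.

## The method

**Features.**  For a voxel `c` with a cubic patch of radius `r_p`
(`n = (2 r_p + 1)^3` voxels), form the difference vector
`y = [x_1 - x_c, ..., x_n - x_c]`.  The 3D LBP code binarizes each entry,
`bit_i = s(y_i)` with `s(t) = 1` for `t >= 0`, else 0 — illumination
invariant but fragile: a small difference flips sign under noise.  The RLBP
code instead binarizes `L` random weighted sums,

    bit_j = s(w_j . y),   w_j ~ Uniform[-1, 1]^n,  j = 1..L,

so large, noise-stable differences dominate each bit.  One `L x n`
projection matrix is drawn per run (seeded) and shared by all voxels.

**Fusion.**  Majority voting over the `N` warped atlas label maps settles
every unanimous voxel.  Each remaining *ambiguous* voxel `x` gets its own
training set `D_x`: the RLBP features and signed labels (+1 foreground, -1
background) of all voxels in a search neighborhood of radius `r_s` around
`x` in every atlas (`M = N (2 r_s + 1)^3` samples).  A ridge regression

    argmin_b  1/2 ||b||^2  +  C/2  sum_(f,l) in D_x (l - b.f)^2

is solved in closed form via `(I/C + F'F) b = F'l` and the voxel is labeled
`sign(b . f_x)`.  Defaults are the published optimum: `N=20`, `L=1000`,
`C=4^-4`, `r_s=1`, `r_p=4`.

Also included: NLP (nonlocal patch-based weighted voting) and plain-LBP
ridge fusion baselines, NMI-based atlas selection, six segmentation metrics
(Dice, Jaccard, Precision, Recall, volume difference, one-sided mean
boundary distance), ICV volume correction with Cohen's d effect sizes, and
a synthetic phantom generator that emulates warped atlas sets with
controlled registration error — so the whole pipeline runs and is tested
without any image download.

## Worked example

`python examples/phantom_segmentation.py` builds a phantom problem — an
ellipsoidal structure seen through 10 atlases with 1.5-voxel residual
registration error and additive intensity noise — and fuses the atlas
labels with every engine:

```
2950 of 64000 voxels are ambiguous (atlases disagree); only these are re-classified by the regression
  Dice(majority vote       ) = 0.9672
  Dice(NLP weighted vote   ) = 0.9899
  Dice(LBP ridge           ) = 0.9586
  Dice(RLBP ridge (L=1000) ) = 0.9777
```

Dice is the volume overlap with the ground truth; the regression engines
only re-decide the ambiguous voxels, so all engines agree everywhere the
atlases were unanimous.  `examples/noise_robustness.py` shows the feature
claim directly — for an intensity-edge patch under noise, the LBP code
flips 14/27 bits while the modal RLBP code flips none:

```
LBP code (27 bits): 14 bits flipped by the noise
RLBP code (20 bits), 100 random projections:
  0 bits differ:  48 / 100 trials
  1 bits differ:  35 / 100 trials
  ...
```

`examples/effect_sizes.py` and `examples/atlas_selection_demo.py` cover the
volumetric analysis and NMI atlas ranking.

## Command line

A thin CLI wraps the library:

```sh
rlbpseg synth --spec phantom.yaml --out-dir phantoms/
rlbpseg select --target t.nii.gz --pool pool.tsv --n 20 --box 0,0,0,48,77,67 --out selected.tsv
rlbpseg segment --target t.nii.gz --manifest selected.tsv --method rlbp --out seg.nii.gz
rlbpseg evaluate --truth manual.nii.gz --pred seg.nii.gz --out scores.tsv
rlbpseg effectsize --table volumes.tsv --pairs NC:MCI,NC:AD,MCI:AD --out effects.tsv
```

Every command writes a YAML manifest (parameters, seed, version) next to
its output, and `rlbpseg --config cfg.yaml <subcommand>` supplies
per-subcommand flag defaults from a YAML file.

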