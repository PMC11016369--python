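# wemdalign

Rigid alignment of 3D density maps — cryo-EM reconstructions in MRC/CCP4
format — by Bayesian optimization of the wavelet earth mover's distance over
the rotation group.

Two independent reconstructions of the same particle sit in arbitrary
relative orientations: they differ by an unknown rotation `R ∈ SO(3)`, a
translation `t`, and possibly a handedness flip. Standard pointwise losses
(L2 / cross-correlation) decorrelate after a few degrees of misrotation, so
aligning with them needs exhaustive search. `wemdalign` instead minimizes a
transport-like loss

    L(R) = WEMD(f1, f2 ∘ Rᵀ),

the wavelet approximation of the 1-Wasserstein distance: a weighted L1 norm
of wavelet-coefficient differences (scale weights `2^(−j(1+d/2))`, `d = 3`,
coarse scales heaviest) that grows with how far mass must move, keeps a wide
basin of attraction, costs near-linear time per evaluation, and accepts
negative voxel values. The rotation search is a Gaussian-process surrogate
loop: squared-exponential kernel on the Frobenius embedding of the rotation
matrices, kriging-mean acquisition minimized by early-stopped Riemannian
steepest descent, ~200 loss evaluations total. Translation is removed first
by thresholded center-of-mass centering; an optional Nelder–Mead polish on
the L2 loss sharpens the estimate below a degree, and handedness is resolved
by also trying the mirrored map. See `docs/methods.md` for the full model.

## Worked example

```python
import numpy as np
import wemdalign as wa

# a reproducible ground-truthed pair: the stock 4-lobe volume, rotated by a
# Haar-random rotation and shifted by 2.5 voxels, no noise
volume = wa.gaussian_mixture_map(wa.default_spec(32))
r_true = wa.random_rotation(5)
f1, f2, truth = wa.make_pair(volume, r_true, t=(1.0, -2.0, 1.0))

result = wa.align_volumes(f1, f2, wa.AlignConfig(iterations=200, seed=0))
print("search error (deg):", round(wa.recovery_error(result.rotation_bo, truth.rotation_align), 2))
print("polished error (deg):", round(wa.recovery_error(result.rotation, truth.rotation_align), 3))
print("shift error (voxels):", round(float(np.linalg.norm(result.shift - truth.shift_align)), 3))
print("loss evaluations:", result.evaluations)
```

prints

```
search error (deg): 2.45
polished error (deg): 0.022
shift error (voxels): 0.003
loss evaluations: 200
```

i.e. 200 evaluations of the wavelet-EMD loss bring the rotation within
2.5° of the truth, the Nelder–Mead polish lands at 0.02°, and the recorded
centering shifts recover the translation to 3/1000 of a voxel.
`result.rotation` applies to the moving map in the `f_R(x) = f(Rᵀx)`
convention; `shift_map(rotate_map(f2, result.rotation), result.shift)`
overlays `f1`.

The same pipeline from the shell:

```
wemdalign synth --size 32 --seed 5 --outdir pair/
wemdalign align --fixed pair/fixed.mrc --moving pair/moving.mrc \
    --iters 200 --seed 0 --out result.json --write-aligned aligned.mrc
wemdalign bench --trials 10 --size 32   # seeded rotation-recovery benchmark
```

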