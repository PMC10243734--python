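# projlddmm

Projective diffeomorphic registration of a dense 3D volume onto sparse,
independently distorted 2D sections — and the downstream machinery for
building 3D pathology maps from the aligned sections.

## The problem

Digital pathology produces stacks of thin 2D sections: each section is
cut from the specimen, independently deformed by handling (rigid motion
plus small nonrigid distortion), stained into a contrast unrelated to
the reference 3D image (e.g. postmortem MRI), and corrupted by tears
and missing tissue.  Reconstructing pathology measurements (e.g.
neurofibrillary tangle densities) in the 3D reference frame requires
solving all of these at once: a 3D diffeomorphism of the template, a
per-section in-plane motion, a cross-modality contrast map, and a
per-pixel artifact interpretation.

## The model

The template `I_temp : R^3 -> R` is deformed by a diffeomorphism
`phi`, generated as the flow of a time-dependent velocity field `v_t`
in a Gaussian reproducing-kernel Hilbert space `V`.  A projection
`P_n` slices the deformed volume at plane `z_n` (or applies a Gaussian
point-spread along z for optically sectioned modalities).  Each section
is further deformed in-plane by `phi_n = R_n ∘ chi_n` (rigid plus a 2D
flow `u_{n,t}` in a 2D kernel space `U`).  The observed section `J_n`
is connected to the template's intensity range by a predictive basis:
a 2D Morlet **scattering transform** expands `J_n` into 48
texture-sensitive filtered images at the template resolution (3
channels x 16 paths at J=2 scales, L=3 orientations, order 2), PCA
over pooled tissue pixels reduces them to a shared 6-dimensional
subspace, and per-section coefficients `alpha_n` map the basis to
template intensity by stratified, outlier-robust least squares:

    J_n^alpha(y) = sum_k alpha_n^k psi_n^k(y).

The estimation problem is

    inf over v, {u_n, R_n, alpha_n} of
        lambda_V * int |v_t|_V^2 dt  +  sum_n lambda_U * int |u_{n,t}|_U^2 dt
        +  sum_n  Match( J_n^alpha , phi_n . P_n (I_temp o phi^{-1}) ),

where the matching term is, per pixel, a three-class conditionally
Gaussian mixture (tissue / artifact / background) whose weights are
estimated by EM — tears and background stop influencing the geometry.
Optimization alternates contrast, mixture and geometry blocks
(Gauss-Newton for the rigid motions, kernel-preconditioned Hilbert
gradient flows for `u_n` and `v`, exact adjoints of the discretized
forward chain) over a three-stage schedule: coarse robust alignment,
full-resolution robust refinement, then the mixture interpretation.

Downstream, detected tangles and sampled tissue area are carried as
**particle measures** `sum_i w_i delta_{y_i} (x) delta_{f_i}`:
transport through the estimated maps follows the varifold action
(positions move, weights scale with the in-plane Jacobian, features
ride along), kernel resampling redistributes mass across scales, and
densities over subregion boundary surfaces are smoothed in the
**Laplace-Beltrami eigenbasis** of each surface with Tikhonov
attenuation `1/(1 + k * lambda_i)`.

## Worked example

Generate the default synthetic specimen (96 x 96 x 48 voxel template at
0.125 mm, four nested regions, 8 pseudo-histology sections 0.75 mm
apart with tears over 10% of tissue), register it, and score the
recovery against the generator's ground truth:

```python
import numpy as np
from projlddmm import (PhantomConfig, make_template, simulate_sections,
                       RegistrationConfig, register_stack, map_labels, dice)

cfg = PhantomConfig()
template, labels, _ = make_template(cfg)
stack, truth = simulate_sections(template, labels, cfg)
result = register_stack(template, stack, RegistrationConfig())

errs = [np.linalg.norm(result.section_to_template(n, lm["y_hist"]) - lm["x_temp"], axis=1)
        for n, lm in enumerate(truth.landmarks)]
print("landmark RMS [mm]:", np.sqrt(np.mean(np.concatenate(errs) ** 2)))
print("artifact weight on torn pixels:",
      np.mean([result.weights[n][truth.tear_masks[n].reshape(96, 4, 96, 4).mean((1, 3)) >= 1, 1].mean()
               for n in range(8) if truth.tear_masks[n].any()]))
```

On the default seed this prints

```
landmark RMS [mm]: 0.116
artifact weight on torn pixels: 0.88
```

— landmark pairs recovered to about 0.12 mm (under one template voxel)
through the composite section-to-template maps, with mapped region
labels overlapping the ground truth at Dice 0.93–0.96 per region, and
the mixture assigning 88% posterior artifact weight to fully torn
pixels.  The run takes a few minutes on one CPU.

A command-line interface mirrors the pipeline stages
(`projlddmm phantom|register|transport|surface|nft|evaluate`).

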