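# shellmap

Analytic, FFT-free calculation of atomic-model density maps distorted by
limited — possibly spatially inhomogeneous — resolution and isotropic
positional disorder, for cryo-EM and crystallographic model building and
real-space refinement.

## The problem and the method

Cutting a Fourier synthesis at resolution *D* turns every atom into a blurred
peak surrounded by *Fourier ripples* — spherical shells of sign-alternating
density. Mathematically the *D*-resolution image of an immobile point atom is

    δᵈ(r; D) = (4π/3) D⁻³ G(r/D),      G(x) = 3 (sin u − u cos u)/u³,  u = 2πx,

where *G* is the 3D interference function, the inverse Fourier transform of
the indicator of the reciprocal ball |s| ≤ 1/D (s = 1/d). Positional disorder
is the usual isotropic Gaussian with B-factor *B*, g(r; B) =
(4π/B)^{3/2} exp(−4π²r²/B), whose transform is exp(−B s²/4). There is no
closed form for G ∗ g — which is why model maps are normally computed by two
FFTs and cannot easily carry a different resolution per atom.

shellmap removes that obstacle with a **shell decomposition**: *G* is
approximated by a sum of Gaussian-blurred unit spherical shells,

    G(x) ≈ Σₘ κₘ Ω(x; μₘ, νₘ),
    Ω(x; μ, ν) = (4π/ν)^{3/2} e^{−4π²(x²+μ²)/ν} · sinh(t)/t,  t = 8π²μx/ν,

one term per ripple. Ω has two exact properties that make everything else
closed-form: **disorder transferability** Ω(·; μ, ν) ∗ g(·; B) = Ω(·; μ, ν+B)
and shape conservation under **rescaling**. With per-element multi-Gaussian
scattering factors f(s) = Σₖ aₖ exp(−bₖ s²/4), the model map becomes a single
real-space sum over atoms n, scattering Gaussians k and shell terms m:

    ρᵈ(r) = Σₙ occₙ (4π/3) Σₖ Σₘ aₙₖ κₘ Ω(|r − rₙ|; μₘDₙ, νₘDₙ² + bₙₖ + Bₙ),

evaluated in one pass, with no Fourier transforms, and with every atom
carrying its own resolution *Dₙ* — the mechanism for inhomogeneous-resolution
maps. Alternatively, the oscillating image of one atom type at a fixed *D*
can be decomposed directly (a dozen terms) and disorder applied later by
shifting ν — useful when resolution varies little.

The package contains the fitting machinery that produces such decompositions
(bound-constrained least squares with analytic derivatives, ripple-based
seeding and a minimax polish), a 21-term reference decomposition of *G* for
|x| ≤ 10, packaged electron and X-ray scattering tables, the single-pass map
engine, a direct-summation Fourier-synthesis oracle for validation,
PDB/mmCIF/CCP4 I/O and deterministic toy-model generators.

## Worked example

```python
import numpy as np
from shellmap import (FitConfig, RadialProfile, interference_G,
                      fit_decomposition, evaluate_decomposition,
                      lookup_scattering, numeric_atom_image, transfer_disorder)

# 1. decompose the interference function: 21 terms over |x| <= 10
x = np.arange(0.0, 11.0001, 0.002)
g_fit = fit_decomposition(
    RadialProfile(x, interference_G(x), 1.0),
    FitConfig(n_terms=21, domain_radius=10.0, grid_step=0.002, seed=0,
              n_restarts=0, tail_fraction=0.1),
    target_id="G")
print(f"max |G - fit| = {g_fit.max_error:.2e}")

# 2. decompose the immobile carbon image at D = 2 A, then apply B = 30 by
#    shifting nu -- no recomputation of the image
carbon = lookup_scattering("C", "electron")
r = np.arange(0.0, 10.4001, 0.004)
image = numeric_atom_image(carbon, 2.0, 0.0, r)
c_fit = fit_decomposition(
    image, FitConfig(n_terms=12, domain_radius=8.0, grid_step=0.004, seed=0),
    target_id="C, D = 2 A")
print(f"carbon fit max_error = {c_fit.max_error:.2e}")

shifted = transfer_disorder(c_fit, 30.0)
rr = np.arange(0.0, 8.0001, 0.002)
blurred = numeric_atom_image(carbon, 2.0, 30.0, rr)
dev = np.max(np.abs(evaluate_decomposition(shifted, rr) - blurred.values))
print(f"B-shift vs direct blurred image: {dev / image.origin_value:.2e}")
```

prints

```
max |G - fit| = 5.97e-05
carbon fit max_error = 2.28e-05
B-shift vs direct blurred image: 1.64e-07
```

i.e. 21 shells reproduce the interference function to 6×10⁻⁵ of its maximum,
12 shells reproduce the carbon image at 2 Å to 2.3×10⁻⁵ of its central value,
and applying B = 30 Å² by the ν-shift agrees with the directly computed
blurred image to ~10⁻⁷ — positional disorder costs nothing once an image is
decomposed.

Maps from the command line:

```sh
shellmap synth --preset helix --n 100 --box 40 --seed 1 --out toy.pdb
shellmap assign-d --model toy.pdb --center-d 2 --edge-d 5 --out dn.csv
shellmap map --model toy.pdb --dn-sidecar dn.csv --grid-step 0.5 --out omega.mrc
shellmap fourier-map --model toy.pdb --resolution 2.0 --out fourier.mrc
```

The first map has resolution varying from 2 Å at the model center to 5 Å at
its periphery, computed in a single run; the second is the constant-D
Fourier-synthesis reference.

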