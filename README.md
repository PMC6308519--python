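# lair — limited-angle iterative reconstruction for micro-CT

Limited-angle (LA) CT acquires projections over only part of the angular
range — here 90° of 360° — cutting radiation dose to roughly a quarter of a
full scan, at the price of a missing band in the sinogram that analytic
reconstruction turns into severe streaking. `lair` implements a two-step
remedy for small-animal micro-CT, entirely on synthetic data:

1. **Sinogram completion.** A fan-beam sinogram repeats after 360°, so a
   full scan extends to 450° by copying its first 90° of rows. The LA
   acquisition is the same array with the [90°, 360°) band zeroed. A
   context-encoder GAN — conv encoder, channel-wise fully-connected
   bottleneck, conv decoder emitting only the band, plus a small
   discriminator — is trained with masked-region L2 + adversarial loss to
   inpaint the band from its context.
2. **Reconstruction.** The completed sinogram is folded back to 360° and
   reconstructed by fan-beam FBP or by TV-constrained iterative solvers —
   EM-TV (multiplicative MLEM fidelity + TV descent) and ASD-POCS (relaxed
   SART + adaptive-steepest-descent TV) — solving
   `argmin_f U(f) + λ‖f‖_TV  s.t. f ≥ 0` over the exact ray-tracing system
   matrix `p = A f` (`a_ij` = intersection length of ray *j* with pixel *i*).

Iteration is stopped on image quality rather than pixel error: among
iterates whose PSNR against a reference exceeds *k* = 35 dB, the score
`UIQI − rTV` is tracked and the best iterate is returned once it stops
improving, where UIQI is the universal image quality index and
`rTV = ‖f*‖_TV / ‖f‖_TV` compares edge content with the reference.

The package is for people studying dose-reduced CT protocols: it provides
the geometry/protocol arithmetic, a Siddon projector with matched adjoint,
phantom and QA-object generators, the LA manipulation chain, the completion
network (a compact self-contained CPU implementation), both iterative
solvers, and the full figure-of-merit suite (PSNR, UIQI, SSIM, rTV, CNR,
SNR, Gaussian-fit FWHM, HA linearity).

## Worked example

```python
import numpy as np
from lair.fbp import fbp_reconstruct
from lair.metrics import psnr
from lair.phantom import shepp_logan
from lair.pipeline import desk_quality_geometry
from lair.projector import build_system_matrix
from lair.sinogram import Sinogram

n, vox = 128, 0.5
geom = desk_quality_geometry()
phantom = shepp_logan(n) * 0.025          # attenuation in mm^-1

for label, angles in (("DSFC", np.arange(0, 360, 1.0)),
                      ("LA  ", np.arange(0, 90, 1.0))):
    A = build_system_matrix(geom, angles, n, vox)
    sino = Sinogram(A.forward(phantom), 1.0, geom.det_pitch_um)
    rec = fbp_reconstruct(sino, geom, n, vox)
    print(label, f"PSNR {psnr(rec, phantom):.2f} dB")
```

prints

```
DSFC PSNR 32.91 dB
LA   PSNR 12.19 dB
```

— the full-coverage scan reconstructs faithfully (and recovers absolute
attenuation to within a few percent: the centre pixel reads 0.0238 mm⁻¹
against a 0.0255 mm⁻¹ truth), while the 90° scan loses ~21 dB to the missing band. The scripts in
`examples/` walk through each capability: geometry arithmetic
(69.00 µm / 17.4088 µm isocenter voxels, 90/360/72 views per protocol),
projection + FBP, iterative reconstruction with the stopping rule, training
the completion network, and the QA-phantom figures of merit. A thin CLI
mirrors the stages (`lair simulate | project | ce-train | ce-inpaint |
fbp | recon | iq | demo`); `lair demo` runs the end-to-end quickstart.

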