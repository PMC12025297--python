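# eitrpca

Spike-noise removal for thoracic electrical impedance tomography (EIT)
recordings by low-rank + sparse matrix decomposition, with a full synthetic
evaluation pipeline: a 16-electrode finite-element forward simulator,
GREIT-style time-difference image reconstruction, and the image-quality and
clinical ventilation metrics used to judge denoising.

## Who this is for

EIT records boundary voltages on a chest electrode belt at video rate and
reconstructs regional lung ventilation at the bedside. In clinical use the
signal is regularly hit by *spike-like noise* — brief, large-amplitude
disturbances from electrode-contact problems or patient movement — which can
bury the ventilation image in artefact. This package is for researchers and
engineers who need to clean such recordings offline, or to benchmark
spike-robust processing against per-channel filtering.

## The method

A recording is a matrix `D` (192 channels × T frames). All channels watch
the same breathing, so the clean signal `L` is near rank-one; spikes `S` are
sparse. The decomposition solves

```
min ‖L‖* + λ‖S‖₁   subject to  D = L + S
```

(nuclear norm + weighted entrywise ℓ1) by an augmented-Lagrangian ADMM:
singular-value thresholding for `L`, entrywise soft-thresholding for `S`,
and a multiplier ascent step, with defaults λ = 0.01, penalty λ₀ = 10,
tolerance ε = 1e-8 (relative Frobenius). `L` is the denoised recording;
`S` is the isolated spike content. See `docs/methods.md` for the model,
conventions and parameter discussion.

## Worked example

```python
import numpy as np
from eitrpca import (
    make_phantom, synth_breathing, forward_voltages, inject_spikes,
    SpikeSpec, rpca_denoise, RPCAConfig, build_reconstructor,
    pick_reference_frame, reconstruct_series, feit_image, index_report,
)

phantom = make_phantom("thorax")
breathing = synth_breathing(n_frames=600)        # 30 s at 20 fps
clean = forward_voltages(phantom, breathing)     # 192 x 600 voltages

# contaminate channel 35 with a 50-frame spike at 50x amplitude
spec = SpikeSpec(channels=frozenset({35}), frame_window=(299, 348), magnitude=50)
noisy = inject_spikes(clean, spec)

denoised, spikes = rpca_denoise(noisy, RPCAConfig())

model = build_reconstructor(phantom)
ref = pick_reference_frame(clean, 255)           # -> 241 (end-expiration)
f_clean = feit_image(reconstruct_series(model, clean, ref))
f_noisy = feit_image(reconstruct_series(model, noisy, ref))
f_rpca = feit_image(reconstruct_series(model, denoised, ref))

for name, img in [("raw", f_noisy), ("rpca", f_rpca)]:
    rep = index_report(img, ref=f_clean)
    print(f"{name}:  corr={rep.img_corr:.4f}  err={rep.img_err:.4g}  "
          f"CoV_err={rep.deltas['cov']:.3f}")
```

Output:

```
raw:  corr=0.2268  err=9.088  CoV_err=11.925
rpca:  corr=0.9990  err=0.001976  CoV_err=0.077
```

The un-denoised fEIT image is dominated by the spike artefact (correlation
0.23 with the clean image, error ≈ 9, centre of ventilation off by ~12 % of
thoracic depth); after the decomposition the image is essentially restored
(correlation 0.999, error 0.002, CoV error 0.08 %).

A console script mirrors the pipeline:
`eitrpca simulate | denoise | baseline-filter | reconstruct | score |
reproduce` (see `eitrpca --help`).

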