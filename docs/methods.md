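# Methods

## Problem and model

Thoracic electrical impedance tomography (EIT) records, at 20 frames/s, the
boundary voltages induced by small injected currents on a 16-electrode belt.
Under the opposite-excitation / adjacent-measurement scheme each frame holds
12 × 16 = 192 channel voltages, and a recording of T frames forms a
192 × T matrix **D**. All channels see the same underlying respiratory
modulation, so clean recordings are very close to rank one (on our simulated
study data the first singular value carries ≈ 97.5 % of the spectrum's
total). Electrode-contact problems and patient movement add brief,
large-amplitude disturbances to a small subset of entries — spike-like
noise, sparse relative to the recording.

The package models the recording as

```
D = L + S,      min ‖L‖* + λ‖S‖₁  s.t.  D = L + S
```

with **L** low rank (the respiratory signal) and **S** sparse (the spikes),
solved by an augmented-Lagrangian ADMM with penalty λ₀:

```
L ← svt(D − S + μ/λ₀, 1/λ₀)
S ← soft(D − L + μ/λ₀, λ/λ₀)
μ ← μ + λ₀ (D − L − S)
```

starting from S = μ = 0, L updated first, stopping when
‖D − L − S‖_F ≤ ε·max(1, ‖D‖_F). The *relative* stopping rule is a
deliberate deviation from a raw absolute Frobenius threshold: clinical
voltages carry an arbitrary scale, and an absolute 1e-8 may be unreachable
(or trivially reached) depending on the device's units.

### Parameters

| name | default | meaning |
|------|---------|---------|
| `lam` (λ) | 0.01 | weight of the sparsity term; larger values push less of the recording into S |
| `rho` (λ₀) | 10 | augmented-Lagrangian penalty; its inverse is the per-iteration singular-value shrinkage |
| `eps` (ε) | 1e-8 | relative Frobenius stopping tolerance |
| `max_iter` | 1000 | iteration cap; exceeded ⇒ `converged=False` + warning, never an exception (partial splits are diagnostically useful) |

The defaults suit voltage matrices on the scale this kind of hardware
produces. They are *not* scale free: the proximal steps 1/λ₀ and λ/λ₀ are
absolute thresholds, so on matrices with entries of order 1–100 the
exchange between L and S slows to a crawl. `RPCAConfig.scaled_for(D)`
provides a scale-aware preset — λ = 1/√max(m, n) (the standard
principal-component-pursuit weight, exposed as `candes_lambda`) and
λ₀ = 1.25/σ₁(D) — which converges in tens of iterations on generic
low-rank + sparse mixtures and is what the exact-recovery property tests
use. On the simulated study recordings the study defaults plateau around a
relative residual of 5e-5 at the iteration cap; this has no measurable
effect on any downstream image metric, and the result is returned with
`converged=False`.

## Synthetic data generator

The generator stands in for a clinical recording and its conditions are
fixed, not tuning knobs:

* **Phantom** — a triangulated 2-D disc (~2100 first-order elements),
  optionally flattened to a chest-like ellipse (dorso-ventral axis 80 % of
  lateral). Two elliptical lung inclusions; background 1 S/m. The
  heterogeneous variant splits the left lung into ventral/dorsal halves.
  This deliberately replaces any CT-derived anatomical mesh: the robustness
  claims under test concern the data-matrix structure, not anatomy.
* **Breathing** — a raised-cosine modulation w(t) ∈ [1 − depth, 1] of lung
  conductivity, default 15 breaths/min, depth 0.5, 600 frames at 20 fps
  (30 s), with optional seeded cycle-to-cycle jitter. "Area 1" lung regions
  take conductivity w(t); "area 2" regions 0.15·w(t). A real recorded
  breathing trace is irregular and non-sinusoidal; any periodic surrogate in
  (0, 1] is admissible here, which is why the headline quantities are
  checked as bounds rather than exact figure values.
* **Forward model** — complete electrode model, first-order FEM, contact
  impedance 0.01 Ω·m per electrode arc, 1 mA opposite-pair excitation.
  Channel values are demodulated voltage *amplitudes* |U_c − U_d|: the
  signed adjacent-pair differences telescope to ≈ 0 when summed around the
  ring, and acquisition systems report non-negative digital voltages. The
  per-frame all-channel sum then anticorrelates with lung conductivity
  (r ≈ −0.997 on defaults), reproducing the usual global respiration
  waveform. Frames with identical modulation values share one FEM solve.
* **Spikes** — multiplicative: selected entries are multiplied by the spike
  magnitude. The three published sweep protocols are hard-coded
  (magnitudes 1–100 at channel 35 / frame 299; widths 5–100 frames from
  frame 299 at magnitude 50; channel counts 5–192 over frames 300–350 at
  magnitude 50), plus a heterogeneous-lung case with 50 seeded-random
  channels, width 61, magnitude 27. Channel and frame indices are 1-based
  at this surface.

What the generator does **not** emulate: measurement noise floors, cardiac
and perfusion signals, electrode-position uncertainty, baseline drift
(step-like noise), and breath-to-breath variability of a real subject.
Passing tests therefore demonstrate the pipeline's behaviour under idealised
spike contamination of structurally realistic recordings, not clinical
performance.

## Reconstruction

Time-difference imaging onto a 32 × 32 grid by a linear GREIT-style matrix.
Training: ~300 small conductivity-*decrease* targets (radius 5 % of the
domain radius) on a uniform grid inside the homogeneous phantom; their
difference voltages are linearised through the FEM sensitivity (adjoint)
matrix; desired images are narrow Gaussians (σ = 8 % of the radius); the
reconstruction matrix is the ridge-regularised least-squares map from
voltages to desired images (regularisation 3e-2 of the mean data
eigenvalue, standing in for a noise-figure criterion). All hyperparameters
are exposed. Rows for out-of-body pixels are zeroed, so masked pixels are
exactly 0 in every image.

Conventions fixed here (they matter for every index downstream): ventral at
the top image row, the subject's right on the left image column; training
on conductivity decreases with positive desired blobs makes inspiration
reconstruct as positive pixels. The reference frame for difference imaging
is auto-picked as the local minimum of the all-channel voltage sum (an
end-expiration) nearest a requested frame, ties to the earlier frame; with
the default waveform and the protocols' neighbourhood of frame 255 this
lands on frame 241.

The functional EIT (fEIT) image is the per-pixel population standard
deviation over the series (sample SD by flag).

## Metrics

Image correlation is plain Pearson over all 1024 pixels. Image error is
`sqrt(Σ (test−ref)²) / Σ |ref|` — the formula implemented verbatim; note it
is *not* divided by √N, so it is a summed-error ratio rather than a true
RMS ratio. CoV normalises the row distance by 31 so it reads as percent of
thoracic depth (uniform image → 50 %). GI uses the median over in-mask
pixels by default, with an optional ROI argument for the lung-restricted
clinical variant. VtoD/RtoL split the grid at row/column 16. The group
comparison is a two-sided equal-variance t-test (Welch by flag).

## Study orchestration and problem sizes

The sweep runners simulate one clean 192 × 600 recording, train one
reconstructor, then per spike spec: inject, denoise (RPCA on the full
matrix — offline processing), reconstruct, score. The magnitude sweep
scores the single image at the spike frame; width/channel/filter studies
score fEIT images of the whole series. These sizes (600 frames, ~2100
elements, ~300 training targets) were chosen as the smallest that keep the
recording several breathing cycles long and the protocols' frame references
(255–359) meaningful; each RPCA run on 192 × 600 takes on the order of ten
seconds at the iteration cap.

## Known limitations

* The absolute values of image metrics depend on the surrogate waveform and
  reconstruction hyperparameters; only orderings and bound-type statements
  are stable, which is what the acceptance surface asserts.
* The decomposition is offline; no streaming variant is provided.
* λ is fixed per dataset; no automatic selection (cross-validation or
  L-method style) is implemented.
* Step-like (baseline-shift) noise is out of scope.
* The forward model is 2-D; out-of-plane current spread of a real thorax is
  not represented.
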