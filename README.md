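# esgrade

Echo-envelope-statistics (ES) parametric imaging and CNN grading of
hepatic steatosis, with a synthetic speckle cohort generator so the whole
pipeline runs and is testable without clinical data.

Fat droplets deposited in liver parenchyma change the scatterer population
of the tissue and, with it, the statistics of the B-mode echo envelope.
`esgrade` turns those statistics into images a classifier can grade:

1. **Iterative speckle normalization** — the envelope `x` is divided by
   the square root of its local second-order moment
   `M₂(i,j) = E[x_k²]`, computed over a 4.6 × 10.8 mm elliptical window,
   removing focus/gain/attenuation brightness; pixels above `3·√M₂` are
   iteratively excluded as non-speckle.
2. **Parametric images** — local moment maps `M₁` and `M₄` over a
   3.0 × 8.1 mm window, plus a moment heat map (2-D histogram of per-pixel
   (M₁, M₄) pairs).  After normalization these are scale-free shape
   descriptors: Rayleigh speckle gives M₁ = √π/2 ≈ 0.886 and M₄ = 2;
   for a Nakagami amplitude with shape m, M₁ = Γ(m+½)/(Γ(m)√m) and
   M₄ = (m+1)/m.
3. **ROI extraction** — 20 mm square ROIs (400 px at 50 µm spacing) on a
   4 mm grid, kept only if < 1% of their pixels are invalid, subsampled
   per case.
4. **CNN classification + hard voting** — case-grouped four-fold
   cross-validation into grades G0 (MRI-PDFF < 5.2%), G1 (5.2–11.3%) and
   G2-3 (≥ 11.3%); each case's grade is the majority vote of its ROI
   predictions.

Intended users: quantitative-ultrasound researchers who want a tested,
reproducible reference implementation of moment-based parametric imaging
and its evaluation loop, and anyone who needs controllable Nakagami /
convolved speckle phantoms with ground-truth statistics.

## Worked example

```python
from esgrade import (SpeckleConfig, simulate_speckle_field,
                     iterative_normalize, build_moment_maps)

field = simulate_speckle_field(SpeckleConfig(
    mode="iid", shape_m=1.0, omega=1.0, image_size_mm=(25.6, 25.6), seed=7))
norm = iterative_normalize(field)
m1, m4 = build_moment_maps(norm)
print(f"sweeps: {norm.iterations_run}, excluded non-speckle pixels: {norm.excluded.sum()}")
print(f"mean M1 = {m1.mean():.4f}   (Rayleigh closed form 0.8862)")
print(f"mean M4 = {m4.mean():.4f}   (Rayleigh closed form 2.0)")
```

prints

```
sweeps: 2, excluded non-speckle pixels: 42
mean M1 = 0.8869   (Rayleigh closed form 0.8862)
mean M4 = 1.9846   (Rayleigh closed form 2.0)
```

A 512 × 512 Rayleigh field normalizes in two sweeps; 42 of 262 144 pixels
(1.6 × 10⁻⁴) exceed the 3·√M₂ threshold, matching the Rayleigh tail
probability e⁻⁹ ≈ 1.2 × 10⁻⁴ within binomial noise.  The map means land
on the closed forms (M₄ slightly below 2 because the exclusion truncates
the amplitude tail; the exact truncated expectation is ≈ 1.99).

## Command line

```sh
esgrade simulate   --config config.yaml --outdir run   # synthetic cohort
esgrade process    --config config.yaml --outdir run   # normalize, maps, ROIs
esgrade train-eval --config config.yaml --outdir run   # 4-fold CV, report
esgrade report     --config config.yaml --outdir run   # markdown + plots
```

All stages are seeded, stamp outputs with a config hash, and skip
themselves under `--resume` when their outputs already exist.

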