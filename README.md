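# mirfluor

Simulation and evaluation toolkit for **multimodal mid-infrared (MIR) +
autofluorescence tissue imaging**.

Label-free chemical imaging of tissue sections faces a three-way trade-off
between speed, spatial resolution and chemical specificity. A four-laser
flying-spot MIR scanner maps lipid and protein distributions (CH₂ stretch at
2928 cm⁻¹, NH stretch at 3352 cm⁻¹, with 3704/2792 cm⁻¹ reference lasers for
the scattering baseline) in seconds per cm², but its ~20 µm spot cannot
resolve the 5–20 µm structures — myelinated fiber bundles, fine
protein-rich networks, microvasculature — that matter for anatomical
segmentation. Full-spectrum FTIR imaging at 6.25 µm resolves them, at the
cost of hours per section. Adding a co-registered autofluorescence camera
path (endogenous collagen/elastin, flavin and lipopigment contrast at 4 µm)
promises FTIR-like segmentation quality at scanner-like speed.

Real tissue has no pixel-level ground truth, so that claim is hard to test
quantitatively. `mirfluor` replaces the tissue with a **synthetic brain-like
phantom** (background, ventricle, gray matter, white matter, reticular fine
structure, each with known chemical and fluorophore composition), runs
physics-based forward models of *both* acquisition paths, and pushes the
simulated data through the same processing-and-clustering chain used for
real data — so every segmentation can be scored against a known answer. It
is aimed at instrument developers and image-analysis researchers who need a
controlled testbed for multimodal fusion and clustering pipelines.

## What is modeled

- **Beer–Lambert forward model.** Per band ν, chemical absorbance
  `A(x,y) = Σ_s ε_s(ν)·c_s(x,y)·l` over species s ∈ {lipid, protein, water}
  with section thickness l = 10 µm, plus a scattering baseline
  `B(x,y,ν) = scatter(x,y)·(b₀ + b₁·ν)` that is linear in wavenumber and is
  all the reference lasers see.
- **Flying-spot scanner.** Gaussian spot of 22 µm 1/e² diameter (σ = d/4),
  raster comb at 20 µm (native) or 5 µm (super-sampling, giving 10 µm
  resolution), transduction `counts = i_ref·10^(−⟨A_eff⟩_spot) + noise`
  against the bare gold-coated slide, clipped to 16 bits.
- **FTIR-like reference modality.** Same physics with exact square-pixel box
  averaging at 6.25 or 25 µm and ideal background subtraction; a 10-band set
  (the 4 laser lines plus OH, CH, amide I/II/III and C–O bands).
- **Autofluorescence camera.** Gaussian excitation/emission spectra for
  collagen/elastin, flavins and lipopigments; LED×filter coupling
  coefficients with deliberate spectral crosstalk; a cooled-CCD model
  (Poisson shot noise, 9 e⁻ read noise, 0.25 e⁻/s dark current, 0.6 e⁻/ADU
  gain) at a 4 µm sample-plane pitch.
- **Processing chain.** Count normalization → absorbance against the gold
  reference → dual-reference scattering correction (exact for the
  linear-in-ν baseline) → bicubic upscaling to the 4 µm fusion grid →
  phase-correlation registration → per-layer z-scoring → K-means (k = 5,
  k-means++ seeding, 10 restarts) → Davies–Bouldin index and adjusted Rand
  index (ARI) evaluation, including cross-resolution comparison by
  nearest-neighbour resampling, harmonized-label registration and cropping.
- **Resolution validation.** Synthetic 1.25–250 lp/mm line gratings scanned
  noiselessly; modulation measured as a phase-insensitive Fourier amplitude,
  thresholded at 0.2.

## Worked example

```python
import mirfluor as mf
from mirfluor.phantom import PhantomConfig

cfg = mf.RunConfig(
    seed=11,
    phantom=PhantomConfig(width=256, height=256),   # 512×512 µm at 2 µm pitch
    modalities=("mir20", "multimodal", "ftir6.25", "ftir25"),
)
report = mf.run_experiment(cfg)
print(report.ari_truth)
```

prints

```
{'mir20': 0.674, 'multimodal': 0.915, 'ftir6.25': 0.811, 'ftir25': 0.646}
```

Reading: against the known phantom labels, the coarse 20 µm MIR scan reaches
ARI 0.674 (it cannot see the fine reticular structure), 6.25 µm FTIR does
much better (0.811) and degrades when its pixels grow to 25 µm (0.646),
while fusing the super-sampled MIR scan with the 4 µm autofluorescence
channels is best of all (0.915). The same report carries Davies–Bouldin
indices per segmentation and the pairwise ARI matrix — here
ARI(FTIR 6.25, multimodal) = 0.795 versus ARI(FTIR 6.25, mir20) = 0.647,
i.e. the fused modality, not the coarse scan, is the faithful stand-in for
slow high-resolution FTIR.

The numbered drivers under `analysis/` run the full studies (grating
resolution, spectral richness, spatial resolution, multimodal fusion over
25 replicates) and write their tables to `results/`. A thin CLI mirrors
them: `mirfluor experiment --seed 11 --out runs/demo`,
`mirfluor grating --raster 5 --out runs/grating`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the grating-resolution figure of merit `t1`: it
generates binary 50 %-duty gratings at each of the 18 ladder frequencies on
a 1 µm grid, convolves with the 22 µm (1/e²) Gaussian spot, samples on the
5 µm raster comb, estimates modulation as twice the Fourier-coefficient
magnitude at the grating frequency over the profile mean, and reports the
highest frequency with modulation ≥ 0.2, in lines/mm.

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
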