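# Methods

This note documents the models behind `mirfluor`, the parameter choices that
matter, what the synthetic world does and does not emulate, and the
numerical conventions a user should know before trusting (or extending) a
result.

## 1. The phantom: a stated world

Every experiment starts from a seeded synthetic "coronal section" on a fine
ground-truth grid (default 2 µm pitch, 512×512 px ≈ 1×1 mm). Five classes:

| class | chemistry (a.u.) | fluorophores (a.u.) | rationale |
|---|---|---|---|
| background | all 0 | all 0 | bare gold-coated slide |
| ventricle | lipid 0.05, protein 0.25, water 0.60 | all ≤ 0.1 | dilute, water-rich CSF residue |
| gray matter | lipid 0.45, protein 1.00, water 0.10 | collagen/elastin 0.25, flavin 0.35, lipopigment 0.90 | protein-rich cell bodies; lipofuscin-like autofluorescence |
| white matter | lipid 1.20, protein 0.55, water 0.10 | collagen/elastin 0.60, flavin 0.90, lipopigment 0.35 | compact myelin; FAD- and matrix-rich |
| fine structure | lipid 0.35, protein 1.50, water 0.10 | collagen/elastin 0.90, flavin 0.50, lipopigment 0.70 | extremely protein-rich reticular network |

Concentrations are arbitrary units: no quantitative tissue reference exists
for them, so they were chosen **once** for class separability (pairwise mean
distance ≥ 3× within-class spread at the default cv = 0.1, asserted by a
test) and to encode the orderings expected of brain compartments:
white matter most lipid-rich and strongest in flavin/collagen-elastin
autofluorescence, gray matter more protein-rich and dominant in
lipopigments. Tissue water is low and uniform (desiccated-section state);
the ventricle keeps a higher water level, which couples into the
3352/3450 cm⁻¹ bands and makes hydration effects testable.

Geometry: a wobbled tissue ellipse; two tilted ventricular ellipses; four
curved white-matter bands (wobbled elliptical annuli) with widths log-spaced
from the minimum (5 µm) to the maximum (100 µm) structure width, capped at
0.22× the effective tissue radius so white matter stays a minority class on
small fields; and a reticular fine-structure network formed by the zero
level-set of a smooth Gaussian random field (kernel 12 µm, ridge width
~8 µm — inside the 5–20 µm range of interest). Within-class texture is
log-normal with unit mean (positivity by construction), clipped to
mean·(1±5 cv); cv = 0 yields exactly piecewise-constant fields. The
scattering baseline is a smooth strictly-positive log-normal field
(~50 µm correlation FWHM) modulating softly-blended per-class levels; the
background level (0.02) is small but nonzero, so a reference-laser image of
a bare-substrate phantom is uniform at the gold level to within a few
percent rather than exactly.

The phantom grid pitch (2 µm) is constrained to at most half the minimum
structure width so the ground truth itself is never aliased by the 4 µm
camera grid or the 5 µm raster comb.

## 2. MIR forward model

Chemical absorbance per band is the additive multi-species Beer–Lambert law
A = Σ_s ε_s·c_s·l with l = 10 µm section thickness. Band absorptivities
follow the standard vibrational assignments: 2928 cm⁻¹ CH₂-stretch
lipid-dominant (ε lipid 0.06, protein 0.01), 3352 cm⁻¹ NH-stretch
protein-dominant with a water contribution (ε protein 0.05, water 0.05,
lipid 0.008); the 3704 and 2792 cm⁻¹ reference lasers have zero tissue
absorptivity. The 10-band FTIR-like set adds OH (3450), CH (2878),
amide I/II/III (1655/1550/1320) and C–O (1159) with protein- or
lipid-weighted ε of the same order.

The scattering baseline is `B = scatter·(b₀ + b₁·ν)` with b₀ = 0.2,
b₁ = 10⁻⁴ per cm⁻¹ — **linear in wavenumber by design**, which makes the
two-reference correction (linear interpolation between the 2792 and
3704 cm⁻¹ absorbances) algebraically exact in the noiseless limit. This is
the strongest idealization in the package: it encodes the instrument's
working assumption that reference-laser subtraction isolates chemical
absorption. A sub- or super-linear baseline would leave a residual the
pipeline cannot see.

The flying-spot scanner interprets the quoted spot size as the 1/e²
intensity diameter of a Gaussian beam (beam-profiler convention), σ = d/4 =
5.5 µm for the 22 µm spot. Scanning is: Gaussian-weighted average of
A_eff on the fine grid → sampling on the raster comb at positions j·step
(so a 20 µm comb is an exact 4× decimation of a 5 µm comb; a property test
pins this) → `counts = clip(i_ref·10^(−⟨A_eff⟩) + η, 0, 65535)` with
additive Gaussian detector noise (default sd 50 counts — the instrument
quotes only a detectivity, not an image-noise model) and i_ref = 58 000
counts for the bare gold reference. Count images are kept as *floats*; the
noiseless inverse `to_absorbance ∘ scan` then reproduces the spot-averaged
A_eff to 1e−9 (tested), which integer quantization would destroy.
Quantization happens only on 16-bit TIFF export.

The FTIR-like modality swaps the Gaussian spot for exact area-weighted box
averaging (integral-image implementation, exact for any pitch ratio) and an
ideal background subtraction, returning absorbance directly with small
additive noise (default sd 0.01). Interferometric effects and apodization
are not modeled.

## 3. Autofluorescence forward model

Published data give peak positions and ranges, not curves, so all spectra
are Gaussians: collagen/elastin exc 340±18 nm → em 420±20 nm; flavins
exc 360±15 and 450±15 → em 530±30; lipopigments exc 450±45 → em 590±55
(sigmas). LED lines at 355/395/435/440 nm (σ 8 nm) and band-pass filters
400/10, 440/10, 550/40 nm (FWHM). The coupling of fluorophore f to a
channel is `k = yield · overlap(exc, LED) · overlap(em, filter)` where each
overlap is the Gaussian product integral normalized to 1 at coincident
centers, `exp(−Δc²/(2(σ₁²+σ₂²)))` — a closed form cross-checked in tests
against numeric integration. The expected photoelectron rate sums over
**all** fluorophores and the channel's LEDs: crosstalk between the broad,
overlapping emission bands is deliberately retained, which is why the API
exposes only relative count images and never absolute concentrations.

The default plan is the four designed channels (collagen/elastin via
355→400 and 355→440, lipopigments via 440→550, flavins via 355+440→550);
the schema accepts additional LED/filter combinations but they are not in
the default plan. LED `power` (800 e⁻/s per concentration unit at unit
coupling) and exposures of 10–20 s were chosen once to give mid-range ADU
with shot-noise-limited SNR; quantum yields (1.0 / 0.55 / 0.7) are relative.

Camera: optical blur of 3 µm FWHM (the resolution bound of the camera
path), box resampling to the fixed 4 µm sample-plane pitch (sensor pitch
and zoom optics are absorbed, not modeled separately), then
`ADU = clip(round((Poisson(rate·t + dark·t) + N(0, read_noise))/gain), 0, 65535)`
with gain 0.6 e⁻/ADU, read noise 9 e⁻, dark current 0.25 e⁻/s. AF counts
*are* integers; their tests are statistical (dark-frame mean, exposure
linearity, shot-noise variance law). Note the dark-frame identity
mean = dark·t/gain only holds with negligible read noise — with 9 e⁻ read
noise, clipping negatives at zero biases the mean — so the dark-frame test
runs in the read-noise→0 limit. Photobleaching and spectral unmixing are
out of scope.

## 4. Processing and fusion

Counts are normalized by 65 535; absorbance uses the normalized gold level
with floor 1/65 535 (one count) inside the log. Scatter-corrected target
layers may contain small negatives under noise; they are retained, since
clipping would bias cluster means. Upscaling to the 4 µm fusion grid is
bicubic with output size rounded toward coverage; label images are only
ever resampled nearest-neighbour.

Registration is phase correlation with sub-pixel refinement on a 0.05 px
grid (reported to 0.1 px; measured shifts at or below 0.1 px are treated as
zero). Inside `assemble_cube`, layers are registered to the first
autofluorescence layer via their **gradient magnitudes**: cross-modality
layers can have opposite contrast (e.g. lipopigment vs collagen images),
and edges co-locate regardless of contrast sign. Implausible shifts
(>10 % of the field) are discarded. This registration genuinely matters
even in simulation: the raster comb (samples at j·step) and the box-pixel
camera grid have different origin conventions, leaving a real sub-pixel
inter-modality offset that the registration removes. Assembly crops to the
common overlap and z-scores each layer (zero mean, unit variance) so MIR
absorbances and AF counts contribute comparably to the Euclidean K-means
metric — the minimal scaling that makes mixed-unit clustering meaningful.
Assembly is idempotent on an already-assembled cube.

The pipeline clusters scatter-corrected absorbances by default; a switch
(`use_corrected=False`) clusters raw normalized target-band absorbances
instead, since the original processing chain does not specify which was
used.

## 5. Segmentation and evaluation

K-means is Lloyd's algorithm with k-means++ seeding, best of 10 restarts
(the default reading of "10 iterations of the enhanced center
initialization"; the alternative — 10 k-means++ candidate draws feeding one
Lloyd run — is exposed as `init_mode="candidates"`). k = 5 by default
(background, ventricle, gray, white, fine structure); `sweep_k` selects k
by Davies–Bouldin minimum when wanted. Nearest-centroid assignment breaks
ties toward the lowest centroid index, documented for reproducibility.

ARI is computed from the contingency-table pair-counting formula and is
pinned, instance by instance, to a brute-force enumeration over all item
pairs (n ≤ 200) plus hand-evaluated cases; Davies–Bouldin is pinned to a
hand-computed instance and to scikit-learn's implementation. Dice and NMI
are deliberately absent: they are fragile under the resampling and cropping
this comparison protocol requires. Cross-resolution comparison resamples
the coarser label map (nearest-neighbour) to the finer pitch, harmonizes
the second map's labels to the first by maximum-overlap assignment
(replacing the manual color/order matching a human would do), registers the
harmonized maps by translation, crops to the intersection and reports the
ARI. Harmonization before registration is essential — phase correlation on
arbitrarily-permuted label values finds spurious shifts — and never changes
the ARI itself, which is permutation-invariant.

## 6. Grating resolution analysis

Binary 50 %-duty bar targets on a 1 µm grid, with pixel-edge area
antialiasing (8×8 subpixel sampling) so the realized duty — and hence the
square-wave fundamental — is unbiased when the period is not an integer
pixel count. The 18-step ladder 1.25…250 lp/mm names only its endpoints and
count in the source material; the intermediate values follow a standard
1–1.25–1.6–2–2.5 resolution-target progression. Modulation is measured by
least-squares projection of the scanned profile onto
{1, cos 2πfx, sin 2πfx} at the exact grating frequency (a phase-insensitive
Fourier coefficient, robust to sampling incommensurate with the period),
normalized by the 4/π square-wave fundamental factor so an ideal system
scores 1. Frequencies at or above the raster comb's Nyquist limit
(1000/(2·step) lp/mm) are reported as contrast 0 with an aliasing flag;
sampling exactly at Nyquist is phase-degenerate, so "at or above" is the
conservative reading. The resolvability threshold is modulation ≥ 0.2 —
"clearly visualized" is not otherwise quantified. With the 22 µm spot and
5 µm raster the measured curve matches the closed form
(π/4)·(4/π)·exp(−2π²σ²f²) within 2–3 % and the limit is 50 lp/mm; with the
20 µm raster the limit is Nyquist-bounded at 20 lp/mm.

## 7. What a green test does and does not establish

The phantom is a favorable world by construction: classes are separable,
noise is moderate, the scattering baseline is exactly linear in wavenumber,
and the two modalities are intrinsically co-registered up to a sub-pixel
grid offset. Green ordering tests (fusion > coarse MIR; 6.25 µm > 25 µm
FTIR, each in ≥90 % of 100 seeded replicates) therefore establish that the
*pipeline* recovers resolution and fusion benefits when they exist — not
that any particular ARI value would be observed on real tissue, where
composition overlaps, baselines misbehave and registration errors are
larger. The exact-recovery test (ARI = 1.0 at k = 5) runs on the
idealized noiseless cv = 0 cube built directly from the phantom fields
(exact corrected absorbances + exact photoelectron rates at the truth
grid): any finite spot, PSF or pixel footprint mixes class vectors at
boundaries, so exact label equality through the degraded chain is
unattainable by construction, and the test isolates the clustering
algebra instead. Absolute ARIs from the original tissue study are not
reproduction targets: they were measured on undeposited real data at
centimeter scale.

## 8. Performance envelope

A full four-modality experiment on a 256×256 phantom runs in ~0.3 s on one
CPU; the 100-replicate ordering study takes ~30 s; the default 512×512
experiment stays well under two minutes. Seeds derive from a single run
seed via `numpy.random.SeedSequence` spawning, so every stage is
independently reproducible and all derived seeds stay below 2³¹.
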