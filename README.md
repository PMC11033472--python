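# modmap

Quantification of the modular (patch/interpatch) organization of horizontal
connections in mouse primary visual cortex (V1), from tangential flatmount
sections.

Layer 1 of mouse V1 is tiled by ~100 µm-scale modules defined by M2
muscarinic acetylcholine receptor immunostaining: M2+ patches (which receive
dLGN input) alternate with M2− interpatches (which receive higher-order
thalamic and feedback input). `modmap` implements the image-analysis chain
used to ask whether tracer-labeled horizontal axons, cell bodies and apical
dendrites prefer one module class:

1. **Segmentation** — the fluorescence image is locally normalized (each
   pixel divided by the mean intensity of a surrounding 100 µm-radius disc),
   blurred with a 30 µm-radius circular averaging filter, and partitioned
   into six equal-count intensity quantiles (sextiles). The top two
   sextiles are M2+ patches, the bottom two M2− interpatches.
2. **Registration** — serial tangential sections are aligned to the L1
   reference frame with projective (homography) transforms fitted to
   blood-vessel landmark correspondences by normalized DLT least squares;
   the L1 module map is transported down the stack, and section indices map
   to layers (L1: sections 1–2, L2-4: 3–7, L5: 8–12, L6: 13–16).
3. **Quantification** — ROI optical density per sextile, radial density
   profiles around the injection centre (annulus sums per module class,
   with the saturated core excluded: 250 µm radius for axon signal, 300 µm
   for point patterns; both curves normalized by their joint maximum),
   point densities per mm² with patch/interpatch ratios, anisotropy aspect
   ratios from intensity-weighted second central moments, and a two-sample
   Kolmogorov–Smirnov (KS) test comparing per-ROI patch vs interpatch mean
   densities (`D = sup |F̂_patch − F̂_interpatch|`, exact p for n ≤ 25).
4. **Synthetic ground truth** — since suitable raw flatmount material is
   not publicly available, a first-class generator produces scenes with
   known structure: a band-pass-noise module field with a 120 µm dominant
   period, an anisotropic exponentially decaying axon field with a planted
   interpatch-preference factor ρ (interpatch/patch density at matched
   distance), inhomogeneous Poisson point sets, and serial sections
   distorted by known homographies. Every downstream claim is validated
   against these planted parameters.

## Worked example

Simulate a reduced-scale scene with a strong planted interpatch preference
(ρ = 4), then run the full chain:

```
$ modmap simulate --seed 7 --out run/ --preset reduced --n-sections 3
simulated scene written to run

$ modmap segment --dir run/
patch fraction 0.3334, interpatch fraction 0.3333

$ modmap align --dir run/
aligned 3 section(s); worst residual 2.45e-13 um

$ modmap quantify --dir run/ --plot
KS D=1.000 p=0.1; rho_hat=3.343; aspect ratio=1.385
```

Reading the output: the sextile partition assigns exactly one third of the
tissue to each module class (by construction of equal-count quantiles).
Landmark registration recovers the generating section distortions to
machine precision because the simulated landmarks are noiseless. The
estimated interpatch preference `rho_hat` = 3.34 recovers the planted ρ = 4
up to the attenuation introduced by delineating modules from the image
rather than using the generator's latent field. The KS statistic is 1.0 —
every interpatch ROI is denser than every patch ROI — but with a single
simulated subject there are only 3 ROIs per sample, so the exact p-value
cannot fall below 0.1; pooling ROIs across subjects (as `modmap.run_study`
does, 4 subjects × 3 ROIs per class) is what gives the comparison its
power. The aspect ratio 1.385 recovers the generator's anisotropic decay
(long axis : short axis = 1.4). `run/quantify/` contains the radial
profile CSV/PNG, point-density tables and `report.json`.

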