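# xfetsim

Simulation pipeline comparing **X-ray fluorescence emission tomography
(XFET)** with approximately dose-matched **energy-integrating (EICT)** and
**photon-counting (PCCT)** fan-beam CT for detecting low concentrations of
gold nanoparticles in soft tissue.

## The problem

Gold nanoparticles are used in preclinical radiation-dose enhancement,
photothermal therapy and drug delivery; mapping *where* and *how much* gold
sits in tissue is an imaging problem. XFET images metal directly: a 120-kVp
pencil beam is rastered through the object, gold atoms along the
illuminated line emit Kα₁ fluorescence at 68.8 keV, and six lead slit
apertures project each emission point onto energy-resolving detector
planes — a 3D metal map with no sinogram and no reconstruction. CT, by
contrast, sees gold only as extra attenuation. The scientific question this
package addresses: *at matched dose, when does direct fluorescence imaging
beat CT, as a function of gold concentration and beam depth?*

The pipeline simulates all three modalities on synthetic phantoms — a
contrast-depth cylinder (4-mm gold spheres at 0.05–4 wt%, at beam depths
3.25–79.75 mm) and a procedural mouse with organ-level gold loadings — and
quantifies performance by the contrast-to-noise ratio

    CNR = (C_Au − C_bkg) / σ_bkg,

the Rose criterion (CNR ≥ 4 = detectable), Rose-crossing detection limits
per depth, and an exponential detection-limit-versus-depth law
`limit(z) = a·exp(b·z)` whose intercept `a` is the surface detection limit.

Dose matching follows the areal-fluence argument: an XFET raster position
receives `Ib` photons over area `A0`; CT delivers the same fluence
`N = Ib/A0` to a channel footprint `h × w_iso` at the isocenter spread over
all projection views, giving `Iproj = N·h·w_iso/N_proj` photons per channel
per view.

The XFET forward model is an analytic expectation (Beer–Lambert beam
transport, thin-voxel fluorescence production, closed-form slit acceptance,
per-plane exit attenuation, single-scatter Klein–Nishina background, lead
slit leakage) with Poisson count sampling. The CT chain is exact Siddon ray
tracing, polychromatic Beer–Lambert, Poisson / compound-Poisson detection,
fourth-degree water beam-hardening correction, and short-scan fan-beam
filtered backprojection with Parker weighting and a sinc-windowed ramp.
See `docs/methods.md` for models, defaults and fidelity limits.

## Worked example

```python
import xfetsim as x
from xfetsim.studies import study_spectrum, xfet_image_from_counts

phantom, inserts, rois = x.build_contrast_depth_phantom()
plan = x.full_fov_plan(phantom, step_mm=0.5, histories=1.25e8)
expectation = x.expected_counts(phantom, study_spectrum(), x.XFETGeometry(), plan)
counts = x.sample_counts(expectation, seed=7)
image = xfet_image_from_counts(counts)   # scatter-subtracted, 2-mm axial

bkg = next(r for r in rois if r.role == "background")
roi = next(r for r in rois if r.label == "Au4pct@3.25mm")
plane = image.axial_slice(roi.axial_mm, counts.axial_origin_mm)
res = x.measure_cnr(plane, roi, bkg, 0.5, (counts.x_mm[0] - 0.25,
                                           counts.y_mm[0] - 0.25))
print(res.cnr)
```

Running `python examples/04_xfet_scan.py` (the same scan) prints:

```
scan: 64x64 beam positions, 3.867e+07 detected photons in the 60-80 keV window
  Au4pct@3.25mm      CNR =   37.5  (detectable)
  Au0.5pct@3.25mm    CNR =    4.5  (detectable)
  Au4pct@79.75mm     CNR =   13.5  (detectable)
```

— the 4 wt% insert at 3.25-mm depth is imaged at CNR ≈ 38; the same insert
79.75 mm deep drops to ≈ 13 (beam attenuation), and 0.5 wt% sits right at
the Rose threshold. The matched-dose CT counterpart
(`python examples/05_ct_scan.py`):

```
PCCT (64x64, 0.5 mm):
   4.0 wt%  CNR =  9.30
   2.0 wt%  CNR =  4.48
EICT (64x64, 0.5 mm):
   4.0 wt%  CNR =  6.53
   2.0 wt%  CNR =  3.56
```

— at shallow depth XFET beats PCCT, which beats EICT, at every loading
≥ 0.5 wt%. The other examples build the phantoms (`02`), print the
dose-matching chain and the ~8 mGy scan dose (`03`), and run the full
comparison with detection-limit fits and the surface extrapolation (`06`).

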