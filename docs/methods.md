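# Methods

`xfetsim` simulates a comparative imaging study: X-ray fluorescence emission
tomography (XFET) versus approximately dose-matched energy-integrating
(EICT) and photon-counting (PCCT) fan-beam CT, on synthetic phantoms loaded
with gold nanoparticles. This note records the models, the parameter
choices, and the limits of what the synthetic results demonstrate.

## Physics data

Elemental mass attenuation coefficients are packaged as a curated grid of
standard published values (NIST XCOM / Hubbell–Seltzer tables, 5–150 keV,
with K-edge discontinuities for Au and Pb as paired rows) and interpolated
log-log; the provenance string is written into phantom sidecar metadata.
Mixtures follow the mass-weighted mixture rule, and gold admixture modifies
both the composition and the density (`1/rho = (1-w)/rho_host + w/rho_Au`),
so gold raises attenuation as well as fluorescence production.

Gold K-shell photoelectric absorption is a power law anchored at the K edge
(`tau_K/rho = 6.44 cm^2/g` at 80.725 keV, falling as `E^-2.7`), within a few
percent of the standard tabulations over 81–150 keV. Fluorescence constants:
K fluorescence yield 0.96, Kalpha1 branching 0.47, line energy 68.8 keV.
Only the Kalpha1 line is modeled (single fluorescence energy bin); Kalpha2
and Kbeta are out of scope.

The tube spectrum is a Kramers-law tungsten-anode bremsstrahlung model with
2.5 mm Al filtration (default) plus tungsten K lines carrying 6% of the
filtered fluence. The study names no anode or filtration, so the spectrum
model is a configuration choice; all spectrum-dependent numbers (e.g. the
23% above-cutoff fraction, versus ~15% for the unnamed spectrum model the
original study used) are model-dependent and are reported, not asserted.

A low-energy cutoff of 65.263 keV defines the transported XFET beam: only
photons above it can excite gold K fluorescence or scatter into the 67–70
keV scoring neighborhood. Histories are counted on the *full* spectrum: a
raster position's `Ib = 1.25e8` histories corresponds to `Ib x
fraction_above(cutoff)` transported photons (`Spectrum.histories_equivalent`
keeps the bookkeeping). CT uses the complete spectrum; this full-spectrum
usage is what gives PCCT its low-energy contrast advantage over EICT.

## Phantoms (synthetic-data generators)

**Contrast-depth cylinder.** A 32-mm-diameter, 90-mm-long ICRP soft-tissue
cylinder (beam along the long axis) holds 4-mm gold spheres at 4.0, 2.0,
1.5, 1.0, 0.5 and 0.05 wt%, repeated at beam depths 3.25, 28.75, 54.25 and
79.75 mm (one phantom, four planes). Each plane's six spheres sit on two
rings (outer r = 13 mm with 16 slots, inner r = 8.5 mm with 8 slots; the
four highest loadings outer, the two lowest inner), slots rotating per
plane, so all 24 transverse footprints are pairwise disjoint — the pencil
beam crosses only soft tissue before reaching any sphere. Gold ROIs are
circles matching the insert footprint; the background ROI is a 12-mm circle
in the gold-free core (3x the insert diameter; the study states only
"larger"). Default pitch 0.5 mm.

**Procedural mouse.** A stand-in for the licensed whole-body rodent phantom:
ellipsoidal organs (brain, lungs, heart, liver, spleen, kidneys, hind-leg
tumor, a cortical-bone spine, adipose shell) in ICRP tissues, with the
study's loadings: kidneys 4 wt%, spleen/lung/heart/tumor 0.75 wt%, liver
0.12 wt%. It reproduces the organ-level imaging task and ROI protocol
(squares over kidneys, tumor, abdominal background), not rodent anatomy, so
absolute mouse-phantom CNRs are qualitative only.

Both builders are deterministic (bit-identical on rebuild). Serialization is
`.npz` plus a JSON sidecar; ROI sets export to CSV.

## XFET forward model

The Monte Carlo of the original study is replaced by an analytic expectation
plus Poisson sampling: expectations are exact at any history count and a
full raster scan computes in seconds, at the cost of multiple-scatter
fidelity. Per beam position and axial voxel:

* **Beam transport:** Beer–Lambert attenuation accumulated on the voxel grid
  to each voxel center.
* **Fluorescence:** thin-voxel production `Phi tau_K l omega_K b_Ka1`
  (first-order; < 1% error for <= 1 mm voxels and <= 4 wt% gold, and the
  source of the linear CNR-concentration behavior).
* **Slit optics:** thin-aperture solid angle of the 0.5-mm slit at
  d1 = 83 mm, in closed form, integrated over the transverse slit extent
  serving the 92-mm detector rows; axial inversion maps emission z to
  detector column -z with unit magnification. A straight 1-mm-thick slit
  channel would fully occlude emissions with axial obliquity above
  w/t = 0.5 rad, inconsistent with the published images, so aperture
  thickness enters only through leakage (below).
* **Exit attenuation:** per-basis density line integrals from the emission
  point toward each of the six detector planes, midpoint-sampled at 0.25 mm
  on the voxel grid, evaluated at 68.8 keV and corrected for axial
  obliquity. Scattered photons reuse the 68.8-keV exit attenuation (the
  60–80 keV window varies slowly).
* **Compton background:** single scatter from the illuminated line through
  the slit, Klein–Nishina per detector row with exact Compton kinematics,
  scattered energies histogrammed into 1-keV bins with 8 sub-samples per
  incident bin (center-only evaluation aliases into a comb across output
  bins and would corrupt the neighbor-bin subtraction).
* **Slit leakage:** fluorescence transmitted through 1 mm of lead onto all
  detector columns (transmission ~1.8% at 68.8 keV) — the axial streak
  mechanism. Leakage of scattered photons is neglected (second-order:
  a few-percent correction to a background term).

Counts are scored in 1-keV bins over a 60–80 keV window (configurable) per
(beam x, beam y, axial mm). The detector is ideal: 100% counting efficiency,
perfect energy binning, no charge sharing or pile-up, matching the
idealized-detector comparison.

**Axial placement.** The 120-mm axial detector span exceeds the 90-mm
phantom; the study does not state the axial offset. The entrance surface is
placed 20 mm upstream of the aperture plane (`entrance_iso_mm = -20`),
which keeps the whole illuminated path on the detector and gives the
shallow, strongly illuminated depths the highest slit acceptance — the way
an operator would position the object. With the phantom centered instead,
the mid-phantom acceptance peak plus the forward-scatter background at the
entrance side inverts the expected monotone CNR-versus-depth ordering in a
single-scatter model.

**Image formation.** The metal image is the 68–69 keV bin summed over rows
and planes per object voxel. The Compton background is the average of the
67–68 and 69–70 keV bins, smoothed per object plane with a sigma = 1 pixel
Gaussian (reflective padding, chosen so constant fields cancel exactly) and
subtracted; negatives are kept for unbiased ROI statistics. The native 1-mm
axial sampling is rebinned to 2 mm (count-conserving) for contrast.
Smoothing is per-slice; 3D smoothing would be a one-line change.

## CT model

Curved equiangular fan-beam geometry: SID 100 mm, SDD 200 mm, 1024 channels
over a 19.37-degree fan, 438 views over 219 degrees. A 2-mm slab is a stack
of 0.0625-mm slices (32 for the cylinder), each receiving the full
per-channel-per-view fluence `Iproj`; detected counts are summed over the
stack (noise is drawn once on the summed expectation — the sum of
independent Poissons). Forward projection uses exact Siddon voxel traversal
of basis-material density maps (host tissue + gold), so any energy's optical
path is a dot product with tabulated mass coefficients.

Detection: PCCT draws `Poisson(sum_E lambda_E)`; EICT draws independent
per-bin Poisson counts and weights them by energy (compound Poisson,
replicate variance `sum_E E^2 lambda_E`). No scatter, no electronic noise.

Beam hardening: a fourth-degree zero-intercept polynomial maps
`-ln(S/S_air)` to `mu_ref t`, fitted on 0–40 mm water slabs under the same
spectrum and detection mode; the reference energy is the spectrum mean (any
fixed choice rescales images uniformly and cancels in CNR).

Reconstruction: cosine pre-weighting, Parker-type short-scan redundancy
weights (required for an artifact-free 219-degree reconstruction; the
conjugate of `(beta, gamma)` is `(beta + pi + 2 gamma, -gamma)` in this
sign convention and the paired weights sum to one), an equiangular ramp
kernel apodized by a sinc window (cutoff fraction 1.0 by default; the exact
window of the original study is unknown), and distance-weighted pixel-driven
backprojection. Short-scan weighting halves the implicit two-fold redundancy
of the full-scan formula, hence the factor 2 in the backprojection sum.
Default grids: 64x64 at 0.5 mm and 256x256 at 0.125 mm.

## Dose matching and dose tally

`Iproj = (Ib/A0) h w_iso / N_proj` with `w_iso = gamma_fan SID /
N_channels`: CT delivers the raster scan's areal fluence to a channel
footprint at the isocenter over all views. Evaluated exactly, the two
operating points are 2355.50 (cylinder: A0 = (0.5 mm)^2, h = 0.0625 mm) and
1177.75 (mouse: A0 = (1 mm)^2, h = 0.125 mm) photons per channel-view —
an exact ratio of 2. The mouse slice width is inferred from the stated
resolution difference. The partial-FOV arithmetic: 6.41e9 / 1.25e8 ~ 51-fold
local dose; 16 mGy x 51 = 81.6 cGy.

The dose tally is a primary-beam collision-kerma sum (`Phi E mu_en` along
the attenuated path, water coefficients standing in for soft tissue within
~2%) divided by phantom mass. It omits scattered-photon redeposition and so
underestimates; the full raster scan tallies ~8 mGy against the study's
Monte Carlo ~16 mGy, inside the stated factor-of-two fidelity.

## Analysis

CNR = (C_Au − C_bkg)/sigma_bkg with ROI means and the sample (n−1)
background SD; CNR >= 4 (boundary inclusive) is detectable (Rose).
Detection limits are the CNR = 4 crossing of a least-squares CNR-vs-
concentration line per depth; limits versus depth are fitted as
`a exp(b z)` on the log scale, `a` being the surface limit. Modality
comparisons use the mean of per-ROI CNR ratios ("mean-of-ratios"), the
convention that best reproduces the published 315%/175% organ-CNR
improvements from the printed organ values (317.7% / 175.8% from the
rounded numbers).

## Study conditions and problem sizes

The default study is the published operating point: 0.5-mm raster,
Ib = 1.25e8 full-spectrum histories per position, dose-matched Iproj, five
noise replicates, 0.5-mm phantom pitch, 64x64 reconstruction (256x256 as a
resolution check). The XFET expectation is computed once (~5 s) and
replicates are Poisson draws from it; a histories sweep rescales the
expectation exactly rather than rescanning.

## What the synthetic results do and do not show

Reproduced, qualitatively and at matched dose: XFET > PCCT > EICT at
shallow depth for >= 0.5 wt% gold; PCCT > EICT everywhere; linear CNR
versus concentration (r^2 >= 0.99); monotone XFET CNR decay with beam
depth; an exponential detection-limit-versus-depth law with a surface limit
of ~0.4 wt% (published: 0.44 wt%); sqrt-dose CNR scaling; dose within a
factor two of the published ~16 mGy.

Not reproduced: absolute Monte Carlo CNRs, and the published XFET/CT
crossover between 28.75 and 54.25 mm — in this single-scatter model the
XFET background falls with depth along with the signal, so XFET CNR decays
more slowly than in the full-physics simulation and stays above PCCT at all
four depths. Multiple scatter, which raises a depth-flat background, is the
main missing ingredient; the crossover is therefore a known fidelity limit,
not a target. Mouse-phantom CNRs are qualitative for the same reason plus
the procedural anatomy.

## Numerical choices

Log-log interpolation with linear extrapolation below 5 keV (heavily
filtered tails only); beam attenuation accumulated to voxel centers
(half-voxel correction); exit integrals float32, midpoint step 0.25 mm;
Poisson sampling via numpy Generator with explicit integer seeds; Siddon
traversal is exact (path lengths sum to the analytic chord to 1e-9 mm);
nonpositive detected signals are flagged and filled from lateral neighbors
before the log; a degenerate CNR (zero background SD) raises rather than
returning infinity.
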