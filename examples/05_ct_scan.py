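"""A dose-matched fan-beam CT acquisition of one sphere plane.

Forward-projects a 2-mm slab of the contrast-depth phantom (32 thin slices)
with the full 120-kVp spectrum, detects it with both the photon-counting and
energy-integrating models, applies the water-based beam-hardening
correction, reconstructs with short-scan FFBP, and reports insert CNRs.
"""

import xfetsim as x
import xfetsim.ct as ct
from xfetsim.studies import ct_spectrum

phantom, inserts, rois = x.build_contrast_depth_phantom()
geometry = ct.CTGeometry()
iproj = x.compute_iproj(1.25e8, 0.5 ** 2, geometry.channel_height_mm).iproj
beam = ct_spectrum()

plane = [i for i in inserts if i.depth == 3.25]
slab = ct.contrast_depth_ct_slab(plane, 3.25)
lam, lam_air, energies = ct.forward_project(slab, beam, geometry, iproj)
print(f"slab: 32 x 0.0625-mm slices, Iproj = {iproj:.1f} photons/channel/"
      f"view/slice, air signal {lam_air.sum():.0f} counts/channel/view")

bkg = next(r for r in rois if r.role == "background")
for mode in ("pcct", "eict"):
    calib = ct.build_water_calibration(beam, mode)
    sino = ct.detect(lam, energies, lam_air, mode, seed=21)
    p = ct.beam_hardening_correct(sino, calib)
    recon = ct.ffbp_reconstruct(p, geometry, 64, 0.5)
    print(f"\n{mode.upper()} (64x64, 0.5 mm):")
    for ins in sorted(plane, key=lambda i: -i.gold_fraction)[:3]:
        roi = next(r for r in rois if r.axial_mm == ins.depth
                   and abs(r.center[0] - ins.center[0]) < 1e-9)
        res = x.measure_cnr(recon.values, roi, bkg, 0.5, (-16.0, -16.0))
        print(f"  {100 * ins.gold_fraction:4.1f} wt%  CNR = {res.cnr:5.2f}")
# the photon-counting detector weights every photon equally and so keeps the
# contrast carried by lower-energy photons, beating the energy-integrating
# detector at matched dose.
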