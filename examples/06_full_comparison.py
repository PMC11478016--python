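"""The full contrast-depth comparison: CNR tables and detection limits.

Runs XFET, PCCT and EICT at the matched dose with three noise replicates,
fits CNR versus concentration per depth, extracts Rose-criterion detection
limits, and extrapolates the exponential depth law to the surface.
Takes a few minutes.
"""

import pandas as pd

import xfetsim as x
from xfetsim.studies import replicate_cnr_summary, run_contrast_depth_study

study = run_contrast_depth_study(seed=1)
xf = study.xfet_cnr_table(seeds=[11, 12, 13])
pc = study.ct_cnr_table(3.25, "pcct", [21, 22, 23])
ei = study.ct_cnr_table(3.25, "eict", [31, 32, 33])

summary = replicate_cnr_summary(pd.concat([xf[xf.depth_mm == 3.25], pc, ei]))
print("mean CNR at 3.25-mm beam depth (3 replicates):")
print(summary.pivot_table(index="concentration_wt_pct", columns="modality",
                          values="cnr_mean").round(2))
# XFET > PCCT > EICT at every loading >= 0.5 wt%: direct fluorescence
# imaging of shallow metal beats both CT detector models at matched dose.

sx = replicate_cnr_summary(xf)
depths = sorted(sx.depth_mm.unique())
limits = []
for depth in depths:
    sd = sx[sx.depth_mm == depth]
    limit, slope, intercept = x.detection_limit(sd.concentration_wt_pct,
                                                sd.cnr_mean)
    _, _, r2 = x.fit_cnr_vs_concentration(sd.concentration_wt_pct, sd.cnr_mean)
    limits.append(limit)
    print(f"depth {depth:5.2f} mm: CNR = {slope:5.2f} c {intercept:+5.2f} "
          f"(r^2 = {r2:.4f}), detection limit {limit:.2f} wt%")

fit = x.extrapolate_surface_limit(depths, limits)
print(f"\nexponential fit: limit(z) = {fit.surface_limit_wt_pct:.2f} wt% "
      f"x exp({fit.decay_per_mm:.4f} z)")
print(f"surface (z = 0) detection limit: {fit.surface_limit_wt_pct:.2f} wt% "
      f"at the ~10-mGy scan dose")
# the detection limit grows exponentially with beam depth because beam
# attenuation is the dominant loss; the z = 0 intercept is the best-case
# sensitivity of the scanner at this dose.
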