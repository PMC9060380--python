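"""From a corrected run to a smoothed, age-indexed otolith profile.

Crops core-to-edge, converts the 88Sr beam to Sr concentration through the
FEBs-1 standard, aligns the marine plateau onto the global marine value
(GMV = 0.70918), maps distance to age through the annuli, and fits the
penalized spline (lambda = 0.6, k = 100) with a Bayesian 95% band.
"""

from otolithsr import (ClassifierConfig, InstrumentModel, crop_profile,
                       gmv_align, make_otolith, reduce_run, smooth_profile)

oto = make_otolith(type_id=1, inst=InstrumentModel(), seed=11)
reduced = reduce_run(oto.raw_run, oto.standards)
profile = crop_profile(reduced, oto.core_offset_um,
                       oto.core_offset_um + oto.core_to_edge_um,
                       oto.annuli_um)
profile, alignment = gmv_align(profile, ClassifierConfig())
smoothed = smooth_profile(profile)

print(f"profile: {len(profile)} readings over "
      f"{profile.positions_um[-1]:.0f} um, ages 0-{profile.age[-1]:.1f} y")
print(f"GMV alignment: offset {alignment.offset:+.2e} applied to "
      f"{alignment.n_marine_points} marine readings")
print(f"spline fit: edf {smoothed.edf:.1f}, residual SD "
      f"{smoothed.sigma2 ** 0.5:.1e}")
print(f"mean 95%-band half-width: "
      f"{((smoothed.upper - smoothed.lower) / 2).mean():.1e}")
print("\nThe offset re-anchors the whole ratio series so the marine plateau "
      "sits exactly\non 0.70918; the band half-width is the pointwise "
      "uncertainty of the fitted ratio.")
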