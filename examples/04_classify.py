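"""Classify one otolith into a life-history type.

Habitat states come from the corrected 88Sr beam (6.13 / 12.26 V
thresholds with a 10-reading persistence filter); the natal region is the
earliest stable freshwater window past any maternally derived core signal;
marine entry is the first sustained run with v88 > 12.26 V and the fitted
ratio within +-0.00006 of the GMV.
"""

from otolithsr.io import PipelineConfig, process_run
from otolithsr.synthetic import InstrumentModel, make_otolith

oto = make_otolith(type_id=3, inst=InstrumentModel(), seed=23)
profile, smoothed, call = process_run(oto.raw_run, oto.standards,
                                      oto.annuli_um, PipelineConfig())

print(f"otolith {oto.otolith_id}: truth type {oto.truth_label}, "
      f"truth entry age {oto.truth_entry_age}")
print(f"call: type {call.type_id} ({call.status}), "
      f"entry age {call.entry_age}")
print(f"natal region: {call.natal.start_um:.0f}-{call.natal.end_um:.0f} um, "
      f"mean ratio {call.natal.mean_ratio:.5f} +- {call.natal.se_ratio:.6f}")
if call.juvenile:
    print(f"juvenile region: {call.juvenile.start_um:.0f}-"
          f"{call.juvenile.end_um:.0f} um, mean {call.juvenile.mean_ratio:.5f}")
print("habitat run-lengths (age span, state):")
for a0, a1, state in call.habitat_states:
    print(f"  {a0:5.2f}-{a1:5.2f} y  {state}")
print("\nType 3 (late transitional anadromous) means age-0 chemistry shows "
      "both freshwater\nand estuarine residence before a marine entry at "
      "age >= 1.")
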