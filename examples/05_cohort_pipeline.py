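"""Full cohort pipeline: simulate, write to disk, analyze, summarize.

Mirrors the command-line flow (`otolithsr simulate` + `otolithsr all`) from
Python: the cohort is written in the pipeline's CSV/JSON layout, re-read,
pushed through reduction -> cropping -> alignment -> smoothing ->
classification, and aggregated.
"""

import tempfile
from pathlib import Path

from otolithsr import InstrumentModel, simulate_cohort
from otolithsr.io import PipelineConfig, run_pipeline, write_cohort

with tempfile.TemporaryDirectory() as tmp:
    base = Path(tmp)
    cohort = simulate_cohort(n_per_type=2, inst=InstrumentModel(), seed=4)
    write_cohort(cohort, base)
    result = run_pipeline(PipelineConfig(seed=4), base_dir=base)

    s = result.summary
    print(f"classified {s.n_total} otoliths "
          f"({s.n_undetermined} undetermined, {len(result.excluded)} excluded)")
    print(f"type percents: {s.percents}")
    print(f"anadromous (types 1-3) combined: {s.pct_anadromous}%")
    print("\nmigration-age table (% per entry age, N per type):")
    print(s.migration_table.to_string())
    print("\nnatal-region ratio statistics:")
    natal = s.region_table[s.region_table.kind == "natal"]
    print(natal.to_string(index=False,
                          float_format=lambda v: f"{v:.5f}"))
    truth_hits = sum(
        c.type_id == int(c.otolith_id[4]) for c in result.calls
        if c.status == "ok")
    print(f"\ntruth-label recovery: {truth_hits}/{len(result.calls)}")
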