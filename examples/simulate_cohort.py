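"""Generate a small synthetic two-class R-R cohort and inspect its calibration.

Builds 120 regular + 60 pre-shock records with the default class
specifications (calibrated to the published group statistics), writes them in
the plain-text record dialect, and prints the calibration report comparing
synthetic feature medians with the published reference columns.
"""

from pathlib import Path

import pandas as pd

from vtwarn.records import write_cohort
from vtwarn.synth import CohortSpec, calibration_report, generate_cohort

out_dir = Path("scratch/example_cohort")
cohort = generate_cohort(CohortSpec(n_regular=120, n_preshock=60, seed=1))
manifest = write_cohort(cohort, out_dir)
print(f"wrote {len(cohort)} records to {out_dir} (manifest: {manifest})")

report = calibration_report(cohort, "five_minute")
pd.set_option("display.width", 160)
cols = ["feature", "class", "synthetic_median", "reference_median", "relative_deviation", "flag"]
print(report[cols].to_string(index=False))
# synthetic_median should track reference_median for mean_nn and reproduce the
# cross-class orderings (pre-shock: shorter intervals, higher mobility, lower
# long-range scaling exponent); flagged rows deviate > 25% from the reference.
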