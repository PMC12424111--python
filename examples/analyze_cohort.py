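"""Full analysis bundle on a simulated cohort with missing data.

Simulates 87 respondents (the study's size) with missing-at-random gaps
in the external measures, then writes every report table — descriptives,
subtest correlations, external-measure correlations with their varying
pairwise n, demographic correlations, regressions, and alphas.
"""

import tempfile
from pathlib import Path

from keystrokes import SimConfig, simulate_cohort
from keystrokes.report import table_external_correlations, table_regressions, write_report

cohort = simulate_cohort(SimConfig(n=87, seed=20, mode="engine", missingness=True))

t3 = table_external_correlations(cohort)
print("subtest x external-measure correlations (pairwise n varies):")
print(t3[["CD", "CD_n", "TMT_B", "TMT_B_n", "OI", "OI_n", "BDI", "BDI_n"]].to_string())
print()
print("age + education regressions:")
print(table_regressions(cohort).to_string())

with tempfile.TemporaryDirectory() as d:
    paths = write_report(cohort, Path(d))
    print(f"\nwrote {len(paths)} report artifacts, e.g. {sorted(p.name for p in paths.values())[:3]}")
print()
print("pairwise-complete n per measure mirrors its configured missingness;")
print("age predicts every subtest while education (restricted to >= 12 y)")
print("typically does not at n = 87.")
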