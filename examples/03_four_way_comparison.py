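"""The four-way estimator comparison on a simulated cohort.

Runs the full pipeline (weights -> four CIF variants -> two Cox variants)
and prints the report table: per arm, the 10-year cumulative incidence
under un-weighted/IPT-weighted x naive-KM/competing-risks, plus hazard
ratios. Two patterns to look for: competing-risks CIFs are uniformly
below their KM counterparts (death steals probability mass), and the
weighted hazard ratios land near the generator's true values while the
unweighted ones are biased on the strongly confounded arms.
"""

import tempfile
from pathlib import Path

import wcr

cohort, truth = wcr.generate_cohort(wcr.SimulationConfig(n=20_000, seed=1))
report = wcr.run_analysis(cohort)

out = Path(tempfile.mkdtemp())
wcr.render_report(report, out)
print((out / "report.txt").read_text())
print("true cause-1 hazard ratios:", truth.hr1)
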