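"""Bootstrap confidence interval for an IPT-weighted cumulative incidence.

The weighted Aalen-Johansen CIF has no convenient closed-form variance, so
the interval comes from a subject-level bootstrap in which the weights are
re-estimated inside every resample. On an unconfounded constant-hazard
cohort the truth is known in closed form, so we can see the interval do
its job.
"""

import wcr

L1, L2 = 2e-4, 4e-4
cfg = wcr.SimulationConfig(
    n=1000, arms=("control", "treated"),
    true_hr1={"treated": 1.0}, true_hr2={"treated": 1.0},
    assignment_intercepts={"treated": 0.0}, assignment_coefs={"treated": (0,) * 7},
    baseline_hazard1=L1, baseline_hazard2=L2, censor_rate=5e-5,
    confounding=0.0, seed=11,
)
cohort, _ = wcr.generate_cohort(cfg)


def weighted_cif10(c):
    ws = wcr.iptw_from_cohort(c, stage1_covariates=["ses", "age"])
    w = ws.align_to(c)
    mask = (c.arm == "treated").to_numpy()
    rs = wcr.build_risk_sets(c.subset(mask), w[mask])
    return wcr.cif_at(wcr.competing_risks_cif(rs, 1), 3650.0)


res = wcr.bootstrap_ci(cohort, weighted_cif10, reps=200, seed=11)
truth = wcr.closed_form_cif(L1, L2, 3650.0)
print(f"10-yr weighted AJ CIF estimate : {res.estimate:.4f}")
print(f"95% percentile bootstrap CI    : ({res.lower:.4f}, {res.upper:.4f})")
print(f"closed-form truth              : {truth:.4f}")
print(f"degenerate replicates excluded : {res.n_degenerate}")
print("the interval should cover the truth in ~95% of repeated cohorts")
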