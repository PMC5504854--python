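"""Stabilized inverse-probability-of-treatment (IPT) weights.

The weighting scheme mirrors a two-stage matched-cohort design: stage 1
models membership (case vs. control) on the full cohort with a binary
logistic regression; stage 2 models the treatment actually received among
cases with a single multinomial-logistic model.  Each subject's stabilized
weight is

* controls:  P(control) / P(control | X)
* cases:     [P(case) / P(case | X)] * [P(arm) / P(arm | X, case)]

with marginal (intercept-only) probabilities in the numerators — the
standard stabilization, which keeps the weight mean near 1.  A single-stage
variant (one binary or multinomial model over all arms) is supported by
passing ``stage2=None``.

Extreme weights are limited by *truncation* at a percentile of the weight
distribution, either by capping at the percentile value (default; preserves
the sample) or by deleting the subjects above it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from ._design import check_full_rank, design_matrix
from .data_model import CohortTable

__all__ = [
    "PropensityFit",
    "WeightSet",
    "fit_propensity",
    "stabilized_weights",
    "truncate_weights",
    "balance_diagnostics",
    "BalanceTable",
    "iptw_from_cohort",
]


@dataclass
class PropensityFit:
    """A fitted propensity model and its per-subject probabilities."""

    model_kind: str                 # "binary-logistic" | "multinomial-logistic"
    levels: list
    coefficients: pd.DataFrame      # terms x levels (first level = reference)
    probabilities: pd.DataFrame     # subjects x levels, rows sum to 1
    fitted_probabilities: np.ndarray  # P(level actually observed | X)
    marginal_probabilities: pd.Series  # observed level proportions
    observed: np.ndarray            # observed level per subject
    subject_id: np.ndarray
    covariate_names: list[str]

    def __post_init__(self) -> None:
        p = self.probabilities.to_numpy()
        if np.any(p <= 0) or np.any(p >= 1):
            raise ValueError("fitted probabilities must lie strictly in (0, 1)")
        if np.max(np.abs(p.sum(axis=1) - 1)) > 1e-8:
            raise ValueError("per-subject probabilities must sum to 1")


def fit_propensity(
    cohort: CohortTable,
    outcome: str,
    covariates: Sequence[str],
    *,
    subset: np.ndarray | None = None,
) -> PropensityFit:
    """ML logistic (2 levels) or multinomial-logistic (>=3) propensity fit.

    ``outcome`` is a column of the cohort (e.g. ``arm`` or a derived
    case/control indicator).  ``fitted_probabilities`` are the estimated
    probabilities of the level each subject actually holds.  Raises on
    perfect separation and on rank-deficient designs.
    """
    df = cohort.data if subset is None else cohort.data.loc[np.asarray(subset)]
    df = df.reset_index(drop=True)
    y_raw = df[outcome]
    if y_raw.isna().any():
        raise ValueError(f"missing values in outcome '{outcome}'")
    levels = list(pd.unique(y_raw.astype(str)))
    counts = y_raw.astype(str).value_counts()
    empty = [lev for lev in levels if counts.get(lev, 0) == 0]
    if len(levels) < 2:
        raise ValueError(f"outcome '{outcome}' has a single level; need >= 2")
    if empty:
        raise ValueError(f"outcome level(s) with zero subjects: {empty}")

    X, names = design_matrix(df, covariates, intercept=True)
    if np.isnan(X).any():
        raise ValueError("missing covariate values in propensity design")
    check_full_rank(X, names)

    y_codes = pd.Categorical(y_raw.astype(str), categories=levels).codes
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if len(levels) == 2:
                res = sm.Logit(y_codes, X).fit(disp=0, maxiter=200)
                p1 = np.asarray(res.predict(X))
                probs = np.column_stack([1 - p1, p1])
                coefs = pd.DataFrame({levels[1]: res.params}, index=names)
                kind = "binary-logistic"
            else:
                res = sm.MNLogit(y_codes, X).fit(disp=0, maxiter=400, method="newton")
                probs = np.asarray(res.predict(X))
                coefs = pd.DataFrame(
                    np.column_stack([np.zeros(len(names)), res.params]),
                    index=names,
                    columns=levels,
                )
                kind = "multinomial-logistic"
        except (np.linalg.LinAlgError, PerfectSeparationError) as err:
            raise ValueError(
                "propensity model failed (likely separation or collinearity); "
                "consider coarsening covariates or penalization"
            ) from err
    if not res.mle_retvals.get("converged", True):
        raise ValueError(
            "propensity likelihood did not converge — possible perfect "
            "separation; consider coarsening covariates or penalization"
        )
    eps = 1e-12
    probs = np.clip(probs, eps, 1 - eps)
    probs /= probs.sum(axis=1, keepdims=True)
    prob_df = pd.DataFrame(probs, columns=levels)
    fitted = probs[np.arange(len(df)), y_codes]
    marginal = pd.Series(
        [np.mean(y_codes == k) for k in range(len(levels))], index=levels
    )
    return PropensityFit(
        model_kind=kind,
        levels=levels,
        coefficients=coefs,
        probabilities=prob_df,
        fitted_probabilities=fitted,
        marginal_probabilities=marginal,
        observed=np.asarray(y_raw.astype(str)),
        subject_id=df["subject_id"].to_numpy(),
        covariate_names=list(names),
    )


@dataclass
class WeightSet:
    """Per-subject stabilized IPT weights with provenance.

    ``table`` columns: subject_id, numerator_prob, denominator_prob,
    raw_weight, final_weight, truncated (bool).  ``removed`` holds subjects
    dropped by delete-mode truncation.
    """

    table: pd.DataFrame
    truncation: str = "none"           # "none" | "cap" | "delete"
    truncation_percentile: float | None = None
    cap_value: float | None = None
    removed: pd.DataFrame = field(default_factory=pd.DataFrame)
    flagged_small_denominator: list = field(default_factory=list)

    @property
    def final_weight(self) -> np.ndarray:
        return self.table["final_weight"].to_numpy(dtype=float)

    @property
    def subject_id(self) -> np.ndarray:
        return self.table["subject_id"].to_numpy()

    def align_to(self, cohort: CohortTable) -> np.ndarray:
        """Weights in cohort row order (delete-mode removals not allowed)."""
        s = self.table.set_index("subject_id")["final_weight"]
        ids = cohort.data["subject_id"]
        if not ids.isin(s.index).all():
            raise ValueError(
                "cohort contains subjects without weights (removed by "
                "delete-mode truncation?); subset the cohort first"
            )
        return s.loc[ids].to_numpy(dtype=float)

    def mean(self) -> float:
        return float(self.table["final_weight"].mean())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def stabilized_weights(
    stage1: PropensityFit,
    stage2: PropensityFit | None,
    cohort: CohortTable,
    *,
    probability_floor: float = 1e-6,
) -> WeightSet:
    """Build stabilized IPT weights from one- or two-stage propensity fits.

    With ``stage2=None`` the weight is P(observed level)/P(observed
    level | X) from ``stage1`` alone.  With two stages, stage-1 must be the
    case/control membership model on the full cohort and stage-2 the
    treatment model fitted on cases only; case weights multiply the two
    stabilized ratios.  Subjects whose denominator probability falls below
    ``probability_floor`` are flagged (not silently dropped).
    """
    ids = cohort.data["subject_id"].to_numpy()
    s1 = pd.Series(stage1.fitted_probabilities, index=stage1.subject_id)
    num1 = pd.Series(
        stage1.marginal_probabilities.loc[stage1.observed].to_numpy(),
        index=stage1.subject_id,
    )
    if not pd.Index(ids).isin(s1.index).all():
        raise ValueError("stage-1 fit does not cover the full cohort")
    numerator = num1.loc[ids].to_numpy(dtype=float)
    denominator = s1.loc[ids].to_numpy(dtype=float)

    if stage2 is not None:
        s2 = pd.Series(stage2.fitted_probabilities, index=stage2.subject_id)
        num2 = pd.Series(
            stage2.marginal_probabilities.loc[stage2.observed].to_numpy(),
            index=stage2.subject_id,
        )
        is_case = pd.Index(ids).isin(s2.index)
        mult_num = np.ones(len(ids))
        mult_den = np.ones(len(ids))
        mult_num[is_case] = num2.loc[ids[is_case]].to_numpy(dtype=float)
        mult_den[is_case] = s2.loc[ids[is_case]].to_numpy(dtype=float)
        numerator = numerator * mult_num
        denominator = denominator * mult_den

    flagged = [sid for sid, d in zip(ids, denominator) if d < probability_floor]
    raw = numerator / denominator
    table = pd.DataFrame(
        {
            "subject_id": ids,
            "numerator_prob": numerator,
            "denominator_prob": denominator,
            "raw_weight": raw,
            "final_weight": raw,
            "truncated": False,
        }
    )
    return WeightSet(table=table, flagged_small_denominator=flagged)


def truncate_weights(
    weights: WeightSet,
    percentile: float = 99.0,
    mode: str = "cap",
) -> WeightSet:
    """Truncate extreme weights at a percentile of the weight distribution.

    The percentile is computed on the *raw* (untruncated) weights of the
    retained subjects, with linear interpolation between order statistics.
    ``cap`` replaces larger weights by the percentile value; ``delete``
    removes those subjects, recording the removals.  Because the threshold
    is a functional of the raw weights, capping is idempotent.
    """
    if not 50 < percentile <= 100:
        raise ValueError("percentile must lie in (50, 100]")
    if mode not in ("cap", "delete"):
        raise ValueError(f"unknown truncation mode '{mode}' (use 'cap' or 'delete')")
    w = weights.table["raw_weight"].to_numpy(dtype=float)
    cap = float(np.percentile(w, percentile, method="linear"))
    table = weights.table.copy()
    above = table["raw_weight"] > cap
    if mode == "cap":
        table["final_weight"] = np.minimum(table["raw_weight"].to_numpy(dtype=float), cap)
        table.loc[above, "truncated"] = True
        removed = weights.removed
    else:
        removed = pd.concat([weights.removed, table.loc[above]], ignore_index=True)
        table = table.loc[~above].reset_index(drop=True)
    return WeightSet(
        table=table,
        truncation=mode,
        truncation_percentile=percentile,
        cap_value=cap,
        removed=removed,
        flagged_small_denominator=list(weights.flagged_small_denominator),
    )


@dataclass
class BalanceTable:
    """Standardized mean differences and weight diagnostics per arm."""

    smd: pd.DataFrame       # rows: covariate term x arm; cols: smd_unweighted, smd_weighted
    weight_summary: pd.DataFrame  # per arm: n, weight mean/max, effective sample size
    flags: list[str] = field(default_factory=list)

    def max_abs_smd(self, weighted: bool) -> float:
        col = "smd_weighted" if weighted else "smd_unweighted"
        return float(self.smd[col].abs().max())


def _weighted_mean_var(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    # frequency-weight variance with a ddof-1 style correction, so that unit
    # weights reproduce the unweighted sample variance exactly
    m = np.average(x, weights=w)
    sw = w.sum()
    v = float(np.sum(w * (x - m) ** 2) / (sw - 1)) if sw > 1 else 0.0
    return float(m), v


def balance_diagnostics(
    cohort: CohortTable,
    weights: WeightSet | None,
    covariates: Sequence[str] | None = None,
) -> BalanceTable:
    """Covariate balance (each arm vs. reference) before and after weighting.

    The SMD is (mean_arm - mean_ref) / pooled SD, with categorical
    covariates expanded to level indicators.  Weighted means/variances use
    the final weights; zero pooled variance yields SMD 0 plus a flag.
    """
    covariates = list(covariates) if covariates is not None else list(cohort.covariates)
    if len(cohort.arms) < 2:
        raise ValueError("balance diagnostics require at least two arms")
    X, names = design_matrix(cohort.data, covariates, intercept=False)
    w = weights.align_to(cohort) if weights is not None else np.ones(cohort.n)
    arm = cohort.arm.astype(str).to_numpy()
    ref = cohort.reference_arm
    flags: list[str] = []

    rows = []
    ref_mask = arm == ref
    for a in cohort.arms[1:]:
        mask = arm == a
        for j, name in enumerate(names):
            x = X[:, j]
            m1 = float(x[mask].mean())
            v1 = float(x[mask].var(ddof=1)) if mask.sum() > 1 else 0.0
            m0 = float(x[ref_mask].mean())
            v0 = float(x[ref_mask].var(ddof=1)) if ref_mask.sum() > 1 else 0.0
            wm1, wv1 = _weighted_mean_var(x[mask], w[mask])
            wm0, wv0 = _weighted_mean_var(x[ref_mask], w[ref_mask])
            pooled = np.sqrt((v1 + v0) / 2)
            wpooled = np.sqrt((wv1 + wv0) / 2)
            if pooled == 0:
                smd_u = 0.0
                flags.append(f"zero pooled variance for '{name}' ({a} vs {ref})")
            else:
                smd_u = (m1 - m0) / pooled
            smd_w = 0.0 if wpooled == 0 else (wm1 - wm0) / wpooled
            rows.append({"covariate": name, "arm": a, "smd_unweighted": smd_u, "smd_weighted": smd_w})
    smd = pd.DataFrame(rows)

    summ = []
    for a in cohort.arms:
        mask = arm == a
        wa = w[mask]
        summ.append(
            {
                "arm": a,
                "n": int(mask.sum()),
                "weight_mean": float(wa.mean()),
                "weight_max": float(wa.max()),
                "ess": float(wa.sum() ** 2 / np.sum(wa**2)),
            }
        )
    return BalanceTable(smd=smd, weight_summary=pd.DataFrame(summ), flags=flags)


def iptw_from_cohort(
    cohort: CohortTable,
    *,
    stage1_covariates: Sequence[str] | None = None,
    stage2_covariates: Sequence[str] | None = None,
    truncation_percentile: float | None = 99.0,
    truncation_mode: str = "cap",
    probability_floor: float = 1e-6,
) -> WeightSet:
    """Convenience pipeline: two-stage stabilized IPT weights from a cohort.

    Stage 1: logistic model of case (any non-reference arm) vs control on
    ``stage1_covariates``; stage 2: multinomial model of the arm received,
    on cases only, on ``stage2_covariates`` (defaults to stage 1's list).
    With exactly two arms a single binary model is used.  Truncation is
    applied unless ``truncation_percentile`` is None.
    """
    stage1_covariates = list(stage1_covariates or cohort.covariates)
    stage2_covariates = list(stage2_covariates or stage1_covariates)
    arms = cohort.arms
    if len(arms) == 2:
        fit = fit_propensity(cohort, "arm", stage1_covariates)
        ws = stabilized_weights(fit, None, cohort, probability_floor=probability_floor)
    else:
        df = cohort.data
        work = cohort.data.copy()
        work["_is_case"] = (work["arm"].astype(str) != cohort.reference_arm).astype(int)
        tmp = CohortTable(
            work,
            reference_arm=cohort.reference_arm,
            covariates=list(cohort.covariates) + ["_is_case"],
            max_cause=cohort.max_cause,
        )
        stage1 = fit_propensity(tmp, "_is_case", stage1_covariates)
        case_mask = (df["arm"].astype(str) != cohort.reference_arm).to_numpy()
        stage2 = fit_propensity(cohort, "arm", stage2_covariates, subset=case_mask)
        ws = stabilized_weights(stage1, stage2, cohort, probability_floor=probability_floor)
    if truncation_percentile is not None:
        ws = truncate_weights(ws, truncation_percentile, truncation_mode)
    return ws
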