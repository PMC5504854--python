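"""Weighted cause-specific Cox proportional-hazards regression.

The cause-specific hazard of cause k is modelled as
``lambda_k(t | x) = lambda_k0(t) exp(x' beta)``; subjects failing from any
other cause are censored at their event time, which is exactly the
cause-specific formulation (no subdistribution / Fine-Gray modelling here).
The weighted partial likelihood (Breslow ties) is

    l(beta) = sum_j [ sum_{i in D_j} w_i x_i' beta
                      - ( sum_{i in D_j} w_i ) log sum_{l in R_j} w_l e^{x_l' beta} ]

maximized by Newton-Raphson with step halving.  Because weighting
invalidates the model-based (inverse-information) variance, confidence
intervals always use the robust sandwich estimator

    V = I^{-1} ( sum_i U_i U_i' ) I^{-1},   U_i = w_i * (score residual)_i,

with subjects as independent units (Binder/Lin-Wei form).  The sandwich is
invariant to rescaling all weights by a positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._design import check_full_rank, design_matrix
from .data_model import CohortTable
from .weights import WeightSet

__all__ = ["CoxFit", "fit_cause_specific_cox", "hazard_ratio_table"]


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge (or the likelihood is monotone)."""


@dataclass
class CoxFit:
    """A fitted weighted cause-specific Cox model."""

    cause: int
    params: pd.Series                # log hazard ratios
    robust_covariance: pd.DataFrame
    hazard_ratios: pd.DataFrame      # columns: hr, ci_low, ci_high, se
    model_covariance: pd.DataFrame   # inverse information (diagnostic only)
    n: int
    n_events: int
    weighted_n: float
    weighted_n_events: float
    ties_method: str
    converged: bool
    n_iter: int
    loglik: float
    reference_arm: str | None = None

    @property
    def robust_se(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.robust_covariance.to_numpy())),
            index=self.params.index,
        )

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "coef": self.params,
                "robust_se": self.robust_se,
                "hr": self.hazard_ratios["hr"],
                "ci_low": self.hazard_ratios["ci_low"],
                "ci_high": self.hazard_ratios["ci_high"],
            }
        )
        out["p"] = 2 * stats.norm.sf(np.abs(out["coef"] / out["robust_se"]))
        return out

    def to_json(self) -> str:
        return self.summary().reset_index(names="term").to_json(orient="records")


def _partial_lik_quantities(
    beta: np.ndarray,
    ts: np.ndarray,
    delta: np.ndarray,
    Xs: np.ndarray,
    ws: np.ndarray,
    ties: str,
):
    """Log-likelihood, score and information at ``beta``.

    Inputs are sorted ascending in time.  Returns (ll, U, I) plus the
    per-event-time pieces needed for residuals: event times, dw_j/S0_j and
    xbar_j under the Breslow convention.
    """
    n, p = Xs.shape
    eta = Xs @ beta
    eta = eta - eta.max()  # guard overflow; cancels in all ratios and ll up to const
    r = ws * np.exp(eta)
    rX = r[:, None] * Xs
    # reverse cumulative sums: index i -> sum over subjects with time >= ts[i]
    S0_tail = np.concatenate([np.cumsum(r[::-1])[::-1], [0.0]])
    S1_tail = np.concatenate([np.cumsum(rX[::-1], axis=0)[::-1], np.zeros((1, p))])
    rXX = r[:, None, None] * (Xs[:, :, None] * Xs[:, None, :])
    S2_tail = np.concatenate(
        [np.cumsum(rXX[::-1], axis=0)[::-1], np.zeros((1, p, p))]
    )

    ev = delta.astype(bool)
    # group events by (tied) time
    t_ev = ts[ev]
    uniq, inv = np.unique(t_ev, return_inverse=True)
    J = uniq.size
    k_idx = np.searchsorted(ts, uniq, side="left")
    S0 = S0_tail[k_idx]
    S1 = S1_tail[k_idx]
    S2 = S2_tail[k_idx]

    w_ev = ws[ev]
    X_ev = Xs[ev]
    eta_ev = eta[ev]
    dw = np.bincount(inv, weights=w_ev, minlength=J)
    m = np.bincount(inv, minlength=J)  # raw tied-event counts
    xw = np.zeros((J, p))
    for j in range(p):
        xw[:, j] = np.bincount(inv, weights=w_ev * X_ev[:, j], minlength=J)
    lin = np.bincount(inv, weights=w_ev * eta_ev, minlength=J)

    ll = 0.0
    U = np.zeros(p)
    info = np.zeros((p, p))
    if ties == "breslow" or np.all(m <= 1):
        ll = float(np.sum(lin - dw * np.log(S0)))
        xbar = S1 / S0[:, None]
        U = xw.sum(axis=0) - (dw[:, None] * xbar).sum(axis=0)
        for j in range(J):
            V = S2[j] / S0[j] - np.outer(xbar[j], xbar[j])
            info += dw[j] * V
    else:
        # Efron: within a tie set, subtract increasing fractions of the tie
        # set's own weighted sums from S0/S1/S2
        r_ev = r[ev]
        rX_ev = rX[ev]
        rXX_ev = rXX[ev]
        S0_D = np.bincount(inv, weights=r_ev, minlength=J)
        S1_D = np.zeros((J, p))
        for jj in range(p):
            S1_D[:, jj] = np.bincount(inv, weights=rX_ev[:, jj], minlength=J)
        for j in range(J):
            mj = int(m[j])
            S2_D = rXX_ev[inv == j].sum(axis=0)
            ll += lin[j]
            for rk in range(mj):
                f = rk / mj
                s0 = S0[j] - f * S0_D[j]
                s1 = S1[j] - f * S1_D[j]
                s2 = S2[j] - f * S2_D
                xb = s1 / s0
                ll -= (dw[j] / mj) * np.log(s0)
                U += xw[j] / mj - (dw[j] / mj) * xb
                info += (dw[j] / mj) * (s2 / s0 - np.outer(xb, xb))
    haz_inc = dw / S0  # Breslow-form baseline-hazard increments (for residuals)
    xbar_b = S1 / S0[:, None]
    return ll, U, info, uniq, haz_inc, xbar_b, r, ev


def _score_residuals(
    beta: np.ndarray,
    ts: np.ndarray,
    delta: np.ndarray,
    Xs: np.ndarray,
    ws: np.ndarray,
    uniq: np.ndarray,
    haz_inc: np.ndarray,
    xbar: np.ndarray,
    r: np.ndarray,
):
    """Breslow-form weighted score residuals U_i (Therneau-Grambsch)."""
    n, p = Xs.shape
    H = np.concatenate([[0.0], np.cumsum(haz_inc)])          # cum hazard at uniq
    G = np.concatenate([np.zeros((1, p)), np.cumsum(haz_inc[:, None] * xbar, axis=0)])
    pos = np.searchsorted(uniq, ts, side="right")
    H_i = H[pos]
    G_i = G[pos]
    exp_eta = r / ws  # w * e^eta / w
    # event-time mean covariate at each subject's own event time
    xbar_at = np.zeros((n, p))
    ev = delta.astype(bool)
    j_of = np.searchsorted(uniq, ts[ev])
    xbar_at[ev] = xbar[j_of]
    s = delta[:, None] * (Xs - xbar_at) - exp_eta[:, None] * (Xs * H_i[:, None] - G_i)
    return ws[:, None] * s


def fit_cause_specific_cox(
    cohort: CohortTable,
    cause: int = 1,
    covariates: Sequence[str] | None = None,
    weights: WeightSet | np.ndarray | None = None,
    *,
    include_arm: bool = True,
    ties: str = "breslow",
    max_iter: int = 100,
    tol: float = 1e-9,
    alpha: float = 0.05,
) -> CoxFit:
    """Fit the weighted Cox model for the cause-k cause-specific hazard.

    Parameters
    ----------
    cohort
        Subject-level data; events of causes other than ``cause`` are
        censored at their time.
    cause
        Event code of the cause of interest (>= 1).
    covariates
        Adjustment covariates (categoricals expanded to indicators).
    weights
        ``WeightSet`` (aligned by subject_id), raw array, or None.
    include_arm
        Include treatment-arm indicators (vs. the reference arm).
    ties
        ``breslow`` (default, matching common weighted-PH practice) or
        ``efron``.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    if cause < 1 or cause > cohort.max_cause:
        raise ValueError(f"cause must be in 1..{cohort.max_cause}")

    if isinstance(weights, WeightSet):
        if len(weights.table) != cohort.n:
            # delete-mode truncation: restrict the cohort to retained subjects
            keep = cohort.data["subject_id"].isin(weights.subject_id).to_numpy()
            cohort = cohort.subset(keep)
        w = weights.align_to(cohort)
    elif weights is None:
        w = np.ones(cohort.n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (cohort.n,):
            raise ValueError("weights must align with subjects")

    cols: list[str] = []
    df = cohort.data.copy()
    if include_arm:
        df["arm"] = pd.Categorical(
            df["arm"].astype(str), categories=[str(a) for a in cohort.arms]
        )
        cols.append("arm")
    cols.extend(covariates or [])
    X, names = design_matrix(df, cols, intercept=False)
    if X.shape[1] == 0:
        raise ValueError("no model terms: need arm indicators and/or covariates")
    check_full_rank(X, names)
    names = [n.replace("arm[", "arm=") .replace("]", "") if n.startswith("arm[") else n for n in names]

    t = cohort.time
    delta = (cohort.event == cause).astype(float)
    n_events = int(delta.sum())
    if n_events == 0:
        raise ValueError(f"no events of cause {cause} in the cohort")

    order = np.argsort(t, kind="mergesort")
    ts, ds, Xs, ws = t[order], delta[order], X[order], w[order]

    p = X.shape[1]
    beta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, U, info, uniq, haz_inc, xbar, r, ev = _partial_lik_quantities(
            beta, ts, ds, Xs, ws, ties
        )
        try:
            step = np.linalg.solve(info, U)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError("singular information matrix") from err
        # step-halving if the likelihood decreases
        new_beta = beta + step
        for _ in range(30):
            ll_new = _partial_lik_quantities(new_beta, ts, ds, Xs, ws, ties)[0]
            if ll_new >= ll - 1e-12:
                break
            new_beta = (beta + new_beta) / 2
        beta = new_beta
        if np.max(np.abs(beta)) > 20:
            raise ConvergenceError(
                "diverging coefficients (monotone partial likelihood / complete "
                "separation); consider collapsing sparse arms or penalization"
            )
        if np.max(np.abs(step)) < tol or (
            np.isfinite(ll_old) and abs(ll_new - ll_old) < 1e-12 * (abs(ll_old) + 1)
        ):
            converged = True
            break
        ll_old = ll_new
    if not converged:
        raise ConvergenceError(
            f"Newton-Raphson did not converge in {max_iter} iterations "
            f"(last |step|max = {np.max(np.abs(step)):.3e})"
        )

    ll, U, info, uniq, haz_inc, xbar, r, ev = _partial_lik_quantities(
        beta, ts, ds, Xs, ws, ties
    )
    resid = _score_residuals(beta, ts, ds, Xs, ws, uniq, haz_inc, xbar, r)
    info_inv = np.linalg.inv(info)
    B = resid.T @ resid
    robust = info_inv @ B @ info_inv

    se = np.sqrt(np.diag(robust))
    z = stats.norm.ppf(1 - alpha / 2)
    hr = pd.DataFrame(
        {
            "hr": np.exp(beta),
            "ci_low": np.exp(beta - z * se),
            "ci_high": np.exp(beta + z * se),
            "se": se,
        },
        index=names,
    )
    return CoxFit(
        cause=cause,
        params=pd.Series(beta, index=names),
        robust_covariance=pd.DataFrame(robust, index=names, columns=names),
        hazard_ratios=hr,
        model_covariance=pd.DataFrame(info_inv, index=names, columns=names),
        n=cohort.n,
        n_events=n_events,
        weighted_n=float(ws.sum()),
        weighted_n_events=float(ws[ds.astype(bool)].sum()),
        ties_method=ties,
        converged=converged,
        n_iter=it,
        loglik=float(ll),
        reference_arm=cohort.reference_arm if include_arm else None,
    )


def hazard_ratio_table(
    fits: Sequence[CoxFit],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Arms x model-variant table of hazard ratios with 95% CIs.

    The reference arm is printed as HR 1 with no interval.  All fits must
    share the same arm structure.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("need at least one fit")
    labels = list(labels) if labels is not None else [f"model_{i}" for i in range(len(fits))]
    arm_terms = [t for t in fits[0].params.index if t.startswith("arm=")]
    ref = fits[0].reference_arm
    for f in fits[1:]:
        if [t for t in f.params.index if t.startswith("arm=")] != arm_terms:
            raise ValueError("fits have mismatched arm structures")
    rows = []
    arms = [ref] + [t.split("=", 1)[1] for t in arm_terms]
    for arm in arms:
        row: dict[str, object] = {"arm": arm}
        for lab, f in zip(labels, fits):
            if arm == ref:
                row[f"{lab}_hr"] = 1.0
                row[f"{lab}_ci"] = ""
            else:
                h = f.hazard_ratios.loc[f"arm={arm}"]
                row[f"{lab}_hr"] = float(h["hr"])
                row[f"{lab}_ci"] = f"{h['ci_low']:.2f}, {h['ci_high']:.2f}"
        rows.append(row)
    return pd.DataFrame(rows).set_index("arm")
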