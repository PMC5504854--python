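"""Nonparametric estimators for competing-risks data.

Implements the weighted and unweighted product-limit (Kaplan-Meier)
survival estimator, the "naive" KM cumulative-incidence estimator that
censors competing events (deliberately biased; kept for comparison), and
the Aalen-Johansen cumulative-incidence estimator

    CIF_k(t) = sum_{t_j <= t}  (d_kj / n_j) * S(t_j-),

where ``S(t-)`` is the left limit of the all-cause KM survival curve,
``d_kj`` the (weight-summed) number of cause-k events at the distinct event
time ``t_j`` and ``n_j`` the (weight-summed) number at risk.  With all
weights equal to one these reduce to the classical counting-process forms;
with inverse-probability-of-treatment weights they estimate the curves in
the weighted pseudo-population.

Conventions: the risk set at t contains every subject with observed time
>= t (events are counted at t; subjects censored at t are still at risk at
t); ties across causes at one time are pooled into a single event time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import CohortTable

__all__ = [
    "StepFunction",
    "RiskSetSeries",
    "build_risk_sets",
    "km_survival",
    "naive_km_cif",
    "competing_risks_cif",
    "cif_at",
    "BootstrapResult",
    "bootstrap_ci",
]


@dataclass
class StepFunction:
    """Right-continuous piecewise-constant function of time.

    ``values[i]`` is the function value on ``[times[i], times[i+1])``;
    ``origin_value`` the value on ``[0, times[0])``.  ``variance``, when
    present, is the pointwise variance at the jump times (Greenwood for the
    unweighted KM).
    """

    times: np.ndarray
    values: np.ndarray
    origin_value: float = 1.0
    variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.shape != self.times.shape:
            raise ValueError("times and values must be matching 1-d arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("jump times must be strictly increasing")

    def __call__(self, t) -> np.ndarray | float:
        """Right-continuous evaluation; beyond the last jump, the last value."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("time must be non-negative")
        idx = np.searchsorted(self.times, t_arr, side="right")
        padded = np.concatenate([[self.origin_value], self.values])
        out = padded[idx]
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.times, "value": self.values})
        if self.variance is not None:
            df["variance"] = self.variance
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class RiskSetSeries:
    """Weighted risk-set and event counts at the distinct event times.

    ``n_at_risk[j]`` is the weight sum of subjects with time >= times[j];
    ``d[c][j]`` the weight sum of cause-c events at times[j] (``d_count``
    the raw counts).  ``weighted`` records whether non-unit weights were
    supplied, which downstream decides whether Greenwood variances apply.
    """

    times: np.ndarray
    n_at_risk: np.ndarray
    d: dict[int, np.ndarray]
    d_count: dict[int, np.ndarray] = field(default_factory=dict)
    weighted: bool = False
    total_weight: float = 0.0

    @property
    def causes(self) -> list[int]:
        return sorted(self.d)

    def d_all(self) -> np.ndarray:
        """Weight-summed events of any cause at each event time."""
        return np.sum([self.d[c] for c in self.causes], axis=0)


def build_risk_sets(
    cohort: CohortTable,
    weights: Sequence[float] | None = None,
) -> RiskSetSeries:
    """Tabulate weighted at-risk and per-cause event sums at event times.

    ``weights=None`` means unit weights; if the cohort carries a weight
    column it is *not* used implicitly — pass ``cohort.weight`` explicitly.
    """
    t = cohort.time
    e = cohort.event
    if weights is None:
        w = np.ones_like(t)
        weighted = False
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != t.shape:
            raise ValueError("weights must align with subjects")
        weighted = bool(np.any(w != 1.0))

    causes = sorted(int(c) for c in np.unique(e) if c != 0)
    event_mask = e != 0
    times = np.unique(t[event_mask])
    if times.size == 0:
        return RiskSetSeries(
            times=times,
            n_at_risk=np.empty(0),
            d={},
            d_count={},
            weighted=weighted,
            total_weight=float(w.sum()),
        )

    # n_j = weight sum over {i : t_i >= tau_j}; computed by sorting once
    order = np.argsort(t, kind="mergesort")
    ts = t[order]
    ws = w[order]
    tail = np.concatenate([np.cumsum(ws[::-1])[::-1], [0.0]])
    first_idx = np.searchsorted(ts, times, side="left")
    n_at_risk = tail[first_idx]

    d: dict[int, np.ndarray] = {}
    d_count: dict[int, np.ndarray] = {}
    for c in causes:
        m = e == c
        idx = np.searchsorted(times, t[m])
        d[c] = np.bincount(idx, weights=w[m], minlength=times.size)
        d_count[c] = np.bincount(idx, minlength=times.size).astype(float)
    return RiskSetSeries(
        times=times,
        n_at_risk=n_at_risk,
        d=d,
        d_count=d_count,
        weighted=weighted,
        total_weight=float(w.sum()),
    )


def km_survival(
    riskset: RiskSetSeries,
    cause_set: Iterable[int] | None = None,
) -> StepFunction:
    """Product-limit survival estimate counting ``cause_set`` as the event.

    Causes outside ``cause_set`` deplete the risk set but are treated as
    censoring (that treatment is exactly what makes the derived "naive" CIF
    biased in the presence of competing events).  ``cause_set=None`` counts
    every cause, giving the all-cause (event-free) survival curve.
    Pointwise Greenwood variance is attached for unweighted data.
    """
    causes = riskset.causes if cause_set is None else [c for c in riskset.causes if c in set(cause_set)]
    if riskset.times.size == 0 or not causes:
        return StepFunction(np.empty(0), np.empty(0), origin_value=1.0)
    d = np.sum([riskset.d[c] for c in causes], axis=0)
    n = riskset.n_at_risk
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(n > 0, d / n, 0.0)
    surv = np.cumprod(1.0 - frac)
    variance = None
    if not riskset.weighted:
        # Greenwood: var(S) = S^2 * sum d / (n (n - d))
        denom = n * (n - d)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(denom > 0, d / denom, 0.0)
        variance = surv**2 * np.cumsum(term)
    return StepFunction(riskset.times, surv, origin_value=1.0, variance=variance)


def naive_km_cif(riskset: RiskSetSeries, cause: int = 1) -> StepFunction:
    """1 - KM with competing events censored: the biased comparison CIF.

    This estimator over-states the cumulative incidence whenever competing
    events occur, because subjects removed by a competing event can never
    experience the event of interest yet are treated as if they still could.
    """
    km = km_survival(riskset, cause_set=[cause])
    if km.times.size == 0:
        return StepFunction(np.empty(0), np.empty(0), origin_value=0.0)
    return StepFunction(km.times, 1.0 - km.values, origin_value=0.0, variance=km.variance)


def competing_risks_cif(riskset: RiskSetSeries, cause: int = 1) -> StepFunction:
    """Aalen-Johansen cumulative incidence for ``cause``.

    Increments are (d_kj / n_j) * S(t_j-) with S the all-cause KM curve;
    weighted counts are used throughout when weights were supplied.
    """
    if riskset.times.size == 0 or cause not in riskset.d:
        return StepFunction(np.empty(0), np.empty(0), origin_value=0.0)
    surv_all = km_survival(riskset, cause_set=None)
    s_left = np.concatenate([[1.0], surv_all.values[:-1]])
    n = riskset.n_at_risk
    with np.errstate(divide="ignore", invalid="ignore"):
        haz = np.where(n > 0, riskset.d[cause] / n, 0.0)
    cif = np.cumsum(haz * s_left)
    return StepFunction(riskset.times, cif, origin_value=0.0)


def cif_at(fn: StepFunction, t: float) -> float:
    """Evaluate a step function at horizon ``t`` (right-continuous)."""
    if t < 0:
        raise ValueError("time must be non-negative")
    if fn.times.size == 0:
        return float(fn.origin_value)
    return float(fn(t))


@dataclass
class BootstrapResult:
    """Percentile bootstrap interval for a cohort-level statistic."""

    estimate: float
    lower: float
    upper: float
    replicates: np.ndarray
    n_degenerate: int
    seed: int


def bootstrap_ci(
    cohort: CohortTable,
    statistic: Callable[[CohortTable], float],
    *,
    reps: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> BootstrapResult:
    """Subject-level percentile bootstrap of ``statistic``.

    ``statistic`` receives a resampled cohort and must re-run the full
    pipeline, including weight re-estimation, so that the interval reflects
    all sources of sampling variability.  Replicates that raise
    ``ValueError`` or return a non-finite value (e.g. a resample without
    any event of the target cause) are recorded as degenerate and excluded
    from the percentiles.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    rng = np.random.default_rng(seed)
    point = float(statistic(cohort))
    values = np.empty(reps)
    n_bad = 0
    for r in range(reps):
        sample = cohort.resample(rng)
        try:
            v = float(statistic(sample))
        except ValueError:
            v = np.nan
        if not np.isfinite(v):
            n_bad += 1
            v = np.nan
        values[r] = v
    good = values[np.isfinite(values)]
    if good.size == 0:
        raise ValueError("all bootstrap replicates were degenerate")
    lo, hi = np.percentile(good, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapResult(
        estimate=point,
        lower=float(lo),
        upper=float(hi),
        replicates=values,
        n_degenerate=n_bad,
        seed=seed,
    )
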