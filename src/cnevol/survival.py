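"""Survival analysis of heterogeneity-defined patient groups.

Kaplan-Meier medians and log-rank comparisons of the CE-low/CE-high
groups, multivariable Cox proportional-hazards regression, an optional
penalized-spline check for a nonlinear CE effect, and a patient-level
bootstrap of the whole dichotomize-and-test procedure.

Durations are stored in days; group medians are reported in months at 30
days per month, rounded to one decimal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import multivariate_logrank_test

from .landscape import lower_median

__all__ = [
    "km_median",
    "logrank_test",
    "cox_fit",
    "spline_hazard",
    "bootstrap_robustness",
    "CoxResult",
    "BootstrapSummary",
]

DAYS_PER_MONTH = 30.0


def km_median(durations, events=None) -> float | None:
    """Kaplan-Meier median survival in months (1 decimal), or None.

    With every event observed this equals the sample median (the smallest
    time at which the survival estimate drops to <= 0.5).  Returns ``None``
    when the survival curve never reaches 0.5.
    """
    durations = np.asarray(durations, dtype=float)
    if len(durations) == 0:
        raise ValueError("need >= 1 subject")
    if events is None:
        events = np.ones_like(durations)
    km = KaplanMeierFitter().fit(durations, np.asarray(events, dtype=bool))
    med = km.median_survival_time_
    if not np.isfinite(med):
        return None
    return round(float(med) / DAYS_PER_MONTH, 1)


def logrank_test(durations, events, groups) -> float:
    """Log-rank chi-squared p-value between two (or more) groups."""
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("log-rank test needs >= 2 groups")
    res = multivariate_logrank_test(
        np.asarray(durations, dtype=float), groups, np.asarray(events, dtype=bool)
    )
    return float(res.p_value)


@dataclass(frozen=True)
class CoxResult:
    hazard_ratios: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    p_values: dict[str, float]
    converged: bool = True

    def hr(self, covariate: str) -> float:
        return self.hazard_ratios[covariate]


def cox_fit(df: pd.DataFrame, duration_col: str, event_col: str, covariates: list[str]) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties) with Wald 95% CIs.

    Non-convergence or complete separation is flagged rather than raised;
    coefficients are then reported as missing.
    """
    for c in covariates:
        if df[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} has zero variance")
    data = df[[duration_col, event_col] + covariates].copy()
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=ConvergenceWarning)
            cph.fit(data, duration_col=duration_col, event_col=event_col)
    except (ConvergenceError, ConvergenceWarning):
        nan = {c: float("nan") for c in covariates}
        return CoxResult(nan, dict(nan), dict(nan), dict(nan), converged=False)
    summ = cph.summary
    return CoxResult(
        hazard_ratios={c: float(summ.loc[c, "exp(coef)"]) for c in covariates},
        ci_lower={c: float(summ.loc[c, "exp(coef) lower 95%"]) for c in covariates},
        ci_upper={c: float(summ.loc[c, "exp(coef) upper 95%"]) for c in covariates},
        p_values={c: float(summ.loc[c, "p"]) for c in covariates},
    )


def spline_hazard(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    value_col: str,
    n_knots: int = 4,
    penalizer: float = 0.1,
    n_grid: int = 50,
) -> pd.DataFrame:
    """Penalized cubic-spline log relative hazard for a continuous marker.

    Fits a Cox model on a natural cubic spline basis of ``value_col``
    (knots at quantiles) with an L2 penalty, and evaluates the centred log
    relative hazard with pointwise Wald 95% bands over the inner 95% range
    of the marker.  Diagnostic stage: the curve shape, not its p-values,
    is the object of interest.
    """
    x = df[value_col].to_numpy(dtype=float)
    if len(np.unique(x)) < n_knots + 1:
        raise ValueError("insufficient unique marker values for a spline fit")
    knots = np.quantile(x, np.linspace(0.05, 0.95, n_knots))

    def basis(v: np.ndarray) -> np.ndarray:
        # natural cubic spline (truncated power basis, linear beyond ends)
        k = knots
        d = lambda j: ((np.maximum(v - k[j], 0) ** 3 - np.maximum(v - k[-1], 0) ** 3)
                       / (k[-1] - k[j]))
        cols = [v] + [d(j) - d(len(k) - 2) for j in range(len(k) - 2)]
        return np.column_stack(cols)

    B = basis(x)
    names = [f"s{j}" for j in range(B.shape[1])]
    data = pd.DataFrame(B, columns=names)
    data[duration_col] = df[duration_col].to_numpy(dtype=float)
    data[event_col] = df[event_col].to_numpy(dtype=bool)
    cph = CoxPHFitter(penalizer=penalizer)
    cph.fit(data, duration_col=duration_col, event_col=event_col)
    beta = cph.params_[names].to_numpy()
    cov = cph.variance_matrix_.loc[names, names].to_numpy()
    lo, hi = np.quantile(x, [0.025, 0.975])
    grid = np.linspace(lo, hi, n_grid)
    G = basis(grid)
    center = basis(np.array([np.median(x)]))
    Gc = G - center
    eta = Gc @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", Gc, cov, Gc))
    return pd.DataFrame(
        {
            value_col: grid,
            "log_hazard": eta,
            "ci_lower": eta - 1.96 * se,
            "ci_upper": eta + 1.96 * se,
        }
    )


@dataclass(frozen=True)
class BootstrapSummary:
    frac_significant: float
    median_hr: float
    hr_ci: tuple[float, float]
    n_effective: int
    n_single_group: int
    alpha: float = 0.05


def bootstrap_robustness(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    ce_col: str = "ce_index",
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> BootstrapSummary:
    """Patient-resampling bootstrap of the median-CE survival comparison.

    Each replicate resamples patients with replacement, recomputes the
    lower-median CE split, and records the log-rank p-value and the
    univariable Cox hazard ratio of CE-high versus CE-low.  Replicates
    collapsing to a single group are counted separately and excluded from
    the significant-fraction denominator.
    """
    rng = np.random.default_rng(seed)
    dur = df[duration_col].to_numpy(dtype=float)
    ev = df[event_col].to_numpy(dtype=bool)
    ce = df[ce_col].to_numpy(dtype=float)
    n = len(df)
    n_sig = 0
    n_single = 0
    hrs: list[float] = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        thr = lower_median(ce[idx])
        grp = ce[idx] > thr
        if grp.all() or (~grp).all() or ev[idx].sum() == 0:
            n_single += 1
            continue
        try:
            p = logrank_test(dur[idx], ev[idx], grp.astype(int))
        except (ValueError, ZeroDivisionError):
            n_single += 1
            continue
        if p < alpha:
            n_sig += 1
        boot = pd.DataFrame({"t": dur[idx], "e": ev[idx], "g": grp.astype(float)})
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = CoxPHFitter().fit(boot, duration_col="t", event_col="e")
            hrs.append(float(np.exp(cph.params_["g"])))
        except Exception:
            pass  # separation in a replicate: HR unavailable, p still counted
    n_eff = n_boot - n_single
    frac = n_sig / n_eff if n_eff else float("nan")
    hrs_arr = np.asarray(hrs) if hrs else np.asarray([np.nan])
    return BootstrapSummary(
        frac_significant=frac,
        median_hr=float(np.nanmedian(hrs_arr)),
        hr_ci=(float(np.nanpercentile(hrs_arr, 2.5)), float(np.nanpercentile(hrs_arr, 97.5))),
        n_effective=n_eff,
        n_single_group=n_single,
        alpha=alpha,
    )
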