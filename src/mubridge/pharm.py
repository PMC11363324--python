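"""Concentration-response and dose-response summaries.

Agonist concentration-response data are fitted with the four-parameter
logistic (4PL, Hill) model

    y(c) = baseline + (Emax − baseline) / (1 + 10^((log10 EC50 − log10 c)·h)),

reported both as EC50 in nM and pEC50 = −log10(EC50 in M). For agonist-mode
BRET data normalised to a reference full agonist the baseline is fixed at 0
and only Emax, pEC50 and the Hill slope h are free (h constrained to
[0.3, 5]). Antinociception time-course data in %MPE (percent maximum
possible effect, bounded in [0, 100] by definition) are fitted with the
two-parameter log-logistic

    %MPE(dose) = 100 / (1 + (ED50/dose)^s),

with the 95% CI computed by the delta method on log10(ED50). Brain:plasma
partitioning is summarised as the concentration ratio, reported rounded to
one decimal alongside full precision.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FitResult",
    "Ed50Result",
    "RatioResult",
    "four_pl",
    "log_logistic_mpe",
    "fit_4pl",
    "normalize_to_reference",
    "fit_ed50",
    "brain_plasma_ratio",
]


def four_pl(logc, emax, pec50, hill, baseline=0.0):
    """4PL response at log10 concentration(s) ``logc`` (concentration in M)."""
    logc = np.asarray(logc, float)
    return baseline + (emax - baseline) / (1.0 + 10.0 ** ((-pec50 - logc) * hill))


def log_logistic_mpe(dose, ed50, slope):
    """Two-parameter log-logistic %MPE with floor 0 and ceiling 100."""
    dose = np.asarray(dose, float)
    return 100.0 / (1.0 + (ed50 / dose) ** slope)


@dataclasses.dataclass
class FitResult:
    """4PL fit summary.

    ``activity`` is one of ``"active"``, ``"no_detectable_activity"``
    (flat, near-zero responses) or ``"not_measurable"`` (fitted Emax not
    distinguishable from 0: its CI includes 0 or its magnitude is below
    3× the residual noise).
    """

    emax: float
    pec50: float
    hill: float
    baseline: float
    ec50_nm: float
    se: dict
    ci95: dict
    converged: bool
    activity: str
    residual_sd: float
    n: int

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _extract_xy(data, x_col: str, y_col: str):
    if isinstance(data, pd.DataFrame):
        x = data[x_col].to_numpy(float)
        y = data[y_col].to_numpy(float)
    else:
        x, y = (np.asarray(v, float) for v in data)
    if np.any(x <= 0):
        raise ValueError(f"{x_col} values must be strictly positive")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    return x, y


def fit_4pl(
    data,
    baseline: float = 0.0,
    free_baseline: bool = False,
    hill_bounds: tuple[float, float] = (0.3, 5.0),
    conc_col: str = "conc_M",
    response_col: str = "response_pct",
) -> FitResult:
    """Least-squares 4PL fit of a concentration-response dataset.

    ``data`` is a DataFrame with columns ``conc_M``/``response_pct`` (or a
    pair of arrays). The fit multi-starts over a pEC50 grid spanning the
    observed concentration range to avoid local minima; standard errors
    come from the scaled covariance at the optimum, CIs are t-based. A
    non-converged fit is flagged, never silently returned.
    """
    conc, resp = _extract_xy(data, conc_col, response_col)
    logc = np.log10(conc)
    if len(np.unique(np.round(logc, 9))) < 4:
        raise ValueError("fit_4pl requires at least 4 distinct concentrations")

    pec_lo, pec_hi = -logc.max() - 2.0, -logc.min() + 2.0
    emax_hi = max(200.0, 3.0 * float(np.max(np.abs(resp))) + 10.0)
    if free_baseline:
        def model(x, emax, pec50, hill, base):
            return four_pl(x, emax, pec50, hill, base)

        lb = [0.0, pec_lo, hill_bounds[0], -50.0]
        ub = [emax_hi, pec_hi, hill_bounds[1], 50.0]
        names = ["emax", "pec50", "hill", "baseline"]
    else:
        def model(x, emax, pec50, hill):
            return four_pl(x, emax, pec50, hill, baseline)

        lb = [0.0, pec_lo, hill_bounds[0]]
        ub = [emax_hi, pec_hi, hill_bounds[1]]
        names = ["emax", "pec50", "hill"]

    emax0 = float(np.clip(np.max(resp), 1.0, emax_hi - 1.0))
    best = None
    for pec0 in np.linspace(-logc.max(), -logc.min(), 5):
        p0 = [emax0, float(np.clip(pec0, pec_lo + 1e-6, pec_hi - 1e-6)), 1.0]
        if free_baseline:
            p0 = p0 + [0.0]
        try:
            popt, pcov = optimize.curve_fit(
                model, logc, resp, p0=p0, bounds=(lb, ub), maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((model(logc, *popt) - resp) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)

    n = len(resp)
    if best is None:
        nan = float("nan")
        return FitResult(
            emax=nan, pec50=nan, hill=nan, baseline=baseline, ec50_nm=nan,
            se={}, ci95={}, converged=False, activity="not_measurable",
            residual_sd=nan, n=n,
        )

    sse, popt, pcov = best
    p = len(popt)
    dof = max(n - p, 1)
    residual_sd = float(np.sqrt(sse / dof))
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    tcrit = float(stats.t.ppf(0.975, dof))
    params = dict(zip(names, (float(v) for v in popt)))
    se_d = dict(zip(names, (float(v) for v in se)))
    ci = {k: (params[k] - tcrit * se_d[k], params[k] + tcrit * se_d[k]) for k in names}

    emax = params["emax"]
    base = params.get("baseline", baseline)
    span = emax - base
    if np.max(resp) - np.min(resp) < 1e-9 and np.max(np.abs(resp)) < 1e-9:
        activity = "no_detectable_activity"
    elif ci["emax"][0] <= 0.0 or span < 3.0 * residual_sd:
        activity = "not_measurable"
    else:
        activity = "active"

    return FitResult(
        emax=emax,
        pec50=params["pec50"],
        hill=params["hill"],
        baseline=base,
        ec50_nm=float(10.0 ** (9.0 - params["pec50"])),
        se=se_d,
        ci95=ci,
        converged=True,
        activity=activity,
        residual_sd=residual_sd,
        n=n,
    )


def normalize_to_reference(raw, reference_max: float):
    """Express raw responses as % of a reference agonist's maximum.

    Values above 100% are allowed (responses can exceed the reference
    maximum, e.g. high-efficacy agonists in low-amplification readouts).
    """
    if reference_max <= 0:
        raise ValueError("reference maximum must be > 0")
    return 100.0 * np.asarray(raw, float) / float(reference_max)


@dataclasses.dataclass
class Ed50Result:
    ed50: float  # same dose units as the input
    slope: float
    ci95: tuple[float, float]
    se_log10_ed50: float
    ci_method: str
    converged: bool
    residual_sd: float
    n: int


def fit_ed50(
    data,
    dose_col: str = "dose_mg_kg",
    response_col: str = "mpe_pct",
) -> Ed50Result:
    """Two-parameter log-logistic fit of graded %MPE dose-response data.

    Subject-level records are fitted directly (no per-dose averaging).
    The 95% CI is the delta-method interval on log10(ED50), back-
    transformed to the dose scale; the method is recorded in the result.
    """
    dose, mpe = _extract_xy(data, dose_col, response_col)
    if len(np.unique(dose)) < 3:
        raise ValueError("fit_ed50 requires at least 3 distinct doses")
    if np.all(mpe <= 1e-9):
        raise ValueError("no intermediate response: all %MPE values are 0")
    if np.all(mpe >= 100.0 - 1e-9):
        raise ValueError("no intermediate response: all %MPE values are 100")

    logd = np.log10(dose)

    def model(ld, log_ed50, slope):
        return 100.0 / (1.0 + 10.0 ** (slope * (log_ed50 - ld)))

    p0 = [float(np.median(logd)), 1.0]
    bounds = ([logd.min() - 3.0, 0.1], [logd.max() + 3.0, 15.0])
    try:
        popt, pcov = optimize.curve_fit(
            model, logd, mpe, p0=p0, bounds=bounds, maxfev=20000
        )
        converged = True
    except (RuntimeError, ValueError):
        popt = np.array([np.nan, np.nan])
        pcov = np.full((2, 2), np.nan)
        converged = False

    n = len(mpe)
    dof = max(n - 2, 1)
    sse = float(np.sum((model(logd, *popt) - mpe) ** 2)) if converged else float("nan")
    residual_sd = float(np.sqrt(sse / dof)) if converged else float("nan")
    se_l = float(np.sqrt(max(pcov[0, 0], 0.0))) if converged else float("nan")
    tcrit = float(stats.t.ppf(0.975, dof))
    log_ed50 = float(popt[0])
    ci = (10.0 ** (log_ed50 - tcrit * se_l), 10.0 ** (log_ed50 + tcrit * se_l))
    return Ed50Result(
        ed50=float(10.0 ** log_ed50),
        slope=float(popt[1]),
        ci95=ci,
        se_log10_ed50=se_l,
        ci_method="delta-method on log10(ED50), t-based",
        converged=converged,
        residual_sd=residual_sd,
        n=n,
    )


@dataclasses.dataclass(frozen=True)
class RatioResult:
    ratio: float
    reported: float  # rounded to 1 decimal, as conventionally reported


def brain_plasma_ratio(brain: float, plasma: float) -> RatioResult:
    """Brain-to-plasma concentration ratio (unitless)."""
    if plasma <= 0:
        raise ValueError("plasma concentration must be > 0")
    ratio = float(brain) / float(plasma)
    return RatioResult(ratio=ratio, reported=round(ratio, 1))
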