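"""Receptor-APEX proximity-proteomics analysis.

Two stages operate on a tidy protein-intensity table with columns
``protein_id, sample_type, location_or_time, replicate, intensity``:

1. **Spatial deconvolution** — for each receptor-sample column (time point
   × replicate), the receptor's subcellular distribution is estimated by
   regressing the intensities of location-specific indicator proteins on
   the spatial reference profiles (plasma membrane, early endosome,
   lysosome): ``min ‖y − Xβ‖²`` with ``β ≥ 0`` (NNLS), optionally
   normalised to sum to 1 for reporting. Fractions of receptor at a
   location cannot be negative, hence the nonnegativity default; an
   unconstrained least-squares mode is available behind a flag.

2. **Time-course statistics** — per protein, log2 intensities are
   regressed on a polynomial in time (degree 2 by default over a 0–30 min
   course) and an F-test of the polynomial model against the
   intercept-only model measures the significance of change over time.
   Log2 fold changes versus the pre-stimulation baseline are computed per
   replicate and averaged. A protein is called a hit iff
   ``max |log2FC| > 0.58`` and ``p < 0.001`` (strict inequalities, no
   multiple-testing correction).

Intensities are log2-transformed after adding a pseudocount of half the
smallest positive intensity in the matrix.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import nnls

__all__ = [
    "RECEPTOR",
    "DeconvolutionError",
    "DeconvolutionResult",
    "TimecourseFit",
    "compute_location_coefficients",
    "reference_profiles",
    "deconvolve_timecourse",
    "fit_timecourse",
    "log2fc",
    "timecourse_stats",
    "call_hits",
    "apex_pipeline",
]

RECEPTOR = "receptor"
REFERENCE_PREFIX = "reference:"

LFC_THRESHOLD = 0.58
P_THRESHOLD = 0.001


class DeconvolutionError(ValueError):
    pass


@dataclasses.dataclass
class DeconvolutionResult:
    coefficients: pd.Series  # per location, normalised if requested
    raw: pd.Series  # unnormalised solution
    residual_norm: float
    method: str  # "nnls" or "lstsq"
    normalized: bool


def compute_location_coefficients(
    y,
    X: pd.DataFrame,
    nonneg: bool = True,
    normalize: bool = True,
) -> DeconvolutionResult:
    """Solve one receptor column against the reference profile matrix.

    ``X`` is (indicator proteins × locations), ``y`` the receptor-sample
    intensities of the same indicator proteins. Raises
    :class:`DeconvolutionError` when ``X`` is rank-deficient, naming the
    locations whose profiles are collinear.
    """
    if isinstance(y, pd.Series):
        y = y.reindex(X.index).to_numpy(float)
    else:
        y = np.asarray(y, float)
    A = X.to_numpy(float)
    locations = list(X.columns)
    if A.shape[0] < A.shape[1]:
        raise DeconvolutionError(
            f"need at least {A.shape[1]} indicator proteins, got {A.shape[0]}"
        )
    if np.linalg.matrix_rank(A) < A.shape[1]:
        full = np.linalg.matrix_rank(A)
        collinear = [
            loc
            for j, loc in enumerate(locations)
            if np.linalg.matrix_rank(np.delete(A, j, axis=1)) == full
        ]
        raise DeconvolutionError(
            "reference profile matrix is rank-deficient; collinear locations: "
            + ", ".join(collinear or locations)
        )
    if nonneg:
        beta, rnorm = nnls(A, y)
        method = "nnls"
    else:
        beta, res, _, _ = np.linalg.lstsq(A, y, rcond=None)
        rnorm = float(np.sqrt(res[0])) if len(res) else float(
            np.linalg.norm(A @ beta - y)
        )
        method = "lstsq"
    raw = pd.Series(beta, index=locations)
    coef = raw.copy()
    if normalize:
        total = coef.sum()
        if total > 0:
            coef = coef / total
    return DeconvolutionResult(
        coefficients=coef,
        raw=raw,
        residual_norm=float(rnorm),
        method=method,
        normalized=normalize,
    )


def _split_samples(tidy: pd.DataFrame):
    st = tidy["sample_type"].astype(str)
    receptor = tidy[st == RECEPTOR]
    references = tidy[st.str.startswith(REFERENCE_PREFIX)].copy()
    if references.empty or receptor.empty:
        raise ValueError("table must contain both receptor and reference samples")
    references["location"] = references["sample_type"].str[len(REFERENCE_PREFIX):]
    return receptor, references


def reference_profiles(
    tidy: pd.DataFrame, indicator_map: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Mean reference intensity per (indicator protein × location).

    Rows are the union of all indicator proteins, columns the locations in
    ``indicator_map`` order.
    """
    _, references = _split_samples(tidy)
    indicators = [p for ids in indicator_map.values() for p in ids]
    if len(set(indicators)) != len(indicators):
        raise ValueError("indicator protein sets must be disjoint across locations")
    prof = (
        references[references["protein_id"].isin(indicators)]
        .groupby(["protein_id", "location"])["intensity"]
        .mean()
        .unstack("location")
    )
    missing = sorted(set(indicators) - set(prof.index))
    if missing:
        raise ValueError(f"indicator proteins missing from references: {missing[:5]}")
    return prof.loc[indicators, list(indicator_map)]


def deconvolve_timecourse(
    tidy: pd.DataFrame,
    indicator_map: Mapping[str, Sequence[str]],
    nonneg: bool = True,
    normalize: bool = True,
) -> pd.DataFrame:
    """Location coefficients for every receptor (time, replicate) column.

    Returns a tidy DataFrame with columns ``time, replicate, <location...>,
    residual_norm``.
    """
    receptor, _ = _split_samples(tidy)
    X = reference_profiles(tidy, indicator_map)
    rows = []
    grouped = receptor[receptor["protein_id"].isin(X.index)].groupby(
        ["location_or_time", "replicate"]
    )
    for (time, rep), g in grouped:
        y = g.set_index("protein_id")["intensity"].reindex(X.index)
        if y.isna().any():
            raise ValueError(
                f"receptor sample (t={time}, rep={rep}) is missing indicator proteins"
            )
        res = compute_location_coefficients(y, X, nonneg=nonneg, normalize=normalize)
        row = {"time": float(time), "replicate": rep, "residual_norm": res.residual_norm}
        row.update({loc: float(v) for loc, v in res.coefficients.items()})
        rows.append(row)
    out = pd.DataFrame(rows).sort_values(["time", "replicate"]).reset_index(drop=True)
    return out[["time", "replicate", *X.columns, "residual_norm"]]


@dataclasses.dataclass
class TimecourseFit:
    f_statistic: float
    p_value: float
    coefficients: np.ndarray
    fitted: np.ndarray
    flag: str  # "", "constant" or "zero_residual"


def fit_timecourse(
    times, values, degree: int = 2, time_scale: str = "index"
) -> TimecourseFit:
    """Polynomial OLS of log2 intensity on time with an overall F-test.

    The F statistic compares the degree-``degree`` polynomial against the
    intercept-only model, with (degree, N − degree − 1) degrees of
    freedom. ``time_scale`` chooses the polynomial axis: ``"index"``
    (default) evaluates the polynomial on the rank of each time point,
    which for the roughly log-spaced 0/1/5/10/30-min sampling grid weights
    early and late dynamics evenly (approximately a log-time axis);
    ``"minutes"`` uses raw time. A perfectly constant series gives F = 0,
    p = 1; a model with zero residual variance is flagged and reported at
    the smallest positive float rather than p = 0.
    """
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    if len(t) != len(y):
        raise ValueError("times and values must have equal length")
    if len(np.unique(t)) < degree + 2:
        raise ValueError(
            f"need at least {degree + 2} distinct time points for degree {degree}"
        )
    if time_scale == "index":
        uniq = np.unique(t)
        ts = np.searchsorted(uniq, t).astype(float) / max(len(uniq) - 1, 1)
    elif time_scale == "minutes":
        tmax = t.max()
        ts = t / tmax if tmax > 0 else t
    else:
        raise ValueError("time_scale must be 'index' or 'minutes'")
    X = np.vander(ts, degree + 1, increasing=True)  # column 0 is the intercept
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 1e-12:
        return TimecourseFit(0.0, 1.0, np.zeros(degree + 1), np.full_like(y, y.mean()),
                             "constant")
    fit = sm.OLS(y, X).fit()
    sse = float(fit.ssr)
    if sse <= 1e-12 * sst:
        return TimecourseFit(
            float("inf"), float(np.nextafter(0, 1)), np.asarray(fit.params),
            np.asarray(fit.fittedvalues), "zero_residual"
        )
    return TimecourseFit(
        float(fit.fvalue), float(fit.f_pvalue), np.asarray(fit.params),
        np.asarray(fit.fittedvalues), ""
    )


def log2fc(protein_df: pd.DataFrame, baseline_time: float = 0.0) -> pd.Series:
    """Per-time log2 fold change vs. baseline for one protein.

    ``protein_df`` has columns ``location_or_time, replicate, intensity``.
    Ratios are formed within each replicate against that replicate's
    baseline, then averaged across replicates.
    """
    df = protein_df.copy()
    df["time"] = df["location_or_time"].astype(float)
    wide = df.pivot_table(index="replicate", columns="time", values="intensity")
    if baseline_time not in wide.columns:
        raise ValueError(f"baseline time point {baseline_time} absent from data")
    base = wide[baseline_time]
    if (base <= 0).any():
        raise ValueError("zero or negative baseline intensity")
    lfc = np.log2(wide.div(base, axis=0))
    return lfc.mean(axis=0)


def _pseudocount(intensities: np.ndarray) -> float:
    pos = intensities[intensities > 0]
    if len(pos) == 0:
        raise ValueError("intensity matrix contains no positive values")
    return float(pos.min()) / 2.0


def timecourse_stats(
    tidy: pd.DataFrame,
    degree: int = 2,
    baseline_time: float = 0.0,
    time_scale: str = "index",
) -> pd.DataFrame:
    """Per-protein time-course statistics for the receptor samples.

    Returns a DataFrame indexed by ``protein_id`` with per-time log2 fold
    changes (``lfc_<t>``), ``lfc_max`` (max |log2FC| over time), the F
    statistic, p-value and fit flag.
    """
    receptor, _ = _split_samples(tidy)
    receptor = receptor.copy()
    pc = _pseudocount(receptor["intensity"].to_numpy(float))
    receptor["intensity"] = receptor["intensity"].astype(float) + pc
    receptor["time"] = receptor["location_or_time"].astype(float)
    rows = []
    for pid, g in receptor.groupby("protein_id", sort=True):
        fit = fit_timecourse(
            g["time"].to_numpy(), np.log2(g["intensity"].to_numpy()),
            degree=degree, time_scale=time_scale,
        )
        lfc = log2fc(g, baseline_time=baseline_time)
        row = {"protein_id": pid, "F": fit.f_statistic, "p": fit.p_value,
               "flag": fit.flag, "lfc_max": float(np.max(np.abs(lfc.to_numpy())))}
        for t, v in lfc.items():
            row[f"lfc_{t:g}"] = float(v)
        rows.append(row)
    return pd.DataFrame(rows).set_index("protein_id")


def call_hits(
    stats_table: pd.DataFrame,
    lfc_threshold: float = LFC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Flag proximal-network hits: max |log2FC| > 0.58 AND p < 0.001.

    Inequalities are strict and no multiple-testing correction is applied.
    """
    out = stats_table.copy()
    out["hit"] = (out["lfc_max"] > lfc_threshold) & (out["p"] < p_threshold)
    return out


@dataclasses.dataclass
class ApexResult:
    coefficients: pd.DataFrame
    hits: pd.DataFrame

    @property
    def hit_ids(self) -> list[str]:
        return sorted(self.hits.index[self.hits["hit"]])


def apex_pipeline(
    tidy: pd.DataFrame,
    indicator_map: Mapping[str, Sequence[str]],
    degree: int = 2,
    baseline_time: float = 0.0,
    time_scale: str = "index",
    nonneg: bool = True,
    normalize: bool = True,
    lfc_threshold: float = LFC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> ApexResult:
    """Full stage: spatial deconvolution + time-course hit calling."""
    coeffs = deconvolve_timecourse(
        tidy, indicator_map, nonneg=nonneg, normalize=normalize
    )
    stats_table = timecourse_stats(
        tidy, degree=degree, baseline_time=baseline_time, time_scale=time_scale
    )
    hits = call_hits(stats_table, lfc_threshold=lfc_threshold, p_threshold=p_threshold)
    return ApexResult(coefficients=coeffs, hits=hits)
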