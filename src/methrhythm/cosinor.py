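"""Single-harmonic cosinor regression.

The cosinor model ``y(t) = M + A*cos(2*pi*(t - phi)/period)`` is linear
in the equivalent parameterization
``y(t) = M + b_c*cos(w t) + b_s*sin(w t)`` with ``w = 2*pi/period``, so
the least-squares fit is closed form.  Amplitude and acrophase follow
as ``A = sqrt(b_c^2 + b_s^2)`` and ``phi = atan2(b_s, b_c)/w`` modulo
the period; with this convention ``phi`` is the clock time at which
the fitted curve peaks.

All fitting is vectorized across probes: one design-matrix solve
serves the whole matrix.  Subjects are pooled as replicates at each
timepoint, which matches a group-level rhythm estimate; per-subject
fits can be obtained by subsetting the matrix first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: amplitudes below this are treated as zero -> acrophase undefined
_AMP_TOL = 1e-12
#: residual sums of squares below this count as an exact fit
_RSS_TOL = 1e-12

FIT_COLUMNS = [
    "mesor",
    "beta_cos",
    "beta_sin",
    "amplitude",
    "acrophase",
    "rss",
    "rss0",
    "n_obs",
    "period",
    "acrophase_defined",
]


def _design(times: np.ndarray, period: float) -> np.ndarray:
    w = 2.0 * np.pi / period
    return np.column_stack(
        [np.ones_like(times), np.cos(w * times), np.sin(w * times)]
    )


def cosinor_fit(
    times: np.ndarray,
    values: np.ndarray | pd.DataFrame,
    period: float = 24.0,
    probe_ids=None,
) -> pd.DataFrame:
    """Fit the cosinor model to one or many probes.

    Parameters
    ----------
    times:
        Observation times in hours (clock times or elapsed hours; the
        acrophase is reported on the same clock, modulo the period).
    values:
        Either a 1-D series of observations or a probes x observations
        array/DataFrame.
    period:
        Oscillation period in hours (24 for a diurnal rhythm).

    Returns
    -------
    DataFrame with one row per probe: mesor, linearized coefficients,
    amplitude, acrophase (NaN with ``acrophase_defined == False`` when
    the amplitude is numerically zero), residual sum of squares of the
    cosinor fit and of the intercept-only fit, observation count and
    period.
    """
    times = np.asarray(times, dtype=float)
    if isinstance(values, pd.DataFrame):
        if probe_ids is None:
            probe_ids = values.index
        values = values.values
    Y = np.atleast_2d(np.asarray(values, dtype=float))
    if Y.shape[1] != times.size:
        raise ValueError(
            f"{Y.shape[1]} observation columns but {times.size} times"
        )
    n = times.size
    if n < 4:
        raise ValueError("cosinor fit needs at least 4 observations")
    unique_phases = np.unique(np.round(times % period, 9))
    if unique_phases.size < 3:
        raise ValueError(
            "collinear design: need >= 3 distinct times modulo the period"
        )
    # circular coverage: the period minus the largest empty gap
    gaps = np.diff(np.concatenate([unique_phases, [unique_phases[0] + period]]))
    if period - gaps.max() < period / 2:
        raise ValueError("observations must span at least half a period")

    X = _design(times, period)
    coef, _, _, _ = np.linalg.lstsq(X, Y.T, rcond=None)
    fitted = X @ coef
    rss = np.sum((Y.T - fitted) ** 2, axis=0)
    rss0 = np.sum((Y.T - Y.T.mean(axis=0)) ** 2, axis=0)

    mesor, beta_cos, beta_sin = coef
    amplitude = np.hypot(beta_cos, beta_sin)
    acrophase = (period / (2.0 * np.pi)) * np.arctan2(beta_sin, beta_cos)
    acrophase = np.mod(acrophase, period)
    defined = amplitude > _AMP_TOL
    acrophase = np.where(defined, acrophase, np.nan)

    if probe_ids is None:
        probe_ids = pd.RangeIndex(Y.shape[0])
    return pd.DataFrame(
        {
            "mesor": mesor,
            "beta_cos": beta_cos,
            "beta_sin": beta_sin,
            "amplitude": amplitude,
            "acrophase": acrophase,
            "rss": rss,
            "rss0": rss0,
            "n_obs": n,
            "period": period,
            "acrophase_defined": defined,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )


def cosinor_rhythm_test(fit: pd.DataFrame) -> pd.DataFrame:
    """Zero-amplitude F-test for each fitted probe.

    Compares the cosinor fit against the intercept-only fit:
    ``F = ((RSS0 - RSS)/2) / (RSS/(n - 3))`` on (2, n-3) degrees of
    freedom.  Probes fitted exactly (RSS ~ 0) get p = 0 and an
    ``exact_fit`` flag rather than a divide-by-zero.
    """
    n = fit["n_obs"].values
    if (n <= 3).any():
        raise ValueError("rhythm test needs more than 3 observations")
    rss = fit["rss"].values
    rss0 = fit["rss0"].values
    exact = rss < _RSS_TOL
    denom = np.where(exact, 1.0, rss / (n - 3))
    F = ((rss0 - rss) / 2.0) / denom
    p = stats.f.sf(F, 2, n - 3)
    p = np.where(exact, 0.0, p)
    F = np.where(exact, np.inf, F)
    return pd.DataFrame(
        {"F": F, "p": p, "exact_fit": exact}, index=fit.index
    )


def order_by_acrophase(fit: pd.DataFrame, subset=None) -> list:
    """Probe IDs sorted by ascending acrophase, ties by probe ID.

    Used to build acrophase-ordered heatmap exports in which rows are
    matched across conditions.  Probes without a defined acrophase in
    the requested subset are an error, listed by ID.
    """
    sub = fit if subset is None else fit.loc[subset]
    undefined = sub.index[~sub["acrophase_defined"].astype(bool)]
    if len(undefined):
        raise ValueError(
            f"acrophase undefined for probes: {list(undefined[:10])}"
        )
    # mergesort is stable; pre-sorting by probe ID makes ties ID-ordered
    order = sub.sort_index(kind="mergesort").sort_values(
        "acrophase", kind="mergesort"
    )
    return list(order.index)


def heatmap_matrix(
    matrix, probe_order: list, sheet: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Group-averaged probe x timepoint matrix in a fixed row order.

    Averages all subjects at each sampling index; with z-scored input
    this reproduces the usual rhythm-heatmap display where two
    conditions can be plotted side by side with identical row order.
    """
    if sheet is None:
        sheet = matrix.sheet
    if sheet is None:
        raise ValueError("heatmap export requires a sample sheet")
    sheet = sheet.loc[matrix.values.columns]
    vals = matrix.values.loc[probe_order]
    grouped = vals.T.groupby(sheet["sampling_index"]).mean().T
    grouped.columns = [f"t{int(i):02d}" for i in grouped.columns]
    return grouped
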