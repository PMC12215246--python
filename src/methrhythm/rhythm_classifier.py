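"""Five-model differential-rhythmicity classification.

Each probe's observations from the two condition windows are pooled and
five nested ordinary-least-squares models are fitted:

====================  =================================================
``arrhy``             condition-specific means, no rhythm
``same``              one shared 24-h harmonic on top of the means
``loss``              harmonic active in the baseline window only
``gain``              harmonic active in the sleep-deprivation window only
``change``            condition-specific harmonics (phase and/or
                      amplitude differ between conditions)
====================  =================================================

Model selection uses the Akaike information criterion in its Gaussian
form ``AIC = n*ln(RSS/n) + 2k`` (k counts the mean parameters plus the
residual variance) and Akaike weights
``w_i = exp(-d_i/2)/sum_j exp(-d_j/2)`` with ``d_i = AIC_i - min AIC``.
A probe is assigned its best model's class only when the best weight
reaches the confidence cutoff (0.6 by default); otherwise it is
reported as ``unclassified``.  An optional pre-filter additionally
requires a probe to pass the per-condition cosinor zero-amplitude test
(BH-adjusted) in at least one condition before a rhythmic class may be
assigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cosinor
from .design import BASELINE, SLEEP_DEPRIVATION
from .preprocess import MethylationMatrix

MODELS = ("arrhy", "same", "loss", "gain", "change")
RHYTHMIC_CLASSES = ("same", "loss", "gain", "change")
UNCLASSIFIED = "unclassified"

#: mean-parameter counts per model; +1 for the residual variance in k
_N_MEAN_PARAMS = {"arrhy": 2, "same": 4, "loss": 4, "gain": 4, "change": 6}


@dataclass(frozen=True)
class ClassifierConfig:
    period: float = 24.0
    criterion: str = "aic"  # "aic" or "aicc"
    weight_cutoff: float = 0.6
    fdr_alpha: float = 0.05
    fdr_prefilter: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.weight_cutoff <= 1:
            raise ValueError("weight_cutoff must lie in (0, 1]")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.criterion not in ("aic", "aicc"):
            raise ValueError(f"unknown criterion {self.criterion!r}")


def design_matrices(
    times: np.ndarray, conditions: np.ndarray, period: float = 24.0
) -> dict[str, np.ndarray]:
    """Explicit design matrix of each candidate model.

    ``conditions`` holds the two condition labels; the baseline label
    is taken to be the one attached to the earlier samples (first
    occurrence).  Every model carries condition-specific intercepts so
    that mean shifts between windows never masquerade as rhythm terms.
    """
    times = np.asarray(times, dtype=float)
    conditions = np.asarray(conditions)
    labels = pd.unique(conditions)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 conditions, got {list(labels)}")
    base = conditions == labels[0]
    sd = ~base
    for name, m in (("baseline", base), ("sleep deprivation", sd)):
        if np.unique(np.round(times[m] % period, 9)).size < 3:
            raise ValueError(
                f"insufficient distinct times in the {name} condition"
            )
    w = 2.0 * np.pi / period
    c, s = np.cos(w * times), np.sin(w * times)
    i_base, i_sd = base.astype(float), sd.astype(float)
    intercepts = [i_base, i_sd]
    return {
        "arrhy": np.column_stack(intercepts),
        "same": np.column_stack(intercepts + [c, s]),
        "loss": np.column_stack(intercepts + [c * i_base, s * i_base]),
        "gain": np.column_stack(intercepts + [c * i_sd, s * i_sd]),
        "change": np.column_stack(
            intercepts + [c * i_base, s * i_base, c * i_sd, s * i_sd]
        ),
    }


def fit_candidate_models(
    values: np.ndarray | pd.DataFrame,
    times: np.ndarray,
    conditions: np.ndarray,
    config: ClassifierConfig = ClassifierConfig(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Residual sum of squares of every candidate model for every probe.

    Returns an (n_probes x 5) RSS table and the parameter count k per
    model (mean parameters + 1 for the residual variance).
    """
    probe_ids = None
    if isinstance(values, pd.DataFrame):
        probe_ids = values.index
        values = values.values
    Y = np.atleast_2d(np.asarray(values, dtype=float)).T  # obs x probes
    designs = design_matrices(times, conditions, config.period)
    rss = {}
    for name, X in designs.items():
        coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
        rss[name] = np.sum((Y - X @ coef) ** 2, axis=0)
    table = pd.DataFrame(rss, index=probe_ids)[list(MODELS)]
    k = {m: _N_MEAN_PARAMS[m] + 1 for m in MODELS}
    return table, k


def information_criterion(
    rss: pd.DataFrame, k: dict[str, int], n_obs: int, criterion: str = "aic"
) -> pd.DataFrame:
    """Gaussian AIC (optionally small-sample corrected) per model."""
    # floor RSS so exact fits give a huge-but-finite criterion instead of -inf
    with np.errstate(divide="ignore"):
        logterm = np.log(np.maximum(rss.values, 1e-300) / n_obs)
    out = {}
    for j, m in enumerate(rss.columns):
        km = k[m]
        aic = n_obs * logterm[:, j] + 2 * km
        if criterion == "aicc":
            aic = aic + 2 * km * (km + 1) / (n_obs - km - 1)
        out[m] = aic
    return pd.DataFrame(out, index=rss.index)


def akaike_weights(aic: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Normalized relative likelihoods exp(-dAIC/2), stable for large dAIC."""
    values = aic.values if isinstance(aic, pd.DataFrame) else np.atleast_2d(aic)
    values = np.asarray(values, dtype=float)
    if values.shape[1] < 2:
        raise ValueError("need at least 2 models")
    finite = np.isfinite(values)
    if not finite.any(axis=1).all():
        raise ValueError("all information criteria are infinite for some probe")
    best = np.nanmin(np.where(finite, values, np.inf), axis=1, keepdims=True)
    delta = values - best
    rel = np.where(finite, np.exp(-0.5 * np.where(finite, delta, 0.0)), 0.0)
    w = rel / rel.sum(axis=1, keepdims=True)
    if isinstance(aic, pd.DataFrame):
        return pd.DataFrame(w, index=aic.index, columns=aic.columns)
    return w if np.asarray(aic).ndim == 2 else w[0]


def classify_windows(
    base: MethylationMatrix,
    sd: MethylationMatrix,
    config: ClassifierConfig = ClassifierConfig(),
) -> pd.DataFrame:
    """Classify every probe from its two z-scored condition windows.

    The two window matrices are stacked into one observation vector per
    probe (overlapping samples contribute to both windows, mirroring
    the split of the 45-h series into two complete 24-h days).  Returns
    a per-probe table with the five AICs, Akaike weights, best model,
    assigned class, and per-condition cosinor acrophases.
    """
    if not base.values.index.equals(sd.values.index):
        raise ValueError("windows must share an identical probe index")
    t_base = base.sheet["clock_time"].values
    t_sd = sd.sheet["clock_time"].values

    # Overlapping samples (the windows share the middle of the series)
    # enter the model-selection fit once, attributed to the nearer
    # window, so neither condition's rhythm terms see the other's data
    # twice.  Cosinor fits below still use each full window.
    shared = base.values.columns.intersection(sd.values.columns)
    if len(shared):
        centre_b = base.sheet["sampling_index"].mean()
        centre_s = sd.sheet["sampling_index"].mean()
        to_base = [
            s
            for s in shared
            if abs(base.sheet.loc[s, "sampling_index"] - centre_b)
            <= abs(sd.sheet.loc[s, "sampling_index"] - centre_s)
        ]
        base_cols = [c for c in base.values.columns if c not in shared or c in to_base]
        sd_cols = [c for c in sd.values.columns if c not in shared or c not in to_base]
    else:
        base_cols = list(base.values.columns)
        sd_cols = list(sd.values.columns)

    tb = base.sheet.loc[base_cols, "clock_time"].values
    ts = sd.sheet.loc[sd_cols, "clock_time"].values
    times = np.concatenate([tb, ts])
    conditions = np.concatenate(
        [np.repeat(BASELINE, len(tb)), np.repeat(SLEEP_DEPRIVATION, len(ts))]
    )
    Y = np.hstack([base.values[base_cols].values, sd.values[sd_cols].values])

    zero_var = Y.std(axis=1) <= 0

    rss, k = fit_candidate_models(
        pd.DataFrame(Y, index=base.values.index), times, conditions, config
    )
    aic = information_criterion(rss, k, n_obs=Y.shape[1], criterion=config.criterion)
    weights = akaike_weights(aic)

    best = aic.idxmin(axis=1)
    best_w = weights.max(axis=1)
    assigned = best.where(best_w >= config.weight_cutoff, UNCLASSIFIED)

    fit_base = cosinor.cosinor_fit(t_base, base.values, config.period)
    fit_sd = cosinor.cosinor_fit(t_sd, sd.values, config.period)

    if config.fdr_prefilter:
        from .differential_methylation import bh_adjust

        q_base = bh_adjust(cosinor.cosinor_rhythm_test(fit_base)["p"].values)
        q_sd = bh_adjust(cosinor.cosinor_rhythm_test(fit_sd)["p"].values)
        eligible = (q_base < config.fdr_alpha) | (q_sd < config.fdr_alpha)
        demote = assigned.isin(RHYTHMIC_CLASSES).values & ~eligible
        assigned = assigned.where(~demote, UNCLASSIFIED)
    else:
        eligible = np.ones(len(assigned), dtype=bool)

    assigned = assigned.where(~zero_var, "arrhy")

    out = pd.DataFrame(index=base.values.index)
    for m in MODELS:
        out[f"aic_{m}"] = aic[m]
        out[f"weight_{m}"] = weights[m]
    out["best_model"] = best
    out["best_weight"] = best_w
    out["assigned_class"] = assigned
    out["acrophase_baseline"] = fit_base["acrophase"]
    out["acrophase_sleep_deprivation"] = fit_sd["acrophase"]
    out["amplitude_baseline"] = fit_base["amplitude"]
    out["amplitude_sleep_deprivation"] = fit_sd["amplitude"]
    out["rhythm_test_eligible"] = np.asarray(eligible, dtype=bool)
    out["zero_variance"] = zero_var
    out.index.name = "probe_id"
    return out


def summarize_classes(
    assigned: pd.Series | dict[str, int]
) -> pd.DataFrame:
    """Class tally with the standard percentage bookkeeping.

    Accepts either a per-probe assigned-class Series or a class->count
    mapping.  Reports, per class and for the derived aggregates
    (classifiable, rhythmic = same+loss+gain+change, rhythmic in both
    conditions = same+change), the count, the percentage of
    classifiable sites, and the percentage of all submitted sites.
    """
    if isinstance(assigned, pd.Series):
        counts = assigned.value_counts().to_dict()
    else:
        counts = dict(assigned)
    counts = {k: int(counts.get(k, 0)) for k in (*MODELS, UNCLASSIFIED)}
    n_total = sum(counts.values())
    classifiable = n_total - counts[UNCLASSIFIED]
    rhythmic = sum(counts[c] for c in RHYTHMIC_CLASSES)
    rhythmic_both = counts["same"] + counts["change"]

    rows = []

    def add(label: str, n: int, of_classifiable: bool = True) -> None:
        rows.append(
            {
                "classification": label,
                "n_sites": n,
                "pct_of_classifiable": (
                    100.0 * n / classifiable if of_classifiable and classifiable else np.nan
                ),
                "pct_of_all": 100.0 * n / n_total if n_total else np.nan,
            }
        )

    add(UNCLASSIFIED, counts[UNCLASSIFIED], of_classifiable=False)
    add("arrhy", counts["arrhy"])
    for c in RHYTHMIC_CLASSES:
        add(c, counts[c])
    add("classifiable", classifiable)
    add("rhythmic", rhythmic)
    add("rhythmic_both_conditions", rhythmic_both)
    return pd.DataFrame(rows).set_index("classification")
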