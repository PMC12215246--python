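"""Paired matched-clock-time differential methylation.

Sleep-deprivation samples are compared with the baseline sample taken
at the same clock time 24 h earlier, within subject.  Per probe and
timepoint pair the mean paired difference is tested with an
empirical-Bayes moderated one-sample t-test: probe-level variances are
shrunk toward an ensemble prior ``s0^2`` with prior degrees of freedom
``d0`` estimated by the method of moments on log sample variances
(the scaled-F closed forms of Smyth's hierarchical model), giving

    s_tilde^2 = (d0*s0^2 + d*s^2) / (d0 + d)
    t_tilde   = mean(delta) / (s_tilde / sqrt(n)),   df = d0 + d.

A joint moderated F over all timepoint pairs, Benjamini-Hochberg FDR
adjustment, hypo/hyper direction calls, differentially-methylated-
position (DMP) counting over a p-value threshold grid, top-N probe
selection, gene mapping, and Fisher-exact gene-set over-representation
complete the stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

#: the reporting grid of uncorrected p-value thresholds
THRESHOLD_GRID = (5e-8, 5e-7, 5e-6, 5e-5, 5e-4, 5e-3, 5e-2)
#: threshold at which hypo/hyper direction shares are tabulated
HEADLINE_THRESHOLD = 5e-4

HYPO = "hypo"
HYPER = "hyper"


# ---------------------------------------------------------------------------
# pairing


def paired_differences(
    matrix, sheet: pd.DataFrame | None = None
) -> tuple[dict[int, pd.DataFrame], pd.DataFrame]:
    """Per-subject differences at matched clock times.

    Pairs sampling index ``i`` (baseline half) with ``i + n/2``
    (sleep-deprivation half); for the 16-sample design this yields the
    eight 3-h pairs with 8-29 h of time awake.  Differences are
    sleep-deprivation minus baseline.  A subject missing either member
    of a pair is dropped from that pair with a warning.

    Returns ``(pair_diffs, pair_info)`` where ``pair_diffs[pair]`` is a
    probes x subjects DataFrame and ``pair_info`` carries the baseline
    and sleep-deprivation sampling indices, clock time and time awake.
    """
    if sheet is None:
        sheet = matrix.sheet
    if sheet is None:
        raise ValueError("paired_differences requires a sample sheet")
    sheet = sheet.loc[matrix.values.columns]
    n = int(sheet["sampling_index"].max())
    if n % 2:
        raise ValueError("paired design needs an even number of sampling indices")
    half = n // 2

    by_key = pd.Series(sheet.index, index=pd.MultiIndex.from_frame(
        sheet[["subject", "sampling_index"]]
    ))
    subjects = sheet["subject"].unique()

    pair_diffs: dict[int, pd.DataFrame] = {}
    info_rows = []
    for pair in range(1, half + 1):
        b_idx, s_idx = pair, pair + half
        cols_b, cols_s, keep = [], [], []
        for subj in subjects:
            have_b = (subj, b_idx) in by_key.index
            have_s = (subj, s_idx) in by_key.index
            if have_b and have_s:
                cols_b.append(by_key[(subj, b_idx)])
                cols_s.append(by_key[(subj, s_idx)])
                keep.append(subj)
            else:
                warnings.warn(
                    f"subject {subj} missing a member of pair {pair}; dropped",
                    stacklevel=2,
                )
        diff = pd.DataFrame(
            matrix.values[cols_s].values - matrix.values[cols_b].values,
            index=matrix.values.index,
            columns=keep,
        )
        pair_diffs[pair] = diff
        sd_row = sheet.loc[cols_s[0]] if cols_s else None
        info_rows.append(
            {
                "pair": pair,
                "baseline_index": b_idx,
                "sd_index": s_idx,
                "clock_time": float(sd_row["clock_time"]) if sd_row is not None else np.nan,
                "time_awake": float(sd_row["time_awake"]) if sd_row is not None else np.nan,
                "n_subjects": len(keep),
            }
        )
    pair_info = pd.DataFrame(info_rows).set_index("pair")
    return pair_diffs, pair_info


# ---------------------------------------------------------------------------
# empirical Bayes moderation


@dataclass(frozen=True)
class EBayesHyperparams:
    """Prior degrees of freedom and prior variance of the probe ensemble."""

    d0: float  # may be inf (complete pooling)
    s0_sq: float

    def posterior_variance(self, s_sq: np.ndarray, df: float) -> np.ndarray:
        if np.isinf(self.d0):
            return np.full_like(np.asarray(s_sq, dtype=float), self.s0_sq)
        return (self.d0 * self.s0_sq + df * s_sq) / (self.d0 + df)


def _trigamma_inverse(x: float, tol: float = 1e-10, maxit: int = 60) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(maxit):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def fit_ebayes(variances: np.ndarray, df: float) -> EBayesHyperparams:
    """Estimate (d0, s0^2) from the ensemble of probe sample variances.

    Under the hierarchical model the sample variances follow a scaled F
    distribution; matching the mean and variance of ``log s^2`` gives
    closed-form moment estimates.  A non-positive moment estimate of
    the excess log-variance means the variances are (at least) as
    concentrated as the prior allows: d0 is then infinite and every
    probe is pooled to ``s0^2``, with a warning.
    """
    s2 = np.asarray(variances, dtype=float)
    s2 = s2[np.isfinite(s2)]
    if s2.size < 10:
        raise ValueError("need >= 10 probes to estimate ebayes hyperparameters")
    if np.all(s2 == 0):
        raise ValueError("all probe variances are zero")
    # offset exactly-zero variances as limma does to keep logs finite
    zero = s2 == 0
    if zero.any():
        s2 = np.where(zero, s2[~zero].min() * 1e-6, s2)
    e = np.log(s2) - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - polygamma(1, df / 2.0)
    if e_var <= 0:
        warnings.warn(
            "variance ensemble tighter than chi-square sampling noise; "
            "using complete pooling (d0 = inf)",
            stacklevel=2,
        )
        return EBayesHyperparams(d0=np.inf, s0_sq=float(np.exp(e_mean)))
    d0 = 2.0 * _trigamma_inverse(float(e_var))
    s0_sq = np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return EBayesHyperparams(d0=float(d0), s0_sq=float(s0_sq))


def moderated_t(
    differences: pd.DataFrame, hyper: EBayesHyperparams | None = None
) -> pd.DataFrame:
    """Moderated one-sample t-test of paired differences per probe.

    ``differences`` is probes x subjects.  With ``hyper`` omitted the
    hyperparameters are estimated from this matrix's own variance
    ensemble.  ``d0 = 0`` reproduces the ordinary paired t-test.
    """
    D = differences.values
    n = D.shape[1]
    if n < 2:
        raise ValueError("need >= 2 subjects per pair")
    df = n - 1
    mean = D.mean(axis=1)
    s_sq = D.var(axis=1, ddof=1)
    if hyper is None:
        hyper = fit_ebayes(s_sq, df)
    post = hyper.posterior_variance(s_sq, df)
    df_total = hyper.d0 + df if np.isfinite(hyper.d0) else np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(post / n)
    if np.isfinite(df_total):
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    else:
        p = 2.0 * stats.norm.sf(np.abs(t))
    return pd.DataFrame(
        {
            "delta": mean,
            "t": t,
            "p": p,
            "s_sq": s_sq,
            "posterior_s_sq": post,
            "df_total": df_total,
            "direction": np.where(mean < 0, HYPO, HYPER),
        },
        index=differences.index,
    )


def moderated_f(
    pair_diffs: dict[int, pd.DataFrame], hyper: EBayesHyperparams | None = None
) -> pd.DataFrame:
    """Joint moderated F-test across all timepoint-pair contrasts.

    Per probe, the within-pair variances are pooled across pairs,
    shrunk with the ensemble prior, and the pair-wise moderated t
    statistics combined as ``F = mean(t_j^2)`` on
    ``(n_pairs, d0 + d)`` degrees of freedom.  A single contrast
    reduces to ``F = t^2``.
    """
    pairs = sorted(pair_diffs)
    if not pairs:
        raise ValueError("need at least one pair")
    per_pair_n = {p: pair_diffs[p].shape[1] for p in pairs}
    index = pair_diffs[pairs[0]].index
    s_sq = np.zeros(len(index))
    df = 0.0
    means = {}
    for p in pairs:
        D = pair_diffs[p].values
        n = per_pair_n[p]
        if n < 2:
            raise ValueError(f"pair {p}: need >= 2 subjects")
        s_sq = s_sq + D.var(axis=1, ddof=1) * (n - 1)
        df += n - 1
        means[p] = D.mean(axis=1)
    s_sq = s_sq / df
    if hyper is None:
        hyper = fit_ebayes(s_sq, df)
    post = hyper.posterior_variance(s_sq, df)
    df_total = hyper.d0 + df if np.isfinite(hyper.d0) else np.inf
    t_sq = np.zeros(len(index))
    for p in pairs:
        with np.errstate(divide="ignore", invalid="ignore"):
            t_sq = t_sq + means[p] ** 2 / (post / per_pair_n[p])
    F = t_sq / len(pairs)
    if np.isfinite(df_total):
        p_val = stats.f.sf(F, len(pairs), df_total)
    else:
        p_val = stats.chi2.sf(F * len(pairs), len(pairs))
    return pd.DataFrame(
        {"F": F, "p": p_val, "df1": len(pairs), "df2": df_total}, index=index
    )


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} min(1, m * p_(j) / j)`` over the sorted
    p-values; monotone in p and invariant to input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# record assembly and bookkeeping


def paired_moderated_tests(
    matrix, sheet: pd.DataFrame | None = None, shared_hyper: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the moderated t-test at every matched-clock-time pair.

    Returns a long record table (probe, pair, time awake, delta,
    moderated t, p, BH q within pair, direction) and the pair info
    table.  BH adjustment is applied across probes within each pair,
    matching a per-timepoint epigenome-wide scan.  With
    ``shared_hyper`` the ebayes prior is estimated once from the pooled
    variances of all pairs instead of per pair.
    """
    pair_diffs, pair_info = paired_differences(matrix, sheet)
    hyper = None
    if shared_hyper:
        all_vars = np.concatenate(
            [d.var(axis=1, ddof=1).values for d in pair_diffs.values()]
        )
        n = next(iter(pair_diffs.values())).shape[1]
        hyper = fit_ebayes(all_vars, n - 1)
    records = []
    for pair, diffs in sorted(pair_diffs.items()):
        res = moderated_t(diffs, hyper)
        res = res.assign(
            pair=pair,
            time_awake=pair_info.loc[pair, "time_awake"],
            q=bh_adjust(res["p"].values),
        )
        res.index.name = "probe_id"
        records.append(res.reset_index())
    table = pd.concat(records, ignore_index=True)
    return table, pair_info


def count_dmps(
    records: pd.DataFrame,
    thresholds: tuple[float, ...] = THRESHOLD_GRID,
    headline: float = HEADLINE_THRESHOLD,
) -> pd.DataFrame:
    """DMP counts per timepoint pair across the p-value threshold grid.

    One row per pair: the count of records with ``p < threshold`` for
    every grid threshold (non-decreasing along the grid), the expected
    count under the global null (threshold x probes tested), and the
    hypo/hyper split at the headline threshold.
    """
    if records.empty:
        cols = ["time_awake", "n_tested"]
        for thr in thresholds:
            cols += [f"n_p_lt_{thr:g}", f"expected_p_lt_{thr:g}"]
        cols += ["n_hypo", "n_hyper", "hypo_share"]
        return pd.DataFrame(columns=cols, index=pd.Index([], name="pair"))
    rows = []
    for pair, block in records.groupby("pair"):
        n_tested = len(block)
        row = {
            "pair": pair,
            "time_awake": block["time_awake"].iloc[0],
            "n_tested": n_tested,
        }
        for thr in thresholds:
            row[f"n_p_lt_{thr:g}"] = int((block["p"] < thr).sum())
            row[f"expected_p_lt_{thr:g}"] = thr * n_tested
        sig = block[block["p"] < headline]
        row["n_hypo"] = int((sig["direction"] == HYPO).sum())
        row["n_hyper"] = int((sig["direction"] == HYPER).sum())
        row["hypo_share"] = (
            row["n_hypo"] / len(sig) if len(sig) else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("pair")


def select_top_dmps(records: pd.DataFrame, n: int) -> pd.DataFrame:
    """Top-N records by ascending p; ties by |delta| descending, then ID."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n > len(records):
        warnings.warn(
            f"requested top {n} but only {len(records)} records; returning all",
            stacklevel=2,
        )
        n = len(records)
    ranked = records.assign(_absd=records["delta"].abs()).sort_values(
        ["p", "_absd", "probe_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return ranked.drop(columns="_absd").head(n)


def map_to_genes(
    probes, manifest: pd.DataFrame
) -> tuple[list[str], pd.DataFrame]:
    """Map probe IDs to gene symbols via a two-column manifest.

    Returns the unique gene list (first-appearance order) and a report
    of unmapped probes and per-gene probe multiplicities.
    """
    if not {"probe_id", "gene"} <= set(manifest.columns):
        raise ValueError("manifest needs 'probe_id' and 'gene' columns")
    lookup = manifest.set_index("probe_id")["gene"]
    probes = list(probes)
    mapped = [p for p in probes if p in lookup.index]
    unmapped = [p for p in probes if p not in lookup.index]
    genes = lookup.loc[mapped]
    if isinstance(genes, pd.Series):
        gene_list = list(pd.unique(genes.values))
    else:
        gene_list = [genes]
    multiplicity = genes.value_counts().rename("n_probes").to_frame()
    report = multiplicity.assign(
        n_unmapped_probes=len(unmapped)
    )
    return gene_list, report


# ---------------------------------------------------------------------------
# gene-set over-representation


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file: name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    if not sets:
        raise ValueError(f"no gene sets parsed from {path}")
    return sets


def overrepresentation_test(
    gene_list, gene_sets: dict[str, list[str]], universe
) -> pd.DataFrame:
    """One-sided Fisher-exact over-representation of each gene set.

    For each set the 2x2 table (in list x in set) over the universe is
    tested with the hypergeometric upper tail; BH adjustment runs
    across sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    if not gene_sets:
        raise ValueError("no gene sets supplied")
    genes = set(gene_list) & universe
    if set(gene_list) - universe:
        warnings.warn(
            f"{len(set(gene_list) - universe)} genes outside the universe ignored",
            stacklevel=2,
        )
    N, n = len(universe), len(genes)
    rows = []
    for name, members in gene_sets.items():
        in_set = set(members) & universe
        m = len(in_set)
        k = len(in_set & genes)
        p = stats.hypergeom.sf(k - 1, N, m, n)
        a, b = k, n - k
        c, d = m - k, N - m - (n - k)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append(
            {
                "gene_set": name,
                "n_overlap": k,
                "set_size": m,
                "list_size": n,
                "universe_size": N,
                "odds_ratio": odds,
                "p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("gene_set")
    out["q"] = bh_adjust(out["p"].values)
    return out.sort_values("p")
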