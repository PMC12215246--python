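"""White-blood-cell composition: imputation, normalization, correlation null.

Thirteen non-exclusive WBC count classes are tracked per subject and
timepoint (cells per microliter).  Methylation matrices can be
normalized against any class by dividing each value by the matching
subject/timepoint count, producing one normalized matrix per class.
A correlation analysis against relative cell proportions at the final
timepoint, with its analytic expected count under the null
(alpha x n_probes x n_classes), checks whether apparent methylation
effects merely track composition shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import MethylationMatrix

#: the 13 WBC count classes; totals are sums of their member classes
CELL_CLASSES = [
    "total_wbc",
    "granulocytes",
    "lymphocytes",
    "total_t",
    "total_b",
    "monocytes",
    "total_cd4",
    "cd4_memory",
    "cd4_naive",
    "total_cd8",
    "cd8_memory",
    "cd8_naive",
    "nk_dendritic",
]

#: composite class -> constituent classes (non-exclusive hierarchy)
CLASS_SUMS = {
    "total_cd4": ["cd4_memory", "cd4_naive"],
    "total_cd8": ["cd8_memory", "cd8_naive"],
    "total_t": ["total_cd4", "total_cd8"],
    "lymphocytes": ["total_t", "total_b", "nk_dendritic"],
    "total_wbc": ["granulocytes", "lymphocytes", "monocytes"],
}


@dataclass
class CellCountTable:
    """Subject x timepoint WBC counts with imputation flags.

    ``counts`` is indexed by (subject, sampling_index) with one column
    per cell class plus ``clock_time``; missing measurements are NaN
    until :func:`impute_missing_counts` fills them.  ``imputed`` is a
    boolean frame of the same shape marking filled-in entries.
    """

    counts: pd.DataFrame
    imputed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing_cols = [c for c in CELL_CLASSES if c not in self.counts.columns]
        if missing_cols:
            raise ValueError(f"cell count table missing classes: {missing_cols}")
        if self.imputed is None:
            self.imputed = pd.DataFrame(
                False, index=self.counts.index, columns=CELL_CLASSES
            )

    @property
    def subjects(self) -> list:
        return list(self.counts.index.get_level_values("subject").unique())

    def to_csv(self, path) -> None:
        out = self.counts.copy()
        for c in CELL_CLASSES:
            out[f"{c}_imputed"] = self.imputed[c]
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "CellCountTable":
        table = pd.read_csv(path).set_index(["subject", "sampling_index"])
        flag_cols = [c for c in table.columns if c.endswith("_imputed")]
        imputed = None
        if flag_cols:
            imputed = table[flag_cols].rename(
                columns=lambda c: c[: -len("_imputed")]
            )
            imputed = imputed.reindex(columns=CELL_CLASSES, fill_value=False)
            table = table.drop(columns=flag_cols)
        return cls(table, imputed)


def impute_missing_counts(table: CellCountTable) -> CellCountTable:
    """Fill missing interior timepoints with the adjacent-timepoint mean.

    For each subject and cell class, a missing count at sampling index
    ``i`` becomes the arithmetic mean of the counts at ``i-1`` and
    ``i+1``.  Missing values at the first or last timepoint, or at two
    consecutive timepoints, have no defined neighbors and raise an
    error listing the offending positions.  Non-missing entries are
    passed through bit-exactly.
    """
    counts = table.counts.copy()
    imputed = table.imputed.copy()
    bad: list[tuple] = []
    for subj, block in counts.groupby(level="subject"):
        block = block.sort_index(level="sampling_index")
        idx = block.index.get_level_values("sampling_index").values
        for cls in CELL_CLASSES:
            vals = block[cls].values.astype(float)
            miss = np.flatnonzero(np.isnan(vals))
            for pos in miss:
                if pos == 0 or pos == len(vals) - 1:
                    bad.append((subj, int(idx[pos]), cls, "boundary"))
                elif np.isnan(vals[pos - 1]) or np.isnan(vals[pos + 1]):
                    bad.append((subj, int(idx[pos]), cls, "consecutive"))
            if bad:
                continue
            for pos in miss:
                fill = 0.5 * (vals[pos - 1] + vals[pos + 1])
                counts.loc[(subj, idx[pos]), cls] = fill
                imputed.loc[(subj, idx[pos]), cls] = True
    if bad:
        raise ValueError(f"cannot impute missing counts at: {bad[:10]}")
    if (counts[CELL_CLASSES] <= 0).any().any():
        raise ValueError("cell counts must be positive after imputation")
    return CellCountTable(counts, imputed)


def normalize_by_cellcount(
    matrix: MethylationMatrix,
    table: CellCountTable,
    cell_class: str,
    sheet: pd.DataFrame | None = None,
) -> MethylationMatrix:
    """Divide each methylation value by the matching per-timepoint count.

    The count for sample ``(subject, sampling_index)`` of the requested
    class scales that sample's whole probe column.  Run once per class
    to produce the 13 per-class normalized matrices.
    """
    if cell_class not in CELL_CLASSES:
        raise ValueError(f"unknown cell class {cell_class!r}")
    if sheet is None:
        sheet = matrix.sheet
    if sheet is None:
        raise ValueError("normalization requires a sample sheet")
    sheet = sheet.loc[matrix.values.columns]
    keys = list(zip(sheet["subject"], sheet["sampling_index"]))
    try:
        counts = table.counts.loc[keys, cell_class].values.astype(float)
    except KeyError as exc:
        raise ValueError(f"cell counts missing for sample keys: {exc}") from exc
    if np.isnan(counts).any():
        raise ValueError(
            f"{cell_class}: counts still missing; run impute_missing_counts first"
        )
    if (counts <= 0).any():
        raise ValueError(f"{cell_class}: non-positive cell count encountered")
    values = matrix.values.div(pd.Series(counts, index=matrix.values.columns), axis=1)
    return replace(matrix, values=values)


@dataclass(frozen=True)
class CorrelationNullConfig:
    alpha: float = 0.05
    n_probes: int = 1000
    n_cell_classes: int = 13
    method: str = "pearson"  # or "spearman"
    fdr_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.method not in ("pearson", "spearman"):
            raise ValueError(f"unknown correlation method {self.method!r}")

    @property
    def expected_significant(self) -> float:
        """Analytic null expectation: alpha x probes x classes."""
        return self.alpha * self.n_probes * self.n_cell_classes


@dataclass
class CorrelationReport:
    table: pd.DataFrame  # probe, cell_class, r, p, q
    n_significant: int
    expected_significant: float
    n_significant_fdr: int
    n_skipped: int
    n_subjects: int


def _pearson_with_p(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r of X (probes x subjects) against y, with p."""
    n = y.size
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return r, p


def composition_correlation(
    matrix: MethylationMatrix,
    table: CellCountTable,
    config: CorrelationNullConfig = CorrelationNullConfig(),
    sheet: pd.DataFrame | None = None,
    sampling_index: int | None = None,
) -> CorrelationReport:
    """Correlate probe methylation with relative WBC proportions.

    At the final sampling timepoint (maximum sampling index unless
    overridden), each cell class's count is converted to a proportion
    of the total-WBC count per subject, and each (probe, class) pair is
    correlated across subjects.  Reports the number of nominally
    significant correlations (p < alpha), the analytic expectation
    under independence, and the count surviving BH adjustment.
    Constant proportion vectors cannot be correlated; those pairs are
    skipped and counted.
    """
    from .differential_methylation import bh_adjust

    if sheet is None:
        sheet = matrix.sheet
    if sheet is None:
        raise ValueError("composition correlation requires a sample sheet")
    sheet = sheet.loc[matrix.values.columns]
    if sampling_index is None:
        sampling_index = int(sheet["sampling_index"].max())
    at_final = sheet[sheet["sampling_index"] == sampling_index]

    subjects = [
        s
        for s in at_final["subject"]
        if (s, sampling_index) in table.counts.index
    ]
    if len(subjects) < 3:
        raise ValueError(
            "need >= 3 subjects with methylation and counts at the final timepoint"
        )
    sample_ids = at_final.index[at_final["subject"].isin(subjects)]
    X = matrix.values[list(sample_ids)].values
    keys = [(s, sampling_index) for s in subjects]
    counts = table.counts.loc[keys, CELL_CLASSES].astype(float)
    props = counts.div(counts["total_wbc"], axis=0)

    n_probes, n_sub = X.shape
    classes = [c for c in CELL_CLASSES if c in props.columns][
        : config.n_cell_classes
    ]
    rows = []
    n_skipped = 0
    for cls in classes:
        y = props[cls].values
        if np.ptp(y) == 0:
            n_skipped += n_probes
            continue
        if config.method == "spearman":
            Xr = stats.rankdata(X, axis=1)
            yr = stats.rankdata(y)
            r, p = _pearson_with_p(Xr, yr)
        else:
            r, p = _pearson_with_p(X, y)
        const = np.ptp(X, axis=1) == 0
        n_skipped += int(const.sum())
        rows.append(
            pd.DataFrame(
                {
                    "probe_id": matrix.values.index,
                    "cell_class": cls,
                    "r": r,
                    "p": p,
                }
            )[~const]
        )
    result = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["probe_id", "cell_class", "r", "p"])
    )
    if len(result):
        result["q"] = bh_adjust(result["p"].values)
    else:
        result["q"] = []
    cfg = replace_config_counts(config, n_probes, len(classes))
    return CorrelationReport(
        table=result,
        n_significant=int((result["p"] < config.alpha).sum()),
        expected_significant=cfg.expected_significant,
        n_significant_fdr=int((result["q"] < config.fdr_alpha).sum()),
        n_skipped=n_skipped,
        n_subjects=n_sub,
    )


def replace_config_counts(
    config: CorrelationNullConfig, n_probes: int, n_classes: int
) -> CorrelationNullConfig:
    """Config with the counts actually analyzed (for the expected count)."""
    from dataclasses import replace as dc_replace

    return dc_replace(config, n_probes=n_probes, n_cell_classes=n_classes)
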