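"""Matrix I/O, probe filtering, condition-window splitting and scaling.

The central container is :class:`MethylationMatrix`: a probe x sample
table of methylation values on either the beta scale (proportions in
[0, 1]) or the M scale (logit of beta), with an explicit scale tag and
a link to the sample sheet.  All downstream stages consume and return
this container.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .design import BASELINE, SLEEP_DEPRIVATION

BETA = "beta"
MSCALE = "m"

#: clip bound used when converting beta -> M so logit stays finite
_BETA_EPS = 1e-6


@dataclass
class MethylationMatrix:
    """Probe x sample methylation values with an explicit scale tag.

    ``values`` is a DataFrame indexed by probe ID with sample IDs as
    columns.  ``sheet`` (optional) is the sample sheet restricted to
    and aligned with those samples.
    """

    values: pd.DataFrame
    scale: str = BETA
    sheet: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in (BETA, MSCALE):
            raise ValueError(f"unknown scale tag {self.scale!r}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate probe ID {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample ID {dup!r}")
        if self.sheet is not None:
            missing = self.values.columns.difference(self.sheet.index)
            if len(missing):
                raise ValueError(
                    f"samples missing from sheet: {list(missing[:5])}"
                )
            self.sheet = self.sheet.loc[self.values.columns]

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_probes(self, probes) -> "MethylationMatrix":
        return replace(self, values=self.values.loc[probes])

    def subset_samples(self, samples) -> "MethylationMatrix":
        sheet = self.sheet.loc[samples] if self.sheet is not None else None
        return MethylationMatrix(self.values[list(samples)], self.scale, sheet)

    def to_m(self) -> "MethylationMatrix":
        """Logit-transform beta values to the unbounded M scale."""
        if self.scale == MSCALE:
            return self
        clipped = self.values.clip(_BETA_EPS, 1.0 - _BETA_EPS)
        return replace(self, values=logit(clipped), scale=MSCALE)

    def to_beta(self) -> "MethylationMatrix":
        if self.scale == BETA:
            return self
        return replace(self, values=expit(self.values), scale=BETA)


def read_matrix(
    path,
    scale: str = BETA,
    sheet: pd.DataFrame | None = None,
    sep: str | None = None,
    chunksize: int | None = 100_000,
) -> MethylationMatrix:
    """Read a delimited probe x sample matrix.

    The delimiter is auto-detected from the header line (tab wins over
    comma) unless ``sep`` is given.  Large files are streamed in chunks
    so an 800k-probe array matrix never has to round-trip through the
    Python csv layer in one piece.
    """
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    try:
        if chunksize is None:
            frame = pd.read_csv(path, sep=sep, index_col=0)
        else:
            chunks = pd.read_csv(path, sep=sep, index_col=0, chunksize=chunksize)
            frame = pd.concat(chunks)
    except ValueError as exc:  # ragged rows / non-numeric surface here
        raise ValueError(f"failed to parse matrix {path}: {exc}") from exc
    bad = frame.columns[~frame.dtypes.map(lambda d: np.issubdtype(d, np.number))]
    if len(bad):
        raise ValueError(f"non-numeric values in column(s) {list(bad[:5])}")
    frame.index = frame.index.astype(str)
    return MethylationMatrix(frame, scale=scale, sheet=sheet)


def write_matrix(matrix: MethylationMatrix, path, sep: str = "\t") -> None:
    matrix.values.to_csv(path, sep=sep, index_label="probe_id")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path)
    required = {"sample_id", "subject", "condition", "sampling_index", "clock_time"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing required columns: {sorted(missing)}")
    sheet = sheet.set_index("sample_id")
    dup = sheet.duplicated(subset=["subject", "sampling_index"])
    if dup.any():
        raise ValueError(
            "duplicate (subject, sampling_index) rows: "
            f"{sheet.index[dup][:5].tolist()}"
        )
    if ((sheet["clock_time"] < 0) | (sheet["clock_time"] >= 24)).any():
        raise ValueError("clock_time must lie in [0, 24)")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# probe filtering


@dataclass
class ProbeMask:
    """Probes to drop, each with at least one named reason.

    Reasons mirror the usual array-QC categories: failed detection
    p-value, SNP-overlapping / cross-reactive probes, and probes on the
    sex chromosomes.  The mask is supplied by the user as a text file
    (probe ID, optional reason column) because this pipeline starts
    from a processed beta matrix, not raw intensities.
    """

    reasons: pd.Series  # index: probe ID, value: reason string

    def __post_init__(self) -> None:
        self.reasons = self.reasons.astype(str)
        if (self.reasons.str.len() == 0).any():
            raise ValueError("every masked probe needs a reason")

    @property
    def probe_ids(self) -> pd.Index:
        return self.reasons.index

    @classmethod
    def from_file(cls, path, default_reason: str = "masked") -> "ProbeMask":
        table = pd.read_csv(
            path, sep=None, engine="python", header=None, comment="#"
        )
        if table.shape[1] == 1:
            reasons = pd.Series(default_reason, index=table[0].astype(str))
        else:
            reasons = pd.Series(
                table[1].astype(str).values, index=table[0].astype(str)
            )
        reasons = reasons[~reasons.index.duplicated()]
        return cls(reasons)


@dataclass
class FilterReport:
    n_input: int
    n_removed: int
    n_surviving: int
    per_reason: dict[str, int] = field(default_factory=dict)

    @property
    def pct_removed(self) -> float:
        """Removal percentage of the input probe count (exact ratio)."""
        return 100.0 * self.n_removed / self.n_input

    @property
    def pct_removed_2dp(self) -> float:
        return round(self.pct_removed, 2)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed": self.n_removed,
            "n_surviving": self.n_surviving,
            "pct_removed": self.pct_removed,
            "per_reason": dict(self.per_reason),
        }


def apply_probe_filters(
    matrix: MethylationMatrix, mask: ProbeMask
) -> tuple[MethylationMatrix, FilterReport]:
    """Drop masked probes and account for every removal by reason."""
    known = mask.reasons.index.intersection(matrix.values.index)
    unknown = mask.reasons.index.difference(matrix.values.index)
    if len(unknown):
        warnings.warn(
            f"{len(unknown)} masked probe IDs not present in matrix; ignored",
            stacklevel=2,
        )
    survivors = matrix.values.index.difference(known, sort=False)
    if len(survivors) == 0:
        raise ValueError("probe filtering removed every probe")
    per_reason = mask.reasons.loc[known].value_counts().to_dict()
    report = FilterReport(
        n_input=matrix.n_probes,
        n_removed=len(known),
        n_surviving=len(survivors),
        per_reason={str(k): int(v) for k, v in per_reason.items()},
    )
    return matrix.subset_probes(survivors), report


# ---------------------------------------------------------------------------
# condition windows


def window_length(n_samples: int, sampling_interval: float, window_hours: float = 24.0) -> int:
    """Samples in one inclusive window of ``window_hours`` (9 for defaults)."""
    w = int(round(window_hours / sampling_interval)) + 1
    if w > n_samples:
        raise ValueError(
            f"window of {window_hours} h needs {w} samples; only {n_samples} available"
        )
    return w


def split_conditions(
    matrix: MethylationMatrix,
    sheet: pd.DataFrame | None = None,
    window_hours: float = 24.0,
) -> tuple[MethylationMatrix, MethylationMatrix]:
    """Split the time course into two overlapping 24-h condition windows.

    With 16 samples at 3-h spacing the baseline window is sampling
    indices 1-9 and the sleep-deprivation window indices 8-16; the two
    windows share indices 8 and 9 so that each covers a complete
    inclusive 24-h day with the same number of samples.  In general the
    overlap is ``2w - n`` samples for window length ``w`` of an
    ``n``-sample series (when positive).
    """
    if sheet is None:
        sheet = matrix.sheet
    if sheet is None:
        raise ValueError("split_conditions requires a sample sheet")
    sheet = sheet.loc[matrix.values.columns]

    per_subject = sheet.groupby("subject")["sampling_index"]
    n = int(sheet["sampling_index"].max())
    incomplete = [
        subj
        for subj, idx in per_subject
        if sorted(idx) != list(range(1, n + 1))
    ]
    if incomplete:
        raise ValueError(
            f"subjects with incomplete sampling grids: {incomplete}"
        )

    clock = sheet.sort_values(["subject", "sampling_index"])["clock_time"].values
    dt = float((clock[1] - clock[0]) % 24.0)
    w = window_length(n, dt, window_hours)

    base_ids = sheet.index[sheet["sampling_index"] <= w]
    sd_ids = sheet.index[sheet["sampling_index"] >= n - w + 1]

    base_sheet = sheet.loc[base_ids].copy()
    base_sheet["condition"] = BASELINE
    sd_sheet = sheet.loc[sd_ids].copy()
    sd_sheet["condition"] = SLEEP_DEPRIVATION

    base = MethylationMatrix(matrix.values[base_ids], matrix.scale, base_sheet)
    sd = MethylationMatrix(matrix.values[sd_ids], matrix.scale, sd_sheet)
    return base, sd


# ---------------------------------------------------------------------------
# scaling and covariate residualization


def zscore_per_probe(
    matrix: MethylationMatrix,
) -> tuple[MethylationMatrix, pd.Series]:
    """Center and scale each probe row to mean 0, sample SD 1.

    Subjects and timepoints within the window are pooled, so the
    between-subject agreement in phase is preserved rather than being
    rescaled per subject.  Zero-variance probes cannot be scaled; they
    are set to all-zeros and flagged instead of raising.
    """
    vals = matrix.values
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    flat = sd <= 0
    safe_sd = sd.where(~flat, 1.0)
    z = vals.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[flat] = 0.0
    out = replace(matrix, values=z)
    return out, flat.rename("zero_variance")


def _design_matrix(sheet: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    cols = []
    for cov in covariates:
        if cov not in sheet.columns:
            raise ValueError(f"covariate {cov!r} not in sample sheet")
        col = sheet[cov]
        if col.dtype == object or col.dtype.name == "category":
            levels = col.value_counts()
            if (levels < 2).any():
                small = levels.index[levels < 2].tolist()
                raise ValueError(
                    f"covariate {cov!r} has singleton level(s) {small}"
                )
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            cols.append(dummies)
        else:
            cols.append(col.astype(float).to_frame(cov))
    X = pd.concat(
        [pd.Series(1.0, index=sheet.index, name="intercept"), *cols], axis=1
    )
    return X


def residualize_covariates(
    matrix: MethylationMatrix, covariates: list[str], sheet: pd.DataFrame | None = None
) -> MethylationMatrix:
    """Remove linear covariate structure (batch, batch position, age...).

    Per probe, fits ordinary least squares on the requested covariates
    (categoricals dummy-coded) and returns residuals plus the probe's
    grand mean, so the output stays on the input scale.  This is an
    optional stage, off by default in the pipeline.
    """
    if sheet is None:
        sheet = matrix.sheet
    if sheet is None:
        raise ValueError("residualize_covariates requires a sample sheet")
    sheet = sheet.loc[matrix.values.columns]
    X = _design_matrix(sheet, covariates).values
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient covariate design (rank {rank} < {X.shape[1]} columns); "
            f"covariates {covariates} are aliased"
        )
    Y = matrix.values.values.T  # samples x probes
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    out = resid.T + matrix.values.values.mean(axis=1, keepdims=True)
    values = pd.DataFrame(
        out, index=matrix.values.index, columns=matrix.values.columns
    )
    return replace(matrix, values=values)
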