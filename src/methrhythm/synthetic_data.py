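"""Synthetic methylation time series with known rhythm ground truth.

The generator emulates the sleep-laboratory design: 15 subjects sampled
every 3 h for 45 h starting at 15:00 (16 samples each), with the first
eight samples on the baseline day and the last eight under total sleep
deprivation.  Each probe is planted into one of five rhythm classes
(``arrhy``, ``same``, ``loss``, ``gain``, ``change``) and its signal is
built on the M-value (logit-beta) scale:

    m = mesor + subject intercept
        + A * cos(2*pi*(t_clock - phi)/24) * [class-dependent mask]
        + drift * ramp(time awake) + noise

then mapped through the logistic function to the (0, 1) beta scale.
Additive Gaussian structure directly on (0, 1) would leak out of range;
the logit scale keeps every generated beta strictly inside the unit
interval while the logistic map preserves ordering of the latent
signal.

The late-wakefulness drift emulates the accumulating methylation change
seen toward the end of sleep deprivation: a per-probe signed offset,
negative (hypomethylating) for 70% of affected probes by default,
applied only to samples with >= 23 h of cumulative time awake and
ramping linearly up to the final sample.

White-blood-cell counts for the 13 (non-exclusive) classes are
generated from sinusoidal diurnal means with lognormal noise; the
composite classes are sums of their members by construction, and
missing timepoints are planted only at interior sampling indices so
the adjacent-mean imputation rule is always defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .cell_composition import CELL_CLASSES, CellCountTable
from .design import BASELINE, SLEEP_DEPRIVATION, StudyDesign
from .preprocess import BETA, MSCALE, MethylationMatrix

#: default class mix: the classifiable-site proportions of a large
#: blood-methylation rhythm screen (arrhythmic roughly half, shared
#: rhythms a third, loss/gain 7% each, phase change rare)
DEFAULT_CLASS_PROPORTIONS = {
    "arrhy": 107476 / 223595,
    "same": 79163 / 223595,
    "loss": 16077 / 223595,
    "gain": 15735 / 223595,
    "change": 5144 / 223595,
}

CLASSES = tuple(DEFAULT_CLASS_PROPORTIONS)


@dataclass(frozen=True)
class PlantedTruthConfig:
    """Ground-truth generation parameters (M-value scale).

    ``amplitude`` and ``noise_sd`` set the per-observation
    signal-to-noise ratio A/sigma that downstream recovery tests sweep;
    ``noise_sd_spread`` is the lognormal sigma of the per-probe noise
    SD around ``noise_sd`` (0 gives homoscedastic probes), emulating
    the strong probe-to-probe variance heterogeneity of real arrays
    that the empirical-Bayes moderation shrinks against.
    ``drift_magnitude`` is the full-ramp M-value offset reached at the
    final sample by drift-affected probes; ``hypo_fraction`` of those
    probes drift negative (hypomethylation).
    """

    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    amplitude: float = 0.5
    mesor_range: tuple[float, float] = (-2.5, 2.5)
    subject_intercept_sd: float = 0.3
    noise_sd: float = 0.25
    noise_sd_spread: float = 0.3
    acrophase_shift_range: tuple[float, float] = (6.0, 12.0)
    drift_fraction: float = 0.15
    drift_magnitude: float = 0.5
    hypo_fraction: float = 0.70
    drift_onset_awake: float = 23.0

    def __post_init__(self) -> None:
        props = self.class_proportions
        unknown = set(props) - set(CLASSES)
        if unknown:
            raise ValueError(f"class_proportions: unknown classes {sorted(unknown)}")
        vals = np.array([props.get(c, 0.0) for c in CLASSES], dtype=float)
        if (vals < 0).any() or not np.isclose(vals.sum(), 1.0, atol=1e-8):
            raise ValueError(
                "class_proportions must be non-negative and sum to 1"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.noise_sd_spread < 0:
            raise ValueError("noise_sd_spread must be non-negative")
        if self.subject_intercept_sd < 0:
            raise ValueError("subject_intercept_sd must be non-negative")
        if not 0.0 <= self.hypo_fraction <= 1.0:
            raise ValueError("hypo_fraction must lie in [0, 1]")
        if not 0.0 <= self.drift_fraction <= 1.0:
            raise ValueError("drift_fraction must lie in [0, 1]")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    @property
    def proportion_vector(self) -> np.ndarray:
        return np.array(
            [self.class_proportions.get(c, 0.0) for c in CLASSES], dtype=float
        )


@dataclass
class SyntheticDataset:
    """A generated dataset plus its planted ground truth."""

    methylation: MethylationMatrix  # beta scale
    m_values: MethylationMatrix  # same data, latent M scale
    sample_sheet: pd.DataFrame
    truth: pd.DataFrame  # per-probe class/mesor/amplitude/acrophases/drift
    cell_counts: CellCountTable | None
    design: StudyDesign
    seed: int


def _drift_ramp(time_awake: np.ndarray, design: StudyDesign, onset: float) -> np.ndarray:
    """Linear 0->1 ramp over samples with time awake >= onset hours.

    The ramp reaches 1 at the final sample; the first affected sample
    sits one sampling interval's worth of ramp above zero so that the
    onset sample itself already carries some drift.
    """
    awake = np.nan_to_num(time_awake, nan=-np.inf)
    final = np.nanmax(time_awake)
    start = onset - design.sampling_interval
    denom = final - start
    ramp = np.clip((awake - start) / denom, 0.0, 1.0)
    ramp[awake < onset] = 0.0
    return ramp


def generate_methylation(
    design: StudyDesign = StudyDesign(),
    truth_config: PlantedTruthConfig = PlantedTruthConfig(),
    n_probes: int = 1000,
    seed: int = 0,
    cellcounts: bool = True,
    missing_rate: float = 0.02,
) -> SyntheticDataset:
    """Generate a full synthetic dataset with planted rhythm classes.

    Deterministic for a fixed seed.  Probe classes are drawn from
    ``truth_config.class_proportions``; rhythmic probes get an
    acrophase uniform on [0, 24) (the ``change`` class a second,
    shifted acrophase for the sleep-deprivation half), and
    ``drift_fraction`` of all probes a signed late-wakefulness drift.
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    rng = np.random.default_rng(seed)

    ages = rng.uniform(*design.age_range, size=design.n_subjects).round(1)
    sheet = design.sample_sheet(ages=ages)

    labels = rng.choice(
        CLASSES, size=n_probes, p=truth_config.proportion_vector
    )
    mesor = rng.uniform(*truth_config.mesor_range, size=n_probes)
    amplitude = np.where(
        labels == "arrhy", 0.0, truth_config.amplitude
    )
    acro_base = rng.uniform(0.0, 24.0, size=n_probes)
    shift_mag = rng.uniform(*truth_config.acrophase_shift_range, size=n_probes)
    shift_sign = rng.choice([-1.0, 1.0], size=n_probes)
    acro_sd = np.where(
        labels == "change",
        (acro_base + shift_sign * shift_mag) % 24.0,
        acro_base,
    )

    spread = truth_config.noise_sd_spread
    # lognormal with unit mean so noise_sd stays the ensemble average
    probe_noise_sd = truth_config.noise_sd * (
        rng.lognormal(-0.5 * spread**2, spread, size=n_probes)
        if spread > 0
        else np.ones(n_probes)
    )

    drifted = rng.random(n_probes) < truth_config.drift_fraction
    drift_sign = np.where(
        rng.random(n_probes) < truth_config.hypo_fraction, -1.0, 1.0
    )
    drift = np.where(drifted, drift_sign * truth_config.drift_magnitude, 0.0)

    probe_ids = [f"cg{i:07d}" for i in range(n_probes)]
    truth = pd.DataFrame(
        {
            "class": labels,
            "mesor": mesor,
            "amplitude": amplitude,
            "acrophase_baseline": np.where(labels == "arrhy", np.nan, acro_base),
            "acrophase_sleep_deprivation": np.where(
                labels == "arrhy", np.nan, acro_sd
            ),
            "drift": drift,
            "noise_sd": probe_noise_sd,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )

    clock = sheet["clock_time"].values  # n_samples total (all subjects)
    cond = sheet["condition"].values
    is_base = cond == BASELINE
    subj_codes = sheet["subject"].map(
        {s: i for i, s in enumerate(design.subject_ids())}
    ).values
    ramp = _drift_ramp(sheet["time_awake"].values, design, truth_config.drift_onset_awake)

    # rhythm activity mask per class and condition half
    active_base = np.isin(labels, ["same", "loss", "change"])
    active_sd = np.isin(labels, ["same", "gain", "change"])

    w = 2.0 * np.pi / 24.0
    # probes x samples phases, condition-dependent for "change"
    phase = np.where(is_base[None, :], acro_base[:, None], acro_sd[:, None])
    active = np.where(
        is_base[None, :], active_base[:, None], active_sd[:, None]
    )
    rhythm = amplitude[:, None] * np.cos(w * (clock[None, :] - phase)) * active

    intercepts = rng.normal(
        0.0, truth_config.subject_intercept_sd, size=(n_probes, design.n_subjects)
    )
    noise = rng.normal(size=(n_probes, len(sheet))) * probe_noise_sd[:, None]

    M = (
        mesor[:, None]
        + intercepts[:, subj_codes]
        + rhythm
        + drift[:, None] * ramp[None, :]
        + noise
    )
    m_frame = pd.DataFrame(M, index=truth.index, columns=sheet.index)
    beta_frame = pd.DataFrame(
        expit(M), index=truth.index, columns=sheet.index
    )

    counts = (
        generate_cellcounts(design, seed=seed + 1, missing_rate=missing_rate)
        if cellcounts
        else None
    )
    return SyntheticDataset(
        methylation=MethylationMatrix(beta_frame, BETA, sheet),
        m_values=MethylationMatrix(m_frame, MSCALE, sheet),
        sample_sheet=sheet,
        truth=truth,
        cell_counts=counts,
        design=design,
        seed=seed,
    )


#: leaf cell classes with (mean cells/ul, relative amplitude, acrophase)
_LEAF_PARAMS = {
    "granulocytes": (3500.0, 0.20, 18.0),
    "monocytes": (400.0, 0.15, 20.0),
    "total_b": (220.0, 0.25, 1.0),
    "nk_dendritic": (300.0, 0.30, 19.0),
    "cd4_memory": (420.0, 0.22, 1.5),
    "cd4_naive": (380.0, 0.22, 2.0),
    "cd8_memory": (210.0, 0.22, 1.0),
    "cd8_naive": (240.0, 0.22, 2.5),
}


def generate_cellcounts(
    design: StudyDesign = StudyDesign(),
    seed: int = 0,
    missing_rate: float = 0.0,
    noise_sd: float = 0.08,
) -> CellCountTable:
    """Generate diurnally rhythmic WBC counts for the 13 classes.

    Leaf classes (granulocytes, monocytes, B cells, NK/dendritic and
    the four CD4/CD8 memory/naive pools) get sinusoidal diurnal means
    with multiplicative lognormal noise, so counts stay positive;
    composite classes are computed as exact sums of their members.
    With ``missing_rate`` > 0, whole timepoints (all 13 classes) are
    blanked to NaN at interior sampling indices only, never at two
    consecutive indices, mirroring sporadically failed blood draws.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    clock = design.clock_times
    rows = []
    for subj in design.subject_ids():
        subj_scale = rng.lognormal(0.0, 0.1)
        leaves = {}
        for cls, (mean, rel_amp, phi) in _LEAF_PARAMS.items():
            base = mean * subj_scale * (
                1.0 + rel_amp * np.cos(2 * np.pi * (clock - phi) / 24.0)
            )
            leaves[cls] = base * rng.lognormal(
                0.0, noise_sd, size=clock.size
            )
        for j, idx in enumerate(design.sampling_indices):
            row = {"subject": subj, "sampling_index": int(idx),
                   "clock_time": float(clock[j])}
            for cls in _LEAF_PARAMS:
                row[cls] = leaves[cls][j]
            rows.append(row)
    counts = pd.DataFrame(rows).set_index(["subject", "sampling_index"])
    for composite, members in [
        ("total_cd4", ["cd4_memory", "cd4_naive"]),
        ("total_cd8", ["cd8_memory", "cd8_naive"]),
    ]:
        counts[composite] = counts[list(members)].sum(axis=1)
    counts["total_t"] = counts["total_cd4"] + counts["total_cd8"]
    counts["lymphocytes"] = (
        counts["total_t"] + counts["total_b"] + counts["nk_dendritic"]
    )
    counts["total_wbc"] = (
        counts["granulocytes"] + counts["lymphocytes"] + counts["monocytes"]
    )
    counts = counts[["clock_time", *CELL_CLASSES]]

    imputed = pd.DataFrame(False, index=counts.index, columns=CELL_CLASSES)
    if missing_rate > 0:
        n = design.n_samples_per_subject
        for subj in design.subject_ids():
            blocked: set[int] = set()
            for idx in range(2, n):  # interior sampling indices only
                if idx in blocked:
                    continue
                if rng.random() < missing_rate:
                    counts.loc[(subj, idx), CELL_CLASSES] = np.nan
                    blocked.update((idx - 1, idx + 1))
    return CellCountTable(counts, imputed)


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, str]:
    """Write matrix, sample sheet, truth and cell counts as text files."""
    from pathlib import Path

    from .preprocess import write_matrix, write_sample_sheet

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "beta_matrix.tsv",
        "sheet": outdir / "sample_sheet.csv",
        "truth": outdir / "truth.tsv",
    }
    write_matrix(dataset.methylation, paths["matrix"])
    write_sample_sheet(dataset.sample_sheet, paths["sheet"])
    dataset.truth.to_csv(paths["truth"], sep="\t")
    if dataset.cell_counts is not None:
        paths["cell_counts"] = outdir / "cell_counts.csv"
        dataset.cell_counts.to_csv(paths["cell_counts"])
    return {k: str(v) for k, v in paths.items()}
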