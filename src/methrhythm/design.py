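"""Study design: a within-subject sleep-laboratory time course.

Fifteen subjects are sampled every 3 hours for 45 hours starting at
15:00, giving 16 samples each.  The first eight samples fall on the
baseline (normal sleep) day/night; the last eight fall on the total
sleep-deprivation day/night.  For rhythm analysis the series is later
split into two overlapping nine-sample 24-hour windows (see
:func:`methrhythm.preprocess.split_conditions`); the per-sample
``condition`` label recorded here drives the matched-clock-time pairing
of the differential-methylation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASELINE = "baseline"
SLEEP_DEPRIVATION = "sleep_deprivation"


@dataclass(frozen=True)
class StudyDesign:
    """Sampling layout of the sleep-deprivation time-series study.

    Parameters
    ----------
    n_subjects:
        Number of participants.
    sampling_interval:
        Hours between consecutive samples.
    n_samples_per_subject:
        Samples per participant across the whole time course.
    start_clock_time:
        Clock time (hours of day, [0, 24)) of the first sample.
    lights_out, lights_on:
        Scheduled sleep window on the baseline night; metadata only,
        except that ``lights_on`` anchors the time-awake annotation of
        the sleep-deprivation samples.
    """

    n_subjects: int = 15
    sampling_interval: float = 3.0
    n_samples_per_subject: int = 16
    start_clock_time: float = 15.0
    condition_labels: tuple[str, str] = (BASELINE, SLEEP_DEPRIVATION)
    lights_out: float = 23.0
    lights_on: float = 7.0
    n_batches: int = 2
    age_range: tuple[float, float] = (19.0, 35.0)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.n_samples_per_subject < 2:
            raise ValueError("n_samples_per_subject must be >= 2")
        if not 0 <= self.start_clock_time < 24:
            raise ValueError("start_clock_time must lie in [0, 24)")

    @property
    def total_span(self) -> float:
        """Hours from first to last sample (45 for the defaults)."""
        return (self.n_samples_per_subject - 1) * self.sampling_interval

    @property
    def elapsed_hours(self) -> np.ndarray:
        """Hours since the first sample, one entry per sampling index."""
        return np.arange(self.n_samples_per_subject) * self.sampling_interval

    @property
    def clock_times(self) -> np.ndarray:
        """Clock time of each sampling index, wrapped modulo 24."""
        return (self.start_clock_time + self.elapsed_hours) % 24.0

    @property
    def sampling_indices(self) -> np.ndarray:
        return np.arange(1, self.n_samples_per_subject + 1)

    @property
    def condition_per_index(self) -> np.ndarray:
        """Condition label of each sampling index (first half baseline)."""
        half = self.n_samples_per_subject // 2
        return np.where(
            self.sampling_indices <= half,
            self.condition_labels[0],
            self.condition_labels[1],
        )

    @property
    def time_awake(self) -> np.ndarray:
        """Cumulative hours awake at each sleep-deprivation sample.

        Subjects wake at ``lights_on`` on the sleep-deprivation day and
        stay awake through the final sample; baseline samples get NaN
        because their wakefulness is interrupted by the baseline sleep
        episode and never enters any contrast.
        """
        awake_at_start = (self.start_clock_time - self.lights_on) % 24.0
        half = self.n_samples_per_subject // 2
        sd_elapsed = self.elapsed_hours - self.elapsed_hours[half]
        awake = awake_at_start + sd_elapsed
        awake[self.sampling_indices <= half] = np.nan
        return awake

    def subject_ids(self) -> list[str]:
        return [f"s{i:02d}" for i in range(1, self.n_subjects + 1)]

    def sample_sheet(self, ages: np.ndarray | None = None) -> pd.DataFrame:
        """Build the per-sample metadata table.

        One row per (subject, sampling index).  Sample IDs are
        ``<subject>_t<index>``.  Batch assignment interleaves subjects
        across ``n_batches`` chips; batch position is the running slot
        within a batch.
        """
        subjects = self.subject_ids()
        if ages is None:
            lo, hi = self.age_range
            ages = lo + (hi - lo) * (np.arange(self.n_subjects) % 5) / 4.0
        ages = np.asarray(ages, dtype=float)
        if ages.shape != (self.n_subjects,):
            raise ValueError("ages must have one entry per subject")

        rows = []
        batch_fill = [0] * self.n_batches
        for si, subj in enumerate(subjects):
            batch = si % self.n_batches
            for idx, clock, cond, awake in zip(
                self.sampling_indices,
                self.clock_times,
                self.condition_per_index,
                self.time_awake,
            ):
                rows.append(
                    {
                        "sample_id": f"{subj}_t{idx:02d}",
                        "subject": subj,
                        "condition": cond,
                        "sampling_index": int(idx),
                        "clock_time": float(clock),
                        "time_awake": float(awake) if np.isfinite(awake) else np.nan,
                        "batch": f"b{batch + 1}",
                        "batch_position": batch_fill[batch] + 1,
                        "age": float(ages[si]),
                    }
                )
                batch_fill[batch] += 1
        sheet = pd.DataFrame(rows).set_index("sample_id")
        return sheet
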