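"""Cohort quality control and ROS-based pooling.

Samples are semen specimens with oxidative-stress measurements. The
analysis pools specimens into a ROS− group (seminal reactive-oxygen-species
chemiluminescence below 20 RLU/sec/10^6 sperm) and a ROS+ group (at or
above that threshold). Specimens positive for the Endtz peroxidase test
(more than 1×10^6 white blood cells/mL, indicating leukocytospermia) are
excluded before pooling. Descriptive statistics per group are reported as
mean ± SD and median with min/max and quartiles.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

ROS_THRESHOLD_DEFAULT = 20.0  # RLU/sec/10^6 sperm
ENDTZ_LIMIT_DEFAULT = 1.0  # 10^6 WBC/mL

#: numeric sample fields summarized by :func:`summarize_group`
NUMERIC_FIELDS = (
    "concentration", "motility", "round_cells", "endtz",
    "morphology", "ros", "tac", "dna_frag",
)
_PERCENT_FIELDS = ("motility", "morphology", "dna_frag")
_OPTIONAL_FIELDS = ("tac", "dna_frag")


class ValidationError(ValueError):
    """A sample failed its field invariants."""


class RosGroup(str, enum.Enum):
    ROS_MINUS = "ROS_minus"
    ROS_PLUS = "ROS_plus"


@dataclass(frozen=True)
class SemenSample:
    """One subject's semen and oxidative-stress measurements.

    Units: concentration 10^6 sperm/mL; motility and morphology percent;
    round_cells and endtz 10^6 cells/mL; ros RLU/sec/10^6 sperm; tac
    micromole trolox equivalents; dna_frag percent TUNEL-positive cells.
    ``tac`` and ``dna_frag`` may be absent (they are measured for patients
    only in the study design this emulates).
    """

    subject_id: str
    cohort: str  # "donor" or "patient"
    concentration: float
    motility: float
    round_cells: float
    endtz: float
    morphology: float
    ros: float
    tac: float | None = None
    dna_frag: float | None = None

    def __post_init__(self) -> None:
        if self.cohort not in ("donor", "patient"):
            raise ValidationError(
                f"sample {self.subject_id!r}: cohort must be 'donor' or "
                f"'patient', got {self.cohort!r}"
            )
        for f in fields(self):
            if f.name in ("subject_id", "cohort"):
                continue
            value = getattr(self, f.name)
            if value is None:
                if f.name in _OPTIONAL_FIELDS:
                    continue
                raise ValidationError(
                    f"sample {self.subject_id!r}: missing value for {f.name}"
                )
            if not math.isfinite(value) or value < 0:
                raise ValidationError(
                    f"sample {self.subject_id!r}: {f.name} must be a finite "
                    f"non-negative number, got {value!r}"
                )
            if f.name in _PERCENT_FIELDS and value > 100:
                raise ValidationError(
                    f"sample {self.subject_id!r}: {f.name} is a percentage "
                    f"and must be <= 100, got {value!r}"
                )


@dataclass(frozen=True)
class GroupSummary:
    """Per-field descriptive statistics for one group of samples."""

    n: int
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    median: dict[str, float] = field(default_factory=dict)
    min: dict[str, float] = field(default_factory=dict)
    max: dict[str, float] = field(default_factory=dict)
    p25: dict[str, float] = field(default_factory=dict)
    p75: dict[str, float] = field(default_factory=dict)


def classify_ros(
    sample: SemenSample, threshold: float = ROS_THRESHOLD_DEFAULT
) -> RosGroup:
    """Assign a sample to the ROS− or ROS+ pool.

    ROS− is strictly below ``threshold`` (RLU/sec/10^6 sperm); a sample at
    exactly the threshold is ROS+.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold!r}")
    ros = sample.ros
    if ros is None or not math.isfinite(ros) or ros < 0:
        raise ValidationError(
            f"sample {sample.subject_id!r}: invalid ROS value {ros!r}"
        )
    return RosGroup.ROS_MINUS if ros < threshold else RosGroup.ROS_PLUS


def apply_exclusions(
    samples: list[SemenSample], endtz_limit: float = ENDTZ_LIMIT_DEFAULT
) -> tuple[list[SemenSample], list[tuple[SemenSample, str]]]:
    """Split samples into (included, excluded-with-reason).

    A sample is excluded when its Endtz count strictly exceeds
    ``endtz_limit`` (10^6 WBC/mL); a sample exactly at the limit is kept.
    """
    included: list[SemenSample] = []
    excluded: list[tuple[SemenSample, str]] = []
    for s in samples:
        if s.endtz > endtz_limit:
            excluded.append((s, "endtz_positive"))
        else:
            included.append(s)
    return included, excluded


def summarize_group(
    samples: list[SemenSample], field_names: tuple[str, ...] = NUMERIC_FIELDS
) -> GroupSummary:
    """Descriptive statistics (mean, SD, median, min/max, quartiles).

    Percentiles use linear interpolation between closest ranks (numpy's
    default). SD is the sample standard deviation (ddof=1); it is NaN for a
    single observation. Optional fields missing in every sample are left
    out of the summary; fields missing in only some samples summarize the
    observed values.
    """
    if not samples:
        raise ValueError("cannot summarize an empty group")
    summary = GroupSummary(n=len(samples))
    for name in field_names:
        values = np.array(
            [getattr(s, name) for s in samples if getattr(s, name) is not None],
            dtype=float,
        )
        if values.size == 0:
            continue
        summary.mean[name] = float(np.mean(values))
        summary.sd[name] = (
            float(np.std(values, ddof=1)) if values.size > 1 else float("nan")
        )
        summary.median[name] = float(np.median(values))
        summary.min[name] = float(np.min(values))
        summary.max[name] = float(np.max(values))
        summary.p25[name] = float(np.percentile(values, 25))
        summary.p75[name] = float(np.percentile(values, 75))
    return summary


def proportion(numerator: int, denominator: int) -> float:
    """Percentage ``100*numerator/denominator`` rounded to one decimal."""
    if denominator <= 0:
        raise ValueError(f"denominator must be positive, got {denominator!r}")
    if not 0 <= numerator <= denominator:
        raise ValueError(
            f"numerator must lie in [0, denominator], got {numerator!r}"
        )
    return round(100.0 * numerator / denominator, 1)


def read_samples_csv(path) -> list[SemenSample]:
    """Read a sample-metadata CSV into validated :class:`SemenSample` rows.

    Expected header: subject_id,cohort,concentration,motility,round_cells,
    endtz,morphology,ros,tac,dna_frag. Empty cells are treated as missing;
    missing values are rejected except for the optional tac/dna_frag.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "cohort": str})
    required = [
        "subject_id", "cohort", "concentration", "motility",
        "round_cells", "endtz", "morphology", "ros",
    ]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"samples CSV missing columns: {missing_cols}")
    samples = []
    for row in df.itertuples(index=False):
        kwargs = {}
        for name in ("tac", "dna_frag"):
            v = getattr(row, name, None)
            kwargs[name] = None if v is None or pd.isna(v) else float(v)
        for name in required[2:]:
            v = getattr(row, name)
            if pd.isna(v):
                raise ValidationError(
                    f"sample {row.subject_id!r}: missing value for {name}"
                )
            kwargs[name] = float(v)
        samples.append(
            SemenSample(subject_id=row.subject_id, cohort=row.cohort, **kwargs)
        )
    return samples


def qc_summary_table(
    samples: list[SemenSample],
    ros_threshold: float = ROS_THRESHOLD_DEFAULT,
    endtz_limit: float = ENDTZ_LIMIT_DEFAULT,
) -> pd.DataFrame:
    """Tidy per-group summary table after exclusions.

    Groups: donor, patient, ROS− and ROS+ (the latter two over the
    included samples regardless of cohort). One row per (group, field,
    statistic).
    """
    included, _ = apply_exclusions(samples, endtz_limit)
    groups: dict[str, list[SemenSample]] = {
        "donor": [s for s in included if s.cohort == "donor"],
        "patient": [s for s in included if s.cohort == "patient"],
        "ROS_minus": [
            s for s in included
            if classify_ros(s, ros_threshold) is RosGroup.ROS_MINUS
        ],
        "ROS_plus": [
            s for s in included
            if classify_ros(s, ros_threshold) is RosGroup.ROS_PLUS
        ],
    }
    rows = []
    for group, members in groups.items():
        if not members:
            continue
        summ = summarize_group(members)
        for stat in ("mean", "sd", "median", "min", "max", "p25", "p75"):
            for name, value in getattr(summ, stat).items():
                rows.append(
                    {"group": group, "n": summ.n, "field": name,
                     "statistic": stat, "value": value}
                )
    return pd.DataFrame(rows, columns=["group", "n", "field", "statistic", "value"])
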