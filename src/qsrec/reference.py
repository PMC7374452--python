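"""BMI-for-age obesity reference table.

Childhood obesity is defined against sex- and age-specific BMI-for-age
growth charts: a child is classified obese when their BMI reaches the
chart's obesity threshold for their sex and age (the 95th-percentile
criterion used to recruit intervention cohorts).  The shipped default
table carries the printed reference points of the Spanish growth charts
used in school-age obesity studies: thresholds at ages 8.5 and 9.5 for
each sex, with the published medians where available.

Thresholds between tabulated ages are linearly interpolated; outside the
tabulated range they are clamped to the nearest tabulated age.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError

__all__ = ["ObesityReferenceTable", "classify_obesity", "compute_bmi", "default_reference_table"]

_SEXES = ("male", "female")


def compute_bmi(weight: float, height: float) -> float:
    """Body-mass index, kg/m², from weight (kg) and height (m)."""
    if not weight > 0:
        raise DomainError(f"weight must be positive, got {weight}")
    if not height > 0:
        raise DomainError(f"height must be positive, got {height}")
    return weight / height**2


@dataclass(frozen=True)
class ObesityReferenceTable:
    """Per-sex (age, obesity-threshold BMI) reference points.

    ``medians`` are optional published median BMIs at the same ages; they
    are metadata only and are not used for classification.
    """

    ages: dict[str, np.ndarray] = field(repr=False)
    thresholds: dict[str, np.ndarray] = field(repr=False)
    medians: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        for sex in self.ages:
            a, t, m = self.ages[sex], self.thresholds[sex], self.medians[sex]
            if len(a) == 0:
                raise ConfigurationError(f"empty reference table for sex {sex!r}")
            if not np.all(np.diff(a) > 0):
                raise ConfigurationError(f"ages not strictly increasing for sex {sex!r}")
            present = ~np.isnan(m)
            if np.any(t[present] <= m[present]):
                raise ConfigurationError(f"obesity threshold not above median for sex {sex!r}")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ObesityReferenceTable":
        """Build from a frame with columns sex, age_years, median_bmi, obesity_bmi."""
        ages: dict[str, np.ndarray] = {}
        thresholds: dict[str, np.ndarray] = {}
        medians: dict[str, np.ndarray] = {}
        for sex, grp in frame.groupby("sex"):
            grp = grp.sort_values("age_years")
            ages[str(sex)] = grp["age_years"].to_numpy(float)
            thresholds[str(sex)] = grp["obesity_bmi"].to_numpy(float)
            medians[str(sex)] = grp["median_bmi"].to_numpy(float)
        return cls(ages=ages, thresholds=thresholds, medians=medians)

    @classmethod
    def from_csv(cls, path) -> "ObesityReferenceTable":
        return cls.from_frame(pd.read_csv(path))

    def threshold(self, sex: str, age: float) -> float:
        """Obesity-threshold BMI, interpolated in age and clamped at the ends."""
        if sex not in self.ages:
            raise DomainError(f"unknown sex {sex!r}; expected one of {sorted(self.ages)}")
        # np.interp clamps outside the tabulated range by construction
        return float(np.interp(age, self.ages[sex], self.thresholds[sex]))


def default_reference_table() -> ObesityReferenceTable:
    """The shipped reference table (printed points at ages 8.5 and 9.5)."""
    ref = importlib.resources.files("qsrec.data") / "obesity_reference.csv"
    with importlib.resources.as_file(ref) as path:
        return ObesityReferenceTable.from_csv(path)


_DEFAULT_TABLE: ObesityReferenceTable | None = None


def _default_table() -> ObesityReferenceTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = default_reference_table()
    return _DEFAULT_TABLE


def classify_obesity(
    sex: str, age: float, bmi: float, ref: ObesityReferenceTable | None = None
) -> str:
    """Classify a BMI as ``"obese"`` or ``"non_obese"`` against the reference chart.

    A child is obese iff their BMI is at or above the sex- and
    age-interpolated obesity threshold.
    """
    if sex not in _SEXES:
        raise DomainError(f"unknown sex {sex!r}; expected one of {_SEXES}")
    table = ref if ref is not None else _default_table()
    return "obese" if bmi >= table.threshold(sex, age) else "non_obese"
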