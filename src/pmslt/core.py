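"""Shared domain constants and the stratum type.

The population is partitioned into 5-year male and female cohorts with
band start ages 20, 25, ..., 95 (32 strata).  Each cohort is simulated by
single year of age until age 100, at which point the life table is closed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SEXES: tuple[str, str] = ("male", "female")

AGE_MIN = 20
AGE_MAX = 100
#: Single-year age grid shared by all rate tables (inclusive of both ends).
AGES = np.arange(AGE_MIN, AGE_MAX + 1)
N_AGES = len(AGES)  # 81

#: 5-year cohort band start ages.
AGE_GROUP_STARTS: tuple[int, ...] = tuple(range(20, 100, 5))


@dataclass(frozen=True, order=True)
class Stratum:
    """One sex x 5-year age-band cohort."""

    sex: str
    age_group: int

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.age_group not in AGE_GROUP_STARTS:
            raise ValueError(
                f"age_group must be one of {AGE_GROUP_STARTS}, got {self.age_group}"
            )

    @property
    def label(self) -> str:
        return f"{self.sex}_{self.age_group}"


def all_strata() -> list[Stratum]:
    """The full 32-stratum partition, in (sex, age) order."""
    return [Stratum(sex, a) for sex in SEXES for a in AGE_GROUP_STARTS]


def age_index(age: int) -> int:
    """Index of ``age`` on the shared single-year grid."""
    if not AGE_MIN <= age <= AGE_MAX:
        raise ValueError(f"age {age} outside [{AGE_MIN}, {AGE_MAX}]")
    return int(age) - AGE_MIN
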