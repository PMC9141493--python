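"""Case-directory naming protocol: ``CASE<n> <SEX> <lo>_<hi>``.

Cohort directories carry the only demographic information that survives
de-identification: the patient's sex and a five-year age range.  Ranges run
15-20, 20-25, ... through 100-105; at stage 2 the *upper bound* of the range
is re-inserted into the header as the Patient's Age.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .core import ProtocolError

_NAME_RE = re.compile(r"^CASE(\d+) ([A-Z]) (\d+)_(\d+)$")

#: the 18 admissible (lo, hi) age ranges
VALID_AGE_RANGES: tuple[tuple[int, int], ...] = tuple(
    (lo, lo + 5) for lo in range(15, 101, 5)
)
_VALID_SEX = ("F", "M", "O")


@dataclass(frozen=True)
class CaseDirInfo:
    """Parsed case-directory metadata."""

    case_number: int
    sex: str
    age_lo: int
    age_hi: int

    def __post_init__(self) -> None:
        if self.case_number < 1:
            raise ProtocolError(f"case number must be positive, got {self.case_number}")
        if self.sex not in _VALID_SEX:
            raise ProtocolError(f"unknown sex code {self.sex!r} (expected F, M or O)")
        if (self.age_lo, self.age_hi) not in VALID_AGE_RANGES:
            raise ProtocolError(
                f"illegal age range {self.age_lo}_{self.age_hi}; ranges run "
                "15_20, 20_25, ... 100_105"
            )


def parse_case_dirname(name: str) -> CaseDirInfo:
    """Parse ``CASE<n> <SEX> <lo>_<hi>``, validating the protocol."""
    m = _NAME_RE.match(name)
    if not m:
        raise ProtocolError(f"directory name {name!r} does not match 'CASE<n> <SEX> <lo>_<hi>'")
    case_number, sex, lo, hi = int(m.group(1)), m.group(2), int(m.group(3)), int(m.group(4))
    return CaseDirInfo(case_number, sex, lo, hi)


def format_case_dirname(info: CaseDirInfo) -> str:
    """Inverse of :func:`parse_case_dirname`."""
    return f"CASE{info.case_number} {info.sex} {info.age_lo}_{info.age_hi}"


def age_insert_value(info: CaseDirInfo) -> int:
    """Age (years) re-inserted at stage 2: the range's upper bound."""
    return info.age_hi


def format_patient_age(years: int) -> str:
    """Encode *years* as a DICOM Age String: three zero-padded digits + 'Y'."""
    if not 0 < years <= 999:
        raise ProtocolError(f"age {years} out of range (1-999 years)")
    return f"{years:03d}Y"


def age_range_for(true_age: int) -> tuple[int, int]:
    """Bin an exact age into its declared five-year range."""
    lo = 5 * (true_age // 5)
    if not 15 <= lo <= 100:
        raise ProtocolError(f"age {true_age} falls outside the 15-105 protocol range")
    return lo, lo + 5
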