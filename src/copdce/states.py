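"""Health-state definitions for the COPD cohort model.

The living states cross three FEV1-defined severity grades with a binary
recent-exacerbation history (an exacerbation in the previous annual cycle);
death is absorbing, giving seven states in total.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np


class Severity(enum.IntEnum):
    """COPD severity grade, defined by FEV1 percent of predicted."""

    MODERATE = 0
    SEVERE = 1
    VERY_SEVERE = 2

    @property
    def fev1_band(self) -> tuple[float, float]:
        """(low, high) FEV1 %-predicted band; low inclusive, high exclusive."""
        return _FEV1_BANDS[self]

    @property
    def label(self) -> str:
        return self.name.lower()


_FEV1_BANDS = {
    Severity.MODERATE: (50.0, 80.0),
    Severity.SEVERE: (30.0, 50.0),
    Severity.VERY_SEVERE: (0.0, 30.0),
}

SEVERITIES = (Severity.MODERATE, Severity.SEVERE, Severity.VERY_SEVERE)

# Living-state ordering: severity-major, no-recent stratum first.
#   0 moderate/no-recent, 1 moderate/recent,
#   2 severe/no-recent,   3 severe/recent,
#   4 very_severe/no-recent, 5 very_severe/recent, 6 death
N_LIVING = 6
DEATH = 6
N_STATES = 7

STATE_LABELS = (
    "moderate_no_recent",
    "moderate_recent",
    "severe_no_recent",
    "severe_recent",
    "very_severe_no_recent",
    "very_severe_recent",
    "death",
)


def state_index(severity: Severity, recent: bool) -> int:
    """Index of a living state in the canonical ordering."""
    return 2 * int(severity) + int(recent)


def state_severity(index: int) -> Severity:
    """Severity grade of a living state index."""
    if not 0 <= index < N_LIVING:
        raise ValueError(f"not a living state index: {index}")
    return Severity(index // 2)


def severity_of_living() -> np.ndarray:
    """Severity index (0/1/2) for each of the six living states."""
    return np.arange(N_LIVING) // 2


@dataclass(frozen=True)
class DistributionCheck:
    valid: bool
    total: float
    min_entry: float
    message: str


def validate_distribution(d: np.ndarray, tol: float = 1e-9) -> DistributionCheck:
    """Check that ``d`` is a cohort occupancy vector.

    Entries must be non-negative and sum to 1 within ``tol`` (death included
    when the vector has seven entries).  Returns a diagnostic record rather
    than raising, so callers can report the deficit.
    """
    d = np.asarray(d, dtype=float)
    total = float(d.sum())
    mn = float(d.min()) if d.size else 0.0
    if mn < -tol:
        return DistributionCheck(False, total, mn, f"negative occupancy {mn:.3g}")
    if abs(total - 1.0) > tol:
        return DistributionCheck(
            False, total, mn, f"occupancy sums to {total:.12f}, deficit {1.0 - total:.3g}"
        )
    return DistributionCheck(True, total, mn, "ok")
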