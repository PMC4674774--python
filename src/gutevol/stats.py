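"""Shared result container for the package's statistical tests."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any


@dataclass
class StatTestResult:
    """Outcome of a single hypothesis test.

    Parameters
    ----------
    name : str
        Name of the statistic (e.g. ``"F"``, ``"W"``, ``"slope"``).
    statistic : float
        Observed value of the statistic.
    p_value : float
        Two-sided p-value unless the test states otherwise; always in [0, 1].
    df : tuple or float, optional
        Degrees of freedom, where applicable.
    n : tuple or int, optional
        Sample size(s) entering the test.
    extra : dict
        Test-specific extras (one-sided p, alternative statistics, flags).
    """

    name: str
    statistic: float
    p_value: float
    df: Any = None
    n: Any = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or self.p_value != self.p_value):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")
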