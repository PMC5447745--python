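"""Chi-square goodness-of-fit tests for Mendelian segregation ratios.

An F2 population segregating a single recessive nuclear sterility gene is
expected to split 1 sterile : 3 fertile; a backcross to the heterozygote
splits 1:1, duplicate-recessive models give 7:9, and so on.  Observed
class counts are tested against such integer ratios with Pearson's X²
statistic (no continuity correction) and the upper tail of the chi-square
distribution with k-1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SegregationTest",
    "InheritanceCall",
    "chi_square_test",
    "classify_inheritance",
    "DEFAULT_RATIOS",
]

#: Candidate sterile:fertile ratios for single- and two-gene recessive
#: models (1:3 single recessive, 1:1 backcross, 7:9 duplicate recessive,
#: 1:15 duplicate dominant).
DEFAULT_RATIOS: tuple[tuple[int, ...], ...] = ((1, 3), (1, 1), (7, 9), (1, 15))


@dataclass(frozen=True)
class SegregationTest:
    """Result of one Pearson goodness-of-fit test against an integer ratio."""

    observed: tuple[int, ...]
    expected_ratio: tuple[int, ...]
    statistic: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        if self.statistic < 0 or not (0.0 <= self.p_value <= 1.0):
            raise ValueError("invalid test result")


@dataclass(frozen=True)
class InheritanceCall:
    """Best-fitting ratio among a candidate set plus an ambiguity verdict."""

    best_ratio: tuple[int, ...] | None
    verdict: str  # "single" | "ambiguous" | "none"
    tests: tuple[SegregationTest, ...] = field(repr=False, default=())


def chi_square_test(
    observed: Sequence[int], ratio: Sequence[int]
) -> SegregationTest:
    """Pearson X² goodness-of-fit of observed class counts to an integer ratio.

    Parameters
    ----------
    observed
        Non-negative counts per phenotypic class, e.g. ``(48, 112)`` for
        48 sterile and 112 fertile plants.
    ratio
        Positive ratio parts in the same class order, e.g. ``(1, 3)``.

    Returns
    -------
    SegregationTest
        With ``statistic = sum((obs - exp)^2 / exp)`` where
        ``exp_i = total * ratio_i / sum(ratio)`` and the p-value from the
        chi-square upper tail at ``k - 1`` degrees of freedom.  No Yates
        continuity correction is applied.
    """
    obs = np.asarray(observed, dtype=float)
    rat = np.asarray(ratio, dtype=float)
    if obs.ndim != 1 or rat.ndim != 1 or obs.size != rat.size:
        raise ValueError(
            f"observed ({obs.size}) and ratio ({rat.size}) lengths must match"
        )
    if obs.size < 2:
        raise ValueError("need at least two phenotypic classes")
    if np.any(obs < 0):
        raise ValueError("observed counts must be non-negative")
    if np.any(rat <= 0):
        raise ValueError("ratio parts must be positive")
    total = obs.sum()
    if total <= 0:
        raise ValueError("total observed count must be positive")

    expected = total * rat / rat.sum()
    statistic, p_value = stats.chisquare(obs, f_exp=expected)
    return SegregationTest(
        observed=tuple(int(x) for x in obs),
        expected_ratio=tuple(int(x) for x in np.asarray(ratio)),
        statistic=float(statistic),
        df=int(obs.size - 1),
        p_value=float(p_value),
    )


def classify_inheritance(
    observed: Sequence[int],
    ratios: Sequence[Sequence[int]] = DEFAULT_RATIOS,
    alpha: float = 0.05,
    ambiguity_margin: float = 0.5,
) -> InheritanceCall:
    """Test one observed count vector against several candidate ratios.

    The best ratio is the one with the smallest X² among those not
    rejected at ``alpha``.  The verdict is ``"ambiguous"`` when more than
    one ratio passes and the two smallest statistics differ by less than
    ``ambiguity_margin``; ``"none"`` when every candidate is rejected.
    """
    if len(ratios) == 0:
        raise ValueError("candidate ratio set must not be empty")
    tests = tuple(chi_square_test(observed, r) for r in ratios)
    passing = sorted(
        (t for t in tests if t.p_value >= alpha), key=lambda t: t.statistic
    )
    if not passing:
        return InheritanceCall(best_ratio=None, verdict="none", tests=tests)
    best = passing[0]
    verdict = "single"
    if len(passing) > 1 and passing[1].statistic - best.statistic < ambiguity_margin:
        verdict = "ambiguous"
    return InheritanceCall(best_ratio=best.expected_ratio, verdict=verdict, tests=tests)
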