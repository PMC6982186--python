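"""Chi-square goodness-of-fit tests for Mendelian segregation ratios.

A cross segregating for a single gene produces phenotype (or marker
genotype) classes in fixed expected proportions: 3:1 in an F2 for a
dominant/recessive pair, 1:1 in a backcross to the recessive parent, and
1:2:1 for codominant marker classes in an F2.  This module tests observed
class counts against such ratios with the uncorrected Pearson statistic

    chi2 = sum_i (O_i - E_i)^2 / E_i,   E_i = N * w_i / sum(w)

and a chi-square tail probability with df = classes - 1.  No Yates
continuity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SegregationResult",
    "RatioScan",
    "chi_square_gof",
    "test_standard_ratios",
    "STANDARD_RATIOS",
]


@dataclass(frozen=True)
class SegregationResult:
    """Outcome of one goodness-of-fit test.

    Attributes
    ----------
    observed : tuple of int
        Observed class counts.
    expected_ratio : tuple of float
        The ratio weights tested against (e.g. ``(3, 1)``).
    chi2 : float
        Uncorrected Pearson statistic.
    df : int
        Degrees of freedom, ``len(observed) - 1``.
    p : float
        Upper-tail chi-square probability.
    """

    observed: tuple[int, ...]
    expected_ratio: tuple[float, ...]
    chi2: float
    df: int
    p: float

    @property
    def expected(self) -> tuple[float, ...]:
        total = sum(self.observed)
        wsum = sum(self.expected_ratio)
        return tuple(total * w / wsum for w in self.expected_ratio)


@dataclass(frozen=True)
class RatioScan:
    """All standard-ratio tests for one count vector plus the best fit."""

    results: dict[str, SegregationResult]
    best: str

    @property
    def best_result(self) -> SegregationResult:
        return self.results[self.best]


def chi_square_gof(
    observed: Sequence[int], expected_ratio: Sequence[float]
) -> SegregationResult:
    """Pearson chi-square goodness-of-fit test of counts against a ratio.

    Parameters
    ----------
    observed
        Non-negative class counts, at least two classes, total > 0.
    expected_ratio
        Positive ratio weights, one per class.

    Returns
    -------
    SegregationResult

    Examples
    --------
    >>> r = chi_square_gof([278, 89], [3, 1])
    >>> round(r.chi2, 3), round(r.p, 3)
    (0.11, 0.74)
    """
    obs = np.asarray(observed, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if obs.ndim != 1 or obs.size < 2:
        raise ValueError("need at least two observed classes")
    if ratio.shape != obs.shape:
        raise ValueError("expected_ratio must have one weight per class")
    if np.any(obs < 0):
        raise ValueError("observed counts must be non-negative")
    total = obs.sum()
    if total <= 0:
        raise ValueError("total observed count must be positive")
    if np.any(ratio <= 0):
        raise ValueError("ratio weights must be positive")

    expected = total * ratio / ratio.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = obs.size - 1
    p = float(stats.chi2.sf(chi2, df))
    return SegregationResult(
        observed=tuple(int(x) for x in obs),
        expected_ratio=tuple(float(w) for w in ratio),
        chi2=chi2,
        df=df,
        p=p,
    )


#: Candidate Mendelian ratios tried by :func:`test_standard_ratios`,
#: in tie-break order.
STANDARD_RATIOS: tuple[tuple[str, tuple[float, ...]], ...] = (
    ("3:1", (3.0, 1.0)),
    ("1:1", (1.0, 1.0)),
    ("1:2:1", (1.0, 2.0, 1.0)),
)


def test_standard_ratios(observed: Sequence[int]) -> RatioScan:
    """Test counts against every standard ratio with a matching class count.

    Two-class counts are tested against 3:1 and 1:1; three-class counts
    against 1:2:1.  The best fit is the ratio with the largest p-value,
    ties broken by the order in :data:`STANDARD_RATIOS`.
    """
    n_classes = len(observed)
    results: dict[str, SegregationResult] = {}
    for name, ratio in STANDARD_RATIOS:
        if len(ratio) == n_classes:
            results[name] = chi_square_gof(observed, ratio)
    if not results:
        raise ValueError(
            f"{n_classes} classes match no standard ratio "
            f"({', '.join(n for n, _ in STANDARD_RATIOS)})"
        )
    best = max(results, key=lambda name: results[name].p)
    return RatioScan(results=results, best=best)


# the name follows the statistical operation, not the test framework
test_standard_ratios.__test__ = False  # type: ignore[attr-defined]
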