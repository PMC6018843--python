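"""Goodness-of-fit tests of k-unlinked-recessive-gene Mendelian models.

In a selfed F1 (an F2 population), a trait requiring homozygosity for the
donor allele at k unlinked loci is expressed by a fraction (1/4)^k of the
plants, i.e. a non-mutant:mutant ratio of (4^k - 1):1 — 3:1 for one locus,
15:1 for two, 63:1 for three.  The observed two-class split
{mutant, non-mutant} is tested against this expectation with an uncorrected
Pearson chi-square on 1 degree of freedom; model selection over a range of k
simply picks the k with the largest upper-tail p-value (ties to smaller k).

No Yates continuity correction is applied: the two-class statistic is used
as printed in the classical segregation-analysis literature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from scipy import stats

from .errors import InvalidInputError

__all__ = [
    "SegregationResult",
    "expected_mutant_fraction",
    "ratio_chisq",
    "select_model",
    "results_table",
]


def _check_count(value, name: str, minimum: int = 0) -> int:
    if isinstance(value, bool) or not float(value).is_integer():
        raise InvalidInputError(f"{name} must be an integer, got {value!r}")
    value = int(value)
    if value < minimum:
        raise InvalidInputError(f"{name} must be >= {minimum}, got {value}")
    return value


def expected_mutant_fraction(k: int) -> float:
    """Expected mutant fraction (1/4)^k in an F2 under k unlinked recessive loci."""
    k = _check_count(k, "k", minimum=1)
    return 0.25**k


@dataclass(frozen=True)
class SegregationResult:
    """Two-class Pearson chi-square fit of a k-recessive-gene model."""

    k: int
    n_total: int
    n_mutant: int
    expected_mutant: float
    chi_square: float
    df: int
    p_value: float

    @property
    def ratio_label(self) -> str:
        """Non-mutant:mutant ratio implied by k, e.g. '63:1' for k=3."""
        return f"{4**self.k - 1}:1"


def ratio_chisq(n_mutant: int, n_total: int, k: int) -> SegregationResult:
    """Pearson chi-square of an observed mutant count against the (4^k-1):1 ratio.

    Two classes (mutant vs non-mutant), expected counts n_total/(4^k) and
    n_total*(1 - 1/4^k), df = 1, no continuity correction; the p-value is the
    upper tail of the chi-square distribution with 1 df.
    """
    n_total = _check_count(n_total, "n_total", minimum=1)
    n_mutant = _check_count(n_mutant, "n_mutant", minimum=0)
    if n_mutant > n_total:
        raise InvalidInputError(
            f"n_mutant ({n_mutant}) exceeds n_total ({n_total})"
        )
    frac = expected_mutant_fraction(k)
    e_mut = n_total * frac
    e_non = n_total - e_mut
    o_mut = n_mutant
    o_non = n_total - n_mutant
    chi2 = (o_mut - e_mut) ** 2 / e_mut + (o_non - e_non) ** 2 / e_non
    p = float(stats.chi2.sf(chi2, df=1))
    return SegregationResult(
        k=int(k),
        n_total=n_total,
        n_mutant=n_mutant,
        expected_mutant=e_mut,
        chi_square=float(chi2),
        df=1,
        p_value=p,
    )


def select_model(
    n_mutant: int, n_total: int, k_range: Iterable[int]
) -> tuple[int, list[SegregationResult]]:
    """Fit every k in ``k_range`` and return (best k, all results).

    The best model maximizes the p-value; exact ties are broken toward the
    smaller (more parsimonious) k.  Results are returned sorted by k.
    """
    ks = sorted({_check_count(k, "k", minimum=1) for k in k_range})
    if not ks:
        raise InvalidInputError("k_range must be non-empty")
    results = [ratio_chisq(n_mutant, n_total, k) for k in ks]
    best = max(results, key=lambda r: (r.p_value, -r.k))
    return best.k, results


def results_table(results: Iterable[SegregationResult]) -> pd.DataFrame:
    """Tabulate segregation results as `k ratio chi2 df p`."""
    rows = list(results)
    return pd.DataFrame(
        {
            "k": [r.k for r in rows],
            "ratio": [r.ratio_label for r in rows],
            "chi2": [r.chi_square for r in rows],
            "df": [r.df for r in rows],
            "p": [r.p_value for r in rows],
        }
    )
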