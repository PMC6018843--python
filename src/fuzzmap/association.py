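"""Single-marker association between genotype class and a quantitative trait.

F2 individuals are partitioned at a marker into donor homozygotes (code 1),
heterozygotes (0.5) and recurrent homozygotes (0); mean fuzz percentages are
compared across the three pairwise contrasts with a two-sided Student's
t-test (pooled variance; Welch available behind a flag).  The pattern of
significant contrasts classifies the locus effect:

* *suppressor* — donor homozygotes have significantly LESS fuzz than
  recurrent homozygotes (donor allele suppresses fuzz);
* *enhancer* — donor homozygotes have significantly MORE fuzz;
* *additive_major* — additionally the heterozygote mean lies strictly
  between the homozygote means and differs significantly from both;
* *none* — no significant homozygote contrast (or untestable).

No multiple-testing correction is applied by default (per-marker reporting);
a Bonferroni option over the tested marker set is available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeMatrix
from .errors import InvalidInputError

__all__ = [
    "GROUPS",
    "CONTRASTS",
    "Contrast",
    "AssociationResult",
    "group_phenotype_by_genotype",
    "marker_trait_test",
    "classify_locus_effect",
    "associate",
    "association_table",
]

log = logging.getLogger(__name__)

GROUPS = ("donor_hom", "het", "recurrent_hom")
_CODE_TO_GROUP = {1.0: "donor_hom", 0.5: "het", 0.0: "recurrent_hom"}
CONTRASTS = ("donor_vs_recurrent", "het_vs_donor", "het_vs_recurrent")
_CONTRAST_GROUPS = {
    "donor_vs_recurrent": ("donor_hom", "recurrent_hom"),
    "het_vs_donor": ("het", "donor_hom"),
    "het_vs_recurrent": ("het", "recurrent_hom"),
}


@dataclass(frozen=True)
class Contrast:
    """One pairwise two-sample t-test (group a minus group b)."""

    t: float
    p_value: float
    n_a: int
    n_b: int
    testable: bool
    reason: str | None = None

    def significant(self, alpha: float) -> bool:
        return self.testable and self.p_value < alpha


@dataclass
class AssociationResult:
    """Genotype-group summary and pairwise contrasts for one marker."""

    marker_id: str
    group_means: dict[str, float]
    group_sizes: dict[str, int]
    contrasts: dict[str, Contrast]
    n_used: int
    n_excluded: int
    effect_call: str | None = None


def group_phenotype_by_genotype(
    gm: GenotypeMatrix, marker_id: str, phenotypes: pd.DataFrame
) -> dict[str, np.ndarray]:
    """Partition phenotype values by genotype code at one marker.

    ``phenotypes`` uses the on-disk layout (columns ``individual`` and
    ``fuzz_pct``).  Individuals with a missing genotype or missing phenotype
    are excluded (count logged).  Raises when the marker is absent or no
    individual matches.
    """
    codes = gm.column(marker_id)
    pheno = phenotypes.set_index("individual")["fuzz_pct"]
    shared = [i for i in codes.index if i in pheno.index]
    n_all = len(set(codes.index) | set(pheno.index))
    groups: dict[str, list[float]] = {g: [] for g in GROUPS}
    n_used = 0
    for ind in shared:
        code = codes[ind]
        value = pheno[ind]
        if isinstance(code, float) and math.isnan(code):
            continue
        if value is None or (isinstance(value, float) and math.isnan(value)):
            continue
        groups[_CODE_TO_GROUP[float(code)]].append(float(value))
        n_used += 1
    if n_used == 0:
        raise InvalidInputError(
            f"no individual has both genotype and phenotype at marker {marker_id!r}"
        )
    if n_used < n_all:
        log.info(
            "marker %s: %d individuals excluded (missing genotype/phenotype)",
            marker_id,
            n_all - n_used,
        )
    return {g: np.asarray(v, dtype=float) for g, v in groups.items()}


def _two_sample_t(
    a: np.ndarray, b: np.ndarray, equal_var: bool
) -> tuple[float, float]:
    """Two-sided two-sample t (pooled variance unless Welch requested)."""
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate: both groups constant
        if a[0] == b[0]:
            return 0.0, 1.0
        return math.copysign(math.inf, a[0] - b[0]), 0.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def marker_trait_test(
    groups: Mapping[str, np.ndarray],
    marker_id: str = "",
    min_group_size: int = 3,
    equal_var: bool = True,
) -> AssociationResult:
    """Run the three pairwise contrasts on a genotype-grouped phenotype.

    A contrast with either group below ``min_group_size`` is marked
    untestable rather than raising.
    """
    means = {
        g: (float(np.mean(v)) if len(v) else float("nan")) for g, v in groups.items()
    }
    sizes = {g: int(len(v)) for g, v in groups.items()}
    contrasts: dict[str, Contrast] = {}
    for name in CONTRASTS:
        ga, gb = _CONTRAST_GROUPS[name]
        a, b = groups[ga], groups[gb]
        if len(a) < min_group_size or len(b) < min_group_size:
            contrasts[name] = Contrast(
                t=float("nan"),
                p_value=float("nan"),
                n_a=len(a),
                n_b=len(b),
                testable=False,
                reason=f"group below min size {min_group_size}",
            )
            continue
        t, p = _two_sample_t(a, b, equal_var=equal_var)
        contrasts[name] = Contrast(t=t, p_value=p, n_a=len(a), n_b=len(b), testable=True)
    return AssociationResult(
        marker_id=marker_id,
        group_means=means,
        group_sizes=sizes,
        contrasts=contrasts,
        n_used=sum(sizes.values()),
        n_excluded=0,
    )


def classify_locus_effect(res: AssociationResult, alpha: float = 0.05) -> str:
    """Classify the locus from the contrast pattern (see module docstring).

    Requires the homozygote-vs-homozygote contrast to be testable; otherwise
    returns ``none``.  The call is stored on ``res.effect_call`` and returned.
    """
    if not 0 < alpha < 1:
        raise InvalidInputError(f"alpha must lie in (0, 1), got {alpha!r}")
    dd = res.contrasts["donor_vs_recurrent"]
    call = "none"
    if dd.testable and dd.significant(alpha):
        m_d = res.group_means["donor_hom"]
        m_h = res.group_means["het"]
        m_r = res.group_means["recurrent_hom"]
        hd = res.contrasts["het_vs_donor"]
        hr = res.contrasts["het_vs_recurrent"]
        between = (
            not math.isnan(m_h)
            and min(m_d, m_r) < m_h < max(m_d, m_r)
        )
        if between and hd.significant(alpha) and hr.significant(alpha):
            call = "additive_major"
        elif m_d > m_r:
            call = "enhancer"
        else:
            call = "suppressor"
    res.effect_call = call
    return call


def associate(
    gm: GenotypeMatrix,
    marker_ids: Sequence[str],
    phenotypes: pd.DataFrame,
    alpha: float = 0.05,
    min_group_size: int = 3,
    equal_var: bool = True,
    bonferroni: bool = False,
) -> list[AssociationResult]:
    """Group, test and classify each marker in ``marker_ids``."""
    if not marker_ids:
        raise InvalidInputError("marker_ids must be non-empty")
    level = alpha / len(marker_ids) if bonferroni else alpha
    results = []
    for mid in marker_ids:
        groups = group_phenotype_by_genotype(gm, mid, phenotypes)
        res = marker_trait_test(
            groups, marker_id=mid, min_group_size=min_group_size, equal_var=equal_var
        )
        classify_locus_effect(res, alpha=level)
        results.append(res)
    return results


def association_table(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Flatten association results into one row per marker."""
    rows = []
    for r in results:
        row: dict[str, object] = {"marker": r.marker_id}
        for g in GROUPS:
            row[f"mean_{g}"] = r.group_means[g]
            row[f"n_{g}"] = r.group_sizes[g]
        for c in CONTRASTS:
            row[f"t_{c}"] = r.contrasts[c].t
            row[f"p_{c}"] = r.contrasts[c].p_value
        row["effect_call"] = r.effect_call
        rows.append(row)
    return pd.DataFrame(rows)
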