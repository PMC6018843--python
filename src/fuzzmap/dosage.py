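"""Homoeolog expression bookkeeping and the two-threshold dosage classifier.

In an allotetraploid, a regulator gene exists as two homoeologous copies (At
and Dt subgenome).  When only the Dt copy and the total can be assayed, the
At level is obtained by subtraction.  The dosage model classifies a genotype
from two expression readings:

* if total expression at ~0 dpa (lint initiation) falls below *threshold 2*,
  no lint initiates -> **fibreless**;
* otherwise, if Dt-homoeolog expression at ~3 dpa (fuzz initiation) falls
  below *threshold 1*, fuzz fails -> **fuzzless_linted**;
* otherwise both fibre types develop -> **fuzzy_linted**.

The fourth logical combination (lint absent but fuzz present) is
unreachable by construction: no lintless-but-fuzzy mutant has ever been
reported, and the classifier's decision order encodes that epistasis.
Threshold values are biological unknowns and therefore user parameters; only
the qualitative mapping is fixed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "PHENOTYPE_CLASSES",
    "DosageThresholds",
    "ExpressionProfile",
    "at_by_subtraction",
    "homoeolog_proportions",
    "dosage_classify",
    "ct_to_relative",
    "summarize_replicates",
    "classify_expression_table",
]

log = logging.getLogger(__name__)

#: Ordered from least to most fibre along both expression axes.
PHENOTYPE_CLASSES = ("fibreless", "fuzzless_linted", "fuzzy_linted")


@dataclass(frozen=True)
class DosageThresholds:
    """The two expression gates of the dosage model.

    ``threshold1`` gates fuzz (Dt homoeolog at ~3 dpa); ``threshold2`` gates
    lint (total expression at ~0 dpa).  Units are whatever relative-quantity
    scale the expression table uses; both must be > 0.
    """

    threshold1: float
    threshold2: float

    def __post_init__(self) -> None:
        if not (self.threshold1 > 0 and self.threshold2 > 0):
            raise InvalidInputError(
                f"thresholds must be > 0, got threshold1={self.threshold1!r}, "
                f"threshold2={self.threshold2!r}"
            )


@dataclass(frozen=True)
class ExpressionProfile:
    """Relative expression of a gene and its Dt homoeolog over a dpa course."""

    genotype_label: str
    timepoints: tuple[float, ...]
    total: tuple[float, ...]
    dt: tuple[float, ...]
    tolerance: float = 0.05

    def __post_init__(self) -> None:
        tp = np.asarray(self.timepoints, dtype=float)
        tot = np.asarray(self.total, dtype=float)
        dt = np.asarray(self.dt, dtype=float)
        if not (len(tp) == len(tot) == len(dt)):
            raise InvalidInputError("timepoints, total and dt differ in length")
        if len(tp) and (np.diff(tp) <= 0).any():
            raise InvalidInputError(
                f"timepoints must be strictly increasing for {self.genotype_label!r}"
            )
        if (tot < 0).any() or (dt < 0).any():
            raise InvalidInputError("expression levels must be >= 0")
        excess = dt > tot * (1 + self.tolerance)
        if excess.any():
            i = int(np.argmax(excess))
            raise InvalidInputError(
                f"Dt expression ({dt[i]!r}) exceeds total ({tot[i]!r}) beyond "
                f"tolerance at {tp[i]} dpa for {self.genotype_label!r}"
            )


def at_by_subtraction(total: float, dt: float, tolerance: float = 0.05) -> float:
    """At-homoeolog expression as total minus Dt.

    Measurement noise may push Dt slightly above the total; an excess of at
    most ``tolerance * total`` is clamped to 0 with a warning, anything larger
    is an inconsistent-measurement error.
    """
    if not (math.isfinite(total) and math.isfinite(dt)) or total < 0 or dt < 0:
        raise InvalidInputError(
            f"expression levels must be finite and >= 0, got total={total!r}, "
            f"dt={dt!r}"
        )
    if dt <= total:
        return total - dt
    if dt <= total * (1 + tolerance):
        log.warning(
            "Dt expression %r slightly exceeds total %r; At clamped to 0", dt, total
        )
        return 0.0
    raise InvalidInputError(
        f"inconsistent measurement: dt ({dt!r}) exceeds total ({total!r}) by more "
        f"than {tolerance:.0%}"
    )


def homoeolog_proportions(profile: ExpressionProfile) -> pd.DataFrame:
    """Per-timepoint At and Dt shares of total expression (sum to 1).

    Timepoints with zero total are reported with undefined (NaN) shares.
    """
    tot = np.asarray(profile.total, dtype=float)
    dt = np.asarray(profile.dt, dtype=float)
    at = np.array(
        [at_by_subtraction(t, d, profile.tolerance) for t, d in zip(tot, dt)]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        at_share = np.where(tot > 0, at / np.where(tot > 0, tot, 1), np.nan)
        dt_share = np.where(tot > 0, 1.0 - at / np.where(tot > 0, tot, 1), np.nan)
    return pd.DataFrame(
        {
            "dpa": list(profile.timepoints),
            "at_share": at_share,
            "dt_share": dt_share,
        }
    )


def dosage_classify(
    total_at_0dpa: float, dt_at_3dpa: float, th: DosageThresholds
) -> str:
    """Classify a genotype's seed-fibre phenotype from the two gates.

    ``total_at_0dpa < threshold2`` -> fibreless; else ``dt_at_3dpa <
    threshold1`` -> fuzzless_linted; else fuzzy_linted.  The
    lintless-but-fuzzy combination cannot be emitted.
    """
    for name, value in (("total_at_0dpa", total_at_0dpa), ("dt_at_3dpa", dt_at_3dpa)):
        if not math.isfinite(value) or value < 0:
            raise InvalidInputError(f"{name} must be finite and >= 0, got {value!r}")
    if total_at_0dpa < th.threshold2:
        return "fibreless"
    if dt_at_3dpa < th.threshold1:
        return "fuzzless_linted"
    return "fuzzy_linted"


def ct_to_relative(ct_target: float, ct_reference: float) -> float:
    """Relative quantity from cycle thresholds, 2^(Ct_ref - Ct_target).

    Assumes perfect doubling per cycle; no per-primer efficiency correction
    is applied.
    """
    return 2.0 ** (ct_reference - ct_target)


def summarize_replicates(expr: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of replicate rows per (genotype, dpa).

    ``expr`` uses the on-disk layout: columns ``genotype``, ``dpa``,
    ``total``, ``dt``, one row per replicate.
    """
    for col in ("genotype", "dpa", "total", "dt"):
        if col not in expr.columns:
            raise InvalidInputError(f"expression table lacks column {col!r}")
    grouped = expr.groupby(["genotype", "dpa"], sort=True)
    out = grouped.agg(
        total_mean=("total", "mean"),
        total_sem=("total", "sem"),
        dt_mean=("dt", "mean"),
        dt_sem=("dt", "sem"),
        n=("total", "size"),
    ).reset_index()
    return out


def classify_expression_table(
    expr: pd.DataFrame,
    th: DosageThresholds,
    lint_dpa: float = 0.0,
    fuzz_dpa: float = 3.0,
) -> pd.DataFrame:
    """Apply the dosage classifier to every genotype in an expression table.

    For each genotype the replicate-mean total at the timepoint nearest
    ``lint_dpa`` and the replicate-mean Dt at the timepoint nearest
    ``fuzz_dpa`` feed :func:`dosage_classify`.
    """
    summary = summarize_replicates(expr)
    rows = []
    for genotype, sub in summary.groupby("genotype", sort=True):
        i_lint = (sub["dpa"] - lint_dpa).abs().idxmin()
        i_fuzz = (sub["dpa"] - fuzz_dpa).abs().idxmin()
        total0 = float(sub.loc[i_lint, "total_mean"])
        dt3 = float(sub.loc[i_fuzz, "dt_mean"])
        rows.append(
            {
                "genotype": genotype,
                "total_at_lint_dpa": total0,
                "dt_at_fuzz_dpa": dt3,
                "lint_dpa_used": float(sub.loc[i_lint, "dpa"]),
                "fuzz_dpa_used": float(sub.loc[i_fuzz, "dpa"]),
                "phenotype_class": dosage_classify(total0, dt3, th),
            }
        )
    return pd.DataFrame(rows)
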