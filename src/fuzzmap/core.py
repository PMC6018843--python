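"""Core domain types: marker maps, parental-origin genotype codes, and the
seed-fuzz phenotype.

Cotton seeds carry two fibre types: lint (long, spinnable, initiating at
~0 days post-anthesis) and fuzz (short, initiating at ~3-4 dpa).  The
quantitative fuzz phenotype used throughout this package is the *fuzz
percentage*,

    100 * (ginned seed weight - delinted seed weight) / ginned seed weight,

i.e. the weight fraction of the ginned seed removed by acid delinting.
Normal-fuzz upland cultivars sit around 10-12 %, fuzzless material near zero.

Genotypes are coded by parental origin relative to the donor (fuzzless)
parent: donor homozygote = 1, heterozygote = 0.5, recurrent homozygote = 0,
missing = NaN.  The mean of these codes over a pool of individuals is the
donor-allele frequency of that pool, which is the quantity the bulk-segregant
scan operates on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, ParseError

__all__ = [
    "MISSING",
    "VALID_CODES",
    "FUZZ_CLASSES",
    "FuzzClassCutoffs",
    "DEFAULT_CUTOFFS",
    "MarkerMap",
    "GenotypeMatrix",
    "PhenotypeRecord",
    "fuzz_percentage",
    "encode_genotype",
    "decode_genotype",
    "classify_fuzz",
    "tabulate_classes",
    "phenotype_frame",
]

#: Marker value used for a missing genotype call.
MISSING = float("nan")

#: The three valid parental-origin codes.
VALID_CODES = (0.0, 0.5, 1.0)

#: Fuzz classes ordered from least to most fuzz.
FUZZ_CLASSES = ("fuzzless", "intermediate", "normal")

_CALL_TO_CODE = {"AA": 1.0, "AB": 0.5, "BA": 0.5, "BB": 0.0}
_MISSING_TOKENS = {"NA", "N/A", "", ".", "NN", "--"}
_CODE_TO_CALL = {1.0: "AA", 0.5: "AB", 0.0: "BB"}


def fuzz_percentage(ginned_weight: float, delinted_weight: float) -> float:
    """Fuzz percentage of a seed sample.

    Parameters
    ----------
    ginned_weight
        Weight of the ginned (lint removed, fuzz intact) seeds; must be > 0.
    delinted_weight
        Weight of the same seeds after acid delinting; 0 <= delinted <= ginned.

    Returns
    -------
    float
        ``100 * (ginned - delinted) / ginned``, in [0, 100].
    """
    if not math.isfinite(ginned_weight) or ginned_weight <= 0:
        raise InvalidInputError(
            f"ginned_weight must be positive and finite, got {ginned_weight!r}"
        )
    if not math.isfinite(delinted_weight) or delinted_weight < 0:
        raise InvalidInputError(
            f"delinted_weight must be non-negative and finite, got {delinted_weight!r}"
        )
    if delinted_weight > ginned_weight:
        raise InvalidInputError(
            f"delinted_weight ({delinted_weight!r}) exceeds ginned_weight "
            f"({ginned_weight!r})"
        )
    return 100.0 * (ginned_weight - delinted_weight) / ginned_weight


def encode_genotype(
    call: str, *, marker: str | None = None, individual: str | None = None
) -> float:
    """Map a parental-origin call to its numeric code.

    ``AA`` (donor/donor) -> 1, ``AB`` (heterozygous) -> 0.5, ``BB``
    (recurrent/recurrent) -> 0, ``NA`` -> NaN.  A is the donor-parent allele.
    Unknown tokens raise :class:`ParseError` with marker/individual context.
    """
    token = str(call).strip().upper()
    if token in _MISSING_TOKENS:
        return MISSING
    try:
        return _CALL_TO_CODE[token]
    except KeyError:
        ctx = ""
        if marker is not None or individual is not None:
            ctx = f" (marker={marker!r}, individual={individual!r})"
        raise ParseError(f"unrecognized genotype call {call!r}{ctx}") from None


def decode_genotype(code: float) -> str:
    """Inverse of :func:`encode_genotype` on the three valid codes (NaN -> NA)."""
    if isinstance(code, float) and math.isnan(code):
        return "NA"
    try:
        return _CODE_TO_CALL[float(code)]
    except (KeyError, TypeError, ValueError):
        raise InvalidInputError(f"invalid genotype code {code!r}") from None


@dataclass(frozen=True)
class FuzzClassCutoffs:
    """Fuzz-percentage cut-offs separating the three visual classes.

    ``fp < fuzzless_below`` -> fuzzless; ``fp < intermediate_below`` ->
    intermediate; otherwise normal.  The boundaries are configuration, not
    biology: visual scoring has no published quantitative boundary, so the
    defaults are anchored loosely to the ~2.7 % mean of fuzzless-type
    accessions against the 10-12 % of normal-fuzz cultivars.
    """

    fuzzless_below: float = 1.5
    intermediate_below: float = 6.0

    def __post_init__(self) -> None:
        if not self.fuzzless_below < self.intermediate_below:
            raise InvalidInputError(
                f"cutoffs must satisfy fuzzless_below < intermediate_below, got "
                f"{self.fuzzless_below!r} >= {self.intermediate_below!r}"
            )


DEFAULT_CUTOFFS = FuzzClassCutoffs()


def classify_fuzz(fp: float, cutoffs: FuzzClassCutoffs = DEFAULT_CUTOFFS) -> str:
    """Assign a fuzz class to a fuzz percentage using the configured cut-offs."""
    if not math.isfinite(fp) or fp < 0 or fp > 100:
        raise InvalidInputError(f"fuzz percentage must lie in [0, 100], got {fp!r}")
    if fp < cutoffs.fuzzless_below:
        return "fuzzless"
    if fp < cutoffs.intermediate_below:
        return "intermediate"
    return "normal"


def tabulate_classes(labels: Iterable[str]) -> pd.DataFrame:
    """Count class labels and express each count as a percentage of the total.

    Returns a frame indexed by label with columns ``n`` and ``pct`` (full
    precision; round to 2 decimals for reporting).  Mirrors the
    genotype-class tabulations used when partitioning an F2 by homoeoallele
    combination.
    """
    counts = pd.Series(list(labels), dtype=object).value_counts().sort_index()
    total = int(counts.sum())
    if total == 0:
        raise InvalidInputError("cannot tabulate an empty label list")
    out = pd.DataFrame({"n": counts.astype(int)})
    out["pct"] = 100.0 * out["n"] / total
    out.index.name = "class"
    return out


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker catalogue: id, chromosome label, 1-based position."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = ["marker", "chrom", "pos"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise InvalidInputError(f"marker table lacks column(s) {missing}")
        tab = self.table.reset_index(drop=True)
        if (tab["pos"] <= 0).any():
            bad = tab.loc[tab["pos"] <= 0, "marker"].iloc[0]
            raise InvalidInputError(f"marker {bad!r} has non-positive position")
        if tab.duplicated(subset=["chrom", "pos"]).any():
            dup = tab.loc[tab.duplicated(subset=["chrom", "pos"]), "marker"].iloc[0]
            raise InvalidInputError(f"duplicate (chrom, pos) at marker {dup!r}")
        if tab["marker"].duplicated().any():
            dup = tab.loc[tab["marker"].duplicated(), "marker"].iloc[0]
            raise InvalidInputError(f"duplicate marker id {dup!r}")
        object.__setattr__(self, "table", tab)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.table["marker"])

    def __len__(self) -> int:
        return len(self.table)

    def sort(self) -> "MarkerMap":
        """Return a copy sorted by (chromosome, position)."""
        return MarkerMap(
            self.table.sort_values(["chrom", "pos"], kind="stable").reset_index(
                drop=True
            )
        )

    def for_chromosome(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom].reset_index(drop=True)


@dataclass
class GenotypeMatrix:
    """Individuals x markers matrix of parental-origin codes.

    ``codes`` is indexed by individual id with one column per marker id, in
    the order of ``markers``.  Values are restricted to {0, 0.5, 1, NaN}.
    """

    markers: MarkerMap
    codes: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if list(self.codes.columns) != self.markers.marker_ids:
            raise InvalidInputError(
                "genotype matrix columns do not match the marker map "
                f"({len(self.codes.columns)} columns vs {len(self.markers)} markers)"
            )
        values = self.codes.to_numpy(dtype=float)
        ok = np.isnan(values)
        for code in VALID_CODES:
            ok |= values == code
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise InvalidInputError(
                f"invalid genotype code {values[i, j]!r} for individual "
                f"{self.codes.index[i]!r} at marker {self.codes.columns[j]!r}"
            )

    @property
    def individuals(self) -> list[str]:
        return list(self.codes.index)

    def column(self, marker_id: str) -> pd.Series:
        if marker_id not in self.codes.columns:
            raise InvalidInputError(f"marker {marker_id!r} not in genotype matrix")
        return self.codes[marker_id]


@dataclass(frozen=True)
class PhenotypeRecord:
    """Per-individual seed-fibre phenotype."""

    individual_id: str
    fuzz_percentage: float
    fuzz_class: str
    lint_percentage: float = MISSING
    tufted: bool | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.fuzz_percentage) or not (
            0 <= self.fuzz_percentage <= 100
        ):
            raise InvalidInputError(
                f"fuzz_percentage for {self.individual_id!r} must lie in "
                f"[0, 100], got {self.fuzz_percentage!r}"
            )
        if self.fuzz_class not in FUZZ_CLASSES:
            raise InvalidInputError(
                f"unknown fuzz_class {self.fuzz_class!r} for {self.individual_id!r}"
            )


def phenotype_frame(records: Sequence[PhenotypeRecord]) -> pd.DataFrame:
    """Tabulate phenotype records in the on-disk column layout."""
    return pd.DataFrame(
        {
            "individual": [r.individual_id for r in records],
            "fuzz_pct": [r.fuzz_percentage for r in records],
            "lint_pct": [r.lint_percentage for r in records],
            "fuzz_class": [r.fuzz_class for r in records],
            "tufted": [r.tufted for r in records],
        }
    )
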