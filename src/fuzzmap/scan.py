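"""Pooled-variant filtering, sliding-window donor-allele frequency, and
dual-pool candidate-region calling — the bulk-segregant mapping engine.

The scan consumes per-marker donor-allele frequencies of two pools:

* a *recessive* pool of fixed mutant-phenotype individuals, where a causal
  locus is expected to sit at donor frequency 1 (or close to 1), and
* a *segregating* pool drawn from progeny of a heterozygous parent, where
  the same locus is expected near 0.5.

Frequencies are smoothed in overlapping physical windows (defaults 1 Mbp
window, 500 kb step) and a window qualifies as candidate evidence when the
recessive-pool frequency exceeds a high threshold while the segregating-pool
frequency stays inside a band around 0.5; runs of consecutive qualifying
windows are merged into candidate regions.  The segregating-band requirement
is what discards loci merely fixed for donor alleles by inbreeding drift
(fixation gives ~0 or ~1 in the segregating pool, never ~0.5).

An analogous single-sided caller handles array-genotyped pools (a
reduced-phenotype pool near 1 and a normal pool below 0.5).

Coordinates: marker positions are 1-based on input (as in VCF); window and
region intervals are 0-based half-open (as in BED).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import GridMismatchError, InvalidInputError

__all__ = [
    "VariantFilterConfig",
    "FilterReport",
    "WindowConfig",
    "WindowTrack",
    "CandidateRegion",
    "filter_pooled_variants",
    "pool_frequency_from_genotypes",
    "pool_frequency_from_reads",
    "sliding_window_frequency",
    "call_candidate_regions",
    "call_array_candidates",
    "intersect_region_sets",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariantFilterConfig:
    """Thresholds applied to pooled variant counts before scanning.

    Defaults reproduce a conventional short-read basic-variant-detection
    setting: coverage >= 10, variant reads >= 3, variant frequency >= 35 %.
    """

    min_coverage: int = 10
    min_variant_reads: int = 3
    min_variant_frequency: float = 0.35

    def __post_init__(self) -> None:
        if self.min_coverage < 0 or self.min_variant_reads < 0:
            raise InvalidInputError("filter count thresholds must be >= 0")
        if not 0.0 <= self.min_variant_frequency <= 1.0:
            raise InvalidInputError(
                f"min_variant_frequency must lie in [0, 1], got "
                f"{self.min_variant_frequency!r}"
            )


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping of a filtering pass (per-criterion failures overlap)."""

    n_input: int
    n_retained: int
    n_fail_coverage: int
    n_fail_variant_reads: int
    n_fail_frequency: int


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{what} lacks column(s) {missing}")


def filter_pooled_variants(
    counts: pd.DataFrame, cfg: VariantFilterConfig = VariantFilterConfig()
) -> tuple[pd.DataFrame, FilterReport]:
    """Retain markers meeting coverage, variant-read and frequency thresholds.

    ``counts`` needs columns ``donor_reads`` and ``total_reads``.  A marker is
    retained iff total_reads >= min_coverage AND donor_reads >=
    min_variant_reads AND donor_reads/total_reads >= min_variant_frequency.
    Returns the retained subset and a :class:`FilterReport`.
    """
    _require_columns(counts, ["donor_reads", "total_reads"], "pooled counts")
    donor = counts["donor_reads"].to_numpy(dtype=float)
    total = counts["total_reads"].to_numpy(dtype=float)
    if (donor < 0).any() or (total < 0).any() or (donor > total).any():
        raise InvalidInputError("pooled counts must satisfy 0 <= donor <= total")
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(total > 0, donor / np.maximum(total, 1), 0.0)
    ok_cov = total >= cfg.min_coverage
    ok_reads = donor >= cfg.min_variant_reads
    ok_freq = freq >= cfg.min_variant_frequency
    keep = ok_cov & ok_reads & ok_freq
    report = FilterReport(
        n_input=len(counts),
        n_retained=int(keep.sum()),
        n_fail_coverage=int((~ok_cov).sum()),
        n_fail_variant_reads=int((~ok_reads).sum()),
        n_fail_frequency=int((~ok_freq).sum()),
    )
    return counts.loc[keep].reset_index(drop=True), report


def pool_frequency_from_genotypes(codes: Iterable[float]) -> float:
    """Donor-allele frequency of a pool as the mean of its genotype codes.

    Missing codes (NaN) are excluded; a marker with no non-missing codes gets
    an undefined (NaN) frequency and a logged warning, and is dropped
    downstream.
    """
    arr = np.asarray(list(codes), dtype=float)
    if arr.size == 0 or np.isnan(arr).all():
        log.warning("pool frequency undefined: all genotype codes missing")
        return float("nan")
    return float(np.nanmean(arr))


def pool_frequency_from_reads(donor_reads: int, total_reads: int) -> float:
    """Donor-allele frequency of a sequenced pool, donor_reads / total_reads."""
    if donor_reads < 0 or total_reads < 0 or donor_reads > total_reads:
        raise InvalidInputError(
            f"read counts must satisfy 0 <= donor ({donor_reads}) <= total "
            f"({total_reads})"
        )
    if total_reads == 0:
        log.warning("pool frequency undefined: zero coverage")
        return float("nan")
    return donor_reads / total_reads


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry: 1 Mbp windows advancing by 500 kb by default."""

    window_length: int = 1_000_000
    step: int = 500_000
    min_snps_per_window: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.step <= self.window_length:
            raise InvalidInputError(
                f"require 0 < step <= window_length, got step={self.step}, "
                f"window_length={self.window_length}"
            )
        if self.min_snps_per_window < 1:
            raise InvalidInputError("min_snps_per_window must be >= 1")


@dataclass(frozen=True)
class WindowTrack:
    """Windowed mean donor-allele frequency along one chromosome.

    ``data`` has columns ``start``, ``end`` (0-based half-open, end clipped to
    the chromosome), ``freq`` (NaN when fewer than ``min_snps_per_window``
    markers fall in the window) and ``n_snps``.
    """

    chromosome: str
    window_length: int
    step: int
    data: pd.DataFrame = field(repr=False)

    @property
    def starts(self) -> np.ndarray:
        return self.data["start"].to_numpy()

    def same_grid(self, other: "WindowTrack") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.window_length == other.window_length
            and self.step == other.step
            and len(self.data) == len(other.data)
            and bool(np.array_equal(self.starts, other.starts))
        )


def sliding_window_frequency(
    positions: Sequence[int],
    frequencies: Sequence[float],
    chrom_length: int,
    cfg: WindowConfig = WindowConfig(),
    chromosome: str = "chr",
    marker_ids: Sequence[str] | None = None,
) -> WindowTrack:
    """Average per-marker donor frequencies in overlapping physical windows.

    Windows are anchored at 0 and advance by ``cfg.step``; every start in
    [0, chrom_length) is emitted, including the trailing partial window.  A
    marker at 1-based position p belongs to window [start, start+window)
    (0-based half-open) iff start <= p-1 < start+window.  Markers with an
    undefined (NaN) frequency are ignored.  The result is independent of the
    input marker order.
    """
    pos = np.asarray(positions, dtype=np.int64)
    freq = np.asarray(frequencies, dtype=float)
    if pos.shape != freq.shape:
        raise InvalidInputError("positions and frequencies differ in length")
    if chrom_length <= 0:
        raise InvalidInputError(f"chrom_length must be > 0, got {chrom_length}")
    out_of_range = (pos < 1) | (pos > chrom_length)
    if out_of_range.any():
        i = int(np.argmax(out_of_range))
        name = marker_ids[i] if marker_ids is not None else f"#{i}"
        raise InvalidInputError(
            f"marker {name} at position {pos[i]} lies outside [1, {chrom_length}] "
            f"on {chromosome}"
        )
    defined = ~np.isnan(freq)
    pos0 = pos[defined] - 1
    fdef = freq[defined]
    order = np.argsort(pos0, kind="stable")
    pos0, fdef = pos0[order], fdef[order]
    prefix = np.concatenate([[0.0], np.cumsum(fdef)])

    starts = np.arange(0, chrom_length, cfg.step, dtype=np.int64)
    ends = np.minimum(starts + cfg.window_length, chrom_length)
    lo = np.searchsorted(pos0, starts, side="left")
    hi = np.searchsorted(pos0, starts + cfg.window_length, side="left")
    n = (hi - lo).astype(np.int64)
    sums = prefix[hi] - prefix[lo]
    with np.errstate(invalid="ignore"):
        mean = np.where(n >= cfg.min_snps_per_window, sums / np.maximum(n, 1), np.nan)
    data = pd.DataFrame({"start": starts, "end": ends, "freq": mean, "n_snps": n})
    return WindowTrack(
        chromosome=chromosome,
        window_length=cfg.window_length,
        step=cfg.step,
        data=data,
    )


@dataclass(frozen=True)
class CandidateRegion:
    """Merged run of qualifying windows (0-based half-open interval)."""

    chromosome: str
    start: int
    end: int
    mean_freq: tuple[float, ...]
    n_windows: int
    evidence: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise InvalidInputError(
                f"region start ({self.start}) must be < end ({self.end})"
            )

    def overlaps(self, chrom: str, pos0: int) -> bool:
        """True when a 0-based point falls inside the region."""
        return self.chromosome == chrom and self.start <= pos0 < self.end


def _regions_from_mask(
    qualifying: np.ndarray,
    tracks: Sequence[WindowTrack],
    min_consecutive: int,
    evidence: str,
) -> list[CandidateRegion]:
    """Merge runs of >= min_consecutive consecutive qualifying windows."""
    ref = tracks[0]
    starts = ref.data["start"].to_numpy()
    ends = ref.data["end"].to_numpy()
    regions: list[CandidateRegion] = []
    i, m = 0, len(qualifying)
    while i < m:
        if not qualifying[i]:
            i += 1
            continue
        j = i
        while j + 1 < m and qualifying[j + 1]:
            j += 1
        if j - i + 1 >= min_consecutive:
            means = tuple(
                float(np.nanmean(t.data["freq"].to_numpy()[i : j + 1])) for t in tracks
            )
            regions.append(
                CandidateRegion(
                    chromosome=ref.chromosome,
                    start=int(starts[i]),
                    end=int(ends[j]),
                    mean_freq=means,
                    n_windows=j - i + 1,
                    evidence=evidence,
                )
            )
        i = j + 1
    return regions


def _check_grids(a: WindowTrack, b: WindowTrack) -> None:
    if not a.same_grid(b):
        raise GridMismatchError(
            f"window tracks do not share a grid: {a.chromosome} "
            f"({len(a.data)} windows) vs {b.chromosome} ({len(b.data)} windows)"
        )


def call_candidate_regions(
    recessive_track: WindowTrack,
    segregating_track: WindowTrack,
    high_threshold: float = 0.9,
    segregating_band: tuple[float, float] = (0.35, 0.65),
    min_consecutive: int = 2,
    evidence: str = "MBS",
) -> list[CandidateRegion]:
    """Dual-bulk candidate calling from sequenced pools.

    A window qualifies iff the recessive-pool frequency is defined and >=
    ``high_threshold`` AND the segregating-pool frequency is defined and lies
    inside ``segregating_band``.  Runs of >= ``min_consecutive`` consecutive
    qualifying windows merge into one region; undefined windows break runs.
    Reported means are (recessive, segregating) over the merged windows.
    """
    _check_grids(recessive_track, segregating_track)
    lo, hi = segregating_band
    if not lo <= hi:
        raise InvalidInputError(f"segregating_band is empty: {segregating_band!r}")
    rec = recessive_track.data["freq"].to_numpy()
    seg = segregating_track.data["freq"].to_numpy()
    with np.errstate(invalid="ignore"):
        qual = (rec >= high_threshold) & (seg >= lo) & (seg <= hi)
    qual &= ~np.isnan(rec) & ~np.isnan(seg)
    return _regions_from_mask(
        qual, (recessive_track, segregating_track), min_consecutive, evidence
    )


def call_array_candidates(
    reduced_fuzz_track: WindowTrack,
    normal_fuzz_track: WindowTrack,
    high_threshold: float = 0.9,
    normal_max: float = 0.5,
    min_consecutive: int = 2,
    evidence: str = "array",
) -> list[CandidateRegion]:
    """Array-pool candidate calling: reduced-phenotype pool high, normal pool low.

    A window qualifies iff the reduced-pool frequency is defined and >=
    ``high_threshold`` AND the normal-pool frequency is defined and <
    ``normal_max``.  Merging as in :func:`call_candidate_regions`.
    """
    _check_grids(reduced_fuzz_track, normal_fuzz_track)
    red = reduced_fuzz_track.data["freq"].to_numpy()
    nor = normal_fuzz_track.data["freq"].to_numpy()
    with np.errstate(invalid="ignore"):
        qual = (red >= high_threshold) & (nor < normal_max)
    qual &= ~np.isnan(red) & ~np.isnan(nor)
    return _regions_from_mask(
        qual, (reduced_fuzz_track, normal_fuzz_track), min_consecutive, evidence
    )


def intersect_region_sets(
    a: Sequence[CandidateRegion], b: Sequence[CandidateRegion]
) -> list[CandidateRegion]:
    """Intersect two candidate sets; overlaps get evidence 'both'.

    Each overlapping pair contributes the interval intersection with evidence
    ``both`` (per-track means concatenated, window count the smaller of the
    two).  Regions overlapping nothing in the other set are retained
    unchanged.  Output sorted by (chromosome, start, end, evidence).
    """
    out: list[CandidateRegion] = []
    hit_a = [False] * len(a)
    hit_b = [False] * len(b)
    for i, ra in enumerate(a):
        for j, rb in enumerate(b):
            if ra.chromosome != rb.chromosome:
                continue
            start = max(ra.start, rb.start)
            end = min(ra.end, rb.end)
            if start < end:
                hit_a[i] = hit_b[j] = True
                out.append(
                    CandidateRegion(
                        chromosome=ra.chromosome,
                        start=start,
                        end=end,
                        mean_freq=ra.mean_freq + rb.mean_freq,
                        n_windows=min(ra.n_windows, rb.n_windows),
                        evidence="both",
                    )
                )
    out.extend(r for i, r in enumerate(a) if not hit_a[i])
    out.extend(r for j, r in enumerate(b) if not hit_b[j])
    out.sort(key=lambda r: (r.chromosome, r.start, r.end, r.evidence))
    return out
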