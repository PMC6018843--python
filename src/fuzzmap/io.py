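"""Readers and writers for the package's plain-text formats.

Conventions:

* genotype TSV — wide table, one row per marker: ``marker chrom pos <ind>...``
  with calls in {AA, AB, BB, NA}, A being the donor-parent allele;
* phenotype TSV — ``individual fuzz_pct lint_pct fuzz_class tufted``;
* variant input — either a TSV ``chrom pos donor_reads total_reads bulk`` or
  a VCF with per-sample allele depths (FORMAT/AD), one sample per bulk, the
  donor allele being ALT by default (variants called against the
  recurrent-parent reference);
* window tracks — bedGraph-style TSV ``chrom start end freq n_snps`` with
  0-based half-open intervals and ``NA`` for undefined frequencies;
* candidate regions — BED5 ``chrom start end name score`` (name = evidence
  label, score = window count), with a header comment.

All coordinate conversion between 1-based marker/VCF positions and the
0-based half-open interval convention happens in this module and nowhere
else.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, MarkerMap, decode_genotype, encode_genotype
from .errors import InvalidInputError, ParseError
from .scan import CandidateRegion, WindowTrack

__all__ = [
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_phenotype_tsv",
    "write_phenotype_tsv",
    "read_variants",
    "write_variants_tsv",
    "write_variants_vcf",
    "write_window_tracks",
    "read_window_tracks",
    "write_regions_bed",
    "read_regions_bed",
]

log = logging.getLogger(__name__)

_NA = "NA"


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    """Read a wide genotype TSV into a :class:`GenotypeMatrix`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("marker", "chrom", "pos"):
        if col not in df.columns:
            raise ParseError(f"{path}: genotype TSV lacks column {col!r}")
    individuals = [c for c in df.columns if c not in ("marker", "chrom", "pos")]
    markers = MarkerMap(
        pd.DataFrame(
            {
                "marker": df["marker"],
                "chrom": df["chrom"],
                "pos": df["pos"].astype(np.int64),
            }
        )
    )
    codes = np.empty((len(individuals), len(df)), dtype=float)
    for j, (_, row) in enumerate(df.iterrows()):
        for i, ind in enumerate(individuals):
            codes[i, j] = encode_genotype(
                row[ind], marker=row["marker"], individual=ind
            )
    matrix = pd.DataFrame(codes, index=individuals, columns=markers.marker_ids)
    return GenotypeMatrix(markers=markers, codes=matrix)


def write_genotype_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a :class:`GenotypeMatrix` in the wide TSV layout."""
    table = gm.markers.table
    out = {
        "marker": table["marker"],
        "chrom": table["chrom"],
        "pos": table["pos"],
    }
    for ind in gm.individuals:
        out[ind] = [decode_genotype(v) for v in gm.codes.loc[ind]]
    pd.DataFrame(out).to_csv(path, sep="\t", index=False)


def read_phenotype_tsv(path: str | Path) -> pd.DataFrame:
    """Read a phenotype TSV; NA allowed in every column but ``individual``."""
    df = pd.read_csv(path, sep="\t", na_values=[_NA], keep_default_na=False)
    for col in ("individual", "fuzz_pct"):
        if col not in df.columns:
            raise ParseError(f"{path}: phenotype TSV lacks column {col!r}")
    if df["individual"].isna().any():
        raise ParseError(f"{path}: phenotype TSV has a missing individual id")
    return df


def write_phenotype_tsv(phenotypes: pd.DataFrame, path: str | Path) -> None:
    phenotypes.to_csv(path, sep="\t", index=False, na_rep=_NA)


def _variant_frame(records: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(
        records,
        columns=["chrom", "pos", "donor_reads", "total_reads", "bulk", "is_indel"],
    )
    df["pos"] = df["pos"].astype(np.int64)
    df["donor_reads"] = df["donor_reads"].astype(np.int64)
    df["total_reads"] = df["total_reads"].astype(np.int64)
    df["is_indel"] = df["is_indel"].astype(bool)
    return df


def read_variants(
    path: str | Path,
    fmt: str | None = None,
    donor_allele: str = "alt",
    snps_only: bool = True,
) -> pd.DataFrame:
    """Read pooled variant counts from TSV or VCF.

    Returns one row per (marker, bulk): ``chrom pos donor_reads total_reads
    bulk is_indel``.  ``fmt`` is inferred from the extension when omitted.
    Indel records are flagged and, with ``snps_only`` (the default), dropped
    with a logged count before scanning.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() in (".vcf", ".gz", ".bcf") else "tsv"
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        for col in ("chrom", "pos", "donor_reads", "total_reads", "bulk"):
            if col not in df.columns:
                raise ParseError(f"{path}: variant TSV lacks column {col!r}")
        if "is_indel" not in df.columns:
            df["is_indel"] = False
        df = _variant_frame(df.to_dict("records"))
    elif fmt == "vcf":
        df = _read_variants_vcf(path, donor_allele=donor_allele)
    else:
        raise InvalidInputError(f"unknown variant format {fmt!r}")
    if (df["donor_reads"] > df["total_reads"]).any() or (df["donor_reads"] < 0).any():
        bad = df.loc[df["donor_reads"] > df["total_reads"]].iloc[0]
        raise ParseError(
            f"{path}: donor reads exceed coverage at {bad['chrom']}:{bad['pos']}"
        )
    if snps_only:
        n_indel = int(df["is_indel"].sum())
        if n_indel:
            log.info("dropping %d indel record(s); scanning SNPs only", n_indel)
        df = df.loc[~df["is_indel"]].reset_index(drop=True)
    return df


def _read_variants_vcf(path: Path, donor_allele: str = "alt") -> pd.DataFrame:
    from cyvcf2 import VCF

    if donor_allele not in ("ref", "alt"):
        raise InvalidInputError(f"donor_allele must be 'ref' or 'alt', got {donor_allele!r}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ParseError(f"{path}: VCF has no samples (one per bulk required)")
    records = []
    for variant in vcf:
        try:
            ad = variant.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            raise ParseError(
                f"{path}: record {variant.CHROM}:{variant.POS} has no AD "
                f"(allele depth) field"
            )
        is_indel = not variant.is_snp
        for s, sample in enumerate(samples):
            depths = np.asarray(ad[s], dtype=np.int64)
            depths = np.where(depths < 0, 0, depths)  # '.' decodes negative
            ref_d = int(depths[0])
            alt_d = int(depths[1:].sum()) if depths.size > 1 else 0
            donor = alt_d if donor_allele == "alt" else ref_d
            records.append(
                {
                    "chrom": variant.CHROM,
                    "pos": variant.POS,
                    "donor_reads": donor,
                    "total_reads": ref_d + alt_d,
                    "bulk": sample,
                    "is_indel": is_indel,
                }
            )
    return _variant_frame(records)


def write_variants_tsv(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "pos", "donor_reads", "total_reads", "bulk"]
    out = df.copy()
    if "bulk" not in out.columns:
        out["bulk"] = "pool"
    if "is_indel" in out.columns:
        cols = cols + ["is_indel"]
    out[cols].to_csv(path, sep="\t", index=False)


def write_variants_vcf(
    per_bulk: dict[str, pd.DataFrame],
    path: str | Path,
    chrom_lengths: dict[str, int] | None = None,
) -> None:
    """Write pooled counts as a minimal VCF, one sample per bulk.

    Counts-only emulation: REF/ALT are placeholder bases (recurrent allele =
    REF, donor allele = ALT) and AD carries (total-donor, donor) depths.
    Every bulk frame must share the same (chrom, pos) grid.
    """
    bulks = list(per_bulk)
    if not bulks:
        raise InvalidInputError("write_variants_vcf needs at least one bulk")
    first = per_bulk[bulks[0]][["chrom", "pos"]].reset_index(drop=True)
    for name, df in per_bulk.items():
        if not first.equals(df[["chrom", "pos"]].reset_index(drop=True)):
            raise InvalidInputError(
                f"bulk {name!r} does not share the marker grid of {bulks[0]!r}"
            )
    lines = ["##fileformat=VCFv4.2"]
    if chrom_lengths:
        for chrom, length in chrom_lengths.items():
            lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
    )
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header += bulks
    lines.append("\t".join(header))
    frames = [per_bulk[b].reset_index(drop=True) for b in bulks]
    for i in range(len(first)):
        row = [
            str(first.loc[i, "chrom"]),
            str(int(first.loc[i, "pos"])),
            ".",
            "A",
            "T",
            ".",
            "PASS",
            ".",
            "AD",
        ]
        for df in frames:
            total = int(df.loc[i, "total_reads"])
            donor = int(df.loc[i, "donor_reads"])
            row.append(f"{total - donor},{donor}")
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


_TRACK_HEADER = ["chrom", "start", "end", "freq", "n_snps"]


def write_window_tracks(tracks: Sequence[WindowTrack], path: str | Path) -> None:
    """Write one or more window tracks as a bedGraph-style TSV."""
    rows = []
    for track in tracks:
        for _, w in track.data.iterrows():
            freq = w["freq"]
            rows.append(
                (
                    track.chromosome,
                    int(w["start"]),
                    int(w["end"]),
                    _NA if (isinstance(freq, float) and math.isnan(freq)) else f"{freq:.6g}",
                    int(w["n_snps"]),
                )
            )
    pd.DataFrame(rows, columns=_TRACK_HEADER).to_csv(path, sep="\t", index=False)


def read_window_tracks(
    path: str | Path, window_length: int, step: int
) -> dict[str, WindowTrack]:
    """Read a window-track TSV back into per-chromosome tracks."""
    df = pd.read_csv(path, sep="\t", na_values=[_NA], keep_default_na=False)
    for col in _TRACK_HEADER:
        if col not in df.columns:
            raise ParseError(f"{path}: window track lacks column {col!r}")
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        out[str(chrom)] = WindowTrack(
            chromosome=str(chrom),
            window_length=window_length,
            step=step,
            data=sub[["start", "end", "freq", "n_snps"]].reset_index(drop=True),
        )
    return out


_BED_HEADER = "#chrom\tstart\tend\tname\tscore"


def write_regions_bed(regions: Sequence[CandidateRegion], path: str | Path) -> None:
    """Write candidate regions as BED5 (0-based half-open), sorted.

    Unsorted input is sorted with a warning; an empty set produces a file
    holding only the header comment.  write -> read -> write is byte-exact.
    """
    ordered = sorted(regions, key=lambda r: (r.chromosome, r.start, r.end, r.evidence))
    if list(ordered) != list(regions):
        log.warning("regions were not sorted; sorting before writing BED")
    lines = [_BED_HEADER]
    for r in ordered:
        lines.append(f"{r.chromosome}\t{r.start}\t{r.end}\t{r.evidence}\t{r.n_windows}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_regions_bed(path: str | Path) -> list[CandidateRegion]:
    """Read a BED5 written by :func:`write_regions_bed` (means are not stored)."""
    regions = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ParseError(f"{path}:{lineno}: expected 5 BED columns, got {len(parts)}")
        chrom, start, end, name, score = parts
        regions.append(
            CandidateRegion(
                chromosome=chrom,
                start=int(start),
                end=int(end),
                mean_freq=(),
                n_windows=int(score),
                evidence=name,
            )
        )
    return regions
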