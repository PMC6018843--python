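"""Run configuration and the end-to-end workflow orchestrator.

``run_pipeline`` replays the published mapping workflow on simulated data:

1. simulate an F2 for segregation-ratio testing and single-marker
   association at the planted loci;
2. simulate the backcross-derived NIL cohorts, draw the recessive and
   segregating sequencing bulks, and emulate pooled sequencing;
3. filter pooled variants, compute windowed donor-allele frequencies for
   both bulks, and call dual-bulk candidate regions (MBS evidence);
4. compute array-style windowed frequencies from the genotype codes of the
   reduced-fuzz and normal-fuzz NIL pools and call array candidates;
5. intersect both candidate sets and score recovery of the planted loci.

Every artifact is written to the run directory; the JSON summary is
deterministic given (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .association import associate, association_table
from .core import FuzzClassCutoffs
from .errors import ConfigError
from .io import (
    write_genotype_tsv,
    write_phenotype_tsv,
    write_regions_bed,
    write_variants_tsv,
    write_window_tracks,
)
from .scan import (
    CandidateRegion,
    VariantFilterConfig,
    WindowConfig,
    call_array_candidates,
    call_candidate_regions,
    filter_pooled_variants,
    intersect_region_sets,
    sliding_window_frequency,
)
from .segregation import results_table, select_model
from .simulate import (
    CausalLocus,
    CausalModel,
    MarkerGrid,
    PedigreeSpec,
    SimGenome,
    build_bulks,
    default_ps_model,
    simulate_nil_study,
    simulate_pool_counts,
    simulate_population,
)

__all__ = ["RunConfig", "run_pipeline", "scan_study", "score_recovery"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat key set of every stage default; validated before any stage runs."""

    seed: int = 7
    # genome
    n_chromosomes: int = 26
    chrom_length: int = 60_000_000
    marker_spacing: int = 250_000
    cm_per_mb: float = 1.0
    # causal model ({chromosome, position, role, effect} dicts; None -> default)
    loci: list[dict] | None = None
    baseline_fuzz: float = 11.0
    noise_sd: float = 1.5
    penetrance: float = 1.0
    # pedigrees
    f2_size: int = 169
    n_backcrosses: int = 4
    n_selfs: int = 4
    progeny_size: int = 60
    # bulks and sequencing
    bulk_recessive: int = 15
    bulk_segregating: int = 24
    depth: float = 30.0
    error_rate: float = 0.0
    # variant filter
    min_coverage: int = 10
    min_variant_reads: int = 3
    min_variant_frequency: float = 0.35
    # windows
    window_length: int = 1_000_000
    step: int = 500_000
    min_snps_per_window: int = 1
    # region calling
    high_threshold: float = 0.9
    seg_band_low: float = 0.35
    seg_band_high: float = 0.65
    normal_max: float = 0.5
    min_consecutive: int = 2
    # association / segregation
    alpha: float = 0.05
    min_group_size: int = 3
    k_range: tuple[int, ...] = (1, 2, 3, 4)
    # fuzz classes
    fuzzless_below: float = 1.5
    intermediate_below: float = 6.0

    def validate(self) -> None:
        try:
            self.window_config()
            self.filter_config()
            self.cutoffs()
            self.model()
            self.genome()
        except Exception as exc:  # surface every module constraint as ConfigError
            raise ConfigError(str(exc)) from exc
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha!r}")
        if not self.seg_band_low <= self.seg_band_high:
            raise ConfigError("seg_band_low must be <= seg_band_high")
        if self.bulk_recessive > self.progeny_size or self.bulk_segregating > self.progeny_size:
            raise ConfigError("bulk sizes cannot exceed progeny_size")
        if not self.k_range:
            raise ConfigError("k_range must be non-empty")

    # --- constructors for stage objects -------------------------------------
    def genome(self) -> SimGenome:
        return SimGenome.default(
            chrom_length=self.chrom_length,
            marker_spacing=self.marker_spacing,
            cm_per_mb=self.cm_per_mb,
            n_chromosomes=self.n_chromosomes,
        )

    def model(self) -> CausalModel:
        base = (
            default_ps_model()
            if self.loci is None
            else CausalModel(loci=tuple(CausalLocus(**d) for d in self.loci))
        )
        return dataclasses.replace(
            base,
            baseline_fuzz=self.baseline_fuzz,
            noise_sd=self.noise_sd,
            penetrance=self.penetrance,
            cutoffs=self.cutoffs(),
        )

    def cutoffs(self) -> FuzzClassCutoffs:
        return FuzzClassCutoffs(
            fuzzless_below=self.fuzzless_below,
            intermediate_below=self.intermediate_below,
        )

    def filter_config(self) -> VariantFilterConfig:
        return VariantFilterConfig(
            min_coverage=self.min_coverage,
            min_variant_reads=self.min_variant_reads,
            min_variant_frequency=self.min_variant_frequency,
        )

    def window_config(self) -> WindowConfig:
        return WindowConfig(
            window_length=self.window_length,
            step=self.step,
            min_snps_per_window=self.min_snps_per_window,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        return d


def _frequency_tracks(
    counts_by_bulk: dict[str, "np.ndarray"],
    grid: MarkerGrid,
    cfg: WindowConfig,
):
    """Per-chromosome window tracks per bulk from filtered read counts."""
    tracks: dict[str, dict[str, object]] = {b: {} for b in counts_by_bulk}
    for bulk, counts in counts_by_bulk.items():
        for chrom in grid.chrom_labels:
            sub = counts[counts["chrom"] == chrom]
            with np.errstate(invalid="ignore", divide="ignore"):
                freq = sub["donor_reads"].to_numpy(float) / np.maximum(
                    sub["total_reads"].to_numpy(float), 1
                )
            tracks[bulk][chrom] = sliding_window_frequency(
                sub["pos"].to_numpy(),
                freq,
                grid.chrom_lengths[chrom],
                cfg,
                chromosome=chrom,
                marker_ids=list(sub["marker"]) if "marker" in sub else None,
            )
    return tracks


def _genotype_tracks(population, grid: MarkerGrid, cfg: WindowConfig):
    """Array-style window tracks from pooled genotype codes of a cohort."""
    codes = population.genotypes.codes
    freqs = codes.mean(axis=0, skipna=True).to_numpy(dtype=float)
    table = grid.marker_map.table
    out = {}
    for chrom in grid.chrom_labels:
        mask = (table["chrom"] == chrom).to_numpy()
        out[chrom] = sliding_window_frequency(
            table.loc[mask, "pos"].to_numpy(),
            freqs[mask],
            grid.chrom_lengths[chrom],
            cfg,
            chromosome=chrom,
            marker_ids=list(table.loc[mask, "marker"]),
        )
    return out


def scan_study(
    study,
    cfg: RunConfig,
    rng: np.random.Generator,
) -> dict:
    """Bulks -> pooled counts -> filter -> windows -> candidate regions.

    Returns a dict with the bulk ids, filtered counts, window tracks and the
    MBS, array and intersected region lists for a simulated NIL study.
    """
    grid = study.grid
    wcfg = cfg.window_config()
    rec_ids = build_bulks(study.fuzzless, "recessive_bulk", cfg.bulk_recessive, rng)
    seg_ids = build_bulks(
        study.segregating, "segregating_bulk", cfg.bulk_segregating, rng
    )
    counts = {
        "RFB2": simulate_pool_counts(
            study.fuzzless.genotypes, rec_ids, cfg.depth, cfg.error_rate, rng
        ),
        "RFB1": simulate_pool_counts(
            study.segregating.genotypes, seg_ids, cfg.depth, cfg.error_rate, rng
        ),
    }
    filtered = {}
    reports = {}
    for bulk, df in counts.items():
        filtered[bulk], reports[bulk] = filter_pooled_variants(df, cfg.filter_config())
    read_tracks = _frequency_tracks(filtered, grid, wcfg)
    mbs_regions: list[CandidateRegion] = []
    for chrom in grid.chrom_labels:
        mbs_regions.extend(
            call_candidate_regions(
                read_tracks["RFB2"][chrom],
                read_tracks["RFB1"][chrom],
                high_threshold=cfg.high_threshold,
                segregating_band=(cfg.seg_band_low, cfg.seg_band_high),
                min_consecutive=cfg.min_consecutive,
            )
        )
    reduced_tracks = _genotype_tracks(study.fuzzless, grid, wcfg)
    normal_tracks = _genotype_tracks(study.normal, grid, wcfg)
    array_regions: list[CandidateRegion] = []
    for chrom in grid.chrom_labels:
        array_regions.extend(
            call_array_candidates(
                reduced_tracks[chrom],
                normal_tracks[chrom],
                high_threshold=cfg.high_threshold,
                normal_max=cfg.normal_max,
                min_consecutive=cfg.min_consecutive,
            )
        )
    return {
        "bulk_ids": {"RFB2": rec_ids, "RFB1": seg_ids},
        "counts": counts,
        "filtered": filtered,
        "filter_reports": reports,
        "read_tracks": read_tracks,
        "array_tracks": {"reduced": reduced_tracks, "normal": normal_tracks},
        "mbs_regions": mbs_regions,
        "array_regions": array_regions,
        "intersection": intersect_region_sets(mbs_regions, array_regions),
    }


def score_recovery(
    regions: Sequence[CandidateRegion], model: CausalModel
) -> dict:
    """Overlap of candidate regions with planted loci, plus off-target count."""
    planted = {l.chromosome for l in model.loci}
    recovered = []
    for locus in model.loci:
        hit = any(r.overlaps(locus.chromosome, locus.position - 1) for r in regions)
        recovered.append({"locus": locus.marker_id, "role": locus.role, "hit": hit})
    off_target = [
        {"chrom": r.chromosome, "start": r.start, "end": r.end}
        for r in regions
        if r.chromosome not in planted
    ]
    return {
        "n_loci": len(model.loci),
        "n_recovered": sum(r["hit"] for r in recovered),
        "loci": recovered,
        "n_off_target_chromosome_regions": len(off_target),
        "off_target": off_target,
    }


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute simulate -> filter -> scan -> call -> intersect -> associate.

    Writes every intermediate artifact under ``outdir`` plus a deterministic
    ``summary.json`` and returns the summary dict.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("fuzzmap")
    root.addHandler(handler)
    try:
        log.info("fuzzmap %s pipeline start; seed=%d", __version__, cfg.seed)
        log.info("config: %s", json.dumps(cfg.to_dict(), sort_keys=True))
        rng = np.random.default_rng(cfg.seed)
        genome = cfg.genome()
        model = cfg.model()
        grid = MarkerGrid(genome, model.loci)

        # stage 1: F2 segregation + association
        f2 = simulate_population(
            PedigreeSpec(design="F2", population_size=cfg.f2_size),
            genome,
            model,
            seed=rng,
            grid=grid,
        )
        write_genotype_tsv(f2.genotypes, outdir / "f2_genotypes.tsv")
        write_phenotype_tsv(f2.phenotypes, outdir / "f2_phenotypes.tsv")
        n_mutant = int((f2.phenotypes["fuzz_class"] == "fuzzless").sum())
        best_k, seg_results = select_model(n_mutant, cfg.f2_size, cfg.k_range)
        seg_table = results_table(seg_results)
        seg_table.to_csv(outdir / "segregation.tsv", sep="\t", index=False)
        assoc = associate(
            f2.genotypes,
            f2.causal_marker_ids,
            f2.phenotypes,
            alpha=cfg.alpha,
            min_group_size=cfg.min_group_size,
        )
        association_table(assoc).to_csv(
            outdir / "association.tsv", sep="\t", index=False
        )

        # stage 2: NIL study, bulks, pooled sequencing, scan
        study = simulate_nil_study(
            genome,
            model,
            n_backcrosses=cfg.n_backcrosses,
            n_selfs=cfg.n_selfs,
            progeny_size=cfg.progeny_size,
            seed=rng,
            grid=grid,
        )
        result = scan_study(study, cfg, rng)
        for bulk, df in result["counts"].items():
            out = df.copy()
            out["bulk"] = bulk
            write_variants_tsv(out, outdir / f"pool_counts_{bulk}.tsv")
        for bulk in ("RFB1", "RFB2"):
            write_window_tracks(
                [result["read_tracks"][bulk][c] for c in grid.chrom_labels],
                outdir / f"windows_{bulk}.tsv",
            )
        write_regions_bed(result["mbs_regions"], outdir / "regions_mbs.bed")
        write_regions_bed(result["array_regions"], outdir / "regions_array.bed")
        write_regions_bed(result["intersection"], outdir / "regions_combined.bed")

        truth = sorted(
            (l.chromosome, l.position - 1, l.position, l.role, 0) for l in model.loci
        )
        truth_lines = ["#chrom\tstart\tend\tname\tscore"] + [
            "\t".join(str(v) for v in row) for row in truth
        ]
        (outdir / "truth_loci.bed").write_text("\n".join(truth_lines) + "\n")

        recovery = score_recovery(result["mbs_regions"], model)
        summary = {
            "version": __version__,
            "seed": cfg.seed,
            "config": cfg.to_dict(),
            "f2": {
                "n": cfg.f2_size,
                "n_fuzzless": n_mutant,
                "best_k": best_k,
                "segregation": seg_table.to_dict("records"),
            },
            "association": {
                r.marker_id: r.effect_call for r in assoc
            },
            "filter_reports": {
                b: dataclasses.asdict(rep)
                for b, rep in result["filter_reports"].items()
            },
            "regions": {
                "mbs": [dataclasses.asdict(r) for r in result["mbs_regions"]],
                "array": [dataclasses.asdict(r) for r in result["array_regions"]],
                "combined": [dataclasses.asdict(r) for r in result["intersection"]],
            },
            "recovery": recovery,
        }
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
        log.info(
            "pipeline done: %d MBS regions, %d/%d loci recovered",
            len(result["mbs_regions"]),
            recovery["n_recovered"],
            recovery["n_loci"],
        )
        return summary
    finally:
        root.removeHandler(handler)
        handler.close()
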