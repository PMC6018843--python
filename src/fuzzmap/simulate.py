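"""Seeded simulator of genomes, pedigrees, genotypes, phenotypes and pooled
sequencing counts with the statistical structure the mapping pipeline assumes.

The generator emulates the two population designs of a recessive multilocus
seed-trait study in an allotetraploid crop:

* an **F2** (selfed F1 of donor x recurrent), used for segregation-ratio
  tests and single-marker association, and
* a **backcross-then-self NIL design**: four backcrosses to the recurrent
  parent with marker-assisted retention of at least one donor allele at
  every causal locus, then repeated selfing during which sister lineages are
  fixed homozygous-donor ("fuzzless NIL"), kept heterozygous ("segregating
  NIL") or fixed homozygous-recurrent ("normal NIL") at the causal loci.
  Selfed progeny of these NILs are the source material for sequencing bulks.

Meiosis uses a Haldane map (no interference) at 1 cM/Mb: the crossover count
per chromosome is Poisson with mean equal to its length in Morgans and
crossover positions are uniform.  Pooled sequencing is emulated per marker
by Poisson coverage and binomial donor-read sampling around the pool's mean
genotype code, with a symmetric per-read error rate.

The phenotype model: an individual homozygous-donor at ALL
``required_recessive`` loci is (with probability ``penetrance``) a mutant
with near-zero residual fuzz |N(0.7, 0.4)| percent; any other individual
gets ``baseline_fuzz`` plus per-locus contributions (additive loci act per
donor-allele copy; enhancer and required loci act when donor-homozygous)
plus N(0, noise_sd), truncated to [0, 100].

Every generator is bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_CUTOFFS,
    FuzzClassCutoffs,
    GenotypeMatrix,
    MarkerMap,
    classify_fuzz,
)
from .errors import (
    InsufficientIndividualsError,
    InvalidInputError,
    SelectionError,
)

__all__ = [
    "LOCUS_ROLES",
    "CausalLocus",
    "CausalModel",
    "SimGenome",
    "PedigreeSpec",
    "MarkerGrid",
    "SimulatedPopulation",
    "SimulatedNILStudy",
    "default_ps_model",
    "simulate_meiosis",
    "simulate_f2",
    "simulate_selfed_progeny",
    "simulate_population",
    "simulate_nil_study",
    "phenotype_from_genotype",
    "build_bulks",
    "simulate_pool_counts",
]

LOCUS_ROLES = ("required_recessive", "additive_major", "enhancer")


@dataclass(frozen=True)
class CausalLocus:
    """One planted trait locus.

    ``effect`` is in fuzz-percentage points: for ``additive_major`` it is the
    shift per donor-allele copy; for ``enhancer`` and ``required_recessive``
    it is added when donor-homozygous (enhancers positive, the others
    typically negative).
    """

    chromosome: str
    position: int
    role: str
    effect: float

    def __post_init__(self) -> None:
        if self.role not in LOCUS_ROLES:
            raise InvalidInputError(
                f"unknown locus role {self.role!r}; expected one of {LOCUS_ROLES}"
            )
        if self.position <= 0:
            raise InvalidInputError("locus position must be positive (1-based)")
        if not np.isfinite(self.effect):
            raise InvalidInputError("locus effect must be finite")

    @property
    def marker_id(self) -> str:
        return f"{self.chromosome}_{self.position}"


@dataclass(frozen=True)
class CausalModel:
    """Phenotype model: causal loci plus baseline, noise and penetrance."""

    loci: tuple[CausalLocus, ...]
    baseline_fuzz: float = 11.0
    noise_sd: float = 1.5
    penetrance: float = 1.0
    residual_mean: float = 0.7
    residual_sd: float = 0.4
    cutoffs: FuzzClassCutoffs = DEFAULT_CUTOFFS

    def __post_init__(self) -> None:
        if not 0 < self.penetrance <= 1:
            raise InvalidInputError(
                f"penetrance must lie in (0, 1], got {self.penetrance!r}"
            )
        if not 0 <= self.baseline_fuzz <= 100:
            raise InvalidInputError(
                f"baseline_fuzz must lie in [0, 100], got {self.baseline_fuzz!r}"
            )
        if self.noise_sd < 0 or self.residual_sd < 0:
            raise InvalidInputError("noise/residual standard deviations must be >= 0")

    @property
    def required(self) -> tuple[CausalLocus, ...]:
        return tuple(l for l in self.loci if l.role == "required_recessive")


@dataclass(frozen=True)
class SimGenome:
    """Physical genome for simulation: chromosome labels/lengths and map.

    The default mirrors a 26-chromosome allotetraploid frame (A01-A13,
    D01-D13), 60 Mb per chromosome, one marker per 250 kb (~6240 markers),
    and a uniform 1 cM/Mb Haldane map.
    """

    chromosomes: tuple[tuple[str, int], ...]
    marker_spacing: int = 250_000
    cm_per_mb: float = 1.0

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise InvalidInputError("genome needs at least one chromosome")
        for label, length in self.chromosomes:
            if length <= 0:
                raise InvalidInputError(f"chromosome {label!r} has length <= 0")
        if self.marker_spacing <= 0 or self.cm_per_mb < 0:
            raise InvalidInputError("marker_spacing must be > 0 and cm_per_mb >= 0")

    @classmethod
    def default(
        cls,
        chrom_length: int = 60_000_000,
        marker_spacing: int = 250_000,
        cm_per_mb: float = 1.0,
        n_chromosomes: int = 26,
    ) -> "SimGenome":
        labels = [f"A{i:02d}" for i in range(1, 14)] + [
            f"D{i:02d}" for i in range(1, 14)
        ]
        labels = labels[:n_chromosomes]
        if len(labels) < n_chromosomes:
            labels += [f"C{i:02d}" for i in range(27, n_chromosomes + 1)]
        return cls(
            chromosomes=tuple((lab, chrom_length) for lab in labels),
            marker_spacing=marker_spacing,
            cm_per_mb=cm_per_mb,
        )

    def morgans(self, length_bp: int) -> float:
        """Genetic length in Morgans at ``cm_per_mb`` centimorgan per megabase."""
        return length_bp / 1e6 * self.cm_per_mb / 100.0


@dataclass(frozen=True)
class PedigreeSpec:
    """Crossing design: plain F2 or backcross-then-self with selection."""

    design: str = "F2"
    n_backcrosses: int = 4
    n_selfs: int = 4
    population_size: int = 169
    marker_assisted: bool = True

    def __post_init__(self) -> None:
        if self.design not in ("F2", "BC_then_self"):
            raise InvalidInputError(f"unknown design {self.design!r}")
        if self.population_size < 1:
            raise InvalidInputError("population_size must be >= 1")
        if self.n_backcrosses < 0 or self.n_selfs < 0:
            raise InvalidInputError("generation counts must be >= 0")


def default_ps_model() -> CausalModel:
    """Five-locus model emulating the mapped architecture of the study trait.

    Three unlinked required-recessive loci (each also a mild suppressor when
    donor-homozygous), one additive major locus and one enhancer, on five of
    the 26 chromosomes.  Effect sizes are chosen so genotype-group contrasts
    are detectable in an F2 of ~170 plants with noise_sd 1.5.
    """
    return CausalModel(
        loci=(
            CausalLocus("A08", 20_000_000, "enhancer", +3.0),
            CausalLocus("A10", 30_000_000, "required_recessive", -2.0),
            CausalLocus("D05", 35_000_000, "required_recessive", -2.0),
            CausalLocus("D07", 25_000_000, "required_recessive", -2.0),
            CausalLocus("D12", 50_000_000, "additive_major", -2.5),
        )
    )


class MarkerGrid:
    """Marker scaffold over a simulated genome: regular grid plus causal sites.

    Stores per-chromosome marker slices and positions so a meiosis touches
    each chromosome with O(markers) numpy work.
    """

    def __init__(self, genome: SimGenome, causal_loci: Sequence[CausalLocus] = ()):
        self.genome = genome
        labels = {lab for lab, _ in genome.chromosomes}
        for locus in causal_loci:
            if locus.chromosome not in labels:
                raise InvalidInputError(
                    f"causal locus on unknown chromosome {locus.chromosome!r}"
                )
        extra: dict[str, set[int]] = {}
        for locus in causal_loci:
            lengths = dict(genome.chromosomes)
            if locus.position > lengths[locus.chromosome]:
                raise InvalidInputError(
                    f"causal locus at {locus.position} beyond chromosome "
                    f"{locus.chromosome!r} length {lengths[locus.chromosome]}"
                )
            extra.setdefault(locus.chromosome, set()).add(locus.position)

        self.chrom_labels: list[str] = []
        self.chrom_lengths: dict[str, int] = {}
        self.chrom_slices: dict[str, slice] = {}
        self.chrom_positions: dict[str, np.ndarray] = {}
        rows = []
        offset = 0
        for label, length in genome.chromosomes:
            grid = np.arange(
                genome.marker_spacing, length + 1, genome.marker_spacing, dtype=np.int64
            )
            pos = np.unique(
                np.concatenate(
                    [grid, np.array(sorted(extra.get(label, ())), dtype=np.int64)]
                )
            )
            self.chrom_labels.append(label)
            self.chrom_lengths[label] = length
            self.chrom_slices[label] = slice(offset, offset + len(pos))
            self.chrom_positions[label] = pos
            for p in pos:
                rows.append((f"{label}_{p}", label, int(p)))
            offset += len(pos)
        self.n_markers = offset
        self.marker_map = MarkerMap(
            pd.DataFrame(rows, columns=["marker", "chrom", "pos"])
        )
        self._marker_index = {m: i for i, m in enumerate(self.marker_map.marker_ids)}

    def index_of(self, chromosome: str, position: int) -> int:
        try:
            return self._marker_index[f"{chromosome}_{position}"]
        except KeyError:
            raise InvalidInputError(
                f"no marker at {chromosome}:{position} in the simulated grid"
            ) from None

    def causal_indices(self, model: CausalModel) -> np.ndarray:
        return np.array(
            [self.index_of(l.chromosome, l.position) for l in model.loci],
            dtype=np.int64,
        )


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_meiosis(
    haplotypes: np.ndarray, grid: MarkerGrid, rng: np.random.Generator | int
) -> np.ndarray:
    """One gamete from a diploid parent under the Haldane map.

    ``haplotypes`` has shape (2, n_markers) with donor-origin alleles coded
    1.  Per chromosome: the starting haplotype is a fair coin, the crossover
    count is Poisson(length in Morgans), crossover positions are uniform and
    independent (no interference).
    """
    rng = _as_rng(rng)
    if haplotypes.shape != (2, grid.n_markers):
        raise InvalidInputError(
            f"haplotypes must have shape (2, {grid.n_markers}), got "
            f"{haplotypes.shape}"
        )
    gamete = np.empty(grid.n_markers, dtype=haplotypes.dtype)
    for label in grid.chrom_labels:
        sl = grid.chrom_slices[label]
        pos = grid.chrom_positions[label]
        length = grid.chrom_lengths[label]
        start = int(rng.integers(2))
        n_co = int(rng.poisson(grid.genome.morgans(length)))
        seg = haplotypes[:, sl]
        if n_co == 0:
            gamete[sl] = seg[start]
        else:
            breaks = np.sort(rng.uniform(0.0, length, n_co))
            crossed = np.searchsorted(breaks, pos - 1, side="right")
            h = (start + crossed) % 2
            gamete[sl] = seg[h, np.arange(seg.shape[1])]
    return gamete


def _cross(
    mother: np.ndarray, father: np.ndarray, grid: MarkerGrid, rng: np.random.Generator
) -> np.ndarray:
    return np.stack(
        [simulate_meiosis(mother, grid, rng), simulate_meiosis(father, grid, rng)]
    )


def _f1(grid: MarkerGrid) -> np.ndarray:
    """Donor x recurrent F1: one all-donor and one all-recurrent haplotype."""
    return np.stack(
        [
            np.ones(grid.n_markers, dtype=np.uint8),
            np.zeros(grid.n_markers, dtype=np.uint8),
        ]
    )


def simulate_f2(
    n: int, grid: MarkerGrid, rng: np.random.Generator | int
) -> np.ndarray:
    """n F2 individuals (selfed F1), as an (n, 2, n_markers) haplotype array."""
    rng = _as_rng(rng)
    f1 = _f1(grid)
    return np.stack([_cross(f1, f1, grid, rng) for _ in range(n)])


def simulate_selfed_progeny(
    parent: np.ndarray, n: int, grid: MarkerGrid, rng: np.random.Generator | int
) -> np.ndarray:
    """n selfed progeny of one diploid parent."""
    rng = _as_rng(rng)
    return np.stack([_cross(parent, parent, grid, rng) for _ in range(n)])


def _codes(haplotypes: np.ndarray) -> np.ndarray:
    """Parental-origin codes from haplotypes: (h1+h2)/2 in {0, 0.5, 1}."""
    return haplotypes.astype(float).mean(axis=-2)


def phenotype_from_genotype(
    causal_codes: Mapping[str, float] | Sequence[float],
    model: CausalModel,
    rng: np.random.Generator | int,
) -> tuple[float, str]:
    """Draw one (fuzz percentage, fuzz class) from causal-locus genotypes.

    ``causal_codes`` gives the genotype code at every causal locus, either as
    a sequence aligned with ``model.loci`` or keyed by locus marker id.
    A mutant (homozygous-donor at every required locus, when at least one
    required locus exists, and passing a penetrance draw) gets the near-zero
    residual distribution; everyone else gets the quantitative model.
    """
    rng = _as_rng(rng)
    if isinstance(causal_codes, Mapping):
        codes = [float(causal_codes[l.marker_id]) for l in model.loci]
    else:
        codes = [float(c) for c in causal_codes]
        if len(codes) != len(model.loci):
            raise InvalidInputError(
                f"expected {len(model.loci)} causal codes, got {len(codes)}"
            )
    if any(np.isnan(c) for c in codes):
        raise InvalidInputError("causal genotypes must be defined at all loci")
    required_idx = [
        i for i, l in enumerate(model.loci) if l.role == "required_recessive"
    ]
    is_mutant = bool(required_idx) and all(codes[i] == 1.0 for i in required_idx)
    if is_mutant and (model.penetrance >= 1.0 or rng.random() < model.penetrance):
        fuzz = abs(rng.normal(model.residual_mean, model.residual_sd))
    else:
        fuzz = model.baseline_fuzz
        for locus, code in zip(model.loci, codes):
            if locus.role == "additive_major":
                fuzz += locus.effect * 2.0 * code  # per donor-allele copy
            elif code == 1.0:  # enhancer / required act when donor-homozygous
                fuzz += locus.effect
        fuzz += rng.normal(0.0, model.noise_sd)
    fuzz = float(min(max(fuzz, 0.0), 100.0))
    return fuzz, classify_fuzz(fuzz, model.cutoffs)


@dataclass
class SimulatedPopulation:
    """A simulated cohort: genotype matrix, phenotype table and provenance."""

    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame = field(repr=False)
    grid: MarkerGrid = field(repr=False)
    model: CausalModel = field(repr=False)
    haplotypes: np.ndarray = field(repr=False)

    @property
    def causal_marker_ids(self) -> list[str]:
        return [l.marker_id for l in self.model.loci]


def _package_population(
    haplos: np.ndarray,
    prefix: str,
    grid: MarkerGrid,
    model: CausalModel,
    rng: np.random.Generator,
) -> SimulatedPopulation:
    n = haplos.shape[0]
    ids = [f"{prefix}_{i + 1:04d}" for i in range(n)]
    codes = pd.DataFrame(
        _codes(haplos), index=ids, columns=grid.marker_map.marker_ids
    )
    causal_idx = grid.causal_indices(model)
    rows = []
    for i, ind in enumerate(ids):
        fuzz, cls = phenotype_from_genotype(
            codes.iloc[i, causal_idx].to_list(), model, rng
        )
        rows.append((ind, fuzz, float("nan"), cls, None))
    pheno = pd.DataFrame(
        rows, columns=["individual", "fuzz_pct", "lint_pct", "fuzz_class", "tufted"]
    )
    gm = GenotypeMatrix(markers=grid.marker_map, codes=codes)
    return SimulatedPopulation(
        genotypes=gm, phenotypes=pheno, grid=grid, model=model, haplotypes=haplos
    )


def simulate_population(
    spec: PedigreeSpec,
    genome: SimGenome,
    model: CausalModel,
    seed: int | np.random.Generator | None = 0,
    grid: MarkerGrid | None = None,
) -> SimulatedPopulation:
    """Simulate a population under the given pedigree design.

    ``F2``: self of the donor x recurrent F1.  ``BC_then_self``: backcross
    the F1 to the recurrent parent ``n_backcrosses`` times with
    marker-assisted retention of >= 1 donor allele at every causal locus,
    self ``n_selfs`` generations under the same retention, then emit
    ``population_size`` selfed progeny of the final plant.
    """
    rng = _as_rng(seed)
    if grid is None:
        grid = MarkerGrid(genome, model.loci)
    if spec.design == "F2":
        haplos = simulate_f2(spec.population_size, grid, rng)
        return _package_population(haplos, "F2", grid, model, rng)
    causal_idx = grid.causal_indices(model)
    plant = _advance_backcrosses(grid, causal_idx, spec, rng)
    for _ in range(spec.n_selfs):
        plant = _select_selfed(
            plant, grid, causal_idx, rng, target="carrier", spec=spec
        )
    haplos = simulate_selfed_progeny(plant, spec.population_size, grid, rng)
    return _package_population(haplos, "BCF", grid, model, rng)


_BATCH = 64
_MAX_TRIES = 4096


def _advance_backcrosses(
    grid: MarkerGrid,
    causal_idx: np.ndarray,
    spec: PedigreeSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """F1 backcrossed n times to the recurrent parent, retaining donor alleles."""
    recurrent_gamete = np.zeros(grid.n_markers, dtype=np.uint8)
    plant = _f1(grid)
    for gen in range(spec.n_backcrosses):
        for attempt in range(_MAX_TRIES):
            gamete = simulate_meiosis(plant, grid, rng)
            child = np.stack([gamete, recurrent_gamete])
            if not spec.marker_assisted or (child[:, causal_idx].sum(axis=0) >= 1).all():
                plant = child
                break
        else:
            raise SelectionError(
                f"no backcross progeny retained all donor alleles after "
                f"{_MAX_TRIES} tries (generation {gen + 1})"
            )
    return plant


def _causal_state(plant: np.ndarray, causal_idx: np.ndarray) -> np.ndarray:
    """Donor-allele dosage (0, 1, 2) at the causal loci."""
    return plant[:, causal_idx].sum(axis=0)


def _select_selfed(
    plant: np.ndarray,
    grid: MarkerGrid,
    causal_idx: np.ndarray,
    rng: np.random.Generator,
    target: str,
    spec: PedigreeSpec | None = None,
) -> np.ndarray:
    """One generation of selfing with single-seed selection at causal loci.

    ``target``: ``carrier`` keeps >= 1 donor allele everywhere; ``het``
    demands heterozygosity at every causal locus; ``donor_hom`` /
    ``recurrent_hom`` greedily fix loci toward the named homozygote while
    never losing the remaining alleles.
    """
    n_loci = len(causal_idx)
    if target in ("carrier", "het"):
        accept = (
            (lambda s: bool((s >= 1).all()))
            if target == "carrier"
            else (lambda s: bool((s == 1).all()))
        )
        for _ in range(_MAX_TRIES):
            child = _cross(plant, plant, grid, rng)
            if accept(_causal_state(child, causal_idx)):
                return child
        raise SelectionError(
            f"selection target {target!r} not reached in {_MAX_TRIES} selfed progeny"
        )
    if target not in ("donor_hom", "recurrent_hom"):
        raise InvalidInputError(f"unknown selection target {target!r}")
    want = 2 if target == "donor_hom" else 0
    # a locus already fixed in the parent stays fixed in every selfed progeny,
    # so requiring validity alone never regresses the fixation score
    valid = (
        (lambda s: bool((s >= 1).all()))  # never lose the donor allele
        if target == "donor_hom"
        else (lambda s: bool((s <= 1).all()))  # never fix the donor allele
    )
    best = None
    best_score = -1
    for attempt in range(1, _MAX_TRIES + 1):
        child = _cross(plant, plant, grid, rng)
        state = _causal_state(child, causal_idx)
        if not valid(state):
            continue
        score = int((state == want).sum())
        if score == n_loci:
            return child
        if score > best_score:
            best, best_score = child, score
        if attempt >= _BATCH and best is not None:
            return best
    if best is not None:
        return best
    raise SelectionError(
        f"selection target {target!r} not reachable in {_MAX_TRIES} selfed progeny"
    )


def _fix_lineage(
    plant: np.ndarray,
    grid: MarkerGrid,
    causal_idx: np.ndarray,
    rng: np.random.Generator,
    target: str,
    n_selfs: int,
    max_extra: int = 6,
) -> np.ndarray:
    """Self ``n_selfs`` generations driving the causal loci to ``target``."""
    want = {"donor_hom": 2, "recurrent_hom": 0, "het": 1}[target]
    for gen in range(n_selfs + max_extra):
        state = _causal_state(plant, causal_idx)
        done = (state == want).all()
        if gen >= n_selfs and done:
            return plant
        plant = _select_selfed(plant, grid, causal_idx, rng, target=target)
    state = _causal_state(plant, causal_idx)
    if (state == want).all():
        return plant
    raise SelectionError(
        f"could not fix causal loci to {target!r} within {n_selfs + max_extra} "
        f"selfed generations (state {state.tolist()})"
    )


@dataclass
class SimulatedNILStudy:
    """Paired NIL progeny cohorts emulating the bulk-sequencing design."""

    fuzzless: SimulatedPopulation  # pooled progeny of homozygous-donor NILs
    segregating: SimulatedPopulation  # pooled progeny of heterozygous NILs
    normal: SimulatedPopulation  # pooled progeny of homozygous-recurrent NILs
    grid: MarkerGrid = field(repr=False)
    model: CausalModel = field(repr=False)


def _lineage_sizes(total: int, n_lineages: int) -> list[int]:
    base = total // n_lineages
    sizes = [base] * n_lineages
    for i in range(total - base * n_lineages):
        sizes[i] += 1
    return [s for s in sizes if s > 0]


def simulate_nil_study(
    genome: SimGenome,
    model: CausalModel,
    n_backcrosses: int = 4,
    n_selfs: int = 4,
    progeny_size: int = 60,
    n_lineages: int = 4,
    seed: int | np.random.Generator | None = 0,
    grid: MarkerGrid | None = None,
) -> SimulatedNILStudy:
    """Simulate the NIL pipeline behind the sequencing and array pools.

    For each of the three cohorts, ``n_lineages`` independent F1 plants are
    backcrossed ``n_backcrosses`` times to the recurrent parent
    (marker-assisted retention of >= 1 donor allele at every causal locus),
    then selfed ``n_selfs`` generations while the causal loci are driven to
    the cohort's target state — homozygous-donor ("fuzzless" NILs),
    heterozygous ("segregating" NILs) or homozygous-recurrent ("normal"
    NILs).  Each cohort pools ``progeny_size`` selfed progeny split evenly
    over its lineages.

    Using several independent lineages per cohort matters: unlinked genomic
    segments fixed for donor alleles by inbreeding drift differ between
    lineages, so pooling progeny across lineages suppresses the
    fixation-driven false-positive regions a single-lineage bulk produces.
    """
    rng = _as_rng(seed)
    if grid is None:
        grid = MarkerGrid(genome, model.loci)
    if n_lineages < 1:
        raise InvalidInputError("n_lineages must be >= 1")
    causal_idx = grid.causal_indices(model)
    spec = PedigreeSpec(
        design="BC_then_self",
        n_backcrosses=n_backcrosses,
        n_selfs=n_selfs,
        population_size=progeny_size,
    )
    populations = {}
    for name, target in (
        ("fuzzless", "donor_hom"),
        ("segregating", "het"),
        ("normal", "recurrent_hom"),
    ):
        cohort = []
        for n_prog in _lineage_sizes(progeny_size, n_lineages):
            founder = _advance_backcrosses(grid, causal_idx, spec, rng)
            nil = _fix_lineage(
                founder, grid, causal_idx, rng, target=target, n_selfs=n_selfs
            )
            cohort.append(simulate_selfed_progeny(nil, n_prog, grid, rng))
        haplos = np.concatenate(cohort, axis=0)
        populations[name] = _package_population(
            haplos, name.upper()[:3], grid, model, rng
        )
    return SimulatedNILStudy(
        fuzzless=populations["fuzzless"],
        segregating=populations["segregating"],
        normal=populations["normal"],
        grid=grid,
        model=model,
    )


def build_bulks(
    population: SimulatedPopulation,
    design: str,
    size: int,
    rng: np.random.Generator | int = 0,
) -> list[str]:
    """Select individual ids for a DNA bulk.

    ``recessive_bulk`` samples (without replacement) only fuzzless-class
    individuals; ``segregating_bulk`` samples from the whole population —
    the caller supplies progeny of a heterozygous parent, phenotype ignored.
    """
    rng = _as_rng(rng)
    pheno = population.phenotypes
    if design == "recessive_bulk":
        eligible = pheno.loc[pheno["fuzz_class"] == "fuzzless", "individual"].tolist()
    elif design == "segregating_bulk":
        eligible = pheno["individual"].tolist()
    else:
        raise InvalidInputError(f"unknown bulk design {design!r}")
    if len(eligible) < size:
        raise InsufficientIndividualsError(
            f"{design} of size {size} requested but only {len(eligible)} "
            f"eligible individuals"
        )
    chosen = rng.choice(len(eligible), size=size, replace=False)
    return [eligible[i] for i in sorted(chosen)]


def simulate_pool_counts(
    genotypes: GenotypeMatrix,
    bulk_ids: Sequence[str],
    depth: float = 30.0,
    error_rate: float = 0.0,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Emulate pooled sequencing of a bulk: per-marker read counts.

    Per marker: coverage ~ Poisson(depth); donor reads ~ Binomial(coverage,
    p(1-e) + (1-p)e) where p is the bulk's mean genotype code and e the
    per-read error rate.  Returns columns marker/chrom/pos/donor_reads/
    total_reads.
    """
    rng = _as_rng(rng)
    if depth <= 0:
        raise InvalidInputError(f"depth must be > 0, got {depth!r}")
    if not 0 <= error_rate < 0.5:
        raise InvalidInputError(f"error_rate must lie in [0, 0.5), got {error_rate!r}")
    missing = [i for i in bulk_ids if i not in genotypes.codes.index]
    if missing:
        raise InvalidInputError(f"bulk ids not in genotype matrix: {missing[:3]}")
    codes = genotypes.codes.loc[list(bulk_ids)]
    p = codes.mean(axis=0, skipna=True).to_numpy(dtype=float)
    p = np.nan_to_num(p, nan=0.0)
    p_read = p * (1 - error_rate) + (1 - p) * error_rate
    m = len(p)
    coverage = rng.poisson(depth, size=m)
    donor = rng.binomial(coverage, p_read)
    table = genotypes.markers.table
    return pd.DataFrame(
        {
            "marker": table["marker"],
            "chrom": table["chrom"],
            "pos": table["pos"],
            "donor_reads": donor,
            "total_reads": coverage,
        }
    )
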