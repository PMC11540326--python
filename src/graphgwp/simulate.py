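"""Synthetic multi-generation populations with additive QTL architecture.

The generator emulates the XVIth QTL-MAS workshop design: discrete
generations produced by a sire/dam mating scheme (each sire mated to a
fixed harem of dams), a genome of equally spaced biallelic SNPs, founder
genotypes in Hardy-Weinberg proportions at allele frequencies drawn from
Uniform(0.05, 0.5), Mendelian transmission with Haldane (no-interference)
recombination at 1 cM/Mb, and a quantitative trait built from a small set
of additive QTLs. Environmental noise is calibrated from the *realized*
genetic variance so the sample heritability matches the target in
expectation even for small populations.

The full-scale preset (:meth:`SimConfig.qtlmas_full`) is 4 generations of
20 males + 1000 females, 5 chromosomes x 2000 SNPs over 100 Mb, 50 QTLs
and target h2 = 0.35; :meth:`SimConfig.desk` is a small configuration for
fast pipelines and the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .snp_data import MarkerMatrix, PhenotypeVector, write_genotypes, write_phenotypes

__all__ = [
    "SimConfig",
    "SimulatedPopulation",
    "simulate_population",
    "realized_heritability",
    "export_population",
]

_BP_PER_MORGAN = 1e8  # 1 cM per Mb


@dataclass
class SimConfig:
    """Design of a simulated population; defaults mirror the full QTLMAS scale."""

    n_sires: int = 20
    n_dams_per_sire: int = 50
    n_generations: int = 4
    n_chromosomes: int = 5
    snps_per_chromosome: int = 2000
    chromosome_length_bp: float = 100e6
    n_qtl: int = 50
    h2_target: float = 0.35
    effect_distribution: str = "standard_normal"
    founder_maf_low: float = 0.05
    founder_maf_high: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_sires,
            self.n_dams_per_sire,
            self.n_generations,
            self.n_chromosomes,
            self.snps_per_chromosome,
            self.n_qtl,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all design counts must be >= 1")
        if not 0.0 < self.h2_target < 1.0:
            raise ValueError(f"h2_target must be in (0, 1), got {self.h2_target}")
        if self.n_qtl > self.n_chromosomes * self.snps_per_chromosome:
            raise ValueError("n_qtl exceeds the total number of SNPs")
        if self.effect_distribution not in ("standard_normal", "laplace"):
            raise ValueError(f"unknown effect distribution {self.effect_distribution!r}")
        if not 0.0 < self.founder_maf_low <= self.founder_maf_high <= 0.5:
            raise ValueError("founder MAF bounds must satisfy 0 < low <= high <= 0.5")

    @property
    def generation_size(self) -> int:
        return self.n_sires * (1 + self.n_dams_per_sire)

    @property
    def n_individuals(self) -> int:
        return self.generation_size * self.n_generations

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.snps_per_chromosome

    @classmethod
    def qtlmas_full(cls, seed: int = 0, **overrides) -> "SimConfig":
        """The workshop-scale design (4080 individuals, 10000 SNPs)."""
        return cls(seed=seed, **overrides)

    @classmethod
    def desk(cls, seed: int = 0, **overrides) -> "SimConfig":
        """Small design for fast runs: 220 individuals, 400 SNPs, 20 QTLs."""
        defaults = dict(
            n_sires=10,
            n_dams_per_sire=10,
            n_generations=2,
            n_chromosomes=2,
            snps_per_chromosome=200,
            n_qtl=20,
        )
        defaults.update(overrides)
        return cls(seed=seed, **defaults)


@dataclass
class SimulatedPopulation:
    """Genotypes, pedigree, QTL truth and phenotypes of one simulated run."""

    markers: MarkerMatrix
    sire: np.ndarray  # index of father, -1 for founders
    dam: np.ndarray  # index of mother, -1 for founders
    sex: np.ndarray  # 0 male, 1 female
    generation: np.ndarray
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    genetic_values: np.ndarray
    phenotypes: np.ndarray
    h2_target: float
    config: SimConfig = field(repr=False, default=None)

    @property
    def n_individuals(self) -> int:
        return self.markers.n_individuals

    def phenotype_vector(self) -> PhenotypeVector:
        return PhenotypeVector(list(self.markers.individual_ids), self.phenotypes)


def _meiosis(
    hapA: np.ndarray,
    hapB: np.ndarray,
    chrom_slices: list[slice],
    snp_morgans: list[np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete: recombine the parent's two haplotypes, Haldane model."""
    gamete = np.empty(hapA.shape, dtype=np.int8)
    for sl, pos in zip(chrom_slices, snp_morgans):
        length = pos[-1] if pos.size else 0.0
        n_xo = rng.poisson(length)
        start = rng.integers(2)
        if n_xo == 0:
            phase = np.full(pos.size, start)
        else:
            xo = np.sort(rng.uniform(0.0, length, size=n_xo))
            phase = (start + np.searchsorted(xo, pos)) % 2
        gamete[sl] = np.where(phase == 0, hapA[sl], hapB[sl])
    return gamete


def _draw_effects(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    if cfg.effect_distribution == "standard_normal":
        return rng.standard_normal(cfg.n_qtl)
    return rng.laplace(0.0, 1.0 / np.sqrt(2.0), cfg.n_qtl)


def simulate_population(cfg: SimConfig) -> SimulatedPopulation:
    """Generate a multi-generation population with an additive trait.

    Founders are drawn locus-wise in Hardy-Weinberg proportions; each
    later generation consists of ``n_sires`` males and ``n_sires *
    n_dams_per_sire`` females bred from the previous generation's sires
    and their harems. QTL columns are chosen uniformly without
    replacement, effects come from ``effect_distribution``, g is the
    dosage-weighted effect sum, and environmental noise has variance
    Var(g) (1 - h2) / h2 computed from the realized sample Var(g).
    Fully reproducible under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_per_gen = cfg.generation_size
    N = cfg.n_individuals
    P = cfg.n_markers

    # genome layout: equally spaced SNPs, genetic positions in Morgans
    per_chrom = cfg.snps_per_chromosome
    step = cfg.chromosome_length_bp / per_chrom
    bp = np.arange(per_chrom) * step + step / 2.0
    chrom_slices = [slice(c * per_chrom, (c + 1) * per_chrom) for c in range(cfg.n_chromosomes)]
    snp_morgans = [bp / _BP_PER_MORGAN for _ in range(cfg.n_chromosomes)]

    hapA = np.empty((N, P), dtype=np.int8)
    hapB = np.empty((N, P), dtype=np.int8)
    sire = np.full(N, -1, dtype=int)
    dam = np.full(N, -1, dtype=int)
    sex = np.empty(N, dtype=np.int8)
    generation = np.empty(N, dtype=int)

    # founders: per-locus allele frequencies, independent HW draws per haplotype
    freqs = rng.uniform(cfg.founder_maf_low, cfg.founder_maf_high, size=P)
    hapA[:n_per_gen] = rng.random((n_per_gen, P)) < freqs
    hapB[:n_per_gen] = rng.random((n_per_gen, P)) < freqs
    sex[: cfg.n_sires] = 0
    sex[cfg.n_sires : n_per_gen] = 1
    generation[:n_per_gen] = 0

    for g in range(1, cfg.n_generations):
        prev = np.arange((g - 1) * n_per_gen, g * n_per_gen)
        males = prev[sex[prev] == 0]
        females = prev[sex[prev] == 1]
        # harems: shuffle the previous generation's females into sire groups
        harems = rng.permutation(females).reshape(cfg.n_sires, cfg.n_dams_per_sire)

        offset = g * n_per_gen
        pairs: list[tuple[int, int, int]] = []  # (sire, dam, sex)
        # the generation's males: one extra offspring per sire from a random dam
        for s_local in range(cfg.n_sires):
            d = harems[s_local, rng.integers(cfg.n_dams_per_sire)]
            pairs.append((males[s_local], d, 0))
        # the generation's females: one offspring per dam
        for s_local in range(cfg.n_sires):
            for d in harems[s_local]:
                pairs.append((males[s_local], d, 1))

        for k, (s_idx, d_idx, child_sex) in enumerate(pairs):
            child = offset + k
            hapA[child] = _meiosis(hapA[s_idx], hapB[s_idx], chrom_slices, snp_morgans, rng)
            hapB[child] = _meiosis(hapA[d_idx], hapB[d_idx], chrom_slices, snp_morgans, rng)
            sire[child], dam[child], sex[child] = s_idx, d_idx, child_sex
        generation[offset : offset + n_per_gen] = g

    dosages = (hapA + hapB).astype(np.int8)
    individual_ids = [f"G{generation[i]}_I{i:05d}" for i in range(N)]
    marker_ids = [
        f"chr{c + 1}_snp{j + 1}" for c in range(cfg.n_chromosomes) for j in range(per_chrom)
    ]
    markers = MarkerMatrix(individual_ids, marker_ids, dosages)

    qtl_indices = np.sort(rng.choice(P, size=cfg.n_qtl, replace=False))
    qtl_effects = _draw_effects(rng, cfg)

    g_values = dosages[:, qtl_indices].astype(float) @ qtl_effects
    var_g = float(g_values.var())
    if var_g <= 0.0:
        raise ValueError(
            "realized genetic variance is zero (no segregating QTL effect); "
            "cannot calibrate environmental noise to the target heritability"
        )
    var_e = var_g * (1.0 - cfg.h2_target) / cfg.h2_target
    phenotypes = g_values + rng.normal(0.0, np.sqrt(var_e), size=N)

    return SimulatedPopulation(
        markers=markers,
        sire=sire,
        dam=dam,
        sex=sex,
        generation=generation,
        qtl_indices=qtl_indices,
        qtl_effects=qtl_effects,
        genetic_values=g_values,
        phenotypes=phenotypes,
        h2_target=cfg.h2_target,
        config=cfg,
    )


def realized_heritability(pop: SimulatedPopulation) -> float:
    """Sample Var(g) / Var(y) over all individuals."""
    var_y = float(np.var(pop.phenotypes))
    if var_y <= 0.0:
        raise ValueError("phenotypic variance is zero")
    return float(np.var(pop.genetic_values)) / var_y


def export_population(pop: SimulatedPopulation, out_dir) -> dict[str, Path]:
    """Write genotypes, phenotypes and truth tables as TSV.

    Output round-trips through :func:`graphgwp.snp_data.load_genotypes` /
    ``load_phenotypes`` and regenerates bit-identically for a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out / "genotypes.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "qtl": out / "qtl_effects.tsv",
        "genetic_values": out / "genetic_values.tsv",
        "pedigree": out / "pedigree.tsv",
    }
    write_genotypes(pop.markers, paths["genotypes"])
    write_phenotypes(pop.phenotype_vector(), paths["phenotypes"])

    ids = pop.markers.individual_ids
    with open(paths["qtl"], "w") as fh:
        fh.write("marker_id\tmarker_index\teffect\n")
        for j, eff in zip(pop.qtl_indices, pop.qtl_effects):
            fh.write(f"{pop.markers.marker_ids[j]}\t{j}\t{eff!r}\n")
    with open(paths["genetic_values"], "w") as fh:
        fh.write("id\tgenetic_value\n")
        for i, g in zip(ids, pop.genetic_values):
            fh.write(f"{i}\t{g!r}\n")
    with open(paths["pedigree"], "w") as fh:
        fh.write("id\tsire\tdam\tsex\tgeneration\n")
        for k, i in enumerate(ids):
            s = ids[pop.sire[k]] if pop.sire[k] >= 0 else "NA"
            d = ids[pop.dam[k]] if pop.dam[k] >= 0 else "NA"
            fh.write(f"{i}\t{s}\t{d}\t{int(pop.sex[k])}\t{int(pop.generation[k])}\n")
    return paths
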