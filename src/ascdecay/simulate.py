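"""Coalescent simulation of founder-event demographies.

Generates synthetic genotype datasets under a two-population model: a target
A and an outgroup O of diploid effective size N_o = 12,500 that diverged
1,800 generations ago, with an optional bottleneck in A during which its size
drops to N_f for D_f generations, ending T_f generations before sampling
(nominal intensity I_f = D_f / (2 N_f)). Genomes are 20 chromosomes of 50 Mb
with mutation rate 1.2e-8 and recombination rate 1e-8 per bp per generation,
and 30 haploid genomes are sampled per population and paired at random
without replacement into 15 diploids. An admixture variant forms A as a
60/40 pulse between two sources 110 generations ago. Pseudo-haploidization
and uniform missingness emulate low-coverage ancient-DNA genotyping.

All generators are deterministic given the config seed. The backing engine is
msprime; only biallelic sites are emitted, and the genetic map is constant at
1 cM/Mb so a 50 Mb chromosome spans 0.5 Morgans.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import msprime
import numpy as np

from .io import MISSING, DataError, GenotypeDataset

__all__ = [
    "DemographyConfig",
    "simulate_founder_model",
    "simulate_admixture_founder",
    "pair_haploids",
    "pseudo_haploidize",
    "inject_missingness",
]


@dataclass(frozen=True)
class AdmixtureSpec:
    """Pulse admixture forming the target: `time` generations ago, the target
    derives `proportions` of its ancestry from the two source populations."""

    time: float = 110.0
    proportions: tuple[float, float] = (0.6, 0.4)

    def validate(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise DataError(
                f"admixture proportions {self.proportions} do not sum to 1"
            )
        if self.time <= 0:
            raise DataError("admixture time must be positive")


@dataclass(frozen=True)
class DemographyConfig:
    """Parameters of the simulated founder-event demography.

    `N_f`/`D_f`/`T_f` describe the bottleneck in the target (set `N_f` to
    None for a constant-size no-event control). Sizes are diploid effective
    sizes; times are in generations before sampling.
    """

    N_o: float = 12_500.0
    N_f: float | None = 100.0
    D_f: float = 20.0
    T_f: float = 10.0
    divergence_time: float = 1_800.0
    mutation_rate: float = 1.2e-8
    recombination_rate: float = 1e-8
    n_chromosomes: int = 20
    chromosome_length_bp: float = 5e7
    haploids_per_pop: int = 30
    admixture: AdmixtureSpec | None = None
    seed: int = 1

    @property
    def T_b(self) -> float:
        return self.T_f + self.D_f

    @property
    def nominal_intensity(self) -> float | None:
        """I_f = D_f / (2 N_f), the coalescence probability during the
        bottleneck."""
        if self.N_f is None:
            return None
        return self.D_f / (2.0 * self.N_f)

    def validate(self) -> None:
        if self.haploids_per_pop % 2:
            raise DataError("haploids_per_pop must be even (paired into diploids)")
        if self.N_f is not None:
            if self.T_f < 0 or self.D_f <= 0 or self.N_f <= 0:
                raise DataError("bottleneck parameters must be positive")
            if self.T_b >= self.divergence_time:
                raise DataError(
                    f"bottleneck onset T_b = {self.T_b} must predate the "
                    f"divergence time {self.divergence_time}"
                )
        if self.admixture is not None:
            self.admixture.validate()
            if self.N_f is not None and self.T_b >= self.admixture.time:
                raise DataError("bottleneck must postdate the admixture pulse")


def _demography(config: DemographyConfig) -> msprime.Demography:
    dem = msprime.Demography()
    dem.add_population(name="A", initial_size=config.N_o)
    dem.add_population(name="O", initial_size=config.N_o)
    if config.admixture is None:
        dem.add_population(name="ANC", initial_size=config.N_o)
        if config.N_f is not None:
            dem.add_population_parameters_change(
                time=config.T_f, population="A", initial_size=config.N_f
            )
            dem.add_population_parameters_change(
                time=config.T_b, population="A", initial_size=config.N_o
            )
        dem.add_population_split(
            time=config.divergence_time, derived=["A", "O"], ancestral="ANC"
        )
    else:
        # A formed by a pulse between sources Ap and Bp; O is drawn from Ap.
        dem.add_population(name="Ap", initial_size=config.N_o)
        dem.add_population(name="Bp", initial_size=config.N_o)
        dem.add_population(name="ANC", initial_size=config.N_o)
        if config.N_f is not None:
            dem.add_population_parameters_change(
                time=config.T_f, population="A", initial_size=config.N_f
            )
            dem.add_population_parameters_change(
                time=config.T_b, population="A", initial_size=config.N_o
            )
        dem.add_admixture(
            time=config.admixture.time,
            derived="A",
            ancestral=["Ap", "Bp"],
            proportions=list(config.admixture.proportions),
        )
        dem.add_population_split(
            time=config.divergence_time, derived=["Ap", "Bp"], ancestral="ANC"
        )
        dem.sort_events()
    return dem


def _haploid_matrices(config: DemographyConfig, outgroup_pop: str):
    """Simulate per-chromosome biallelic variants; returns lists of genotype
    matrices (sites x haploids), positions and chromosome labels."""
    n_dip = config.haploids_per_pop // 2
    dem = _demography(config)
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(1, 2**31 - 1, size=(config.n_chromosomes, 2))
    chroms, positions, matrices = [], [], []
    for k in range(config.n_chromosomes):
        ts = msprime.sim_ancestry(
            samples={"A": n_dip, outgroup_pop: n_dip},
            demography=dem,
            sequence_length=config.chromosome_length_bp,
            recombination_rate=config.recombination_rate,
            random_seed=int(seeds[k, 0]),
        )
        ts = msprime.sim_mutations(ts, rate=config.mutation_rate, random_seed=int(seeds[k, 1]))
        keep = np.array(
            [len(v.alleles) == 2 for v in ts.variants()], dtype=bool
        )
        g = ts.genotype_matrix()[keep]
        pos = ts.tables.sites.position[keep]
        # back/stacked mutations can leave a nominally biallelic site with no
        # variation among the samples; drop those too
        seg = g.min(axis=1) != g.max(axis=1)
        g, pos = g[seg], pos[seg]
        chroms.append(str(k + 1))
        positions.append(pos)
        matrices.append(g.astype(np.int8))
    return chroms, positions, matrices, rng


def _assemble(config: DemographyConfig, outgroup_pop: str) -> GenotypeDataset:
    config.validate()
    chroms, positions, matrices, rng = _haploid_matrices(config, outgroup_pop)
    n_hap = 2 * config.haploids_per_pop
    half = config.haploids_per_pop

    # random perfect matching of haploid genomes within each population,
    # consistent across chromosomes
    perm_a = rng.permutation(half)
    perm_o = half + rng.permutation(half)
    order = np.concatenate([perm_a, perm_o])

    snp_ids, chrom_col, gpos, ppos = [], [], [], []
    geno_blocks = []
    morgans_per_bp = config.recombination_rate
    for chrom, pos, hap in zip(chroms, positions, matrices):
        if hap.shape[1] != n_hap:
            raise DataError("unexpected haploid sample count from the engine")
        # genotype = count of ancestral (reference) alleles
        ref_counts = 1 - hap[:, order]
        dip = (ref_counts[:, 0::2] + ref_counts[:, 1::2]).astype(np.int8)
        geno_blocks.append(dip)
        chrom_col.extend([chrom] * len(pos))
        gpos.extend((pos * morgans_per_bp).tolist())
        ppos.extend(pos.astype(np.int64).tolist())
        snp_ids.extend(f"{chrom}_{int(p)}" for p in pos)

    genotypes = np.concatenate(geno_blocks, axis=0)
    n_dip_per_pop = half // 2
    individual_ids = [f"A{i:03d}" for i in range(n_dip_per_pop)] + [
        f"{outgroup_pop}{i:03d}" for i in range(n_dip_per_pop)
    ]
    populations = ["A"] * n_dip_per_pop + [outgroup_pop] * n_dip_per_pop
    n = len(snp_ids)
    ds = GenotypeDataset(
        snp_ids=np.asarray(snp_ids, dtype=object),
        chromosomes=np.asarray(chrom_col, dtype=object),
        genetic_pos=np.asarray(gpos, dtype=np.float64),
        physical_pos=np.asarray(ppos, dtype=np.int64),
        ref_alleles=np.full(n, "A", dtype=object),
        alt_alleles=np.full(n, "G", dtype=object),
        individual_ids=individual_ids,
        populations=populations,
        sexes=["U"] * len(individual_ids),
        genotypes=genotypes,
        ploidy_mode="diploid",
        metadata={
            "seed": config.seed,
            "nominal_T_f": config.T_f if config.N_f is not None else None,
            "nominal_I_f": config.nominal_intensity,
            "engine": f"msprime {msprime.__version__}",
        },
    )
    ds.validate()
    return ds


def simulate_founder_model(config: DemographyConfig) -> GenotypeDataset:
    """Two-population founder model: target A (with the bottleneck epoch,
    unless `N_f` is None) and outgroup O, diverged `divergence_time`
    generations ago. Returns a diploid dataset of 15 + 15 individuals under
    the default sample sizes."""
    if config.admixture is not None:
        raise DataError("use simulate_admixture_founder for admixture configs")
    return _assemble(config, "O")


def simulate_admixture_founder(config: DemographyConfig) -> GenotypeDataset:
    """Admixture-then-founder model: the target A forms by a pulse between
    sources Ap and Bp (diverged `divergence_time` generations ago), optionally
    followed by a bottleneck in A; the emitted outgroup population is Ap."""
    if config.admixture is None:
        config = replace(config, admixture=AdmixtureSpec())
    return _assemble(config, "Ap")


def pair_haploids(haploid_matrix: np.ndarray, seed: int | None = None) -> np.ndarray:
    """Pair haploid columns at random without replacement; diploid genotype =
    sum of the two haploid allele counts. Standalone building block (the
    simulators pair internally, consistently across chromosomes)."""
    h = np.asarray(haploid_matrix)
    if h.shape[1] % 2:
        raise DataError("need an even number of haploid genomes to pair")
    rng = np.random.default_rng(seed)
    order = rng.permutation(h.shape[1])
    paired = h[:, order]
    return (paired[:, 0::2] + paired[:, 1::2]).astype(np.int8)


def pseudo_haploidize(dataset: GenotypeDataset, seed: int | None = None) -> GenotypeDataset:
    """Replace each heterozygous call by a random homozygote (fair coin),
    emulating single-read genotype calling; 0/2/missing are unchanged."""
    if dataset.ploidy_mode != "diploid":
        raise DataError("dataset is already pseudo-haploid")
    rng = np.random.default_rng(seed)
    g = dataset.genotypes.copy()
    het = g == 1
    g[het] = rng.choice(np.array([0, 2], dtype=np.int8), size=int(het.sum()))
    out = GenotypeDataset(
        snp_ids=dataset.snp_ids,
        chromosomes=dataset.chromosomes,
        genetic_pos=dataset.genetic_pos,
        physical_pos=dataset.physical_pos,
        ref_alleles=dataset.ref_alleles,
        alt_alleles=dataset.alt_alleles,
        individual_ids=list(dataset.individual_ids),
        populations=list(dataset.populations),
        sexes=list(dataset.sexes),
        genotypes=g,
        ploidy_mode="pseudo_haploid",
        metadata=dict(dataset.metadata),
    )
    return out


def inject_missingness(
    dataset: GenotypeDataset, rate: float, seed: int | None = None
) -> GenotypeDataset:
    """Set each genotype to missing independently with probability `rate`."""
    if not 0.0 <= rate <= 1.0:
        raise DataError("missingness rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    g = dataset.genotypes.copy()
    drop = rng.random(g.shape) < rate
    g[drop] = MISSING
    out = GenotypeDataset(
        snp_ids=dataset.snp_ids,
        chromosomes=dataset.chromosomes,
        genetic_pos=dataset.genetic_pos,
        physical_pos=dataset.physical_pos,
        ref_alleles=dataset.ref_alleles,
        alt_alleles=dataset.alt_alleles,
        individual_ids=list(dataset.individual_ids),
        populations=list(dataset.populations),
        sexes=list(dataset.sexes),
        genotypes=g,
        ploidy_mode=dataset.ploidy_mode,
        metadata=dict(dataset.metadata),
    )
    return out
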