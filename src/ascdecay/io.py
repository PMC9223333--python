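"""EIGENSTRAT genotype I/O and the in-memory genotype data model.

Genotypes are held as an N (SNPs) x M (individuals) int8 matrix with codes
0/1/2 counting reference alleles and 9 for missing. Pseudo-haploid data
(single-read homozygous calls, standard for low-coverage ancient DNA) carry
only 0/2/9; the reader autodetects this.

Genetic positions are stored in Morgans (EIGENSTRAT .snp column 3). A genetic
map is mandatory: distances between SNPs drive everything downstream, and an
implicit physical->genetic conversion would silently bias the inferred founder
age.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

MISSING = 9

__all__ = [
    "MISSING",
    "DataError",
    "FormatError",
    "SnpRecord",
    "GenotypeDataset",
    "read_eigenstrat",
    "write_eigenstrat",
    "filter_sites",
    "select_outgroup",
]


class DataError(Exception):
    """Invalid or unusable input data."""


class FormatError(DataError):
    """Malformed EIGENSTRAT file."""


@dataclass(frozen=True)
class SnpRecord:
    """One SNP of the map: identifier, chromosome, genetic position (Morgans),
    physical position (bp) and allele labels."""

    id: str
    chromosome: str
    genetic_pos: float
    physical_pos: int
    ref_allele: str
    alt_allele: str


@dataclass
class GenotypeDataset:
    """Genotype matrix plus SNP map and sample sheet.

    SNPs are kept sorted by (chromosome block, genetic position): chromosome
    labels partition the rows into contiguous blocks, in order of first
    appearance, and positions are non-decreasing within a block.
    """

    snp_ids: np.ndarray
    chromosomes: np.ndarray
    genetic_pos: np.ndarray
    physical_pos: np.ndarray
    ref_alleles: np.ndarray
    alt_alleles: np.ndarray
    individual_ids: list[str]
    populations: list[str]
    sexes: list[str]
    genotypes: np.ndarray
    ploidy_mode: str = "diploid"
    metadata: dict = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[1]

    def snps(self) -> Iterator[SnpRecord]:
        for i in range(self.n_snps):
            yield SnpRecord(
                str(self.snp_ids[i]),
                str(self.chromosomes[i]),
                float(self.genetic_pos[i]),
                int(self.physical_pos[i]),
                str(self.ref_alleles[i]),
                str(self.alt_alleles[i]),
            )

    def chromosome_order(self) -> list[str]:
        """Chromosome labels in the order their blocks appear."""
        seen: dict[str, None] = {}
        for c in self.chromosomes:
            seen.setdefault(str(c), None)
        return list(seen)

    def chromosome_slices(self) -> dict[str, slice]:
        out: dict[str, slice] = {}
        chroms = np.asarray(self.chromosomes)
        start = 0
        while start < len(chroms):
            stop = start
            while stop < len(chroms) and chroms[stop] == chroms[start]:
                stop += 1
            label = str(chroms[start])
            if label in out:
                raise DataError(f"chromosome {label!r} is not contiguous")
            out[label] = slice(start, stop)
            start = stop
        return out

    def columns_for(self, ids: Sequence[str]) -> np.ndarray:
        index = {iid: k for k, iid in enumerate(self.individual_ids)}
        try:
            return np.array([index[i] for i in ids], dtype=np.intp)
        except KeyError as exc:
            raise DataError(f"unknown individual id {exc.args[0]!r}") from None

    def members_of(self, population: str) -> list[str]:
        return [
            iid
            for iid, pop in zip(self.individual_ids, self.populations)
            if pop == population
        ]

    def subset_snps(self, index: np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        return dataclasses.replace(
            self,
            snp_ids=self.snp_ids[index],
            chromosomes=self.chromosomes[index],
            genetic_pos=self.genetic_pos[index],
            physical_pos=self.physical_pos[index],
            ref_alleles=self.ref_alleles[index],
            alt_alleles=self.alt_alleles[index],
            genotypes=self.genotypes[index],
            metadata=dict(self.metadata),
        )

    def snp_counts_per_chromosome(self) -> dict[str, int]:
        return {c: s.stop - s.start for c, s in self.chromosome_slices().items()}

    def validate(self) -> None:
        n, m = self.genotypes.shape
        if not (len(self.snp_ids) == len(self.chromosomes) == len(self.genetic_pos) == n):
            raise DataError("SNP annotation length does not match genotype rows")
        if len(self.individual_ids) != m or len(self.populations) != m:
            raise DataError("sample sheet length does not match genotype columns")
        if any(not p for p in self.populations):
            raise DataError("every individual needs a non-empty population label")
        codes = np.unique(self.genotypes)
        allowed = {0, 1, 2, MISSING}
        if not set(codes.tolist()) <= allowed:
            raise DataError(f"invalid genotype codes {sorted(set(codes.tolist()) - allowed)}")
        if self.ploidy_mode == "pseudo_haploid" and (self.genotypes == 1).any():
            raise DataError("pseudo_haploid dataset contains heterozygous calls")
        for s in self.chromosome_slices().values():
            g = self.genetic_pos[s]
            if len(g) > 1 and (np.diff(g) < 0).any():
                raise DataError("genetic positions decrease within a chromosome")


def _detect_ploidy(genotypes: np.ndarray) -> str:
    return "diploid" if (genotypes == 1).any() else "pseudo_haploid"


def read_eigenstrat(
    geno_path,
    snp_path,
    ind_path,
    *,
    ploidy_mode: str | None = None,
) -> GenotypeDataset:
    """Read an EIGENSTRAT triplet.

    The .snp file needs at least six whitespace-separated columns
    (id, chromosome, genetic position in Morgans, physical position, alleles).
    SNPs are sorted by (chromosome block, genetic position) on load. Ploidy is
    autodetected (no code 1 anywhere => pseudo-haploid) unless `ploidy_mode`
    is given.
    """
    with open(ind_path) as fh:
        ind_rows = [line.split() for line in fh if line.strip()]
    for k, row in enumerate(ind_rows, 1):
        if len(row) < 3:
            raise FormatError(f"{ind_path}: line {k}: expected 'id sex population'")
    individual_ids = [r[0] for r in ind_rows]
    sexes = [r[1] for r in ind_rows]
    populations = [r[2] for r in ind_rows]
    m = len(individual_ids)

    ids, chroms, gpos, ppos, refs, alts = [], [], [], [], [], []
    with open(snp_path) as fh:
        for k, line in enumerate(fh, 1):
            if not line.strip():
                continue
            cols = line.split()
            if len(cols) < 6:
                raise FormatError(
                    f"{snp_path}: line {k}: expected >= 6 columns, got {len(cols)}"
                )
            try:
                g = float(cols[2])
            except ValueError:
                raise FormatError(
                    f"{snp_path}: line {k}: unparseable genetic position {cols[2]!r}"
                ) from None
            try:
                p = int(float(cols[3]))
            except ValueError:
                raise FormatError(
                    f"{snp_path}: line {k}: unparseable physical position {cols[3]!r}"
                ) from None
            ids.append(cols[0])
            chroms.append(cols[1])
            gpos.append(g)
            ppos.append(p)
            refs.append(cols[4])
            alts.append(cols[5])
    n = len(ids)

    rows = np.empty((n, m), dtype=np.int8)
    with open(geno_path) as fh:
        k = 0
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if len(line) != m:
                raise FormatError(
                    f"{geno_path}: line {lineno}: row length {len(line)} != {m} individuals"
                )
            rows[k] = np.frombuffer(line.encode("ascii"), dtype=np.uint8) - ord("0")
            k += 1
    if k != n:
        raise FormatError(f"{geno_path}: {k} genotype rows but {n} SNPs in {snp_path}")
    bad = ~np.isin(rows, (0, 1, 2, MISSING))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(f"{geno_path}: line {i + 1}: invalid genotype character")

    gpos_arr = np.asarray(gpos, dtype=np.float64)
    if n and not gpos_arr.any():
        raise DataError(
            "all genetic positions are zero; supply a genetic map in .snp column 3 "
            "(Morgans) - distances cannot be derived from physical positions"
        )

    # sort: chromosome blocks in first-appearance order, positions within
    chrom_arr = np.asarray(chroms, dtype=object)
    first_seen: dict[str, int] = {}
    for c in chroms:
        first_seen.setdefault(c, len(first_seen))
    block = np.array([first_seen[c] for c in chroms])
    order = np.lexsort((gpos_arr, block))

    ds = GenotypeDataset(
        snp_ids=np.asarray(ids, dtype=object)[order],
        chromosomes=chrom_arr[order],
        genetic_pos=gpos_arr[order],
        physical_pos=np.asarray(ppos, dtype=np.int64)[order],
        ref_alleles=np.asarray(refs, dtype=object)[order],
        alt_alleles=np.asarray(alts, dtype=object)[order],
        individual_ids=individual_ids,
        populations=populations,
        sexes=sexes,
        genotypes=rows[order],
        ploidy_mode=ploidy_mode or _detect_ploidy(rows),
    )
    ds.validate()
    return ds


def write_eigenstrat(dataset: GenotypeDataset, geno_path, snp_path, ind_path) -> None:
    """Write a canonical EIGENSTRAT triplet (missing written as '9').

    Genetic positions are written with `repr` so that read -> write round-trips
    exactly.
    """
    dataset.validate()
    with open(snp_path, "w") as fh:
        for s in dataset.snps():
            fh.write(
                f"{s.id} {s.chromosome} {s.genetic_pos!r} {s.physical_pos} "
                f"{s.ref_allele} {s.alt_allele}\n"
            )
    with open(ind_path, "w") as fh:
        for iid, sex, pop in zip(
            dataset.individual_ids, dataset.sexes, dataset.populations
        ):
            fh.write(f"{iid} {sex} {pop}\n")
    digits = (dataset.genotypes + ord("0")).astype(np.uint8)
    with open(geno_path, "wb") as fh:
        for row in digits:
            fh.write(row.tobytes() + b"\n")


def filter_sites(
    dataset: GenotypeDataset,
    target_pop: str,
    outgroup_ids: Sequence[str] = (),
) -> GenotypeDataset:
    """Keep SNPs informative for allele sharing in the analysis samples.

    A site survives when, across the target plus outgroup individuals, at least
    one genotype is non-missing and both alleles are observed. All-missing and
    monomorphic sites carry constant sharing (zero variance), so they cannot
    contribute to any correlation and are dropped. Idempotent; never reorders
    surviving SNPs.
    """
    members = dataset.members_of(target_pop)
    if not members:
        raise DataError(f"target population {target_pop!r} not in dataset")
    cols = dataset.columns_for(list(members) + list(outgroup_ids))
    g = dataset.genotypes[:, cols]
    has_ref = ((g == 0) | (g == 1)).any(axis=1)
    has_alt = ((g == 2) | (g == 1)).any(axis=1)
    keep = has_ref & has_alt
    if not keep.any():
        raise DataError("no informative sites after filtering")
    return dataset.subset_snps(np.flatnonzero(keep))


def select_outgroup(
    dataset: GenotypeDataset,
    target_pop: str,
    n_outgroup: int = 15,
    seed: int | None = None,
) -> list[str]:
    """Sample `n_outgroup` individuals uniformly without replacement from all
    populations other than the target. Deterministic given `seed`."""
    candidates = [
        iid
        for iid, pop in zip(dataset.individual_ids, dataset.populations)
        if pop != target_pop
    ]
    if len(candidates) < n_outgroup:
        raise DataError(
            f"only {len(candidates)} individuals outside {target_pop!r}; "
            f"need {n_outgroup} (lower n_outgroup or pass explicit ids)"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_outgroup, replace=False)
    return [candidates[i] for i in sorted(chosen)]
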