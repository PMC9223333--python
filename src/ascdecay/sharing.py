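"""Allele-sharing statistics and their decay profiles over genetic distance.

For every pair of individuals and every SNP we count the alleles identical by
state (0, 1 or 2); heterozygous genotypes share one allele with anything, so
no phase information is needed. The signal of a founder event is that sharing
counts at nearby SNPs are correlated, and that this correlation decays with
the genetic distance between the SNPs.

Two per-bin statistics are implemented:

* correlation mode (z): the mean, over SNP pairs in a distance bin, of the
  Pearson correlation between the two SNPs' sharing vectors taken across
  individual pairs; optionally corrected by subtracting the same statistic
  computed against an outgroup (z = z_w - z_c) to remove ancestral sharing.
* weighted covariance mode (w): the sharing covariance divided by the product
  of the two SNPs' expected heterozygosities. Pseudo-haploid calls and heavy
  missingness deflate the correlation's amplitude but not this statistic, so
  it is the estimator of choice for sparse/ancient data.

The engines here are the direct ("naive") O(N^2) SNP-pair implementations;
:mod:`ascdecay.fftengine` computes the same profiles via masked
autocorrelation on a genetic-distance mesh.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import MISSING, DataError, GenotypeDataset

__all__ = [
    "DistanceBins",
    "PairSharingMatrix",
    "ChromBinSums",
    "SharingProfile",
    "sharing_count",
    "sharing_values",
    "build_pair_sharing",
    "bin_snp_pairs",
    "within_pairs",
    "cross_pairs",
    "within_profile_naive",
    "cross_profile_naive",
    "corrected_profile",
    "expected_heterozygosity",
    "reference_allele_frequency",
    "weighted_cov_profile",
]


# ---------------------------------------------------------------------------
# distance bins
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceBins:
    """Half-open genetic-distance bins [left, right) in centimorgans.

    Defaults follow the standard profile: 0.1 to 30 cM in steps of 0.1 cM
    (D = 299 bins). The representative distance of a bin is its midpoint.
    """

    min_cM: float = 0.1
    max_cM: float = 30.0
    step_cM: float = 0.1

    def __post_init__(self):
        if not (0 <= self.min_cM < self.max_cM and self.step_cM > 0):
            raise ValueError("need 0 <= min < max and step > 0")
        n = (self.max_cM - self.min_cM) / self.step_cM
        if abs(n - round(n)) > 1e-9:
            raise ValueError("bin step must divide (max - min)")

    @property
    def n_bins(self) -> int:
        return int(round((self.max_cM - self.min_cM) / self.step_cM))

    @property
    def left_edges_cM(self) -> np.ndarray:
        return self.min_cM + self.step_cM * np.arange(self.n_bins)

    @property
    def right_edges_cM(self) -> np.ndarray:
        return self.left_edges_cM + self.step_cM

    @property
    def mid_cM(self) -> np.ndarray:
        return self.left_edges_cM + 0.5 * self.step_cM

    def index_of(self, d_cM: np.ndarray) -> np.ndarray:
        """Bin index per distance; -1 for distances outside [min, max)."""
        d_cM = np.asarray(d_cM, dtype=np.float64)
        # the small epsilon keeps distances that sit on a boundary up to fp
        # rounding (e.g. exactly min_cM) in their intended bin
        idx = np.floor((d_cM - self.min_cM) / self.step_cM + 1e-9).astype(np.int64)
        idx[(idx < 0) | (idx >= self.n_bins)] = -1
        return idx


# ---------------------------------------------------------------------------
# sharing counts
# ---------------------------------------------------------------------------

def sharing_count(g_a: int, g_b: int) -> int | None:
    """IBS alleles shared by two genotypes; None when either is missing.

    Heterozygotes share exactly one allele with any non-missing genotype,
    irrespective of phase; homozygotes share 2 (same) or 0 (opposite).
    """
    if g_a == MISSING or g_b == MISSING:
        return None
    if g_a == 1 or g_b == 1:
        return 1
    return 2 if g_a == g_b else 0


def sharing_values(ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    """Vectorized :func:`sharing_count`: float array with NaN for missing."""
    ga = np.asarray(ga)
    gb = np.asarray(gb)
    out = np.where((ga == 1) | (gb == 1), 1.0, 2.0 - np.abs(ga - gb))
    out[(ga == MISSING) | (gb == MISSING)] = np.nan
    return out


@dataclass
class PairSharingMatrix:
    """N x P matrix of IBS sharing counts plus the SNP map it refers to.

    `pair_index` lists the individual-id pairs (columns); `sharing` holds the
    counts as float32 with NaN where either member is missing.
    """

    pair_index: list[tuple[str, str]]
    sharing: np.ndarray
    chromosomes: np.ndarray
    genetic_pos: np.ndarray

    @property
    def n_snps(self) -> int:
        return self.sharing.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.sharing.shape[1]

    def chromosome_slices(self) -> dict[str, slice]:
        out: dict[str, slice] = {}
        start = 0
        chroms = self.chromosomes
        while start < len(chroms):
            stop = start
            while stop < len(chroms) and chroms[stop] == chroms[start]:
                stop += 1
            out[str(chroms[start])] = slice(start, stop)
            start = stop
        return out


def within_pairs(ids: Sequence[str]) -> list[tuple[str, str]]:
    """All M(M-1)/2 unordered pairs within one sample set."""
    ids = list(ids)
    return [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]


def cross_pairs(target_ids: Sequence[str], outgroup_ids: Sequence[str]) -> list[tuple[str, str]]:
    """All |A| x |O| target-by-outgroup pairs."""
    return [(a, x) for a in target_ids for x in outgroup_ids]


def build_pair_sharing(
    dataset: GenotypeDataset, pairs: Sequence[tuple[str, str]]
) -> PairSharingMatrix:
    """Elementwise sharing counts for the given individual pairs."""
    if not pairs:
        raise DataError("no individual pairs given")
    a_cols = dataset.columns_for([p[0] for p in pairs])
    b_cols = dataset.columns_for([p[1] for p in pairs])
    g = dataset.genotypes
    sharing = np.empty((dataset.n_snps, len(pairs)), dtype=np.float32)
    for k in range(len(pairs)):
        sharing[:, k] = sharing_values(g[:, a_cols[k]], g[:, b_cols[k]])
    return PairSharingMatrix(
        pair_index=[tuple(p) for p in pairs],
        sharing=sharing,
        chromosomes=np.asarray(dataset.chromosomes),
        genetic_pos=np.asarray(dataset.genetic_pos, dtype=np.float64),
    )


def bin_snp_pairs(
    chromosomes: np.ndarray, genetic_pos: np.ndarray, bins: DistanceBins
) -> dict[int, list[tuple[int, int]]]:
    """Map bin index -> list of intra-chromosome SNP index pairs (i, j), j > i.

    Enumerates pairs explicitly, so only suitable for small maps (the profile
    engines bin implicitly); used for inspection and as a testing surface.
    """
    pos_cM = np.asarray(genetic_pos, dtype=np.float64) * 100.0
    out: dict[int, list[tuple[int, int]]] = {}
    n = len(pos_cM)
    for i in range(n):
        for j in range(i + 1, n):
            if chromosomes[i] != chromosomes[j]:
                continue
            b = bins.index_of(np.array([pos_cM[j] - pos_cM[i]]))[0]
            if b >= 0:
                out.setdefault(int(b), []).append((i, j))
    return out


# ---------------------------------------------------------------------------
# profile container
# ---------------------------------------------------------------------------

@dataclass
class ChromBinSums:
    """Per-bin accumulator for one chromosome: sum of per-SNP-pair (or per
    pair-lag) statistic values and the count of contributions."""

    sums: np.ndarray
    counts: np.ndarray

    @classmethod
    def zeros(cls, n_bins: int) -> "ChromBinSums":
        return cls(np.zeros(n_bins), np.zeros(n_bins, dtype=np.int64))

    def __iadd__(self, other: "ChromBinSums") -> "ChromBinSums":
        self.sums += other.sums
        self.counts += other.counts
        return self


@dataclass
class SharingProfile:
    """Binned decay profile, kept per chromosome for the block jackknife.

    `mode` is 'correlation' or 'weighted_cov'. `within` holds z_w (or w);
    `cross` holds z_c when an outgroup correction is in use. Bins with no
    usable SNP pairs are absent (NaN in the pooled arrays), never zero.
    """

    bins: DistanceBins
    mode: str
    within: dict[str, ChromBinSums]
    cross: dict[str, ChromBinSums] | None = None
    snp_counts: dict[str, int] = field(default_factory=dict)
    engine: str = "naive"

    @property
    def chromosomes(self) -> list[str]:
        return list(self.within)

    @staticmethod
    def _pool(per_chrom: dict[str, ChromBinSums], exclude) -> tuple[np.ndarray, np.ndarray]:
        sums = None
        counts = None
        for chrom, acc in per_chrom.items():
            if chrom in exclude:
                continue
            if sums is None:
                sums = acc.sums.copy()
                counts = acc.counts.copy()
            else:
                sums += acc.sums
                counts += acc.counts
        if sums is None:
            raise DataError("no chromosomes left to pool")
        with np.errstate(invalid="ignore"):
            value = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        return value, counts

    def pooled(self, exclude: Sequence[str] = ()) -> tuple[np.ndarray, np.ndarray]:
        """(value, n_pairs) per bin pooled over chromosomes not in `exclude`.

        In correlation mode with an outgroup, value = z_w - z_c; bins absent
        in either component are absent in the result.
        """
        zw, nw = self._pool(self.within, exclude)
        if self.cross is None:
            return zw, nw
        zc, _ = self._pool(self.cross, exclude)
        return zw - zc, nw

    @property
    def z_w(self) -> np.ndarray:
        return self._pool(self.within, ())[0]

    @property
    def z_c(self) -> np.ndarray | None:
        if self.cross is None:
            return None
        return self._pool(self.cross, ())[0]

    @property
    def value(self) -> np.ndarray:
        return self.pooled()[0]

    @property
    def n_pairs(self) -> np.ndarray:
        return self.pooled()[1]

    def to_frame(self, per_chromosome: bool = False) -> pd.DataFrame:
        """Tabular export (pooled row set uses chromosome 'ALL')."""
        rows = []

        def block(label, within, cross):
            zw, nw = self._pool({label: within} if label != "ALL" else self.within, ())
            zc = None
            if cross is not None:
                zc = self._pool({label: cross} if label != "ALL" else self.cross, ())[0]
            val = zw if zc is None else zw - zc
            for k in range(self.bins.n_bins):
                rows.append(
                    {
                        "bin_left_cM": self.bins.left_edges_cM[k],
                        "bin_right_cM": self.bins.right_edges_cM[k],
                        "d_mid_cM": self.bins.mid_cM[k],
                        "z_w": zw[k],
                        "z_c": np.nan if zc is None else zc[k],
                        "z_or_w": val[k],
                        "n_snp_pairs": nw[k],
                        "chromosome": label,
                    }
                )

        block("ALL", None, self.cross)
        if per_chromosome:
            for chrom in self.within:
                block(chrom, self.within[chrom], None if self.cross is None else self.cross[chrom])
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# allele frequency helpers
# ---------------------------------------------------------------------------

def reference_allele_frequency(genotypes: np.ndarray) -> np.ndarray:
    """Per-SNP reference-allele frequency from non-missing genotypes.

    With genotype codes counting reference alleles, p = sum(g) / (2 n_obs).
    NaN where every genotype is missing.
    """
    g = np.asarray(genotypes, dtype=np.float64)
    obs = g != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, g, 0.0).sum(axis=1) / (2.0 * obs.sum(axis=1))
    return p


def expected_heterozygosity(p) -> np.ndarray:
    """He = 2 p (1 - p) for reference-allele frequency p in [0, 1]."""
    p = np.asarray(p, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequency outside [0, 1]")
    return 2.0 * p * (1.0 - p)


# ---------------------------------------------------------------------------
# naive engines
# ---------------------------------------------------------------------------

def _naive_chrom_sums(
    sharing: np.ndarray,
    pos_cM: np.ndarray,
    bins: DistanceBins,
    mode: str,
    he: np.ndarray | None,
) -> ChromBinSums:
    """Accumulate the per-SNP-pair statistic into distance bins for one
    chromosome.

    Correlation mode: Pearson r between the sharing vectors of the two SNPs
    across individual pairs, pairwise-complete; SNP pairs with fewer than two
    complete observations or zero variance on either side are skipped and do
    not count toward the bin. Weighted mode: pairwise-complete sample
    covariance (denominator n-1) divided by He_i * He_j.
    """
    acc = ChromBinSums.zeros(bins.n_bins)
    n, p = sharing.shape
    if n < 2:
        return acc
    complete = not np.isnan(sharing).any()
    # j-window per i from the distance range
    j_lo = np.searchsorted(pos_cM, pos_cM + bins.min_cM - 1e-12, side="left")
    j_hi = np.searchsorted(pos_cM, pos_cM + bins.max_cM - 1e-12, side="left")
    j_lo = np.maximum(j_lo, np.arange(n) + 1)

    if complete:
        mean = sharing.mean(axis=1, dtype=np.float64)
        centered = sharing.astype(np.float64) - mean[:, None]
        sq = np.einsum("ij,ij->i", centered, centered)
        if mode == "correlation":
            with np.errstate(invalid="ignore", divide="ignore"):
                rows = centered / np.sqrt(sq)[:, None]
            valid_row = sq > 0
        else:
            rows = centered
            valid_row = np.ones(n, dtype=bool)
        block = 2048
        for b0 in range(0, n, block):
            b1 = min(b0 + block, n)
            w0 = int(j_lo[b0:b1].min(initial=n))
            w1 = int(j_hi[b0:b1].max(initial=0))
            if w0 >= w1:
                continue
            stat = rows[b0:b1] @ rows[w0:w1].T
            if mode == "weighted_cov":
                # covariance of sharing FRACTIONS (counts / 2): on the 0..1
                # match scale the He-normalized covariance has the same
                # amplitude I_f e^-1 as the correlation statistic
                stat /= 4.0 * (p - 1)
                stat /= np.outer(he[b0:b1], he[w0:w1])
            dist = pos_cM[w0:w1][None, :] - pos_cM[b0:b1][:, None]
            binidx = bins.index_of(dist.ravel()).reshape(dist.shape)
            jj = np.arange(w0, w1)[None, :]
            ok = (binidx >= 0) & (jj >= j_lo[b0:b1, None]) & (jj < j_hi[b0:b1, None])
            if mode == "correlation":
                ok &= valid_row[b0:b1, None] & valid_row[None, w0:w1]
            if not ok.any():
                continue
            acc.sums += np.bincount(binidx[ok], weights=stat[ok], minlength=bins.n_bins)
            acc.counts += np.bincount(binidx[ok], minlength=bins.n_bins)
        return acc

    # missing-data path: per-SNP loop, vectorized across the j-window
    s = sharing.astype(np.float64)
    obs = ~np.isnan(s)
    s0 = np.where(obs, s, 0.0)
    for i in range(n):
        lo, hi = j_lo[i], j_hi[i]
        if lo >= hi:
            continue
        both = obs[lo:hi] & obs[i]
        cnt = both.sum(axis=1)
        xi = np.where(both, s0[i], 0.0)
        xj = np.where(both, s0[lo:hi], 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sx = xi.sum(axis=1)
            sy = xj.sum(axis=1)
            sxx = (xi * xi).sum(axis=1)
            syy = (xj * xj).sum(axis=1)
            sxy = (xi * xj).sum(axis=1)
            cov = sxy - sx * sy / np.maximum(cnt, 1)
            vx = sxx - sx * sx / np.maximum(cnt, 1)
            vy = syy - sy * sy / np.maximum(cnt, 1)
            if mode == "correlation":
                stat = cov / np.sqrt(vx * vy)
                usable = (cnt >= 2) & (vx > 1e-12) & (vy > 1e-12)
            else:
                # fraction scale: cov(A_i/2, A_j/2) = cov/4
                stat = cov / (4.0 * np.maximum(cnt - 1, 1)) / (he[i] * he[lo:hi])
                usable = cnt >= 2
        binidx = bins.index_of(pos_cM[lo:hi] - pos_cM[i])
        usable &= binidx >= 0
        if usable.any():
            acc.sums += np.bincount(binidx[usable], weights=stat[usable], minlength=bins.n_bins)
            acc.counts += np.bincount(binidx[usable], minlength=bins.n_bins)
    return acc


def _profile_from_psm(
    psm: PairSharingMatrix,
    bins: DistanceBins,
    mode: str,
    he: np.ndarray | None = None,
) -> dict[str, ChromBinSums]:
    per_chrom: dict[str, ChromBinSums] = {}
    for chrom, sl in psm.chromosome_slices().items():
        he_c = None if he is None else np.asarray(he, dtype=np.float64)[sl]
        per_chrom[chrom] = _naive_chrom_sums(
            psm.sharing[sl], psm.genetic_pos[sl] * 100.0, bins, mode, he_c
        )
    return per_chrom


def within_profile_naive(psm: PairSharingMatrix, bins: DistanceBins) -> SharingProfile:
    """Within-population allele-sharing correlation z_w(d), direct engine."""
    if psm.n_pairs < 2:
        raise DataError("need at least two individual pairs for a correlation")
    within = _profile_from_psm(psm, bins, "correlation")
    prof = SharingProfile(bins=bins, mode="correlation", within=within)
    if not any(acc.counts.any() for acc in within.values()):
        raise DataError("profile empty: every SNP pair was skipped")
    return prof


def cross_profile_naive(
    dataset: GenotypeDataset,
    target_pop: str,
    outgroup_ids: Sequence[str],
    bins: DistanceBins,
) -> SharingProfile:
    """Cross-population allele-sharing correlation z_c(d) over target x
    outgroup individual pairs."""
    target_ids = dataset.members_of(target_pop)
    if not outgroup_ids:
        raise DataError("outgroup is empty")
    if set(outgroup_ids) & set(target_ids):
        raise DataError("outgroup overlaps the target population")
    psm = build_pair_sharing(dataset, cross_pairs(target_ids, list(outgroup_ids)))
    return within_profile_naive(psm, bins)


def corrected_profile(z_w: SharingProfile, z_c: SharingProfile) -> SharingProfile:
    """Combine within and cross profiles into the corrected z = z_w - z_c."""
    if z_w.bins != z_c.bins:
        raise DataError("within and cross profiles use different bins")
    if z_w.mode != "correlation" or z_c.mode != "correlation":
        raise DataError("corrected profile requires correlation mode on both sides")
    if list(z_w.within) != list(z_c.within):
        raise DataError("within and cross profiles cover different chromosomes")
    return SharingProfile(
        bins=z_w.bins,
        mode="correlation",
        within=z_w.within,
        cross=z_c.within,
        snp_counts=dict(z_w.snp_counts),
        engine=z_w.engine,
    )


def weighted_cov_profile(
    psm: PairSharingMatrix, he: np.ndarray, bins: DistanceBins
) -> SharingProfile:
    """Weighted allele-sharing covariance w(d) = cov(A_i, A_j) / (He_i He_j)."""
    he = np.asarray(he, dtype=np.float64)
    if len(he) != psm.n_snps:
        raise DataError("He vector length does not match SNP count")
    if np.any(he <= 0):
        raise DataError("He must be positive at every used SNP (filter sites first)")
    if psm.n_pairs < 2:
        raise DataError("need at least two individual pairs for a covariance")
    within = _profile_from_psm(psm, bins, "weighted_cov", he)
    prof = SharingProfile(bins=bins, mode="weighted_cov", within=within)
    if not any(acc.counts.any() for acc in within.values()):
        raise DataError("profile empty: every SNP pair was skipped")
    return prof
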