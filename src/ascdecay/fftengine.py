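"""FFT engine: decay profiles via product sums on a genetic-distance mesh.

The direct engine iterates over SNP pairs (O(N^2) in the number of SNPs).
This engine computes the same binned statistic in O(n log n) per individual
pair by a change of summation order. For the correlation statistic, each
SNP's sharing vector is first standardized across individual pairs
(u_{i,pi} = (c_{i,pi} - mean_pi) / sd_pi), which turns the Pearson
correlation between two SNPs into a plain mean of products:
r(i, j) = (1/P) sum_pi u_i u_j. The bin value - the mean of r over the SNP
pairs in a distance bin - is then a single ratio of pooled sums,

    z(d) = sum_{pi, (i,j) in S_d} u_i u_j / (P |S_d|),

and the inner sums over SNP pairs at a fixed genetic lag are
cross-correlation sums, computed for all lags at once with FFTs of each
pair's standardized sharing rasterized onto mesh points spaced every delta
centimorgans. The weighted-covariance statistic factorizes the same way with
v_i = (c_i - mean_pi) / He_i and an overall P/(P-1) to match the direct
engine's sample-covariance denominator.

Missingness is handled with an occupancy mask per pair: a second FFT gives
the number of co-occupied cell pairs per lag, so pooled sums divide by the
exact product count. SNPs with zero across-pair variance (or zero He) are
masked out, mirroring the direct engine's skip rule. Mesh assignment to the
nearest point (distance distortion at most delta/2) is the only
approximation on complete one-SNP-per-cell meshes; cells receiving several
SNPs store their mean. The engine is deterministic.
"""
from __future__ import annotations

import warnings

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft

from .io import DataError
from .sharing import ChromBinSums, DistanceBins, PairSharingMatrix, SharingProfile

__all__ = ["MeshSpec", "build_mesh", "fft_profile"]

_PAIR_CHUNK = 48
_SD_TOL = 1e-9


@dataclass(frozen=True)
class MeshSpec:
    """Mesh of equally spaced genetic positions, spacing `delta_cM`.

    The default 0.001 cM puts 100 mesh points inside each default 0.1 cM bin
    and bounds the distance distortion of nearest-point assignment by
    delta/2 = 0.0005 cM.
    """

    delta_cM: float = 0.001

    def __post_init__(self):
        if self.delta_cM <= 0:
            raise ValueError("mesh spacing must be positive")


def build_mesh(
    values: np.ndarray, pos_cM: np.ndarray, delta_cM: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize one value vector onto the mesh of one chromosome.

    Each SNP is assigned to its nearest mesh point; cells receiving several
    SNPs store the mean of their non-missing values. Returns (mesh_values,
    occupancy_mask); unoccupied cells hold 0 and mask False.
    """
    pos_cM = np.asarray(pos_cM, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    cell = np.rint((pos_cM - pos_cM[0]) / delta_cM).astype(np.int64)
    n_cells = int(cell[-1]) + 1
    obs = ~np.isnan(values)
    cnt = np.bincount(cell[obs], minlength=n_cells).astype(np.float64)
    tot = np.bincount(cell[obs], weights=values[obs], minlength=n_cells)
    mask = cnt > 0
    out = np.zeros(n_cells)
    out[mask] = tot[mask] / cnt[mask]
    return out, mask


def _corr(Fa: np.ndarray, Fb: np.ndarray, pad: int, lo: int, hi: int) -> np.ndarray:
    """Cross-correlation sums C_ab(tau) = sum_i a_i b_{i+tau}, tau in [lo, hi]."""
    return sfft.irfft(np.conj(Fa) * Fb, pad, axis=1)[:, lo : hi + 1]


def fft_profile(
    psm: PairSharingMatrix,
    bins: DistanceBins,
    mesh: MeshSpec = MeshSpec(),
    mode: str = "correlation",
    he: np.ndarray | None = None,
) -> SharingProfile:
    """Binned decay profile via mesh product sums; same statistic as the
    direct engine.

    In weighted mode `he` gives per-SNP expected heterozygosities; each SNP's
    centered sharing is divided by its He before rasterization, so the
    weighting is exact at SNP level.
    """
    if mode not in ("correlation", "weighted_cov"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "weighted_cov":
        if he is None:
            raise DataError("weighted mode needs per-SNP He values")
        he = np.asarray(he, dtype=np.float64)
        if len(he) != psm.n_snps:
            raise DataError("He vector length does not match SNP count")
        if np.any(he <= 0):
            raise DataError("He must be positive at every used SNP")
    delta = mesh.delta_cM
    n_pairs = psm.n_pairs
    if n_pairs < 2:
        raise DataError("need at least two individual pairs")
    # matches the direct engine's cov denominator (P-1) after pooling
    scale = n_pairs / (n_pairs - 1.0) if mode == "weighted_cov" else 1.0
    per_chrom: dict[str, ChromBinSums] = {}

    for chrom, sl in psm.chromosome_slices().items():
        pos = psm.genetic_pos[sl] * 100.0  # cM
        acc = ChromBinSums.zeros(bins.n_bins)
        per_chrom[chrom] = acc
        if len(pos) < 2 or pos[-1] - pos[0] <= 0:
            warnings.warn(f"chromosome {chrom}: zero genetic length, skipped")
            continue
        cell = np.rint((pos - pos[0]) / delta).astype(np.int64)
        n_cells = int(cell[-1]) + 1
        lag_lo = int(np.ceil(bins.min_cM / delta - 1e-9))
        lag_hi = min(int(np.ceil(bins.max_cM / delta - 1e-9)) - 1, n_cells - 1)
        if lag_hi < lag_lo:
            continue
        lags = np.arange(lag_lo, lag_hi + 1)
        binidx = bins.index_of(lags * delta)
        # contiguous runs of equal bin index -> reduceat boundaries
        starts = np.flatnonzero(np.diff(binidx, prepend=binidx[0] - 1))
        run_bins = binidx[starts]
        keep_run = run_bins >= 0
        pad = sfft.next_fast_len(n_cells + lag_hi + 1)

        # standardize each SNP across individual pairs; zero-variance SNPs
        # (and, in weighted mode, zero-He SNPs, excluded upstream) get NaN
        # and drop out of the mesh, mirroring the direct engine's skip rule
        # standardize in place to keep the peak footprint at one float64
        # copy of the chromosome's sharing block
        u = psm.sharing[sl].astype(np.float64)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            u -= np.nanmean(u, axis=1, keepdims=True)
            if mode == "correlation":
                sd = np.nanstd(u, axis=1)
                sd[sd <= _SD_TOL] = np.nan
                u /= sd[:, None]
            else:
                # sharing-fraction scale (counts / 2), He-normalized: the
                # product sums then reproduce the direct engine's
                # cov(A_i/2, A_j/2) / (He_i He_j)
                u /= 2.0 * he[sl][:, None]

        for c0 in range(0, n_pairs, _PAIR_CHUNK):
            c1 = min(c0 + _PAIR_CHUNK, n_pairs)
            k = c1 - c0
            # rasterize per-cell SUMS and SNP counts: cross-products between
            # cell sums expand to the exact sum over SNP-pair products, and
            # count cross-correlation gives the exact product count, so cells
            # holding several SNPs introduce no averaging error
            V = np.zeros((k, pad))
            Ct = np.zeros((k, pad))
            for j in range(k):
                vals = u[:, c0 + j]
                obs = ~np.isnan(vals)
                Ct[j, :n_cells] = np.bincount(cell[obs], minlength=n_cells)
                V[j, :n_cells] = np.bincount(
                    cell[obs], weights=vals[obs], minlength=n_cells
                )
            Fv = sfft.rfft(V, pad, axis=1)
            Fm = sfft.rfft(Ct, pad, axis=1)
            prod = _corr(Fv, Fv, pad, lag_lo, lag_hi)
            n = np.rint(_corr(Fm, Fm, pad, lag_lo, lag_hi))
            run_sums = np.add.reduceat(prod, starts, axis=1).sum(axis=0)
            run_cnts = np.add.reduceat(n, starts, axis=1).sum(axis=0)
            acc.sums += scale * np.bincount(
                run_bins[keep_run], weights=run_sums[keep_run], minlength=bins.n_bins
            )
            acc.counts += np.bincount(
                run_bins[keep_run], weights=run_cnts[keep_run], minlength=bins.n_bins
            ).astype(np.int64)

    prof = SharingProfile(bins=bins, mode=mode, within=per_chrom, engine="fft")
    if not any(acc.counts.any() for acc in per_chrom.values()):
        raise DataError("profile empty: no co-occupied mesh cells at any lag")
    return prof
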