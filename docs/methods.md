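# Methods

## Model

A founder event is a transient reduction of a population's effective size to
*N_f* diploids for *D_f* generations, ending *T_f* generations before
sampling, followed by recovery to the pre-event size *N_o*. During the
bottleneck a pair of lineages coalesces with probability ≈ D_f/(2N_f) per
pair, which we call the founder intensity I_f; pairs that coalesce then share
long haplotypes whose present-day length distribution is governed by the
recombination that has happened in the T_f generations since.

The observable is identity-by-state allele sharing between individuals,
N_{a,b,i} ∈ {0, 1, 2} at SNP i (heterozygous genotypes share one allele with
any non-missing genotype, making the statistic phase-free). Writing z(d) for
the mean Pearson correlation of sharing between SNPs at genetic distance d
(within-population, minus the same quantity against an outgroup to remove
ancestral sharing), a one-generation recursion — decay (1−d)² from
recombination and (1 − 1/2N) from drift — integrates to

    z(d) = I_f · e^{−(1 + 2 d T_f)}         (d in Morgans)

under three stated approximations: a single recombination event between SNP
pairs (d small), no recombination *during* the bottleneck, and equilibrium
beforehand (which contributes the e^{−1} through the 2N_o-generation
coalescence time of the pre-event population). The fitted form is
o(d) = a·e^{−2dt} + c with the affine offset c absorbing residual
distance-independent covariance (sampling noise, uncorrected background
relatedness); then Î_f = e·a and T̂_f = t per Morgan (100·t when d is in
cM).

### What the age estimate means for a prolonged bottleneck

Because the derivation treats all bottleneck coalescences as happening at one
time, while in the coalescent they spread over [T_f, T_f + D_f], the fitted
decay rate is a mixture of rates 2u for u across that window. For
N_f ≫ D_f the coalescence density within the bottleneck is nearly uniform,
so the estimator's expectation sits mid-window, ≈ T_f + D_f/2. We verified
this with the simulator: T_f=10, D_f=20, N_f=100 gives T̂_f ≈ 18 (CI width
~±3 at full scale), while a single-generation bottleneck of the same
intensity (D_f=1, N_f=5) gives T̂_f ≈ 9.5 with the CI covering 10. Age
checks in the test suite therefore treat the interval [T_f, T_f + D_f] as
the expectation for simulated truths; intensity has no such ambiguity and is
checked as a point value.

## Statistics

**Correlation mode (diploid data, outgroup available).** Per distance bin
(default 0.1–30 cM in 0.1 cM steps; bin abscissa = midpoint), the unweighted
mean over SNP pairs of Pearson r between the two SNPs' sharing vectors taken
across individual pairs, pairwise-complete over non-missing pairs; SNP pairs
with fewer than two complete observations or zero variance are skipped. The
corrected profile subtracts the target×outgroup statistic bin-wise. Bins
with no usable SNP pairs are absent (NaN), never zero. Cross-chromosome SNP
pairs are excluded; per-bin sums and counts are kept per chromosome and
pooled, which both reproduces the global mean over SNP pairs and feeds the
jackknife.

**Weighted covariance mode (pseudo-haploid / sparse data, no outgroup).**
Pseudo-haploid calls delete heterozygotes, deflating the correlation's
amplitude (ages survive; intensities do not). Writing the sharing *fraction*
s_i = N_{a,b,i}/2 and the expected heterozygosity He_i = 2p_i(1−p_i)
(reference-allele frequency from the target samples' non-missing genotypes),
the pseudo-haploid match indicator satisfies E[s_i | IBD state] =
1 − He_i·(1 − IBD_i), so

    cov(s_i, s_j) = He_i He_j · cov(IBD_i, IBD_j),

and w(i,j) = cov(s_i, s_j)/(He_i·He_j) = cov(N_i, N_j)/(4·He_i·He_j) has
the same amplitude I_f e^{−1} as the correlation statistic. The covariance
is the pairwise-complete sample covariance (denominator n−1). We verified
empirically that on pseudo-haploidized data with 50% missingness the
weighted intensity lands inside the diploid correlation estimate's CI, while
the uncorrected correlation underestimates it roughly two-fold. On fully
heterozygous diploid data the weighted statistic is not calibrated the same
way (it is the estimator for single-allele data); the pipeline selects it
automatically only for pseudo-haploid input or when no outgroup is given.

## Engines

**Direct engine.** O(N²) over SNP pairs within a distance window, vectorized:
on complete data, rows are standardized once and bin sums come from blocked
matrix products; with missing data, a per-SNP loop computes
pairwise-complete statistics against the SNP's whole distance window at
once.

**FFT engine.** The Pearson correlation across individual pairs becomes a
plain product once each SNP's sharing vector is standardized across pairs
(u_{i,π} = (N_{i,π} − mean_π)/sd_π): r(i,j) = Σ_π u_i u_j / P. The binned
mean over SNP pairs is then a single ratio of pooled product sums, and the
inner sums over SNP pairs at a fixed genetic lag are cross-correlation sums.
Each pair's u-vector is rasterized onto mesh points every δ cM (default
0.001, i.e. 100 lags per 0.1 cM bin; nearest-point assignment bounds the
distance distortion by δ/2); cells accumulate *sums* and *SNP counts*, so
cells holding several SNPs contribute their exact SNP-level cross-products
and counts (no averaging error). Two real FFTs per pair chunk (values and
counts) give, per lag, the product sum and the exact number of SNP-pair
products, accumulated into bins per chromosome. Missing genotypes simply
leave cells empty for that pair. Zero-variance SNPs (and, in weighted mode,
the per-SNP 1/(2He) weighting) are applied before rasterization, so the
engine skips exactly what the direct engine skips. On meshes with one SNP
per cell the two engines agree to machine precision; on simulated data at
δ = 0.001 cM the maximum per-bin difference is ~6×10⁻⁴ (discretization
only). The engine is deterministic and O(P · L log L) for mesh length L.

Design note: an alternative reading of the mesh approach — per-lag Pearson
autocorrelation of each pair's raw mesh values, centered per pair — was
implemented first and rejected: the per-SNP mean across pairs (the
allele-frequency profile) then dominates the along-chromosome variance and
per-pair centering removes each pair's baseline sharing, producing a
statistic systematically ~3–4× smaller than the SNP-pair correlation and not
interchangeable with the direct engine.

## Fitting and uncertainty

Bounded trust-region least squares (a ∈ [0,1], t ∈ [0, 20 per cM] — capping
T̂_f at 2,000 — c free), initialized from a log-linear regression of
offset-corrected positive bins (offset guess = mean of the last decile of
bins; fallback: first-bin amplitude, t = 1 per cM). At least 10 non-absent
bins are required; a fit ending on the t bound is flagged not converged. Fit
quality: NRMSD = RMS(z − ẑ) / (max ẑ − min ẑ) over non-absent bins; a
constant fitted curve has no range and is reported as a degenerate fit
(infinite NRMSD downstream).

Uncertainty: delete-one-chromosome jackknife, refitting on the pooled bins
of the remaining chromosomes, with block weights w_j proportional to SNP
counts. The point estimate is the weighted mean Σ w_j θ̂_(−j); the variance
follows the weighted block-jackknife of Busing, Meijer & van der Leeden
(1999), with h_j = 1/w_j and θ̂ the full-data fit:

    θ̃  = g·θ̂ − Σ_j (1 − 1/h_j)·θ̂_(−j)
    var = (1/g) Σ_j (h_j·θ̂ − (h_j−1)·θ̂_(−j) − θ̃)² / (h_j − 1)

which reduces to the classical delete-one jackknife for equal weights (unit
tested). CI95 = estimate ± 1.96·SE (normal approximation). At least three
usable blocks are required; if more than 20% of replicates fail to fit, the
jackknife fails.

Significance requires all four of: both CIs exclude 0; T̂_f < 200
generations (configurable `max_age`; e.g. 300 for deep-time ancient-DNA
comparisons) with SE < 50; Î_f > 0.5%; NRMSD < 0.29. All thresholds are
strict inequalities.

## Simulator

msprime coalescent, two populations (target A, outgroup O) of diploid size
N_o = 12,500 diverged 1,800 generations ago; the bottleneck is an epoch of
size N_f on A over [T_f, T_f + D_f]. Genome: 20 chromosomes × 50 Mb,
mutation 1.2×10⁻⁸ and recombination 1×10⁻⁸ per bp per generation (constant
map, 1 cM/Mb, so positions in Morgans are bp × 10⁻⁸). Thirty haploid
genomes per population are paired at random without replacement —
consistently across chromosomes — into 15 diploids. Only biallelic sites
with actual sample variation are emitted (stacked/back mutations can leave
invariant "biallelic" sites). Variants: a no-event control (N_f = None); an
admixture model where A forms 110 generations ago as a 60/40 pulse of two
sources that diverged 1,800 generations ago (outgroup = first source);
pseudo-haploidization (heterozygote → fair-coin homozygote) and uniform
missingness. All generators are deterministic given the config seed; nominal
(T_f, I_f) are recorded in dataset metadata.

What the simulations do not emulate: array ascertainment (simulated SNP
density is ~15× a genotyping array's; the engine-equivalence test thins to
array-like density for the direct engine's benefit), variable recombination
maps, sequencing error beyond uniform missingness, and selection. Passing
tests therefore validate the estimator under the model's own generative
assumptions, not robustness to real-data artifacts.

## Problem sizes used in the test suite

Chosen so the suite runs on one CPU at desk scale: one full-scale recovery
run (20 × 50 Mb, all defaults); replicate studies (coverage, false-discovery)
at 5 chromosomes × 15 Mb × 20 replicates; engine equivalence on 2 × 50 Mb
thinned 10× for the direct engine; pseudo-haploid correction on 6 × 20 Mb.
Replicate profiles use δ = 0.002 cM (50 lags per bin; equivalence to the
direct engine is unchanged at this δ within ~10⁻³). The acceptance script
uses the full-scale setup with δ = 0.001 cM.

## Detection floor: recent coalescence in small panmictic populations

Any pair of lineages in a population of effective size N coalesces at rate
1/2N per generation, so even without a founder event the allele-sharing
correlation carries a background

    z_bg(d) ≈ e^{−1} / (1 + 4Nd),

the method's analogue of background linkage disequilibrium. An outgroup only
cancels the part of this background older than the target–outgroup
separation. Fitting the model exponential to the noiseless background at
N = 12,500 yields T̂ ≈ 130 generations, Î ≈ 1.7%, NRMSD ≈ 0.02 — a
formally significant "founder event" that simply describes the population's
small size. Consequences:

- A constant-size population below N ≈ 40,000 paired with a deeply diverged
  outgroup is *expected* to produce a significant call; this is a real
  property of the statistic, not a false positive in the software, and the
  test suite documents it (the deep-outgroup constant-size control is
  flagged in most replicates, matching the analytic prediction).
- The practically meaningful negative control — and the estimator's
  practical usage — pairs the target with an outgroup that shares its
  recent history (e.g. random individuals of the same broad ancestry), so
  z_c removes the background; with an outgroup separated 10 generations
  ago, no-event simulations yield no significant calls.
- Interpreted positively: the 0.5% intensity gate corresponds to a
  detection floor of roughly N ≲ 40,000 for the recent effective size, and
  founder-event calls in populations suspected of persistently small N
  should be read as dating "recent strong drift", which the bottleneck and
  the small-constant-size histories both produce.

## Known limitations

- The age estimate dates the bottleneck's coalescences, not its endpoint
  (band [T_f, T_f + D_f] above); reporting conventions that need the end of
  the event should subtract an assumed D_f/2.
- No model selection among alternative histories (exponential growth,
  no-recovery, two epochs): a significant call means "decay consistent with
  a founder event", and two successive events yield intermediate parameters
  (dominated by the stronger event).
- Only the ratio I_f = D_f/(2N_f) is identifiable, not D_f and N_f
  separately.
- The weighted covariance assumes He is estimated without bias from the
  analysis samples; with very few target samples He (and hence Î_f) gets
  noisy, which is why runs warn below six samples.
- CI95 uses a normal approximation on ~20 jackknife blocks (fewer in reduced
  runs); coverage below the nominal 95% is expected when only a handful of
  chromosomes are available.
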