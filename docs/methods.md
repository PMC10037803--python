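# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package, and what the synthetic-data generator does and
does not emulate.

## Data model and conventions

Dosage is the alternate-allele count (0/1/2, `nan` missing); inbred lines
are effectively homozygous, so fixtures use {0, 2} and all
frequency-based estimators treat a line as a single haploid allele draw
(its two chromosomes are not independent). Coordinates are 1-based
inclusive internally; BED I/O converts to 0-based half-open explicitly.
Effect signs are reported per alternate allele. Missing dosages are
mean-imputed per marker only inside kinship/PC computation; association
scans use pairwise-complete observations and the mixed model skips
markers with missing calls.

## Synthetic-data generator

The generator emulates the statistical structure of a replicated RNA-seq
diversity panel of inbred lines from two diverged subpopulations.

**Genotypes.** Per marker, an ancestral frequency `p` is drawn (uniform,
kept away from the MAF floor) and subpopulation frequencies follow the
Balding–Nichols model, `p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F)`; each line
contributes one allele draw, giving dosages {0, 2} with no heterozygotes.
Local LD is produced by three AR(1) Gaussian-copula fields sharing a
`exp(−d / ld_scale_bp)` decay (default 150 kb): a per-line haplotype
field, an ancestral-frequency field, and per-subpopulation
Balding–Nichols quantile fields. The copulas leave site marginals
untouched, so allele-frequency structure — and hence E[Fst] = F — is
exactly Balding–Nichols; nearby sites share both haplotype background and
frequency, giving r² that decays with distance. At the default desk-scale
marker spacing (~4 kb) this reproduces the dense-map regime in which an
association peak is tagged by many correlated SNPs, which the ≥ 3-SNP
peak rule requires. Markers whose realized pooled MAF falls below the
floor have their ancestral frequency pulled toward 0.5 and are redrawn on
the *same* latent fields, preserving LD; the floor then holds for ≥ 99%
of markers (in practice all). Fst calibration is assessed with
`ld_scale_bp = 0`: the calibration concerns the frequency model, and with
LD on, the reduced number of effectively independent loci inflates the
genome-wide estimator's sampling variance without biasing it.

**Expression.** Built on the log scale, where variance components are
exact: `y = μ_g + t(genotype) + a(genotype) + e(replicate)`, exponentiated
to an FPKM-like scale (nonnegative, right-skewed — so the Box-Cox step
downstream has real work to do; its fitted λ ≈ 0 recovers the log scale
up to an affine map, under which H² is invariant). Total log-variance
defaults to 0.25. Per gene, the genotype-level fraction equals the target
H²; planted cis effects are scaled so that the causal marker explains the
stated fraction (PVE) of *genotype-mean* variance `σ²_G + σ²_E/r`, which
is what an OLS of genotype means on the causal marker estimates. Module
genes additionally load (share 0.7 of their remaining genotype variance)
on a shared activation: the module's driver-marker dosage plus a small
heavy-tailed (t₃) term. Drivers are drawn with pooled MAF in (0.05, 0.09)
— a standardized Bernoulli(p) activation has kurtosis `(1−6pq)/pq + 3`,
well above the retention cut of 6 only for rare p — are kept out of
planted sweep regions (sweep resampling would destroy their frequency),
and are forced ≥ 4 LD scales apart so module activations stay separable
by ICA.

**Splicing.** Intron coverage sums are `Poisson(rate × size)` and
junction counts `Poisson(PSI_target × rate)` with a Gamma-distributed
per-sample rate, so expected PSI equals the genotype-dependent target;
planted sQTLs shift the PSI target per alternate allele. Zero expression
yields zero depth and hence missing PSI downstream.

**Sweeps.** Inside a planted region the swept population is resampled to
fixation (post-sweep diversity ≈ 0) and the other population offset by
the target frequency gap; outside markers are untouched. Phenotypes are
`exp(linear predictor + Gaussian noise)`, so the log transform used by
the GWAS stage is always defined.

**What the generator does not emulate** — and therefore what passing
tests do not show about real data: coalescent genealogies (LD is
stationary AR(1), no recombination hotspots or haplotype blocks of
varying age), allele-frequency spectra from demography, expression count
noise (FPKM is lognormal, not NB read counts), shared batch/technical
structure across genes, GO-term correlation structure, multi-allelic
sites and indels, genotyping error and missingness patterns.

## Estimators and numerics

**REML for H².** The one-way random-intercept REML criterion is profiled
analytically: with γ = σ²_G/σ²_E and group weights `w_i = n_i/(1+n_i γ)`,
the GLS mean, quadratic form and residual variance have closed forms, and
a bounded 1-D search over log γ (± 14) finds the optimum; the γ → 0
boundary is checked explicitly and negative components clamp to zero.
Only genotypes with ≥ 2 replicates enter the fit. Constant input returns
H² = 0 with a flag. Tests verify agreement with an independent
full-covariance matrix REML oracle to 1e-4 and with expected-mean-squares
ANOVA on balanced designs.

**Box-Cox.** λ by profile maximum likelihood on a grid [−2, 2] step 0.01
(log branch at λ = 0), shift `−min + 1e-6` only when values are
nonpositive, output standardized. Matches `scipy.stats.boxcox_normmax`
to grid precision.

**Association.** The fast path residualizes traits and dosages against
the covariate QR basis and converts correlations to t statistics
(df = n − p − 1); markers with missing data fall back to per-marker
least squares on complete rows (≥ 20 required). The mixed model is
EMMA-style: one spectral decomposition of the kinship, a single REML
estimate of the variance ratio under the null, then per-marker GLS Wald
tests in the rotated basis. Peak grouping merges consecutive significant
SNPs < 1 Mb apart (run-splitting on sorted positions; lead = minimum p,
ties to the smaller position) and is verified against a naive
single-linkage oracle. PVE is in-sample R² of lead dosages (cumulative:
joint OLS; per-peak: marginal) and is upwardly biased by construction;
collinear leads are greedily dropped. The permutation null shuffles
genotype rows only, keeping trait/covariate alignment, and pools
`-log10(min p)` across traits and permutations (default 100
permutations).

**Fst / π.** Weir–Cockerham variance components on haploid allele
samples, windowed as ratio-of-sums (better small-sample behavior than
mean-of-ratios and the convention of the standard tools). π sums per-SNP
unbiased heterozygosity `2p̂(1−p̂)n/(n−1)` over a window divided by window
bp; absolute π underestimates sequence diversity (monomorphic sites are
not modeled) but the tropical/temperate π-ratio QC uses the same
convention in numerator and denominator. A fully swept window can have
π = 0 in the swept population; the resulting infinite ratio counts as
passing QC (maximal diversity loss) and is excluded from the genome-wide
mean.

**XP-CLR.** Model class: reference frequency p₁ observed (shrunk off the
boundary by `(k+0.5)/(n+1)`, since the drift law is degenerate at 0/1);
neutral law for the object frequency `q ~ N(p₁, ω·p₁(1−p₁))`, truncated
to [0, 1] with tail mass as point masses on the boundaries; sweep
alternative compounds the neutral drift with the post-sweep transform
`q → c·q + (1−c)·Bernoulli(q)` where the escape probability is
`c = 1 − exp(−r/s)` (r = map distance in Morgans to the grid point,
s maximized over a log-spaced grid of 100 values whose small-c limit is
the neutral model, so CLR ≥ 0 by construction). Count likelihoods are
binomial, integrated by 60-node Gauss–Legendre quadrature; per-site
likelihoods are precomputed on a 41-point grid of c and interpolated,
which keeps a 1000-grid-point chromosome scan near one second. ω is a
genome-wide method-of-moments estimate with binomial sampling terms
subtracted. Sites in pairwise dosage correlation > 0.95 within a window
are down-weighted 1/group-size (greedy grouping). Boundary handling and
the quadrature are verified against an independent adaptive-quadrature
oracle to 1e-6.

**ICA.** FastICA (scikit-learn; logcosh, whitened, max 500 iterations,
seeded) applied so that gene loadings are the independent sources and
per-sample coefficients the mixing — the convention for expression
matrices, where independence is assessed across the many genes.
Components are sign-fixed (largest-magnitude loading positive). Kurtosis
is the raw fourth standardized moment (Gaussian = 3), making the
retention cut "kurtosis > 6" a strong non-Gaussianity filter; this
reading is configurable since raw-vs-excess is ambiguous in common usage.
Membership uses median/MAD robust z-scores with BH FDR within component;
the default membership FDR is 0.01 with 0.001 available (two conventions
exist in the field; both are exposed). Per-gene standardization before
ICA is the default (configurable). BLUPs use the closed-form
random-intercept shrinkage `σ²_G/(σ²_G + σ²_E/n_g)`.

**GO tests.** Heritability shift: two-sample KS of term vs remaining
tested genes, BH FDR, and a relative median-shift criterion (≥ 20% of
the background median) — both must hold. The shift criterion is read as
*relative* to the background median. Enrichment: one-sided hypergeometric
with BH FDR. Annotations are taken as given (no GO-graph propagation).

## Pipeline defaults and problem sizes

Stage thresholds default to the study's printed values: MAF ≥ 0.05, het ≤
0.02 (markers) and ≤ 0.20 (samples); expressed = FPKM ≥ 1 in ≥ 80% of
samples; Bonferroni α = 0.05; peak gap 1 Mb, ≥ 3 SNPs, ≤ 10 peaks per
trait; cis window 1 Mb; sQTL |β| ≥ 0.05; coloc r² ≥ 0.6; ICA variance
target 0.80, kurtosis 6, cluster size 10; sweep windows 100 kb / 10 kb
step, top decile, π-ratio QC. The default synthetic study is 200
genotypes × 2 replicates, 5,000 markers on two 10-Mb chromosomes, 2,000
genes, 500 introns, 3 modules and one sweep window per chromosome; tests
and the acceptance script use this scale (recovery experiments: 300
genotypes for eQTL, 20 single-chromosome fixtures for the sweep scan) so
the full suite runs in a few minutes on one CPU.

## Known limitations

- PVE and H² are in-sample quantities; PVE in particular is inflated
  relative to out-of-sample replication.
- The permutation threshold preserves trait correlation but destroys
  genotype LD structure along with the trait–genotype link, as in the
  label-shuffling scheme it implements.
- The XP-CLR implementation pins the model class, not any particular
  historical tool's internals; scores are comparable within a scan (and
  that is how the top-decile rule uses them), not across tools.
- The LD-pruning scan is greedy left-to-right within marker-count
  windows; the window/step for the real data's pruned kinship set is not
  derivable from the study description, so both are exposed parameters.
- `run_pipeline` currently drives the synthetic study design end-to-end;
  analyses of user-supplied files go through the library API (the I/O
  readers accept VCF/TSV/BED directly).
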