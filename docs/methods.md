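# Methods

## The model

A 100-bp genomic tile is treated as a heritable biallelic locus whose
two states are "methylated" and "unmethylated". Methylation is gained
at rate µ and lost at rate ν per tile per generation — both orders of
magnitude faster than point mutation, which is what makes standard
SNP-oriented population genetics inappropriate and an equilibrium
treatment defensible. With a selection coefficient s per methylated
tile and effective population size Ne, the stationary density of the
methylated-epiallele frequency q under mutation–selection–drift
balance is

    φ(q) = C e^{γq} (1 − q)^{α−1} q^{β−1},   q ∈ (0, 1)

with α = 4Neµ, β = 4Neν, γ = 4Nes and C chosen so that φ integrates
to one. Typical fitted values put α and β well below one, so the
density is singular at both endpoints — most tiles sit near fixation
for one epiallele, with a continuum of intermediate frequencies.

The data summary is the methylome site frequency spectrum (mSFS): for
each tile, the number k of methylated epialleles among m sampled
(m = 2n for n outbred individuals, m = n for inbred lines), tabulated
over k = 0..m. Sampling k given q is binomial, so the expected
spectrum is

    p_k = ∫₀¹ C(m,k) q^k (1 − q)^{m−k} φ(q) dq

and an observed spectrum {n_k} contributes the multinomial
log-likelihood Σ_k n_k log p_k (up to a constant). Several cohorts
with different m can share one parameter set; their log-likelihoods
add.

Only the scaled parameters (α, β, γ) enter p_k, so (µ, ν, s) are
identifiable only once Ne is fixed. The inference therefore holds Ne
at a grid of plausible values; the raw rates trade off against Ne
while 4Neµ, 4Neν and Ne·s remain stable, which is exactly the
behaviour `ne_grid_fit` exposes.

An `swap_exponents` flag provides the alternative exponent assignment
(α − 1 on q, β − 1 on 1 − q), which is the conventional notation for
two-allele mutation models where the gain rate scales the exponent of
the gained allele's frequency. The default keeps the assignment given
above; the two differ only by exchanging the roles of α and β, and
both are tested.

## Numerics

Integrals against the singular kernel q^{β−1}(1 − q)^{α−1} use
Gauss–Jacobi quadrature, which absorbs both endpoint singularities
into the weight function exactly; order 128 is the default and agrees
with a doubled-order rule to relative 1e-8 across α, β ∈ [0.01, 5],
|γ| ≤ 20 (degrading to ~4e-8 only in the extreme corners where an
exponent is 0.01 and |γ| = 20 — a double-precision floor of the
node/weight computation itself, not a truncation error).

The expected spectrum also has an exact closed form through Kummer's
confluent hypergeometric function,

    p_k = C(m,k) B(k+β, m−k+α) ₁F₁(k+β; m+α+β; γ)
          / [B(β, α) ₁F₁(β; α+β; γ)],

which the likelihood uses as its default evaluation route (it is
analytically exact and avoids re-deriving quadrature nodes for every
proposed parameter set). ₁F₁ overflows double precision near γ ≈ 700;
beyond |γ| = 600 the evaluation falls back to log-space Gauss–Jacobi
sums, which remain finite and informative at any γ. Log-probabilities
are kept in log space throughout — bins whose p_k underflows to zero
in linear space still contribute their exact log term, so the
likelihood surface keeps its gradient in the strong-selection regime.

## MCMC

`run_mcmc` is a Metropolis–Hastings sampler over (µ, ν, s) at fixed
Ne. Priors are exponential with rates 1e5 (µ, ν; prior mean 1e-5, the
order of magnitude of plant epimutation rates) and 1e2 (s). A signed
mode replaces the prior on s with a symmetric Laplace density and adds
a sign-flip move.

Proposals are multiplicative: θ′ = θ e^{λz} with z standard normal
and λ = 0.05 by default. This walk is asymmetric in θ, and the
acceptance ratio includes the Hastings correction θ′/θ; omitting it
demonstrably collapses a prior-only chain toward zero (a regression
test keeps this honest). One iteration sweeps the three parameters in
turn, each with its own step and accept/reject decision. Component
sweeps rather than a joint proposal are used because the posterior
log-scales of µ and s are an order of magnitude tighter than ν's on
informative spectra; a joint walk at any single λ then accepts almost
nothing, while sweeps hold the acceptance rate in a usable 0.1–0.6
band across λ ∈ {0.01, 0.05, 0.1}.

Defaults: 1,000,000 iterations, first 20% discarded, thinning by 500
— exactly 1600 retained draws. The chain initializes at the prior
means, clamped so the initial scaled parameters satisfy α, β, |γ| ≤ 50:
at Ne = 10⁶ the raw prior mean of s implies γ = 4×10⁴, where the
likelihood is numerically flat and an unclamped chain would only
diffuse for far longer than the burn-in. Summaries report means, SDs
and 2.5–97.5% quantiles for the raw and the Ne-scaled parameters,
with scaled quantiles computed on the per-draw products.

## State calling

Tile methylation levels of a population of outbred individuals are
modelled as a three-component normal mixture (unmethylated ≈ 0,
heterozygous ≈ 0.5, methylated ≈ 1; two components for inbred lines),
fitted by expectation maximization: percentile initialization
(5/50/95), equal starting weights, variance floored at 1e-4, stopped
at log-likelihood gain < 1e-6 or 1000 iterations, plus one seeded
random restart. The discrete calls themselves use fixed thresholds —
level > 0.7 → methylated (2), < 0.3 → unmethylated (0), otherwise
heterozygous (1); inbred cut 0.5 — with strict inequalities, so a
level exactly at a threshold falls to the middle (respectively
unmethylated) class. `derive_thresholds` instead places cuts at the
crossing points of adjacent weighted component densities (grid scan +
Brent refinement), falling back to the fixed values when the fit is
degenerate or a crossing leaves (0, 1). `cutoff_sensitivity`
quantifies the spectral consequence of the choice as total-variation
distances between mSFS built under different cutoff pairs; for
well-separated mixtures these are below 0.01.

## Tiling and filters

Per-cytosine input follows the Bismark cytosine-report layout (both
the methylated/unmethylated and methylated/total count dialects are
accepted). Sites need more than three mapped reads (total ≥ 4) to
survive; CHH records never enter a tile matrix destined for inference
(the overwhelming majority of CHH sites are unmethylated). Tiles are
anchored at multiples of 100 bp on the reference; a tile's level is
the unweighted mean of its sites' levels (a read-pooling weighted
mean is available behind a flag) and requires at least 3 covered
cytosines, else missing. Symmetric CpG pairs are deliberately kept as
separate records — no strand merging is applied.

Pseudo-reference construction substitutes homozygous-alt SNP alleles
into the reference per individual; heterozygous and missing genotypes
keep the reference base, since a single sequence cannot carry IUPAC
ambiguity codes without breaking downstream bisulfite logic.

## mSFS construction

Heterozygous outbred calls contribute one methylated and one
unmethylated allele. Tiles with any missing call are dropped by
default; a hypergeometric projection to a smaller common allele count
is available for sparse data and accumulates expected (fractional)
counts. Multi-cohort fits keep one spectrum per cohort (allele sample
sizes differ) under shared parameters rather than pooling counts.

Frequency categories partition tiles exactly as: 0 →
invariant-unmethylated; (0, 0.1) → rarely methylated; [0.1, 0.9] →
high-frequency variable; (0.9, 1) → rarely unmethylated; 1 →
invariant-methylated. Feature stratification assigns a tile to the
first feature in a precedence list (default exon > intron > up5k >
down5k > TE) covering ≥ 50% of it, else intergenic. Ancestral
polarization takes the majority epiallele of the wild-progenitor
(teosinte) sample; exact ties and all-missing tiles are ambiguous and
excluded from polarized fits.

## Permutation statistics

Sweep calling from scored sliding windows: windows in the upper 10%
tail merge when overlapping or book-ended (merged regions keep the
maximum window score); merged regions reaching the upper 0.5%
quantile of window scores are the selection targets.

The overlap test counts query intervals touching ≥ 1 bp of the
target; the null re-places query intervals uniformly within the
merged mappable universe, preserving lengths, within their own
chromosome by default (genome-wide mode available), with
non-overlap enforced by rejection. The DMR–SNP LD test uses squared
Pearson correlation between per-individual genotypes and methylation
states, with one shared permutation stream per DMR so per-SNP
p-values are comparable; a DMR is "in LD" when ≥ 3 SNPs reach
p < 0.01. All empirical p-values use the add-one rule, so the
smallest attainable p with 999 permutations is 0.001 and p is never
zero. Monomorphic vectors carry no information and return p = 1.
Candidate-set enrichment is an upper-tail hypergeometric probability.

## Synthetic data

The generator emulates the statistical structure the analysis
assumes: tile frequencies drawn from φ by inverse CDF on a
2048-node quadrature grid; Hardy–Weinberg Binomial(2, q) genotypes
(Bernoulli for inbreds); tile levels from beta distributions around
the class centers — Beta(1, κ₀) near 0, Beta(κ_h/2, κ_h/2) at 0.5,
Beta(κ₁, 1) near 1, defaults κ₀ = κ₁ = 50, κ_h = 100 (heterozygous
sd ≈ 0.05) — chosen beta rather than normal to respect the [0, 1]
support, with a clipped-normal option for strict parity with the
caller's mixture assumption; negative-binomial site coverage (mean
20, dispersion 5, emulating ~20× whole-genome bisulfite data);
SNPs that copy the methylation call with probability √r² per
individual; and DMR/sweep interval sets with a controlled expected
overlap fraction inside a mappable universe. Every generator is a
pure function of its configuration and seed.

What the generator does **not** emulate: linkage between tiles,
context-dependent epimutation heterogeneity along the genome,
non-equilibrium demography, bisulfite conversion failure, and mapping
bias. Passing recovery tests therefore demonstrates correctness of
the estimator under the model's own assumptions, not robustness to
their violation in real data.

## Validation design and problem sizes

Parameter recovery uses spectra of 50,000 tiles at m = 40 sampled
from the stationary model at the published posterior-mean parameters
(CG: µ = 3.6e-6, ν = 1.8e-7, Ne·s = 2.0 at Ne = 50,000; CHG:
µ = 7.6e-6, ν = 3.0e-7, Ne·s = 2.2), fitted with 200,000-iteration
chains (20% burn-in, thinning 100 → 1600 draws); posterior means land
within a few percent of truth, comfortably inside the 25% acceptance
band. The Ne-grid experiment refits the same spectrum at Ne = 50,000
and 1,000,000 with 100,000-iteration chains: Ne·s agrees across the
grid while s scales as 1/Ne. Permutation calibration uses 500 null
simulations with 40 query intervals (few-interval counting statistics
are conservative purely through discreteness) and 99–199 permutations.
The end-to-end check runs the whole chain —
frequencies → genotypes → noisy levels → per-cytosine reports →
coverage filter → tile aggregation → calls → mSFS — at 2000 tiles ×
10 individuals × 5 sites/tile across 10 seeds and accepts the
analytic expected spectrum by chi-square goodness of fit (small-
expectation bins pooled to ≥ 5).

## Known limitations

- The equilibrium assumption ignores maize's recent demographic
  upheaval; fitted rates are effective, equilibrium-scaled values.
- Selection enters as e^{γq} with no dominance term.
- The multinomial SFS likelihood treats tiles as independent;
  linkage between nearby tiles would shrink the effective sample
  size and make credible intervals anti-conservative.
- EM components are plain (untruncated) normals, so a component mean
  near 0 or 1 can place density outside [0, 1]; threshold derivation
  is unaffected in practice because crossings lie in the interior.
- The permutation null for interval overlap assumes the mappable
  universe is exchangeable for query placement; clustered genomic
  features violate this and would require a more structured null.
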