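# epimsfs

Population epigenetics of hypermutable DNA-methylation loci: from
per-cytosine bisulfite calls to 100-bp-tile methylation states,
methylome site frequency spectra (mSFS), Bayesian inference of
epimutation rates and selection coefficients, and permutation
statistics for the association of differentially methylated regions
(DMRs) with selective sweeps and local SNPs.

## The problem

Cytosine methylation at a locus is gained and lost orders of
magnitude faster than point mutations arise, so SNP-oriented
population-genetic machinery does not transfer to methylome data.
For a hypermutable biallelic locus — here a 100-bp tile whose two
states are methylated and unmethylated — with gain rate µ, loss rate
ν, selection coefficient s and effective population size Ne, the
stationary density of the methylated-epiallele frequency q is

    φ(q) = C e^{γq} (1 − q)^{α−1} q^{β−1},
    α = 4Neµ,  β = 4Neν,  γ = 4Nes,

with C normalizing φ on (0, 1). Sampling m epialleles per tile (2 per
outbred individual, 1 per inbred line) gives the expected spectrum
p_k = ∫ C(m,k) q^k (1−q)^{m−k} φ(q) dq, and an observed mSFS {n_k}
is fitted by its multinomial likelihood with a Metropolis–Hastings
sampler over (µ, ν, s) at fixed Ne. Only (α, β, γ) are identifiable,
so fits are run across a grid of Ne values: the raw rates trade off
against Ne while 4Neµ, 4Neν and Ne·s stay put.

The package is aimed at plant population epigenomics — the defaults
mirror a maize/teosinte study design (outbred wild and landrace
populations, inbred modern lines, CG and CHG contexts, ~20× WGBS) —
but every stage is generic.

## What's in the box

| module | contents |
| --- | --- |
| `epimsfs.io` | Bismark-style cytosine reports, coverage filter, 100-bp tile aggregation, pseudo-reference substitution, BED/FASTA/TSV round trips |
| `epimsfs.calling` | EM normal-mixture fit, threshold derivation, discrete epigenotype calls (0/1/2 outbred, 0/1 inbred), cutoff sensitivity |
| `epimsfs.sfs` | mSFS construction (drop or hypergeometric projection), frequency categories, feature stratification, ancestral polarization |
| `epimsfs.model` | stationary density, Gauss–Jacobi normalization, expected SFS (exact ₁F₁ closed form), multinomial likelihood |
| `epimsfs.mcmc` | Metropolis–Hastings sampler, exponential priors, multiplicative proposals with Hastings correction, Ne-grid fits |
| `epimsfs.simulate` | synthetic frequencies, genotypes, tile levels, cytosine reports, LD-tuned SNPs, interval sets |
| `epimsfs.enrichment` | sweep-window outlier merging, overlap permutation test, DMR–SNP LD test, hypergeometric enrichment |

A thin CLI (`epimsfs tiles|call|msfs|fit|simulate|enrich|ld`) wraps
the library for shell pipelines.

## Worked example

Simulate a CG spectrum from the stationary model and re-estimate the
parameters:

```python
import numpy as np
import epimsfs as em

params = em.ModelParams(mu=3.6e-6, nu=1.8e-7, s=4.0e-5, ne=50_000)
q = em.simulate_tile_frequencies(params, 20_000, seed=1)
k = np.random.default_rng(2).binomial(40, q)
spectrum = em.MSFS(40, np.bincount(k, minlength=41), context="CG")

cfg = em.McmcConfig(n_iter=50_000, burnin_frac=0.2, thin=25, lam=0.05,
                    seed=3, ne=50_000)
post = em.run_mcmc(spectrum, em.PriorSpec(), cfg)
print(f"retained draws : {post.n_retained}")
print(f"acceptance rate: {post.acceptance_rate:.2f}")
for name in ("mu", "nu", "s", "Ne_s"):
    lo, hi = post.ci95[name]
    print(f"{name:>5}: mean {post.means[name]:.3e}  sd {post.sds[name]:.1e}"
          f"  95% CI [{lo:.3e}, {hi:.3e}]")
```

Output:

```
retained draws : 1600
acceptance rate: 0.31
   mu: mean 3.562e-06  sd 4.2e-08  95% CI [3.475e-06, 3.641e-06]
   nu: mean 2.036e-07  sd 1.4e-08  95% CI [1.784e-07, 2.320e-07]
    s: mean 3.922e-05  sd 4.7e-07  95% CI [3.827e-05, 4.009e-05]
 Ne_s: mean 1.961e+00  sd 2.3e-02  95% CI [1.914e+00, 2.005e+00]
```

The chain recovers the generating gain rate (3.6e-6), loss rate
(1.8e-7) and scaled selection coefficient Ne·s = 2 within a few
percent from 20,000 tiles; the credible intervals are tight because
the tiles are treated as independent. `em.ne_grid_fit` repeats the
fit across Ne ∈ {50k, 100k, 500k, 1M} to show which combinations are
actually identified.

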